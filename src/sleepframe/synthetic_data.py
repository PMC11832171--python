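"""Seeded generators of Δ-pixel experiments and compound-fingerprint libraries.

Every downstream module is testable without external data through two
generators:

* an alternating renewal-process simulator of larval swimming — active bouts
  (exponential durations, ~0.2 s mean) alternate with quiescent gaps drawn
  from a two-component exponential mixture whose heavy tail crosses the 60-s
  sleep threshold, so sleep bouts emerge naturally; day/night phases modulate
  bout amplitude and the long-gap weight, and a startle spike is inserted at
  each lights-off transition;
* a compound-fingerprint library generator producing 12-entry fingerprints
  with sparse many-to-many annotations, optionally planting an enrichment
  effect for one annotation relative to a query fingerprint.

Both generators fan one global seed out to per-larva/per-compound streams by
hashing stable identifiers, so output is independent of well ordering.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tracking_io import (
    LIGHTS_OFF,
    LIGHTS_ON,
    DeltaPixelTimeseries,
    GroupMap,
    LightSchedule,
)
from .bout_detection import sleep_window_frames

logger = logging.getLogger(__name__)


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Per-entity RNG derived by hashing (seed, keys); order-independent."""
    entropy = [int(seed)] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Larva trace simulation
# ---------------------------------------------------------------------------


@dataclass
class LarvaSimConfig:
    """Parameters of the renewal-process swimming simulator.

    Durations are in seconds, amplitudes in Δ-pixel counts.  The defaults
    give a realistic diurnal larva: near-continuous short swim bouts during
    the day with little sleep, and long quiescent gaps at night producing a
    few hours of sleep.
    """

    fps: float = 25.0
    active_bout_mean_s: float = 0.2
    gap_short_mean_s: float = 0.8
    gap_long_mean_s: float = 150.0
    gap_long_weight_day: float = 0.002
    gap_long_weight_night: float = 0.02
    amplitude_mean: float = 8.0
    night_activity_multiplier: float = 0.7
    bout_rate_multiplier: float = 1.0  # divides gap means; 0 disables bouts
    night_bout_rate_multiplier: float = 1.0  # 0 ⇒ fully quiescent nights
    startle_amplitude: float = 80.0
    startle_duration_s: float = 0.3
    darkness: float = 1.0  # pigmentation factor scaling all amplitudes
    seed: int = 0

    def __post_init__(self) -> None:
        for w in (self.gap_long_weight_day, self.gap_long_weight_night):
            if not 0 <= w <= 1:
                raise ValueError("gap mixture weights must lie in [0, 1]")
        if self.active_bout_mean_s <= 0 or self.gap_short_mean_s <= 0:
            raise ValueError("durations must be positive")


@dataclass
class SimGroundTruth:
    """Per-larva, per-window truths recorded by the generator.

    ``per_window`` rows: well, window (window name), total_sleep_hr,
    sleep_bout_count, active_bout_count, total_activity.  Truths are computed
    from the discretised bout layout the generator emitted, so they are
    consistent with the trace by construction.
    """

    per_window: pd.DataFrame

    def value(self, well: str, window: str, column: str) -> float:
        df = self.per_window
        row = df[(df["well"] == well) & (df["window"] == window)]
        return float(row[column].iloc[0])


def _simulate_bout_layout(
    cfg: LarvaSimConfig, schedule: LightSchedule, n_frames: int, rng: np.random.Generator
) -> list[tuple[int, int, np.ndarray]]:
    """Alternating renewal process in frames: list of (start, end, amplitudes)."""
    fps = cfg.fps
    bouts: list[tuple[int, int, np.ndarray]] = []
    if cfg.bout_rate_multiplier <= 0:
        return bouts
    transitions = schedule.transition_times(n_frames / fps, include_start=True)
    # lights-off startles begin the night, so fully quiescent nights have none
    pending = (
        [int(round(t * fps)) for t, k in transitions if k == LIGHTS_OFF]
        if cfg.night_bout_rate_multiplier > 0
        else []
    )
    lights_on_frames = [int(round(t * fps)) for t, k in transitions if k == LIGHTS_ON]
    t = 0
    rate = cfg.bout_rate_multiplier
    while t < n_frames:
        while pending and pending[0] < t:
            pending.pop(0)
        is_day = schedule.is_day_at(t / fps)
        eff_rate = rate if is_day else rate * cfg.night_bout_rate_multiplier
        if eff_rate <= 0:
            # fully quiescent phase: jump to the next lights-on, dropping any
            # startle that would have fallen inside the silent stretch
            nxt = next((f for f in lights_on_frames if f > t), n_frames)
            while pending and pending[0] < nxt:
                pending.pop(0)
            t = nxt
            continue
        w_long = cfg.gap_long_weight_day if is_day else cfg.gap_long_weight_night
        mean = (
            cfg.gap_long_mean_s if rng.random() < w_long else cfg.gap_short_mean_s
        ) / eff_rate
        gap_frames = max(1, int(round(rng.exponential(mean) * fps)))
        # force a startle bout at lights-off when the gap would cross it
        if pending and t + gap_frames > pending[0] >= t:
            start = pending.pop(0)
            dur = max(1, int(round(cfg.startle_duration_s * fps)))
            end = min(start + dur, n_frames)
            amp = np.maximum(
                1,
                np.round(
                    rng.normal(cfg.startle_amplitude, cfg.startle_amplitude / 10, end - start)
                    * cfg.darkness
                ),
            ).astype(np.int64)
            if end > start:
                bouts.append((start, end, amp))
            t = end
            continue
        t += gap_frames
        if t >= n_frames:
            break
        is_day = schedule.is_day_at(t / fps)
        if (rate if is_day else rate * cfg.night_bout_rate_multiplier) <= 0:
            continue  # gap ran into a quiescent phase; no bout here
        amp_mean = cfg.amplitude_mean * (1.0 if is_day else cfg.night_activity_multiplier)
        dur = max(1, int(round(rng.exponential(cfg.active_bout_mean_s) * fps)))
        end = min(t + dur, n_frames)
        amp_mean = max(amp_mean * cfg.darkness, 1.0)
        amp = rng.geometric(min(1.0, 1.0 / amp_mean), end - t).astype(np.int64)
        bouts.append((t, end, amp))
        t = end
    return bouts


def _truth_from_layout(
    bouts: list[tuple[int, int, np.ndarray]],
    n_frames: int,
    fps: float,
    windows: list[tuple[str, int, int]],
) -> pd.DataFrame:
    """Ground truth per window from the discrete bout layout.

    Sleep bouts are the inter-bout gaps of at least round(60·fps) frames
    (including leading/trailing gaps); per-window sleep time counts sleep
    frames inside the window, while bout counts attribute a bout to the
    window containing its start frame.
    """
    w = sleep_window_frames(fps)
    edges = []
    prev_end = 0
    for s, e, _ in bouts:
        if s > prev_end:
            edges.append((prev_end, s))
        prev_end = e
    if n_frames > prev_end:
        edges.append((prev_end, n_frames))
    sleep_bouts = [(s, e) for s, e in edges if e - s >= w]
    sleep_mask_edges = np.zeros(n_frames + 1, dtype=np.int64)
    for s, e in sleep_bouts:
        sleep_mask_edges[s] += 1
        sleep_mask_edges[e] -= 1
    sleep_mask = np.cumsum(sleep_mask_edges[:-1]) > 0
    rows = []
    for name, ws, we in windows:
        total_sleep_frames = int(sleep_mask[ws:we].sum())
        rows.append(
            {
                "window": name,
                "total_sleep_hr": total_sleep_frames / fps / 3600.0,
                "sleep_bout_count": sum(ws <= s < we for s, _ in sleep_bouts),
                "active_bout_count": sum(ws <= s < we for s, _, _ in bouts),
                "total_activity": float(
                    sum(a[max(ws - s, 0) : max(we - s, 0)].sum() for s, _, a in bouts)
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_larva_trace(
    cfg: LarvaSimConfig,
    schedule: LightSchedule,
    duration_s: float,
    windows: list[tuple[str, int, int]] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One larva's Δ-pixel trace plus its per-window ground truth.

    ``windows`` is an optional list of (name, start_frame, end_frame); when
    omitted the whole trace is a single window named "all".  The same config
    (including seed) always yields a bit-identical trace.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n_frames = int(round(duration_s * cfg.fps))
    rng = _stream(cfg.seed, "larva")
    layout = _simulate_bout_layout(cfg, schedule, n_frames, rng)
    trace = np.zeros(n_frames, dtype=np.int64)
    for s, e, amp in layout:
        trace[s:e] = amp
    if windows is None:
        windows = [("all", 0, n_frames)]
    truth = _truth_from_layout(layout, n_frames, cfg.fps, windows)
    truth.insert(0, "well", "w1")
    return trace, truth


def simulate_experiment(
    n_per_group: dict[str, int],
    group_effects: dict[str, dict[str, float]],
    cfg: LarvaSimConfig,
    schedule: LightSchedule,
    duration_s: float,
    seed: int | None = None,
    experiment: str = "clutch1",
    windows: list[tuple[str, int, int]] | None = None,
) -> tuple[DeltaPixelTimeseries, GroupMap, SimGroundTruth]:
    """A multi-well experiment with per-group planted effects.

    Wells are interleaved across groups (mimicking the alternating-column
    plating of knockout and control larvae).  Effect keys per group:
    ``day_activity`` / ``night_activity`` multiply the Δ-pixel amplitude mean
    in that phase, ``day_sleep`` / ``night_sleep`` multiply the long-gap
    mixture weight, ``bout_rate`` divides the gap means, ``darkness``
    multiplies all amplitudes (pigmentation).  Effects compose
    multiplicatively with the base config.
    """
    known = {"day_activity", "night_activity", "day_sleep", "night_sleep",
             "bout_rate", "darkness"}
    for grp, effects in group_effects.items():
        unknown = set(effects) - known
        if unknown:
            raise KeyError(f"unknown effect key(s) {sorted(unknown)} for group {grp!r}")
    if seed is None:
        seed = cfg.seed
    groups = list(n_per_group)
    order: list[tuple[str, str]] = []  # (well, group), interleaved
    counts = dict.fromkeys(groups, 0)
    total = sum(n_per_group.values())
    gi = 0
    while len(order) < total:
        grp = groups[gi % len(groups)]
        if counts[grp] < n_per_group[grp]:
            counts[grp] += 1
            order.append((f"{experiment}-w{len(order) + 1:02d}", grp))
        gi += 1
    n_frames = int(round(duration_s * cfg.fps))
    if windows is None:
        windows = [("all", 0, n_frames)]
    traces, truths = {}, []
    for well, grp in order:
        effects = group_effects.get(grp, {})
        wcfg = replace(
            cfg,
            amplitude_mean=cfg.amplitude_mean,  # phase multipliers handled below
            gap_long_weight_day=min(1.0, cfg.gap_long_weight_day * effects.get("day_sleep", 1.0)),
            gap_long_weight_night=min(1.0, cfg.gap_long_weight_night * effects.get("night_sleep", 1.0)),
            bout_rate_multiplier=cfg.bout_rate_multiplier * effects.get("bout_rate", 1.0),
            darkness=cfg.darkness * effects.get("darkness", 1.0),
        )
        # phase-specific amplitude effects: fold the day effect into the base
        # amplitude and the night effect into the night multiplier
        day_mult = effects.get("day_activity", 1.0)
        night_mult = effects.get("night_activity", 1.0)
        wcfg = replace(
            wcfg,
            amplitude_mean=cfg.amplitude_mean * day_mult,
            night_activity_multiplier=cfg.night_activity_multiplier
            * night_mult
            / max(day_mult, 1e-12),
        )
        rng = _stream(seed, experiment, well)
        layout = _simulate_bout_layout(wcfg, schedule, n_frames, rng)
        trace = np.zeros(n_frames, dtype=np.int64)
        for s, e, amp in layout:
            trace[s:e] = amp
        traces[well] = trace
        truth = _truth_from_layout(layout, n_frames, cfg.fps, windows)
        truth.insert(0, "well", well)
        truths.append(truth)
    ts = DeltaPixelTimeseries(pd.DataFrame(traces), fps=cfg.fps)
    gm = GroupMap(
        group_of={w: g for w, g in order},
        experiment_of={w: experiment for w, _ in order},
        control_group=groups[0],
    )
    logger.info(
        "simulated experiment %s: %d wells × %d frames, groups %s",
        experiment, total, n_frames, dict(n_per_group),
    )
    return ts, gm, SimGroundTruth(pd.concat(truths, ignore_index=True))


# ---------------------------------------------------------------------------
# Compound-library simulation
# ---------------------------------------------------------------------------


@dataclass
class LibrarySimConfig:
    """Shape of a synthetic annotated fingerprint library."""

    n_compounds: int = 100
    replicates: int = 1
    fingerprint_length: int = 12
    n_indications: int = 8
    n_targets: int = 10
    n_pathways: int = 6
    annotation_rate: float = 0.5  # fraction of compounds with ≥1 annotation/class
    planted_class: str | None = None  # "indication" | "target" | "pathway"
    planted_annotation: str | None = None
    planted_members: int = 10
    effect: float = 0.0  # alignment strength of planted members with query
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect size must be nonnegative")


def _catalogue(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(n)]


def simulate_compound_library(cfg: LibrarySimConfig, query: np.ndarray):
    """Synthetic annotated fingerprint library (see :class:`~.enrichment.CompoundLibrary`).

    Null compounds draw fingerprints from an isotropic Gaussian (random
    direction ⇒ cosines vs any query are symmetric about 0).  Planted-member
    compounds draw ``±effect·q̂ + noise``, elevating |cosine| against the
    query; with a very large effect their fingerprints are exactly ±query.
    """
    from .enrichment import CompoundLibrary  # local import to avoid a cycle

    query = np.asarray(query, dtype=np.float64)
    if query.size != cfg.fingerprint_length:
        raise ValueError("query length must match cfg.fingerprint_length")
    qhat = query / np.linalg.norm(query)
    catalogues = {
        "indication": _catalogue("IND", cfg.n_indications),
        "target": _catalogue("TGT", cfg.n_targets),
        "pathway": _catalogue("PWY", cfg.n_pathways),
    }
    if cfg.planted_class is not None:
        if cfg.planted_annotation not in catalogues.get(cfg.planted_class, []):
            raise ValueError(
                f"planted annotation {cfg.planted_annotation!r} absent from "
                f"{cfg.planted_class!r} catalogue"
            )
    compounds = [f"CID{i + 1:05d}" for i in range(cfg.n_compounds)]
    rng_global = _stream(cfg.seed, "library")
    planted_members: set[str] = set()
    if cfg.planted_class is not None and cfg.effect > 0:
        planted_members = set(
            rng_global.choice(compounds, size=min(cfg.planted_members, len(compounds)),
                              replace=False)
        )
    fp_rows = []
    for cid in compounds:
        rng = _stream(cfg.seed, "fp", cid)
        for rep in range(cfg.replicates):
            noise = rng.standard_normal(cfg.fingerprint_length)
            if cid in planted_members:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                vec = sign * cfg.effect * qhat + (0.0 if np.isinf(cfg.effect) else noise)
                if np.isinf(cfg.effect):
                    vec = sign * query
            else:
                vec = noise
            fp_rows.append([f"{cid}-r{rep + 1}", cid, *vec])
    fingerprints = pd.DataFrame(
        fp_rows,
        columns=["fingerprint_id", "compound_id"]
        + [f"p{i + 1}" for i in range(cfg.fingerprint_length)],
    )
    ann_frames = {}
    for cls, cat in catalogues.items():
        # the planted annotation's membership is exactly the planted set, so
        # random draws for null compounds avoid it
        cat_null = [
            a for a in cat
            if not (cls == cfg.planted_class and planted_members
                    and a == cfg.planted_annotation)
        ]
        rows = []
        rng = _stream(cfg.seed, "ann", cls)
        for cid in compounds:
            if cls == cfg.planted_class and cid in planted_members:
                rows.append({"compound_id": cid, "annotation_id": cfg.planted_annotation})
                continue
            if rng.random() < cfg.annotation_rate:
                k = 1 + rng.poisson(0.5)
                chosen = rng.choice(cat_null, size=min(k, len(cat_null)), replace=False)
                rows.extend({"compound_id": cid, "annotation_id": a} for a in chosen)
        ann_frames[cls] = pd.DataFrame(rows, columns=["compound_id", "annotation_id"])
    shortlisted = pd.Series(
        _stream(cfg.seed, "shortlist").random(len(fingerprints)) < 0.1,
        index=fingerprints.index,
        name="shortlisted",
    )
    return CompoundLibrary(
        fingerprints=fingerprints, annotations=ann_frames, shortlisted=shortlisted
    )
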