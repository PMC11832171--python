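"""Behavioural fingerprints: z-scores, distances, cosine similarity, legacy format.

A larva's behavioural fingerprint is the vector of z-scores of its parameter
values against same-clutch controls, one entry per unique (parameter,
day/night) key: z = (x − μ_con) / σ_con computed per window, then day1/day2
(and night1/night2) averaged into a single day and night value per
parameter.  The native fingerprint has 32 entries (15 day + 17 night).

The legacy 12-entry fingerprint reproduces the one-minute format of the
historical compound screen: six parameters — average activity (sec
active/min), average waking activity, total sleep (hr), sleep bout count,
sleep bout length (min), sleep latency (min) — for day then night, computed
from the per-minute middur series (a sleep minute is a minute with zero
middur) and z-scored the same way.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .tracking_io import DeltaPixelTimeseries, GroupMap
from .behaviour_parameters import NIGHT_ONLY, PARAMETER_NAMES, WindowSet
from .bout_detection import compute_middur

logger = logging.getLogger(__name__)

#: native key order: all day keys in roster order, then all night keys
FINGERPRINT_KEYS: list[tuple[str, str]] = [
    (p, "day") for p in PARAMETER_NAMES if p not in NIGHT_ONLY
] + [(p, "night") for p in PARAMETER_NAMES]

assert len(FINGERPRINT_KEYS) == 32

LEGACY_PARAMETERS = [
    "average_activity",
    "average_waking_activity",
    "total_sleep",
    "sleep_bout_count",
    "sleep_bout_length",
    "sleep_latency",
]

#: legacy key order: the six parameters for the day block then the night block
LEGACY_KEYS: list[tuple[str, str]] = [
    (p, phase) for phase in ("day", "night") for p in LEGACY_PARAMETERS
]


def _key_label(key: tuple[str, str]) -> str:
    return f"{key[0]}|{key[1]}"


# ---------------------------------------------------------------------------
# Z-scoring
# ---------------------------------------------------------------------------


def _zscore_values(values: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Z-score a (experiment, well, group, phase, window, parameter, value)
    long table against same-clutch controls, then average windows per phase."""
    out = []
    for (exp, phase, parameter), sub in values.groupby(
        ["experiment", "phase", "parameter"], sort=False
    ):
        for window, wsub in sub.groupby("window", sort=False):
            con = wsub.loc[wsub["group"] == control_group, "value"].to_numpy()
            con = con[np.isfinite(con)]
            if con.size < 2:
                raise ValueError(
                    f"control group {control_group!r} needs ≥2 finite values for "
                    f"{parameter} {window} in {exp}"
                )
            mu, sigma = float(np.mean(con)), float(np.std(con, ddof=1))
            if sigma == 0:
                warnings.warn(
                    f"zero control s.d. for {parameter} {window} in {exp}; "
                    "entry marked missing",
                    stacklevel=2,
                )
                z = np.full(len(wsub), np.nan)
            else:
                z = (wsub["value"].to_numpy() - mu) / sigma
            out.append(wsub.assign(z=z))
    zlong = pd.concat(out, ignore_index=True)
    # average day1/day2 (night1/night2) into one z per (larva, parameter, phase)
    merged = (
        zlong.groupby(["experiment", "well", "group", "phase", "parameter"],
                      sort=False, dropna=False)["z"]
        .mean()
        .reset_index()
    )
    return merged


def zscore_parameters(
    params: pd.DataFrame, control_group: str
) -> pd.DataFrame:
    """Per-larva native fingerprints from a parameter table.

    Returns a DataFrame indexed by (experiment, well, group) with one column
    per fingerprint key (ordered per :data:`FINGERPRINT_KEYS`); missing
    entries (zero control s.d., sleepless-night latency) are NaN.
    """
    values = params.rename(columns={"is_day": "phase"}).copy()
    values["phase"] = np.where(values["phase"], "day", "night")
    merged = _zscore_values(values, control_group)
    wide = merged.pivot_table(
        index=["experiment", "well", "group"],
        columns=["parameter", "phase"],
        values="z",
        dropna=False,
    )
    present = {
        (r.parameter, r.phase)
        for r in merged[["parameter", "phase"]].drop_duplicates().itertuples()
    }
    return _order_keys(wide, FINGERPRINT_KEYS, present)


def _order_keys(
    wide: pd.DataFrame,
    canonical: list[tuple[str, str]],
    present: set[tuple[str, str]],
) -> pd.DataFrame:
    """Keep only keys present in the data (the pivot fabricates the full
    parameter × phase product, e.g. a day sleep-latency column) and order
    them canonically; non-roster keys keep their position after the roster
    block."""
    cols = [c for c in wide.columns if tuple(c) in present]
    known = [k for k in canonical if k in cols]
    others = [c for c in cols if c not in set(known)]
    return wide.reindex(columns=pd.MultiIndex.from_tuples(known + others))


def group_fingerprint(fingerprints: pd.DataFrame, group: str) -> pd.DataFrame:
    """Group mean fingerprint: per-clutch mean ± SEM, then averaged across clutches.

    Returns a DataFrame with rows ``mean`` and ``sem`` and one column per key.
    """
    sub = fingerprints.loc[
        fingerprints.index.get_level_values("group") == group
    ]
    if sub.empty:
        raise ValueError(f"no larvae in group {group!r}")
    per_clutch_mean = sub.groupby(level="experiment").mean()
    per_clutch_sem = sub.groupby(level="experiment").sem()
    return pd.DataFrame(
        {"mean": per_clutch_mean.mean(axis=0), "sem": per_clutch_sem.mean(axis=0)}
    ).T


# ---------------------------------------------------------------------------
# Distances and similarity
# ---------------------------------------------------------------------------


def euclidean_distance(fp: np.ndarray | pd.Series) -> float:
    """Distance of a fingerprint from the origin, over non-missing keys.

    The control-group centre is the origin by z-construction, so this is a
    larva's overall behavioural displacement from controls.
    """
    z = np.asarray(fp, dtype=np.float64)
    finite = np.isfinite(z)
    if not finite.any():
        raise ValueError("all-missing fingerprint")
    return float(np.sqrt(np.sum(z[finite] ** 2)))


def cosine_similarity(a: np.ndarray | pd.Series, b: np.ndarray | pd.Series) -> float:
    """Cosine similarity over the shared non-missing keys of two fingerprints."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("fingerprints must share the same key schema")
    shared = np.isfinite(a) & np.isfinite(b)
    if shared.sum() < 2:
        raise ValueError("need at least 2 shared non-missing keys")
    av, bv = a[shared], b[shared]
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm fingerprint")
    return float(np.dot(av, bv) / (na * nb))


# ---------------------------------------------------------------------------
# Legacy one-minute fingerprint
# ---------------------------------------------------------------------------


def _legacy_window_values(middur_min: np.ndarray) -> dict[str, float]:
    """The six legacy parameters from one window's per-minute middur values.

    Unlike the native roster, the legacy format defines sleep latency for
    days too: minutes from window start to the first zero-middur minute.
    """
    m = np.asarray(middur_min, dtype=np.float64)
    asleep = m == 0
    vals: dict[str, float] = {}
    vals["average_activity"] = float(m.mean()) if m.size else float("nan")
    waking = m[~asleep]
    vals["average_waking_activity"] = float(waking.mean()) if waking.size else float("nan")
    vals["total_sleep"] = float(asleep.sum()) / 60.0  # hours
    padded = np.diff(np.concatenate(([0], asleep.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    vals["sleep_bout_count"] = float(starts.size)
    vals["sleep_bout_length"] = (
        float(np.mean(ends - starts)) if starts.size else float("nan")
    )
    vals["sleep_latency"] = float(starts[0]) if starts.size else float("nan")
    return vals


def legacy_parameter_table(
    ts: DeltaPixelTimeseries,
    windows: WindowSet,
    groups: GroupMap,
    freeze: float = 0,
    burst: float = 200,
) -> pd.DataFrame:
    """Per-larva per-window legacy (one-minute) parameter values."""
    fps = ts.fps
    rows = []
    for well in ts.well_ids:
        if well in groups.excluded:
            continue
        trace = ts.trace(well)
        for win in windows.analysis:
            seg = trace[win.start_frame : win.end_frame]
            mid = compute_middur(seg, fps, freeze=freeze, burst=burst)
            vals = _legacy_window_values(mid.seconds_active)
            phase = "day" if win.is_day else "night"
            for name, val in vals.items():
                rows.append(
                    {
                        "experiment": groups.experiment_of.get(well, "exp1"),
                        "well": well,
                        "group": groups.group_of[well],
                        "window": win.name,
                        "phase": phase,
                        "parameter": name,
                        "value": val,
                    }
                )
    return pd.DataFrame(rows)


def to_legacy_fingerprint(
    ts: DeltaPixelTimeseries,
    windows: WindowSet,
    groups: GroupMap,
    control_group: str,
    freeze: float = 0,
    burst: float = 200,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-larva legacy fingerprints and the group-collapsed query vector.

    Returns ``(per_larva, query)`` where ``per_larva`` has one column per
    legacy key and ``query`` is the mean across clutches of per-clutch mean
    z-scores for the non-control group(s) — the vector sent to the
    compound-library ranking.
    """
    table = legacy_parameter_table(ts, windows, groups, freeze=freeze, burst=burst)
    merged = _zscore_values(table, control_group)
    wide = merged.pivot_table(
        index=["experiment", "well", "group"],
        columns=["parameter", "phase"],
        values="z",
        dropna=False,
    )
    present = {
        (r.parameter, r.phase)
        for r in merged[["parameter", "phase"]].drop_duplicates().itertuples()
    }
    wide = _order_keys(wide, LEGACY_KEYS, present)
    non_control = [g for g in wide.index.get_level_values("group").unique()
                   if g != control_group]
    if len(non_control) != 1:
        logger.warning("expected one treatment group, found %s", non_control)
    grp = non_control[0]
    query = group_fingerprint(wide, grp).loc["mean"]
    return wide, query
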