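"""Frame-resolution sleep and active-bout scoring.

Sleep in larval zebrafish is behaviourally defined as any period of complete
inactivity (Δ pixel = 0) lasting at least one minute.  The scorer follows the
rolling-sum construction: a trailing 60-s rolling sum of the Δ-pixel trace is
computed, every frame where that sum is zero certifies that the preceding
60 s were all zeros (a sleep bout started exactly 60 s earlier), and each
flagged run is then back-extended 60 s to recover the true bout start.  The
result is identical to scanning for maximal zero runs of at least
round(60·fps) frames, and the test suite holds the implementation to that
oracle.

An active bout is a maximal run of consecutive frames with Δ pixel > 0,
approximating a single swimming bout (~0.2 s on average).

Also here: trace binning/smoothing for activity and sleep traces, the legacy
one-minute "middur" summary (seconds per minute spent between the freeze and
burst thresholds), and the pigmentation adjustment that rescales one group's
Δ-pixel values by the ratio of mean startle-response maxima.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking_io import DeltaPixelTimeseries, GroupMap

logger = logging.getLogger(__name__)

SLEEP_WINDOW_S = 60.0
DEFAULT_EPOCH_MIN = 10.0
DEFAULT_SMOOTH_MIN = 60.0
DEFAULT_FREEZE = 3
DEFAULT_BURST = 200

SLEEP = "sleep"
ACTIVE = "active"

BOUT_COLUMNS = ["start_frame", "end_frame", "duration_s"]


def sleep_window_frames(fps: float) -> int:
    """Number of frames in the one-minute sleep window (round(60·fps))."""
    return int(round(SLEEP_WINDOW_S * fps))


def _runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Starts and (half-open) ends of maximal True runs of a boolean array."""
    if mask.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return starts, ends


def _bout_frame(starts, ends, fps) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_frame": starts.astype(np.int64),
            "end_frame": ends.astype(np.int64),
            "duration_s": (ends - starts) / fps,
        }
    )


def sleep_flags(trace: np.ndarray, fps: float) -> np.ndarray:
    """Per-frame boolean sleep flags via rolling sum + 60-s back-extension."""
    trace = np.asarray(trace)
    n = trace.size
    w = sleep_window_frames(fps)
    if n < w:
        warnings.warn(
            f"trace of {n} frames is shorter than the {w}-frame sleep window; "
            "no sleep can be scored",
            stacklevel=2,
        )
        return np.zeros(n, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(trace, dtype=np.int64)))
    rolling = csum[w:] - csum[:-w]  # trailing sum ending at frame w-1 .. n-1
    flags = np.zeros(n, dtype=bool)
    flags[w - 1 :] = rolling == 0
    # back-extension: the first flagged frame of each run marks second 60 of
    # the bout, so the preceding w-1 frames also belong to it
    starts, _ = _runs(flags)
    for s in starts:
        flags[max(0, s - (w - 1)) : s] = True
    # a leading zero-run of >= w frames is fully flagged by the above; a
    # truncated bout at the start shorter than 60 s observed remains unflagged
    return flags


def detect_sleep_bouts(trace: np.ndarray, fps: float) -> pd.DataFrame:
    """Sleep bouts (maximal inactivity runs ≥ 60 s) for one trace.

    Returns a DataFrame with columns start_frame, end_frame (half-open),
    duration_s.  Bouts truncated by the experiment edges are kept when their
    observed portion is at least 60 s.
    """
    flags = sleep_flags(trace, fps)
    starts, ends = _runs(flags)
    return _bout_frame(starts, ends, fps)


def detect_active_bouts(trace: np.ndarray, fps: float) -> pd.DataFrame:
    """Active bouts (maximal runs of Δ pixel > 0) for one trace."""
    trace = np.asarray(trace)
    starts, ends = _runs(trace > 0)
    return _bout_frame(starts, ends, fps)


def active_bout_stats(trace: np.ndarray, bouts: pd.DataFrame) -> pd.DataFrame:
    """Per-bout Δ-pixel statistics (mean, max, min, sum, std), vectorised.

    The std is the population standard deviation across the frames of one
    bout (0 for single-frame bouts).
    """
    trace = np.asarray(trace, dtype=np.float64)
    if bouts.empty:
        return bouts.assign(mean=[], max=[], min=[], sum=[], std=[])
    starts = bouts["start_frame"].to_numpy()
    ends = bouts["end_frame"].to_numpy()
    lengths = (ends - starts).astype(np.float64)
    # reduceat segments run from one bout start to the next, spilling over the
    # inter-bout gap; gaps are all zeros (bouts are maximal positive runs), so
    # sums, squared sums and maxima are unaffected.  Minima would see the
    # zeros, so the gap frames are masked to +inf for the min reduction.
    tr = trace[: ends[-1]]
    sums = np.add.reduceat(tr, starts)
    sums_sq = np.add.reduceat(tr**2, starts)
    maxs = np.maximum.reduceat(tr, starts)
    mins = np.minimum.reduceat(np.where(tr > 0, tr, np.inf), starts)
    means = sums / lengths
    var = sums_sq / lengths - means**2
    var[var < 0] = 0.0
    return bouts.assign(
        mean=means, max=maxs, min=mins, sum=sums, std=np.sqrt(var)
    )


def bout_table(ts: DeltaPixelTimeseries) -> pd.DataFrame:
    """Sleep and active bouts for every well of a timeseries.

    Columns: well, bout_type ∈ {sleep, active}, start_frame, end_frame,
    duration_s.  Bouts of the same type per well are sorted and
    non-overlapping by construction.
    """
    parts = []
    for well in ts.well_ids:
        trace = ts.trace(well)
        for kind, fn in ((SLEEP, detect_sleep_bouts), (ACTIVE, detect_active_bouts)):
            df = fn(trace, ts.fps)
            df.insert(0, "bout_type", kind)
            df.insert(0, "well", well)
            parts.append(df)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Binned traces
# ---------------------------------------------------------------------------


@dataclass
class BinnedTrace:
    """Epoch-binned trace: activity (summed Δ pixel) or sleep (min asleep)."""

    epoch_start_frame: np.ndarray
    value: np.ndarray
    epoch_min: float
    smoothing: str = "none"


def _epoch_frames(fps: float, epoch_min: float) -> int:
    return int(round(epoch_min * 60 * fps))


def bin_sleep_trace(
    flags: np.ndarray, fps: float, epoch_min: float = DEFAULT_EPOCH_MIN
) -> BinnedTrace:
    """Minutes asleep per epoch: (flagged frames) · (1/fps) / 60.

    Partial epochs at the end of the trace are dropped.
    """
    flags = np.asarray(flags, dtype=bool)
    w = _epoch_frames(fps, epoch_min)
    n_ep = flags.size // w
    counts = flags[: n_ep * w].reshape(n_ep, w).sum(axis=1)
    minutes = counts / fps / 60.0
    return BinnedTrace(np.arange(n_ep) * w, minutes, epoch_min)


def bin_activity_trace(
    trace: np.ndarray,
    fps: float,
    smooth_min: float = DEFAULT_SMOOTH_MIN,
    epoch_min: float = DEFAULT_EPOCH_MIN,
) -> BinnedTrace:
    """Sum of the smoothed Δ-pixel trace per epoch.

    The trace is first smoothed with a trailing rolling mean of
    ``smooth_min`` minutes (partial windows at the start use the available
    frames), then summed in ``epoch_min`` epochs; partial tail epochs are
    dropped.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if smooth_min > 0:
        w = max(1, int(round(smooth_min * 60 * fps)))
        smoothed = (
            pd.Series(trace).rolling(w, min_periods=1).mean().to_numpy()
        )
        label = f"rolling_mean_{smooth_min:g}min"
    else:
        smoothed = trace
        label = "none"
    we = _epoch_frames(fps, epoch_min)
    n_ep = smoothed.size // we
    sums = smoothed[: n_ep * we].reshape(n_ep, we).sum(axis=1)
    return BinnedTrace(np.arange(n_ep) * we, sums, epoch_min, smoothing=label)


# ---------------------------------------------------------------------------
# Legacy one-minute summary (middur)
# ---------------------------------------------------------------------------


@dataclass
class MiddurSeries:
    """Per-minute seconds-active, the legacy one-minute tracking summary."""

    seconds_active: np.ndarray  # one value per full minute, in [0, 60]
    freeze: float
    burst: float


def compute_middur(
    trace: np.ndarray,
    fps: float,
    freeze: float = DEFAULT_FREEZE,
    burst: float = DEFAULT_BURST,
) -> MiddurSeries:
    """Seconds per minute with freeze < Δ pixel < burst (strict on both).

    Setting freeze to 0 reproduces the re-computation mode used to compare
    the one-minute rule against frame-resolution scoring.  Partial trailing
    minutes are dropped.
    """
    if freeze >= burst:
        raise ValueError(f"freeze ({freeze}) must be below burst ({burst})")
    trace = np.asarray(trace)
    w = int(round(60 * fps))
    n_min = trace.size // w
    active = (trace[: n_min * w] > freeze) & (trace[: n_min * w] < burst)
    seconds = active.reshape(n_min, w).sum(axis=1) / fps
    return MiddurSeries(seconds, freeze=freeze, burst=burst)


# ---------------------------------------------------------------------------
# Pigmentation adjustment
# ---------------------------------------------------------------------------


def startle_maxima(
    ts: DeltaPixelTimeseries,
    wells: list[str],
    startle_windows: list[tuple[int, int]],
) -> np.ndarray:
    """Per-well mean of the maximum Δ pixel over the given frame windows."""
    out = []
    for well in wells:
        trace = ts.trace(well)
        maxima = [
            trace[s:e].max() if e > s and s < trace.size else 0
            for s, e in startle_windows
        ]
        out.append(np.mean(maxima))
    return np.asarray(out, dtype=np.float64)


def adjust_pigmentation(
    ts: DeltaPixelTimeseries,
    groups: GroupMap,
    reference_group: str,
    target_group: str,
    startle_windows: list[tuple[int, int]],
) -> DeltaPixelTimeseries:
    """Downscale the target group's Δ-pixel traces to the reference group.

    Fainter (less pigmented) larvae displace fewer pixels; to compare groups
    fairly, the target group's traces are multiplied by
    mean(startle maxima of reference) / mean(startle maxima of target) and
    rounded back to integers.  Other wells are untouched.
    """
    ref_wells = groups.wells_of(reference_group)
    tgt_wells = groups.wells_of(target_group)
    if not ref_wells or not tgt_wells:
        raise ValueError("both groups need at least one well")
    ref_mean = startle_maxima(ts, ref_wells, startle_windows).mean()
    tgt_mean = startle_maxima(ts, tgt_wells, startle_windows).mean()
    if ref_mean == 0 or tgt_mean == 0:
        raise ValueError("zero mean startle maximum; cannot scale")
    factor = ref_mean / tgt_mean
    logger.info(
        "pigmentation adjustment: scaling %s by %.4f (ref %s mean %.1f / target mean %.1f)",
        target_group, factor, reference_group, ref_mean, tgt_mean,
    )
    values = ts.values.copy()
    for well in tgt_wells:
        values[well] = np.round(values[well].to_numpy() * factor).astype(np.int64)
    return DeltaPixelTimeseries(values, fps=ts.fps)
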