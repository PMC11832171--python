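"""Day/night windowing and the 17 behavioural parameters.

Full days and nights of a tracking run are named ``night0, day1, night1,
day2, night2, ...``: days are numbered from 1 in the order of full light
phases, and each night takes the index of the day it follows (so the night
after the partial starting day is ``night0``).  Night0 is excluded from
analysis as a habituation period by default.  Larval age in days
post-fertilisation (dpf) during a window is the age at experiment start plus
the window index.

Seventeen parameters are computed per larva per window, in three categories:

========================  =========================================  =========
parameter                 definition                                 units
========================  =========================================  =========
percentage_time_active    % of frames with Δ pixel > 0               %
total_activity            sum of Δ pixel over the window             Δpx
sunset_startle            max Δ pixel in the first 3 s of the night  Δpx
                          (night only)
activity_slope            least-squares slope of the 10-min binned   Δpx/10min
                          activity across the window                 per hr
transition_delta          mean binned activity, first 30 min minus   Δpx/10min
                          last 30 min of the window
activity_cv               coefficient of variation of the 10-min     —
                          binned activity
active_bout_count         number of active bouts starting in window  bouts
active_bout_length_mean   mean active-bout duration                  s
active_bout_mean          mean over bouts of within-bout mean Δpx    Δpx
active_bout_max           mean over bouts of within-bout max Δpx     Δpx
active_bout_min           mean over bouts of within-bout min Δpx     Δpx
active_bout_sum           mean over bouts of within-bout summed Δpx  Δpx
active_bout_std           mean over bouts of within-bout std of Δpx  Δpx
total_sleep               hours asleep in window                     hr
sleep_bout_count          number of sleep bouts starting in window   bouts
sleep_bout_length_mean    mean sleep-bout duration                   min
sleep_latency             minutes from lights-off to first sleep     min
                          bout (night only; missing if sleepless)
========================  =========================================  =========

That is 15 day + 17 night = 32 unique (parameter, day/night) keys.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking_io import (
    LIGHTS_ON,
    DeltaPixelTimeseries,
    GroupMap,
    LightSchedule,
)
from . import bout_detection as bd

logger = logging.getLogger(__name__)

DEFAULT_STARTLE_WINDOW_S = 3.0

ACTIVITY = "activity"
ACTIVE_BOUT = "active bout"
SLEEP_CAT = "sleep"


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    category: str
    night_only: bool
    units: str


PARAMETERS: list[ParameterSpec] = [
    ParameterSpec("percentage_time_active", ACTIVITY, False, "%"),
    ParameterSpec("total_activity", ACTIVITY, False, "Δpx"),
    ParameterSpec("sunset_startle", ACTIVITY, True, "Δpx"),
    ParameterSpec("activity_slope", ACTIVITY, False, "Δpx/10min/hr"),
    ParameterSpec("transition_delta", ACTIVITY, False, "Δpx/10min"),
    ParameterSpec("activity_cv", ACTIVITY, False, ""),
    ParameterSpec("active_bout_count", ACTIVE_BOUT, False, "bouts"),
    ParameterSpec("active_bout_length_mean", ACTIVE_BOUT, False, "s"),
    ParameterSpec("active_bout_mean", ACTIVE_BOUT, False, "Δpx"),
    ParameterSpec("active_bout_max", ACTIVE_BOUT, False, "Δpx"),
    ParameterSpec("active_bout_min", ACTIVE_BOUT, False, "Δpx"),
    ParameterSpec("active_bout_sum", ACTIVE_BOUT, False, "Δpx"),
    ParameterSpec("active_bout_std", ACTIVE_BOUT, False, "Δpx"),
    ParameterSpec("total_sleep", SLEEP_CAT, False, "hr"),
    ParameterSpec("sleep_bout_count", SLEEP_CAT, False, "bouts"),
    ParameterSpec("sleep_bout_length_mean", SLEEP_CAT, False, "min"),
    ParameterSpec("sleep_latency", SLEEP_CAT, True, "min"),
]

PARAMETER_NAMES = [p.name for p in PARAMETERS]
NIGHT_ONLY = {p.name for p in PARAMETERS if p.night_only}
UNITS = {p.name: p.units for p in PARAMETERS}

assert len(PARAMETERS) == 17 and len(NIGHT_ONLY) == 2


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Window:
    name: str
    start_frame: int
    end_frame: int
    is_day: bool
    dpf: int
    excluded: bool = False


@dataclass
class WindowSet:
    windows: list[Window]

    @property
    def analysis(self) -> list[Window]:
        return [w for w in self.windows if not w.excluded]

    @property
    def names(self) -> list[str]:
        return [w.name for w in self.windows]

    def __iter__(self):
        return iter(self.windows)

    def __len__(self):
        return len(self.windows)


def define_windows(
    schedule: LightSchedule,
    ts: DeltaPixelTimeseries,
    exclude_habituation: bool = True,
) -> WindowSet:
    """Full day/night windows of a tracking run.

    Only windows lying entirely within the tracked span are returned;
    partial windows at both ends are dropped.  With ``exclude_habituation``
    the first night (night0) is flagged excluded.
    """
    fps = ts.fps
    duration = ts.duration_s
    tol = 0.5 / fps
    transitions = schedule.transition_times(duration, include_start=True)
    windows: list[Window] = []
    for i, (t, kind) in enumerate(transitions):
        is_day = kind == LIGHTS_ON
        full_len = schedule.day_len_s if is_day else schedule.night_len_s
        end = transitions[i + 1][0] if i + 1 < len(transitions) else t + full_len
        if end > duration + tol or abs(end - t - full_len) > tol:
            continue  # truncated phase at the end of the track
        # a day starting at the k-th observed lights-on is day k; a night
        # takes the index of the day it follows (0 before any full day)
        n_on = sum(1 for tt, kk in transitions[: i + 1] if kk == LIGHTS_ON)
        windows.append(_make_window(is_day, n_on, t, t + full_len, fps, schedule))
    if exclude_habituation:
        windows = [
            Window(w.name, w.start_frame, w.end_frame, w.is_day, w.dpf,
                   excluded=(w.name == "night0"))
            for w in windows
        ]
    analysis = [w for w in windows if not w.excluded]
    if not analysis:
        raise ValueError("no full day/night window in the tracked span")
    logger.info("windows: %s (analysis set %s)",
                [w.name for w in windows], [w.name for w in analysis])
    return WindowSet(windows)


def _make_window(
    is_day: bool, n_on: int, start_s: float, end_s: float, fps: float,
    schedule: LightSchedule,
) -> Window:
    # day k starts at the k-th observed lights-on; the night following day k
    # is night k, so night0 precedes the first full day
    idx = n_on
    name = f"{'day' if is_day else 'night'}{idx}"
    return Window(
        name=name,
        start_frame=int(round(start_s * fps)),
        end_frame=int(round(end_s * fps)),
        is_day=is_day,
        dpf=schedule.start_dpf + idx,
    )


# ---------------------------------------------------------------------------
# Per-window parameter extraction
# ---------------------------------------------------------------------------


def param_sunset_startle(
    trace: np.ndarray,
    lights_off_frame: int,
    fps: float,
    window_s: float = DEFAULT_STARTLE_WINDOW_S,
) -> float:
    """Maximum Δ pixel within ``window_s`` seconds after lights-off."""
    trace = np.asarray(trace)
    if not 0 <= lights_off_frame < trace.size:
        raise ValueError("lights_off_frame outside trace")
    end = lights_off_frame + int(round(window_s * fps))
    if end > trace.size:
        warnings.warn("startle window extends past trace end; using available frames",
                      stacklevel=2)
        end = trace.size
    seg = trace[lights_off_frame:end]
    return float(seg.max()) if seg.size else 0.0


def param_sleep_latency(
    sleep_bouts: pd.DataFrame, night_start_frame: int, night_end_frame: int, fps: float
) -> float:
    """Minutes from lights-off to the first sleep bout of the night (NaN if none)."""
    starts = sleep_bouts["start_frame"].to_numpy()
    in_night = starts[(starts >= night_start_frame) & (starts < night_end_frame)]
    if in_night.size == 0:
        return float("nan")
    return float((in_night.min() - night_start_frame) / fps / 60.0)


def _binned_activity_params(trace_win: np.ndarray, fps: float) -> dict[str, float]:
    """Slope, transition delta, and CV of the 10-min binned activity."""
    binned = bd.bin_activity_trace(trace_win, fps, smooth_min=0, epoch_min=10.0)
    v = binned.value
    out = {"activity_slope": float("nan"), "transition_delta": float("nan"),
           "activity_cv": float("nan")}
    if v.size >= 2:
        hours = (np.arange(v.size) * 10.0 + 5.0) / 60.0  # epoch centres
        out["activity_slope"] = float(np.polyfit(hours, v, 1)[0])
    if v.size >= 6:
        out["transition_delta"] = float(v[:3].mean() - v[-3:].mean())
    if v.size >= 2 and v.mean() > 0:
        out["activity_cv"] = float(v.std(ddof=1) / v.mean())
    return out


def compute_parameter_table(
    ts: DeltaPixelTimeseries,
    bouts: pd.DataFrame,
    windows: WindowSet,
    groups: GroupMap,
    startle_window_s: float = DEFAULT_STARTLE_WINDOW_S,
) -> pd.DataFrame:
    """The larva × window × parameter long table, the LME input.

    ``bouts`` is the combined bout table from
    :func:`~sleepframe.bout_detection.bout_table` computed on the same
    timeseries.  Night-only parameters are absent for day windows and
    excluded (habituation) windows yield no rows.
    """
    fps = ts.fps
    rows = []
    for well in ts.well_ids:
        if well not in groups.group_of:
            raise KeyError(f"well {well!r} absent from group map")
        if well in groups.excluded:
            continue
        trace = ts.trace(well)
        flags = bd.sleep_flags(trace, fps)
        wb = bouts[bouts["well"] == well]
        sleep_b = wb[wb["bout_type"] == bd.SLEEP]
        active_b = wb[wb["bout_type"] == bd.ACTIVE]
        active_stats = bd.active_bout_stats(trace, active_b.reset_index(drop=True))
        for win in windows.analysis:
            sl = slice(win.start_frame, win.end_frame)
            tw = trace[sl]
            values = {}
            values["percentage_time_active"] = 100.0 * float(np.mean(tw > 0))
            values["total_activity"] = float(tw.sum())
            values.update(_binned_activity_params(tw, fps))
            ab = active_stats[
                (active_stats["start_frame"] >= win.start_frame)
                & (active_stats["start_frame"] < win.end_frame)
            ]
            values["active_bout_count"] = float(len(ab))
            if len(ab):
                values["active_bout_length_mean"] = float(ab["duration_s"].mean())
                for stat in ("mean", "max", "min", "sum", "std"):
                    values[f"active_bout_{stat}"] = float(ab[stat].mean())
            else:
                values["active_bout_length_mean"] = float("nan")
                for stat in ("mean", "max", "min", "sum", "std"):
                    values[f"active_bout_{stat}"] = float("nan")
            values["total_sleep"] = float(flags[sl].sum()) / fps / 3600.0
            sb = sleep_b[
                (sleep_b["start_frame"] >= win.start_frame)
                & (sleep_b["start_frame"] < win.end_frame)
            ]
            values["sleep_bout_count"] = float(len(sb))
            values["sleep_bout_length_mean"] = (
                float(sb["duration_s"].mean() / 60.0) if len(sb) else float("nan")
            )
            if not win.is_day:
                values["sunset_startle"] = param_sunset_startle(
                    trace, win.start_frame, fps, startle_window_s
                )
                values["sleep_latency"] = param_sleep_latency(
                    sleep_b, win.start_frame, win.end_frame, fps
                )
            for name, val in values.items():
                rows.append(
                    {
                        "experiment": groups.experiment_of.get(well, "exp1"),
                        "well": well,
                        "group": groups.group_of[well],
                        "window": win.name,
                        "is_day": win.is_day,
                        "dpf": win.dpf,
                        "parameter": name,
                        "value": val,
                        "units": UNITS[name],
                    }
                )
    table = pd.DataFrame(rows)
    _census(table)
    return table


def _census(table: pd.DataFrame) -> None:
    """Assert the normative parameter counts (17 names, 15 day + 17 night keys)."""
    names = set(table["parameter"])
    if not names <= set(PARAMETER_NAMES):
        raise AssertionError(f"unexpected parameters {names - set(PARAMETER_NAMES)}")
    keys = table[["parameter", "is_day"]].drop_duplicates()
    n_day = int((keys["is_day"]).sum())
    n_night = int((~keys["is_day"]).sum())
    if {True, False} <= set(table["is_day"]):
        if len(names) != 17 or n_day != 15 or n_night != 17:
            raise AssertionError(
                f"parameter census failed: {len(names)} names, {n_day} day + "
                f"{n_night} night keys"
            )
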