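"""I/O for Δ-pixel tracking tables, group maps, and light schedules.

The raw substrate of every analysis in this package is a frame-by-frame
Δ-pixel table: one column per well, one row per frame-to-frame transition,
each cell the number of camera pixels that changed intensity for that well at
that transition.  The supported on-disk dialect is a plain UTF-8 CSV whose
header row holds the well labels and whose cells are nonnegative integers.

Group maps ("genotype files") assign each well to an experimental group and,
optionally, to an experiment/clutch; light schedules describe the 14 h:10 h
light:dark cycle that defines the day and night analysis windows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 24 * 3600

LIGHTS_ON = "lights_on"
LIGHTS_OFF = "lights_off"


class MalformedInputError(ValueError):
    """A cell-level problem in an input table (negative, non-numeric, ...)."""


class StructuralError(ValueError):
    """A table-level problem in an input file (ragged rows, duplicates, ...)."""


# ---------------------------------------------------------------------------
# Δ-pixel timeseries
# ---------------------------------------------------------------------------


@dataclass
class DeltaPixelTimeseries:
    """Per-well frame-indexed Δ-pixel values.

    Parameters
    ----------
    values
        DataFrame with one integer column per well, one row per frame
        transition.  Row order is frame order (0-based).
    fps
        Camera frame rate in frames per second (25 for the standard assay).
    """

    values: pd.DataFrame
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
                raise MalformedInputError("Δ-pixel values must be integral")
            self.values = self.values.astype(np.int64)
        if arr.size and (arr < 0).any():
            raise MalformedInputError("Δ-pixel values must be nonnegative")

    @property
    def well_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def frame_index(self) -> np.ndarray:
        return np.arange(self.n_frames)

    @property
    def clock_time(self) -> np.ndarray:
        """Seconds since experiment start for each frame: k / fps."""
        return self.frame_index / self.fps

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def trace(self, well: str) -> np.ndarray:
        return self.values[well].to_numpy()


def read_deltapixel_table(path, fps: float = 25.0) -> DeltaPixelTimeseries:
    """Read a Δ-pixel CSV (header = well labels, cells = nonnegative ints).

    Raises
    ------
    MalformedInputError
        On a negative or non-numeric cell, naming the offending row/column.
    StructuralError
        On ragged rows.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise StructuralError(f"ragged or unparsable CSV {path}: {exc}") from exc
    out = {}
    for col in df.columns:
        s = df[col]
        numeric = pd.to_numeric(s, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise MalformedInputError(
                f"non-numeric Δ-pixel value {s.iloc[row]!r} at row {row}, column {col!r}"
            )
        if (numeric < 0).any():
            row = int(np.argmax((numeric < 0).to_numpy()))
            raise MalformedInputError(
                f"negative Δ-pixel value {numeric.iloc[row]} at row {row}, column {col!r}"
            )
        if (numeric != np.round(numeric)).any():
            row = int(np.argmax((numeric != np.round(numeric)).to_numpy()))
            raise MalformedInputError(
                f"non-integral Δ-pixel value {numeric.iloc[row]} at row {row}, column {col!r}"
            )
        out[str(col)] = numeric.astype(np.int64)
    ts = DeltaPixelTimeseries(pd.DataFrame(out), fps=fps)
    logger.info("read Δ-pixel table %s: %d wells × %d frames", path, len(out), ts.n_frames)
    return ts


def write_deltapixel_table(ts: DeltaPixelTimeseries, path) -> None:
    ts.values.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Group map
# ---------------------------------------------------------------------------


@dataclass
class GroupMap:
    """Well → group assignment, with optional clutch/experiment identity."""

    group_of: dict[str, str]
    experiment_of: dict[str, str] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # well -> reason
    control_group: str | None = None

    def __post_init__(self) -> None:
        for well, grp in self.group_of.items():
            if not str(grp).strip():
                raise StructuralError(f"empty group label for well {well!r}")
        if not self.experiment_of:
            self.experiment_of = {w: "exp1" for w in self.group_of}

    @property
    def wells(self) -> list[str]:
        return list(self.group_of)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_of.values():
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def experiments(self) -> list[str]:
        seen: list[str] = []
        for e in self.experiment_of.values():
            if e not in seen:
                seen.append(e)
        return seen

    def wells_of(self, group: str) -> list[str]:
        return [w for w, g in self.group_of.items() if g == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": self.wells,
                "group": [self.group_of[w] for w in self.wells],
                "experiment": [self.experiment_of.get(w, "exp1") for w in self.wells],
            }
        )


def read_group_map(path) -> GroupMap:
    """Read a delimited well→group(→experiment) map (CSV or TSV)."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "well" not in cols or "group" not in cols:
        # headerless two/three-column file
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, header=None)
        names = ["well", "group", "experiment"][: df.shape[1]]
        df.columns = names
    if df["well"].duplicated().any():
        dup = df["well"][df["well"].duplicated()].iloc[0]
        raise StructuralError(f"well {dup!r} listed more than once in group map")
    group_of = dict(zip(df["well"], df["group"]))
    experiment_of = (
        dict(zip(df["well"], df["experiment"])) if "experiment" in df.columns else {}
    )
    return GroupMap(group_of=group_of, experiment_of=experiment_of)


def write_group_map(gm: GroupMap, path) -> None:
    gm.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Light schedule
# ---------------------------------------------------------------------------


def _parse_clock(value) -> float:
    """Clock time of day → seconds past midnight ('09:00', '23:15:30', or s)."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"(\d{1,2}):(\d{2})(?::(\d{2}))?", str(value).strip())
    if not m:
        raise ValueError(f"cannot parse clock time {value!r}")
    h, mi, s = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
    return float(h * 3600 + mi * 60 + s)


@dataclass
class LightSchedule:
    """The light:dark cycle defining day and night.

    Defaults match the standard assay: lights on at 09:00 for 14 h, off at
    23:00 for 10 h.  ``start_clock_s`` is the time of day at frame 0 and
    ``start_dpf`` the larval age (days post-fertilisation) at frame 0.
    """

    lights_on_s: float = 9 * 3600.0
    day_len_s: float = 14 * 3600.0
    night_len_s: float = 10 * 3600.0
    start_clock_s: float = 11 * 3600.0
    start_dpf: int = 5

    def __post_init__(self) -> None:
        if abs(self.day_len_s + self.night_len_s - SECONDS_PER_DAY) > 1e-6:
            raise ValueError("day length + night length must equal 24 h")

    @property
    def lights_off_s(self) -> float:
        return (self.lights_on_s + self.day_len_s) % SECONDS_PER_DAY

    def is_day_at(self, t_s: float) -> bool:
        """True when t_s seconds after experiment start fall in the light phase."""
        clock = (self.start_clock_s + t_s) % SECONDS_PER_DAY
        delta = (clock - self.lights_on_s) % SECONDS_PER_DAY
        return delta < self.day_len_s

    def transition_times(self, duration_s: float, include_start: bool = False):
        """All light transitions in [0, duration_s) as (t_s, type) pairs.

        Transition times are seconds since experiment start.  With
        ``include_start`` a transition coinciding exactly with t=0 is kept.
        """
        out: list[tuple[float, str]] = []
        for kind, clock in ((LIGHTS_ON, self.lights_on_s), (LIGHTS_OFF, self.lights_off_s)):
            first = (clock - self.start_clock_s) % SECONDS_PER_DAY
            t = first
            while t < duration_s:
                if t > 0 or include_start:
                    out.append((t, kind))
                t += SECONDS_PER_DAY
        out.sort(key=lambda p: p[0])
        return out

    @classmethod
    def from_yaml(cls, path) -> "LightSchedule":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "lights_on" in raw:
            kwargs["lights_on_s"] = _parse_clock(raw["lights_on"])
        if "day_hours" in raw:
            kwargs["day_len_s"] = float(raw["day_hours"]) * 3600
        if "night_hours" in raw:
            kwargs["night_len_s"] = float(raw["night_hours"]) * 3600
        if "start_clock" in raw:
            kwargs["start_clock_s"] = _parse_clock(raw["start_clock"])
        if "start_dpf" in raw:
            kwargs["start_dpf"] = int(raw["start_dpf"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "lights_on": self.lights_on_s,
                    "day_hours": self.day_len_s / 3600,
                    "night_hours": self.night_len_s / 3600,
                    "start_clock": self.start_clock_s,
                    "start_dpf": self.start_dpf,
                },
                fh,
            )


def frame_of_transitions(
    schedule: LightSchedule, ts: DeltaPixelTimeseries
) -> list[tuple[int, str]]:
    """Interior light transitions of a tracking run as (frame, type) pairs.

    Frames are 0-based; a transition at t seconds after start maps to frame
    round(t·fps).  Transitions alternate in type and frames are strictly
    increasing; an experiment shorter than its first transition yields an
    empty list.
    """
    out = []
    for t_s, kind in schedule.transition_times(ts.duration_s):
        frame = int(round(t_s * ts.fps))
        if 0 < frame < ts.n_frames:
            out.append((frame, kind))
    return out
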