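import numpy as np
import pandas as pd
import pytest

from sleepframe.behaviour_parameters import define_windows
from sleepframe.bout_detection import bout_table
from sleepframe.synthetic_data import LarvaSimConfig, simulate_experiment
from sleepframe.tracking_io import LightSchedule


@pytest.fixture(scope="session")
def schedule():
    # start 16:00 at 5 dpf: a 65-h track then spans night0..night2 in full
    return LightSchedule(start_clock_s=16 * 3600)


@pytest.fixture(scope="session")
def experiment65(schedule):
    """A 65-h two-group simulated experiment (4 wells, 5 fps) with windows,
    bouts, and ground truth — shared by the window/parameter/fingerprint
    tests."""
    cfg = LarvaSimConfig(fps=5, seed=11)
    duration = 65 * 3600
    n_frames = int(duration * cfg.fps)
    # ground-truth windows mirror the analysis windows
    win_frames = _expected_windows(cfg.fps)
    ts, gm, truth = simulate_experiment(
        {"scr": 2, "ko": 2},
        {"ko": {"day_activity": 0.7, "night_sleep": 2.0}},
        cfg,
        schedule,
        duration,
        seed=11,
        windows=win_frames,
    )
    windows = define_windows(schedule, ts)
    bouts = bout_table(ts)
    return {"ts": ts, "gm": gm, "truth": truth, "windows": windows, "bouts": bouts}


def _expected_windows(fps):
    """night0..night2 frame spans for a 16:00 start (clock arithmetic)."""
    h = 3600 * fps
    out = []
    night0 = (7 * h, 17 * h)  # 23:00 -> 09:00
    out.append(("night0", *map(int, night0)))
    t = 17
    for d in (1, 2):
        out.append((f"day{d}", int(t * h), int((t + 14) * h)))
        out.append((f"night{d}", int((t + 14) * h), int((t + 24) * h)))
        t += 24
    return out


def simulate_parameter_sample(seed, delta=0.0, n_per_group=24, clutches=2,
                              parameter="total_sleep", phase="night"):
    """Parameter-table rows with clutch, larva and dpf random intercepts.

    Direct simulation at the parameter level (not via traces) for the
    mixed-model calibration and recovery checks, drawn exactly from the
    fitted model's structure: value = grand mean + clutch intercept + larva
    intercept + global dpf intercept + noise (+ delta for the ko group).
    """
    rng = np.random.default_rng(seed)
    is_day = phase == "day"
    wins = ["day1", "day2"] if is_day else ["night1", "night2"]
    rows = []
    dpf_eff = rng.normal(0, 0.3, size=2)  # crossed with clutch, as modelled
    for c in range(clutches):
        clutch_eff = rng.normal(0, 0.5)
        for i in range(2 * n_per_group):
            grp = "ko" if i % 2 else "scr"
            larva_eff = rng.normal(0, 0.7)
            for wi, win in enumerate(wins):
                rows.append(
                    {
                        "experiment": f"clutch{c + 1}",
                        "well": f"w{i:02d}",
                        "group": grp,
                        "window": win,
                        "is_day": is_day,
                        "dpf": 6 + wi,
                        "parameter": parameter,
                        "value": 8.0
                        + clutch_eff
                        + larva_eff
                        + dpf_eff[wi]
                        + (delta if grp == "ko" else 0.0)
                        + rng.normal(0, 1.0),
                    }
                )
    return pd.DataFrame(rows)
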