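import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepframe.bout_detection import (
    adjust_pigmentation,
    bin_activity_trace,
    bin_sleep_trace,
    compute_middur,
    detect_active_bouts,
    detect_sleep_bouts,
    sleep_flags,
    sleep_window_frames,
)
from sleepframe.tracking_io import DeltaPixelTimeseries, GroupMap


def zero_run_scan(trace, fps):
    """Independent oracle: maximal zero runs of ≥ round(60·fps) frames."""
    w = int(round(60 * fps))
    trace = np.asarray(trace)
    bouts = []
    start = None
    for i, v in enumerate(trace):
        if v == 0 and start is None:
            start = i
        elif v != 0 and start is not None:
            if i - start >= w:
                bouts.append((start, i))
            start = None
    if start is not None and len(trace) - start >= w:
        bouts.append((start, len(trace)))
    return bouts


class TestSleepBouts:
    def test_all_zero_trace_is_one_bout(self):
        df = detect_sleep_bouts(np.zeros(3000, dtype=int), fps=25)
        assert len(df) == 1
        assert (df.iloc[0]["start_frame"], df.iloc[0]["end_frame"]) == (0, 3000)
        assert df.iloc[0]["duration_s"] == 120.0

    def test_sub_threshold_runs_are_not_sleep(self):
        # 59-s zero runs separated by single active frames
        fps = 25
        piece = np.concatenate([np.zeros(59 * fps, dtype=int), [5]])
        trace = np.tile(piece, 4)
        assert detect_sleep_bouts(trace, fps).empty

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            df = detect_sleep_bouts(np.zeros(100, dtype=int), fps=25)
        assert df.empty

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_zero_run_oracle_on_random_traces(self, seed):
        rng = np.random.default_rng(seed)
        fps = 25
        # sparse binary traces so ≥60-s zero runs actually occur
        trace = (rng.random(100_000) < 0.0005).astype(int) * rng.integers(
            1, 50, 100_000
        )
        got = list(
            zip(
                detect_sleep_bouts(trace, fps)["start_frame"],
                detect_sleep_bouts(trace, fps)["end_frame"],
            )
        )
        assert got == zero_run_scan(trace, fps)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=10, max_size=400),
        st.sampled_from([2.0, 5.0]),
    )
    def test_oracle_equivalence_property(self, values, fps):
        trace = np.asarray(values)
        df = detect_sleep_bouts(trace, fps) if len(trace) >= sleep_window_frames(fps) else None
        if df is None:
            return
        got = list(zip(df["start_frame"], df["end_frame"]))
        assert got == zero_run_scan(trace, fps)

    def test_truncated_edge_bouts_kept_when_observed_60s(self):
        fps = 25
        w = sleep_window_frames(fps)
        trace = np.concatenate([np.zeros(w, dtype=int), [3], np.zeros(w + 10, dtype=int)])
        df = detect_sleep_bouts(trace, fps)
        assert [(r.start_frame, r.end_frame) for r in df.itertuples()] == [
            (0, w),
            (w + 1, 2 * w + 11),
        ]


class TestActiveBouts:
    def test_hand_enumerated_case(self):
        df = detect_active_bouts(np.array([0, 5, 7, 0, 0, 3, 0]), fps=25)
        assert [(r.start_frame, r.end_frame) for r in df.itertuples()] == [(1, 3), (5, 6)]

    def test_all_zero_has_no_bouts(self):
        assert detect_active_bouts(np.zeros(100, dtype=int), fps=25).empty

    def test_all_positive_is_one_bout(self):
        df = detect_active_bouts(np.full(50, 7), fps=25)
        assert len(df) == 1 and df.iloc[0]["end_frame"] == 50


class TestBinnedTraces:
    def test_worked_sleep_binning_example(self):
        # 5000 of 15,000 flagged frames at 25 fps -> 3.33 min asleep
        flags = np.zeros(15_000, dtype=bool)
        flags[:5000] = True
        binned = bin_sleep_trace(flags, fps=25, epoch_min=10)
        assert binned.value[0] == pytest.approx(5000 * (1 / 25) * (1 / 60))
        assert round(binned.value[0], 2) == 3.33

    def test_sleep_binning_bounds(self):
        assert bin_sleep_trace(np.zeros(15_000, dtype=bool), 25).value[0] == 0.0
        assert bin_sleep_trace(np.ones(15_000, dtype=bool), 25).value[0] == 10.0

    def test_constant_trace_bins_to_constant_sum(self):
        fps, c = 5.0, 4
        binned = bin_activity_trace(np.full(3 * 3000, c), fps, smooth_min=60, epoch_min=10)
        np.testing.assert_allclose(binned.value, c * 3000)

    def test_zero_trace_bins_to_zero(self):
        assert (bin_activity_trace(np.zeros(9000), 5.0).value == 0).all()

    def test_matches_rolling_mean_plus_block_sum_oracle(self):
        rng = np.random.default_rng(1)
        fps = 2.0
        trace = rng.integers(0, 20, size=20_000)
        binned = bin_activity_trace(trace, fps, smooth_min=10, epoch_min=5)
        w = int(10 * 60 * fps)
        smoothed = pd.Series(trace).rolling(w, min_periods=1).mean().to_numpy()
        we = int(5 * 60 * fps)
        expected = smoothed[: (len(trace) // we) * we].reshape(-1, we).sum(axis=1)
        np.testing.assert_allclose(binned.value, expected)

    def test_epoch_sleep_conserves_bout_total(self):
        rng = np.random.default_rng(2)
        fps = 5.0
        trace = (rng.random(90_000) < 0.001).astype(int)
        flags = sleep_flags(trace, fps)
        binned = bin_sleep_trace(flags, fps, epoch_min=10)
        n_full = (len(trace) // int(10 * 60 * fps)) * int(10 * 60 * fps)
        total_from_bins = binned.value.sum()
        total_from_flags = flags[:n_full].sum() / fps / 60
        assert total_from_bins == pytest.approx(total_from_flags)


class TestMiddur:
    def test_fully_active_minute_is_60s(self):
        mid = compute_middur(np.full(1500, 10), fps=25, freeze=3, burst=200)
        assert mid.seconds_active[0] == 60.0

    def test_zero_minute_is_0s(self):
        assert compute_middur(np.zeros(1500, dtype=int), 25).seconds_active[0] == 0.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(3)
        trace = rng.integers(0, 250, size=6000)
        mid = compute_middur(trace, fps=25, freeze=3, burst=200)
        for m in range(4):
            seg = trace[m * 1500 : (m + 1) * 1500]
            expected = ((seg > 3) & (seg < 200)).sum() / 25
            assert mid.seconds_active[m] == pytest.approx(expected)

    def test_freeze_must_be_below_burst(self):
        with pytest.raises(ValueError):
            compute_middur(np.zeros(1500, dtype=int), 25, freeze=200, burst=200)

    def test_thresholds_are_strict(self):
        trace = np.full(1500, 3)
        assert compute_middur(trace, 25, freeze=3, burst=200).seconds_active[0] == 0.0


class TestLegacyVsFrameResolution:
    @pytest.mark.parametrize("seed", range(5))
    def test_one_minute_rule_never_finds_more_sleep(self, seed):
        """A zero-middur minute needs 60 aligned zero seconds, which always
        lie inside a frame-resolution sleep bout, so the legacy totals are
        bounded above by the frame-resolution ones."""
        rng = np.random.default_rng(seed)
        fps = 5.0
        trace = (rng.random(360_000) < 0.0008).astype(int) * rng.integers(1, 30, 360_000)
        mid = compute_middur(trace, fps, freeze=0, burst=200)
        asleep_min = mid.seconds_active == 0
        legacy_sleep_min = asleep_min.sum()
        frame_sleep_min = sleep_flags(trace, fps).sum() / fps / 60
        assert legacy_sleep_min <= frame_sleep_min + 1e-9
        runs = np.diff(np.concatenate(([0], asleep_min.view(np.int8), [0])))
        legacy_bouts = (runs == 1).sum()
        frame_bouts = len(detect_sleep_bouts(trace, fps))
        assert legacy_bouts <= frame_bouts


class TestPigmentationAdjustment:
    def _ts(self, scr_amp, ko_amp):
        n = 200
        vals = pd.DataFrame(
            {
                "A1": np.full(n, scr_amp),
                "A2": np.full(n, ko_amp),
            }
        )
        gm = GroupMap(group_of={"A1": "scr", "A2": "ko"})
        return DeltaPixelTimeseries(vals, fps=25), gm

    def test_scaling_by_startle_ratio(self):
        # startle means 78 (ko) vs 82 (scr): scr scaled by 78/82 ≈ 0.9512
        ts, gm = self._ts(82, 78)
        out = adjust_pigmentation(ts, gm, "ko", "scr", [(0, 200)])
        assert out.values["A1"].iloc[0] == round(82 * 78 / 82)
        assert (out.values["A2"] == 78).all()  # reference untouched

    def test_equal_means_is_identity(self):
        ts, gm = self._ts(80, 80)
        out = adjust_pigmentation(ts, gm, "ko", "scr", [(0, 200)])
        pd.testing.assert_frame_equal(out.values, ts.values)

    def test_rescaled_startle_means_equalise(self):
        rng = np.random.default_rng(4)
        vals = pd.DataFrame(
            {
                "A1": rng.integers(60, 100, 500),
                "A2": rng.integers(50, 80, 500),
            }
        )
        gm = GroupMap(group_of={"A1": "scr", "A2": "ko"})
        ts = DeltaPixelTimeseries(vals, fps=25)
        out = adjust_pigmentation(ts, gm, "ko", "scr", [(0, 500)])
        ref_max = out.values["A2"].max()
        tgt_max = out.values["A1"].max()
        assert tgt_max == pytest.approx(ref_max, rel=0.02)

    def test_zero_startle_mean_rejected(self):
        ts, gm = self._ts(0, 78)
        with pytest.raises(ValueError, match="zero mean startle"):
            adjust_pigmentation(ts, gm, "ko", "scr", [(0, 200)])
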