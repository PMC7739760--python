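import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mocapkit.body25 import NAME_TO_INDEX
from mocapkit.cleaning import (
    DUAL_PASS_CUTOFF_CORRECTION,
    FilterSpec,
    butter_zero_lag,
    correct_lr_swaps,
    flag_temporal_outliers,
    interpolate_gaps,
    residual_analysis_cutoff,
)
from mocapkit.exceptions import ConfigError
from mocapkit.synthetic_scene import SceneConfig, generate_skeleton_motion, inject_swaps


class TestCorrectLrSwaps:
    def test_clean_trajectory_untouched(self, walk_truth):
        out, events = correct_lr_swaps(walk_truth)
        assert events == []
        np.testing.assert_array_equal(out.data, walk_truth.data)

    def test_injected_ankle_swap_block_is_undone(self, walk_truth):
        corrupted = walk_truth.copy()
        l, r = NAME_TO_INDEX["l_ankle"], NAME_TO_INDEX["r_ankle"]
        for t in range(40, 46):
            corrupted.data[t, [l, r]] = corrupted.data[t, [r, l]]
        out, events = correct_lr_swaps(corrupted)
        np.testing.assert_allclose(out.data, walk_truth.data)
        assert sorted(e.frame_index for e in events) == list(range(40, 46))
        assert all(e.keypoint_pair == (14, 11) for e in events)

    def test_idempotent(self, walk_truth, rng):
        corrupted, _ = inject_swaps(walk_truth, 0.1, rng)
        once, _ = correct_lr_swaps(corrupted)
        twice, events2 = correct_lr_swaps(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert events2 == []

    def test_positions_multiset_preserved_per_frame(self, walk_truth, rng):
        corrupted, _ = inject_swaps(walk_truth, 0.2, rng)
        out, _ = correct_lr_swaps(corrupted)
        for t in range(0, out.n_frames, 17):
            a = np.sort(corrupted.data[t].round(9), axis=0)
            b = np.sort(out.data[t].round(9), axis=0)
            np.testing.assert_array_equal(a, b)

    def test_majority_flip_recovers_swap_on_first_frame(self, walk_truth):
        corrupted = walk_truth.copy()
        l, r = NAME_TO_INDEX["l_knee"], NAME_TO_INDEX["r_knee"]
        corrupted.data[0, [l, r]] = corrupted.data[0, [r, l]]
        out, _ = correct_lr_swaps(corrupted)
        np.testing.assert_allclose(out.data, walk_truth.data)


class TestFlagTemporalOutliers:
    def _smooth(self, n=200):
        t = np.arange(n) / 120.0
        return np.stack([100 * np.sin(2 * np.pi * t), 50 * np.cos(2 * np.pi * t), 900 + 0 * t], axis=1)

    def test_smooth_series_unflagged(self):
        x = self._smooth()
        flags = flag_temporal_outliers(x, np.ones(len(x), bool), vmax=50.0)
        assert not flags.any()

    def test_isolated_spike_flagged_exactly(self):
        x = self._smooth()
        x[100] += 500.0
        flags = flag_temporal_outliers(x, np.ones(len(x), bool), vmax=50.0)
        assert list(np.flatnonzero(flags)) == [100]

    def test_sustained_step_is_signal_not_spike(self):
        x = self._smooth()
        x[100:] += 500.0
        flags = flag_temporal_outliers(x, np.ones(len(x), bool), vmax=50.0)
        assert not flags.any()


class TestInterpolateGaps:
    def test_gap_free_series_identity(self, rng):
        x = rng.normal(size=(50, 3))
        filled, valid, unfilled = interpolate_gaps(x, np.ones(50, bool))
        np.testing.assert_array_equal(filled, x)
        assert valid.all() and unfilled == []

    def test_cubic_gap_filled_exactly(self):
        t = np.arange(60, dtype=float)
        x = (0.02 * t**3 - t**2 + 3 * t)[:, None]
        valid = np.ones(60, bool)
        valid[20:23] = False
        filled, newvalid, unfilled = interpolate_gaps(x, valid)
        assert newvalid.all() and unfilled == []
        np.testing.assert_allclose(filled, x, atol=1e-8)

    def test_oversized_gap_reported_unfilled(self):
        x = np.arange(100, dtype=float)[:, None]
        valid = np.ones(100, bool)
        valid[20:70] = False
        filled, newvalid, unfilled = interpolate_gaps(x, valid, max_gap_frames=24)
        assert unfilled == [(20, 69)]
        assert not newvalid[20:70].any()

    def test_leading_trailing_invalid_untouched(self):
        x = np.arange(30, dtype=float)[:, None]
        valid = np.ones(30, bool)
        valid[:3] = False
        valid[-2:] = False
        _, newvalid, _ = interpolate_gaps(x, valid)
        assert not newvalid[:3].any() and not newvalid[-2:].any()


class TestButterZeroLag:
    FS = 120.0

    def test_constant_series_unchanged(self):
        x = np.full(400, 11.0)
        y = butter_zero_lag(x, FilterSpec(6.0, self.FS))
        np.testing.assert_allclose(y, 11.0, atol=1e-9)

    def test_passband_amplitude_and_zero_lag(self):
        t = np.arange(1200) / self.FS
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butter_zero_lag(x, FilterSpec(6.0, self.FS))
        core = slice(200, -200)
        assert y[core].std() / x[core].std() == pytest.approx(1.0, abs=0.01)
        xc = np.correlate(y[core] - y[core].mean(), x[core] - x[core].mean(), "full")
        assert np.argmax(xc) == len(xc) // 2  # peak at lag 0

    def test_stopband_attenuation_matches_butterworth_magnitude(self):
        t = np.arange(1200) / self.FS
        x = np.sin(2 * np.pi * 30.0 * t)
        y = butter_zero_lag(x, FilterSpec(6.0, self.FS))
        core = slice(200, -200)
        gain = y[core].std() / x[core].std()
        fc_design = 6.0 * DUAL_PASS_CUTOFF_CORRECTION
        analytic = 1.0 / (1.0 + (30.0 / fc_design) ** 4)
        assert gain < 0.02
        assert gain == pytest.approx(analytic, abs=0.01)

    def test_time_reversal_symmetry(self, rng):
        x = rng.normal(size=600)
        spec = FilterSpec(8.0, self.FS)
        fwd = butter_zero_lag(x, spec)
        rev = butter_zero_lag(x[::-1], spec)[::-1]
        core = slice(100, -100)
        np.testing.assert_allclose(fwd[core], rev[core], rtol=1e-9, atol=1e-9)

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            FilterSpec(60.0, self.FS)


class TestResidualAnalysisCutoff:
    FS = 120.0

    def test_white_noise_selects_near_smallest_candidate(self):
        grid = np.arange(0.5, 0.9 * 60 + 1e-9, 0.5)  # the default grid
        tenth_pct = np.percentile(grid, 10)
        picks = [
            residual_analysis_cutoff(
                np.random.default_rng(s).normal(0, 2, 600), self.FS
            )
            for s in range(50)
        ]
        assert np.mean(picks) <= tenth_pct

    def test_noiseless_sinusoid_returns_largest_candidate(self):
        t = np.arange(600) / self.FS
        x = 100 * np.sin(2 * np.pi * 2 * t)
        grid = np.arange(0.5, 0.9 * 60 + 1e-9, 0.5)  # the default grid
        assert residual_analysis_cutoff(x, self.FS) == grid[-1]

    def test_sinusoid_plus_noise_lands_in_plausible_band(self):
        t = np.arange(600) / self.FS
        for seed in range(5):
            x = 100 * np.sin(2 * np.pi * 2 * t) + np.random.default_rng(seed).normal(0, 2, 600)
            assert 2.0 <= residual_analysis_cutoff(x, self.FS) <= 12.0

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        t = np.arange(400) / self.FS
        x = 50 * np.sin(2 * np.pi * 3 * t) + np.random.default_rng(seed).normal(0, 1.5, 400)
        assert residual_analysis_cutoff(x, self.FS) == residual_analysis_cutoff(scale * x, self.FS)

    def test_degenerate_noise_band_rejected(self):
        with pytest.raises(ConfigError):
            residual_analysis_cutoff(
                np.random.default_rng(0).normal(size=300),
                self.FS,
                grid=np.array([1.0, 2.0, 3.0]),
                noise_band=(0.6, 0.9),
            )


class TestCleaningEfficacy:
    def test_post_cleaning_error_below_pre_cleaning(self, rng):
        cfg = SceneConfig(task="walk", duration=2.0, seed=5)
        truth = generate_skeleton_motion(cfg)
        noisy = truth.copy()
        noisy.data = noisy.data + rng.normal(0, 2, noisy.data.shape)
        corrupted, log = inject_swaps(noisy, 0.1, rng)
        corrected, _ = correct_lr_swaps(corrupted)
        pre = np.mean(np.abs(corrupted.data - truth.data))
        post = np.mean(np.abs(corrected.data - truth.data))
        assert post < pre
        undone = sum(
            np.allclose(corrected.data[t, l], noisy.data[t, l])
            and np.allclose(corrected.data[t, r], noisy.data[t, r])
            for t, (l, r) in log
        )
        assert undone / len(log) >= 0.95
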