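"""Generator correctness: noises, cascades, samplers, two-state traces, frames."""

import numpy as np
import pytest
from scipy import stats

import mfkinetics as mk
from mfkinetics.synthetic import blob_mask


class TestNoise:
    def test_white_is_uncorrelated(self):
        x = mk.generate_noise("white", 2 ** 16, seed=1).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.02

    def test_brown_is_cumsum_of_white_same_seed(self):
        w = mk.generate_noise("white", 1024, seed=7).values
        b = mk.generate_noise("brown", 1024, seed=7).values
        np.testing.assert_array_equal(b, np.cumsum(w))

    def test_bit_reproducible(self):
        for kind in ("white", "pink", "brown"):
            a = mk.generate_noise(kind, 256, seed=5).values
            b = mk.generate_noise(kind, 256, seed=5).values
            np.testing.assert_array_equal(a, b)

    def test_pink_periodogram_slope(self):
        """Independent oracle: log-log periodogram regression over mid-band."""
        x = mk.generate_noise("pink", 2 ** 16, seed=3).values
        freqs = np.fft.rfftfreq(x.size)
        power = np.abs(np.fft.rfft(x)) ** 2
        band = (freqs > 1e-3) & (freqs < 1e-1)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(power[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_invalid_inputs(self):
        with pytest.raises(mk.ConfigurationError):
            mk.generate_noise("violet", 128, seed=0)
        with pytest.raises(mk.InputError):
            mk.generate_noise("white", 32, seed=0)


class TestCascade:
    def test_sigma_zero_gives_all_ones(self):
        out = mk.generate_cascade(10, 0.0, seed=123)
        np.testing.assert_array_equal(out.values, np.ones(1024))
        assert out.values.size == 2 ** 10

    def test_leaves_are_products_of_branch_weights(self):
        """Each leaf equals the product of the weights on its root-to-leaf path."""
        series, tree = mk.generate_cascade(2, 0.5, seed=11, return_weights=True)
        w1, w2 = tree
        expected = np.array([w1[0] * w2[0], w1[0] * w2[1],
                             w1[1] * w2[2], w1[1] * w2[3]])
        np.testing.assert_allclose(series.values, expected, rtol=1e-12)

    def test_log_mass_identity(self):
        """Mean log value equals the sum over levels of the mean log weight."""
        series, tree = mk.generate_cascade(8, 0.4, seed=2, return_weights=True)
        expected = sum(np.mean(np.log(w)) for w in tree)
        assert np.mean(np.log(series.values)) == pytest.approx(expected, abs=1e-10)

    def test_positive_and_bounds(self):
        assert np.all(mk.generate_cascade(6, 1.0, seed=9).values > 0)
        with pytest.raises(mk.InputError):
            mk.generate_cascade(0, 0.1, seed=0)
        with pytest.raises(mk.InputError):
            mk.generate_cascade(25, 0.1, seed=0)


class TestTruncatedPowerLaw:
    def test_cdf_matches_empirical(self, rng):
        a, lo, hi = 1.89, 0.1, 200.0
        samples = mk.sample_truncated_power_law(a, lo, hi, 100_000, rng)
        assert samples.min() >= lo and samples.max() <= hi
        ks = stats.kstest(samples, lambda t: mk.truncated_power_law_cdf(t, a, lo, hi))
        assert ks.statistic < 0.01

    def test_invalid_bounds(self, rng):
        with pytest.raises(mk.InputError):
            mk.sample_truncated_power_law(1.5, 2.0, 1.0, 10, rng)
        with pytest.raises(mk.InputError):
            mk.sample_truncated_power_law(0.9, 0.1, 1.0, 10, rng)


class TestFractionalGaussianNoise:
    def test_hurst_half_is_white(self):
        rng = np.random.default_rng(3)
        x = mk.fractional_gaussian_noise(0.5, 4096, rng)
        assert abs(np.corrcoef(x[:-1], x[1:])[0, 1]) < 0.05

    def test_lag_one_autocorrelation_matches_theory(self):
        """fGn lag-1 autocorrelation is 2^(2H-1) - 1."""
        hurst = 0.8
        rng = np.random.default_rng(4)
        x = mk.fractional_gaussian_noise(hurst, 2 ** 14, rng)
        expected = 2 ** (2 * hurst - 1) - 1
        assert np.corrcoef(x[:-1], x[1:])[0, 1] == pytest.approx(expected, abs=0.05)


class TestTwoStateGenerator:
    def test_duration_sum_equals_trace_length(self, two_state_pair):
        series, truth = two_state_pair
        assert truth.total_frames() == series.n
        assert truth.boundary_policy == "keep"

    def test_trace_is_bimodal_with_empty_valley(self):
        params = mk.TwoStateParams(n_rounds=300, level_active=30.0,
                                   level_inactive=0.0, amplitude_noise_sd=2.0)
        series, _ = mk.generate_two_state_activity(params, seed=8)
        counts = series.counts
        gap = np.mean((counts > 8) & (counts < 16))
        assert gap < 1e-3
        assert np.mean(counts < 8) > 0.1 and np.mean(counts > 16) > 0.1

    def test_exponent_recovery_through_fit(self):
        """Downstream log-log fit recovers the generator exponents.

        dt = 0.01 keeps frame rounding far below the 0.3-5 s fit band.
        """
        params = mk.TwoStateParams(a_active=1.89, a_inactive=1.62,
                                   n_rounds=20_000, dt=0.01,
                                   t_max_active=50.0, t_max_inactive=200.0)
        _, truth = mk.generate_two_state_activity(params, seed=3)
        fit_a = mk.fit_powerlaw(mk.residence_npd(truth.active_durations),
                                fit_range=mk.ACTIVE_FIT_RANGE)
        fit_i = mk.fit_powerlaw(mk.residence_npd(truth.inactive_durations),
                                fit_range=mk.INACTIVE_FIT_RANGE)
        assert fit_a.a == pytest.approx(1.89, abs=0.15)
        assert fit_i.a == pytest.approx(1.62, abs=0.15)

    def test_invalid_params(self):
        with pytest.raises(mk.InputError):
            mk.generate_two_state_activity(
                mk.TwoStateParams(t_min_active=2.0, t_max_active=1.0), seed=0)
        with pytest.raises(mk.InputError):
            mk.generate_two_state_activity(mk.TwoStateParams(n_rounds=0), seed=0)


class TestFrameStack:
    def test_static_scene_counts_zero(self):
        stack = mk.generate_frame_stack(10, blob_radius=6, step=0, seed=0)
        counts = mk.count_active_pixels(stack).counts
        np.testing.assert_array_equal(counts, np.zeros(9))

    def test_subthreshold_flicker_counts_zero(self):
        rng = np.random.default_rng(0)
        base = np.full((5, 40, 60), 200.0)
        flicker = base + rng.uniform(-5, 5, size=base.shape)
        stack = mk.FrameStack(frames=np.clip(np.rint(flicker), 0, 255).astype(np.uint8))
        counts = mk.count_active_pixels(stack, intensity_threshold=12).counts
        np.testing.assert_array_equal(counts, 0)

    def test_trajectory_must_stay_inside(self):
        with pytest.raises(mk.InputError):
            mk.generate_frame_stack(50, blob_radius=8, step=10, width=100)

    def test_disjoint_footprints_match_set_difference_oracle(self):
        """Signed counts = vacated footprint; |diff| counts = symmetric difference."""
        r, step = 6.0, 14.0
        stack = mk.generate_frame_stack(6, blob_radius=r, step=step,
                                        height=80, width=200, seed=0)
        signed = mk.count_active_pixels(stack).counts
        both = mk.count_active_pixels(stack, absolute=True).counts
        x0, y0 = r + 1.0, 40.0
        for t in range(5):
            old = blob_mask(x0 + step * t, y0, r, 80, 200)
            new = blob_mask(x0 + step * (t + 1), y0, r, 80, 200)
            assert not np.any(old & new)          # footprints disjoint
            assert signed[t] == np.sum(old & ~new)
            assert both[t] == np.sum(old ^ new)
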