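"""MF-DFA: profile, fluctuation function, Hurst exponents, spectrum."""

import numpy as np
import pytest

import mfkinetics as mk
from mfkinetics.mfdfa import FluctuationMatrix


def plain_dfa(series, scales):
    """Independent loop-based detrended fluctuation analysis (the oracle).

    Classic DFA: integrate the mean-subtracted series, cut into windows of
    size s from both ends, remove a least-squares line per window, and take
    the root mean square of the residuals over all windows.
    """
    x = np.asarray(series, dtype=float)
    y = np.cumsum(x - np.mean(x))
    out = []
    for s in scales:
        ns = len(y) // s
        f2s = []
        starts = [i * s for i in range(ns)] + \
                 [len(y) - (i + 1) * s for i in range(ns)]
        for st in starts:
            seg = y[st:st + s]
            t = np.arange(s)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            f2s.append(np.mean(resid ** 2))
        out.append(np.sqrt(np.mean(f2s)))
    return np.asarray(out)


class TestProfile:
    def test_constant_input_gives_zero_profile(self):
        prof = mk.profile(np.full(32, 3.7))
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_hand_computed_profile(self):
        prof = mk.profile([1.0, -1.0, 1.0, -1.0] * 4)
        np.testing.assert_allclose(prof.values[:4], [1.0, 0.0, 1.0, 0.0])

    def test_last_value_is_near_zero(self, rng):
        x = rng.normal(5.0, 2.0, 1000)
        prof = mk.profile(x)
        assert abs(prof.values[-1]) < 1e-6 * np.sum(np.abs(x))

    def test_white_noise_profile_diffuses_linearly(self):
        """Var of the profile grows proportionally to the index (random walk)."""
        n, reps = 1024, 200
        rng = np.random.default_rng(6)
        profs = np.stack([mk.profile(rng.standard_normal(n)).values
                          for _ in range(reps)])
        v_quarter = profs[:, n // 4].var()
        v_half = profs[:, n // 2].var()
        # Brownian-bridge-corrected growth: var(k) ~ k (1 - k/n)
        expected_ratio = (n // 2 * (1 - 0.5)) / (n // 4 * (1 - 0.25))
        assert v_half / v_quarter == pytest.approx(expected_ratio, rel=0.35)


class TestFluctuationFunction:
    def test_q2_matches_plain_dfa_oracle(self, rng):
        """Order-2 column reduces to classic DFA to 1e-10 on 20 random inputs."""
        scales = np.array([8, 16, 32, 64])
        for i in range(20):
            kind = i % 3
            if kind == 0:
                x = rng.standard_normal(512)
            elif kind == 1:
                x = np.cumsum(rng.standard_normal(512))
            else:
                x = rng.pareto(1.5, 512)
            fmat = mk.fluctuation_function(mk.profile(x), scales=scales,
                                           q_values=np.array([2.0]))
            np.testing.assert_allclose(fmat.F[0], plain_dfa(x, scales),
                                       rtol=0, atol=1e-10)

    def test_linear_trend_profile_is_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fmat = mk.fluctuation_function(np.arange(256, dtype=float),
                                           scales=np.array([8, 16, 32]))
        assert fmat.degenerate
        np.testing.assert_array_equal(fmat.F, 0.0)
        with pytest.raises(mk.DegenerateSeriesError):
            mk.generalized_hurst(fmat)

    def test_F_nondecreasing_in_q(self):
        """Generalized-mean inequality: F(q, s) grows with q at fixed s."""
        x = mk.generate_noise("white", 4096, seed=12).values
        fmat = mk.fluctuation_function(mk.profile(x))
        for j in range(fmat.scales.size):
            col = fmat.F[:, j]
            assert np.all(np.diff(col) >= -1e-12)

    def test_dual_end_segmentation_counts(self):
        x = mk.generate_noise("white", 1000, seed=1).values
        fmat = mk.fluctuation_function(mk.profile(x), scales=np.array([16, 64]))
        np.testing.assert_array_equal(fmat.n_segments, [2 * (1000 // 16),
                                                        2 * (1000 // 64)])

    def test_scale_validation(self):
        prof = mk.profile(np.random.default_rng(0).standard_normal(128))
        with pytest.raises(mk.InputError):
            mk.fluctuation_function(prof, scales=np.array([8, 64]))  # > n/4
        with pytest.raises(mk.InputError):
            mk.fluctuation_function(prof, scales=np.array([16, 8]))


class TestGeneralizedHurst:
    def test_exact_scaling_recovered_to_machine_precision(self):
        scales = np.array([8, 16, 32, 64, 128])
        q = mk.default_q_grid(-5, 5, 11)
        F = np.tile(scales.astype(float) ** 0.7, (q.size, 1))
        fmat = FluctuationMatrix(q_values=q, scales=scales, F=F,
                                 n_segments=np.full(5, 10),
                                 excluded_segments=np.zeros(5, dtype=int))
        H = mk.generalized_hurst(fmat)
        np.testing.assert_allclose(H, 0.7, atol=1e-12)

    def test_fit_range_needs_four_scales(self):
        scales = np.array([8, 16, 32, 64, 128])
        q = mk.default_q_grid(-5, 5, 11)
        fmat = FluctuationMatrix(q_values=q, scales=scales,
                                 F=np.ones((q.size, 5)),
                                 n_segments=np.full(5, 10),
                                 excluded_segments=np.zeros(5, dtype=int))
        with pytest.raises(mk.FitError):
            mk.generalized_hurst(fmat, fit_range=(8, 20))


class TestSingularitySpectrum:
    def test_monofractal_limit(self):
        q = mk.default_q_grid()
        spec = mk.singularity_spectrum(np.full(q.size, 0.7), q)
        np.testing.assert_allclose(spec.h, 0.7, atol=1e-12)
        np.testing.assert_allclose(spec.D, 1.0, atol=1e-12)
        assert spec.h_peak == pytest.approx(0.7, abs=1e-12)
        assert spec.width == pytest.approx(0.0, abs=1e-12)

    def test_D_at_q_zero_is_exactly_one(self, rng):
        q = mk.default_q_grid()
        H = 1.0 / (1.0 + np.exp(0.2 * q)) + 0.5   # smooth decreasing H(q)
        spec = mk.singularity_spectrum(H, q)
        i0 = np.argmin(np.abs(q))
        assert spec.D[i0] == 1.0
        assert np.all(spec.D <= 1.0 + 1e-6)
        assert min(spec.h) <= spec.h_peak <= max(spec.h)

    def test_folded_spectrum_is_flagged_not_raised(self):
        q = mk.default_q_grid(-5, 5, 21)
        H = 0.5 + 0.05 * np.sin(q)                # non-monotone
        spec = mk.singularity_spectrum(H, q)
        assert "non_monotone_h" in spec.quality_flags


class TestSpectrumPipeline:
    def test_binomial_cascade_width_matches_analytic(self):
        """Deterministic p-model: width has the closed form a(-q*) - a(q*)."""
        p = 0.3
        x = np.ones(1)
        for _ in range(12):
            x = np.concatenate([p * x, (1 - p) * x])

        def alpha(q):
            num = p ** q * np.log(p) + (1 - p) ** q * np.log(1 - p)
            return -num / ((p ** q + (1 - p) ** q) * np.log(2))

        spec = mk.mfdfa_spectrum(x)
        analytic = alpha(-10.0) - alpha(10.0)
        assert spec.width == pytest.approx(analytic, rel=0.10)

    def test_deterministic_for_fixed_seed(self):
        x = mk.generate_noise("pink", 2 ** 12, seed=5).values
        a = mk.mfdfa_spectrum(x)
        b = mk.mfdfa_spectrum(x)
        np.testing.assert_array_equal(a.h, b.h)
        assert a.h_peak == b.h_peak and a.width == b.width

    def test_white_noise_hurst_near_half(self):
        x = mk.generate_noise("white", 2 ** 14, seed=21).values
        spec = mk.mfdfa_spectrum(x)
        assert spec.h_peak == pytest.approx(0.5, abs=0.12)

    def test_residence_series_floor_and_warning(self):
        rng = np.random.default_rng(0)
        with pytest.raises(mk.InputError):
            mk.analyze_residence_series(rng.pareto(2, 50) + 0.1)
        with pytest.warns(UserWarning, match="noisy"):
            mk.analyze_residence_series(rng.pareto(2, 200) + 0.1)

    def test_ground_truth_hurst_self_consistency(self):
        """iid-ordered bout durations give h_peak near 0.5.

        Mild tails (t_max = 10 s) keep the finite-size heavy-tail bias of
        the local Hurst exponent small.
        """
        params = mk.TwoStateParams(n_rounds=4096, t_max_active=10.0,
                                   correlation_hurst=0.5)
        _, truth = mk.generate_two_state_activity(params, seed=11)
        spec = mk.analyze_residence_series(truth.active_durations)
        assert spec.h_peak == pytest.approx(0.5, abs=0.1)
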