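import numpy as np
import pytest
from scipy.optimize import brentq

from desmokit.frap import (FrapFit, FrapTrace, fit_two_phase, halftime,
                           normalize_trace, qc_filter, summarize_cohort,
                           two_phase_model)
from desmokit.synthetic import FRAP_PRESETS, FrapPreset, gen_frap_traces


class TestHalftime:
    def test_unit_and_printed_values(self):
        assert halftime(np.log(2)) == pytest.approx(1.0)
        assert halftime(np.log(2) / 231.0) == pytest.approx(231.0)

    def test_matches_root_finding_oracle(self, rng):
        # independent oracle: solve 1 - exp(-k t) = 0.5 numerically
        for k in rng.uniform(1e-4, 1.0, size=20):
            t_star = brentq(lambda t: 1 - np.exp(-k * t) - 0.5, 1e-9, 1e6)
            assert halftime(k) == pytest.approx(t_star, abs=1e-9 * t_star + 1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            halftime(0.0)


class TestNormalizeTrace:
    def test_midpoint_maps_to_half(self):
        tr = normalize_trace([0, 10], [0, 50], pre_bleach_mean=100,
                             post_bleach_value=0)
        assert tr.values[1] == pytest.approx(0.5)

    def test_flat_at_post_bleach_gives_zero_trace(self):
        tr = normalize_trace([0, 10, 20], [7.0, 7.0, 7.0],
                             pre_bleach_mean=20.0, post_bleach_value=7.0)
        np.testing.assert_array_equal(tr.values, 0.0)

    def test_inverts_affine_transform(self, rng):
        # scale/offset a known normalized trace, then normalize it back
        truth = gen_frap_traces(FRAP_PRESETS["DSC2A"], 1, noise_sd=0.0,
                                seed=0)[0]
        pre, post = 837.0, 214.5
        raw = truth.values * (pre - post) + post
        back = normalize_trace(truth.times, raw, pre, post)
        np.testing.assert_allclose(back.values, truth.values, atol=1e-12)

    def test_degenerate_bleach_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_trace([0, 10], [1, 2], pre_bleach_mean=5,
                            post_bleach_value=5)


class TestFitTwoPhase:
    def test_noiseless_exact_recovery(self):
        p = FrapPreset("toy", 0.5, 200.0, fast_halftime=20.0, fast_share=0.1)
        tr = gen_frap_traces(p, 1, noise_sd=0.0, seed=0)[0]
        fit = fit_two_phase(tr)
        assert fit.plateau == pytest.approx(0.5, rel=1e-6)
        assert fit.fast_share == pytest.approx(0.1, rel=1e-6)
        assert fit.halftime_fast_s == pytest.approx(20.0, rel=1e-6)
        assert fit.halftime_slow_s == pytest.approx(200.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nested_single_exponential(self):
        # fast share 0 collapses to one exponential; slow rate must match
        p = FrapPreset("mono", 0.4, 150.0, fast_halftime=15.0, fast_share=0.0)
        tr = gen_frap_traces(p, 1, noise_sd=0.0, seed=0)[0]
        fit = fit_two_phase(tr)
        assert fit.plateau == pytest.approx(0.4, rel=1e-5)
        assert fit.halftime_slow_s == pytest.approx(150.0, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_labels_swap_normalized(self):
        for seed in range(5):
            tr = gen_frap_traces(FRAP_PRESETS["DSG2"], 1, noise_sd=0.02,
                                 seed=seed)[0]
            fit = fit_two_phase(tr)
            assert fit.k_fast >= fit.k_slow > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_two_phase(FrapTrace(np.arange(5) * 10.0, np.zeros(5)))

    def test_mean_per_trace_plateau_near_truth_under_noise(self):
        traces = gen_frap_traces(FRAP_PRESETS["DSG2"], 50, noise_sd=0.02,
                                 seed=0)
        plateaus = [fit_two_phase(t).plateau for t in traces]
        assert np.mean(plateaus) == pytest.approx(0.269, abs=0.05)


class TestQcFilter:
    @staticmethod
    def _trace(tail=0.32):
        t = np.arange(0, 100, 10.0)
        v = np.linspace(0, tail, t.size)
        return FrapTrace(t, v)

    def test_low_r2_excluded(self):
        fit = FrapFit(0.3, 0.1, 0.03, 0.003, r_squared=0.84, converged=True)
        dec = qc_filter(fit, self._trace())
        assert (dec.keep, dec.reason) == (False, "low_r2")

    def test_plateau_deviation_excluded(self):
        fit = FrapFit(0.60, 0.1, 0.03, 0.003, r_squared=0.90, converged=True)
        dec = qc_filter(fit, self._trace(tail=0.32))
        assert (dec.keep, dec.reason) == (False, "plateau_deviation")

    def test_boundaries_are_kept(self):
        tr = self._trace(tail=0.32)
        tail_mean = float(np.mean(tr.values[-4:]))
        fit = FrapFit(tail_mean + 0.25, 0.1, 0.03, 0.003, r_squared=0.85,
                      converged=True)
        dec = qc_filter(fit, tr)
        assert (dec.keep, dec.reason) == (True, "kept")

    def test_monotone_in_thresholds(self, rng):
        # relaxing either threshold never excludes a previously kept trace
        for _ in range(50):
            r2 = rng.uniform(0.7, 1.0)
            plateau = rng.uniform(0.0, 1.0)
            tr = self._trace(tail=rng.uniform(0.0, 1.0))
            fit = FrapFit(plateau, 0.1, 0.03, 0.003, r_squared=r2,
                          converged=True)
            strict = qc_filter(fit, tr, r2_min=0.9, plateau_dev_max=0.2)
            relaxed = qc_filter(fit, tr, r2_min=0.8, plateau_dev_max=0.3)
            if strict.keep:
                assert relaxed.keep

    def test_short_trace_rejected(self):
        fit = FrapFit(0.3, 0.1, 0.03, 0.003, r_squared=0.99, converged=True)
        with pytest.raises(ValueError):
            qc_filter(fit, FrapTrace(np.array([0.0, 10, 20]), np.zeros(3)))


class TestCohortSummary:
    def test_noiseless_cohort_reproduces_preset(self):
        traces = gen_frap_traces(FRAP_PRESETS["DSG2"], 50, noise_sd=0.0,
                                 seed=0)
        s = summarize_cohort(traces, n_boot=0)
        assert s.halftime_slow_s == pytest.approx(231.0, abs=0.1)
        assert s.mobile_fraction_pct == pytest.approx(26.9, abs=0.1)

    def test_noiseless_pkp2_mobile_fraction(self):
        traces = gen_frap_traces(FRAP_PRESETS["PKP2"], 50, noise_sd=0.0,
                                 seed=0)
        s = summarize_cohort(traces, n_boot=0)
        assert s.mobile_fraction_pct == pytest.approx(53.3, abs=0.1)

    def test_identical_traces_have_zero_ci_width(self):
        tr = gen_frap_traces(FRAP_PRESETS["DSP"], 1, noise_sd=0.0, seed=0)[0]
        s = summarize_cohort([tr, tr, tr], n_boot=0)
        np.testing.assert_allclose(s.ci95_upper - s.ci95_lower, 0.0,
                                   atol=1e-12)

    def test_pooled_fit_invariant_to_duplication(self):
        traces = gen_frap_traces(FRAP_PRESETS["DSC2B"], 10, noise_sd=0.02,
                                 seed=4)
        s1 = summarize_cohort(traces, n_boot=0)
        s2 = summarize_cohort(traces * 2, n_boot=0)
        assert s2.mobile_fraction_pct == pytest.approx(
            s1.mobile_fraction_pct, abs=1e-6)
        assert s2.halftime_slow_s == pytest.approx(s1.halftime_slow_s,
                                                   rel=1e-6)

    def test_noisy_cohort_within_five_percent_relative(self):
        # pooled estimates at sd 0.02, n=50 recover the generator within 5%
        for name in ("DSG2", "PKP2", "DSC2B"):
            p = FRAP_PRESETS[name]
            traces = gen_frap_traces(p, 50, noise_sd=0.02, seed=0)
            s = summarize_cohort(traces, n_boot=0)
            assert s.mobile_fraction_pct / 100.0 == pytest.approx(
                p.mobile_fraction, rel=0.05)
            assert s.halftime_slow_s == pytest.approx(p.slow_halftime,
                                                      rel=0.05)

    def test_bootstrap_ci_contains_estimate(self):
        traces = gen_frap_traces(FRAP_PRESETS["PKP2"], 12, noise_sd=0.02,
                                 seed=6)
        s = summarize_cohort(traces, n_boot=60, seed=1)
        lo, hi = s.ci95_mobile
        assert lo <= s.mobile_fraction_pct <= hi

    def test_too_few_traces_rejected(self):
        tr = gen_frap_traces(FRAP_PRESETS["DSG2"], 2, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            summarize_cohort(tr, n_boot=0)


def test_model_intercept_is_zero():
    assert two_phase_model(0.0, 0.7, 0.3, 0.1, 0.01) == 0.0
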