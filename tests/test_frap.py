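"""FRAP chain: bleaching formulas, correction, normalization, fits."""

import math

import numpy as np
import pytest
from scipy import stats

from epipolarity import frap as fr
from epipolarity import synthetic as syn


def make_trace(i_pre=100.0, i0=30.0, u_end_frac=1.0, bg=0.0, n_post=33):
    t = fr.default_schedule()[:n_post]
    i_post = np.full(n_post, i0)
    u_post = np.full(n_post, i_pre)
    u_post[-1] = i_pre * u_end_frac
    return fr.FrapTrace(
        pupa_id="p0",
        roi_id="r0",
        orientation_class="PD",
        t_post=t,
        i_pre=np.full(3, i_pre),
        i_post=i_post,
        u_pre=np.full(3, i_pre),
        u_post=u_post,
        background=bg,
    )


class TestBleachingFormulas:
    @pytest.mark.parametrize("i0,expected", [(30.0, 70.0), (100.0, 0.0), (0.0, 100.0)])
    def test_initial_bleaching(self, i0, expected):
        assert fr.initial_bleaching(make_trace(i0=i0)) == pytest.approx(expected)

    def test_acquisition_bleaching(self):
        assert fr.acquisition_bleaching(make_trace(i_pre=1.0, u_end_frac=0.8)) == pytest.approx(20.0)
        assert fr.acquisition_bleaching(make_trace(u_end_frac=1.0)) == pytest.approx(0.0)
        tr = make_trace(i_pre=1.2, bg=0.2)
        tr.u_post[-1] = 0.9
        assert fr.acquisition_bleaching(tr) == pytest.approx(30.0)

    def test_qc_gates_follow_printed_bounds(self):
        # 60% initial bleach, low acquisition bleach: pass
        ok = fr.quality_control(make_trace(i0=40.0, u_end_frac=0.9))
        assert ok.passed and 50 <= ok.initial_bleaching_pct <= 75
        # 30% initial bleach: fail
        assert not fr.quality_control(make_trace(i0=70.0, u_end_frac=0.9)).passed
        # 30% acquisition bleach: fail
        bad = fr.quality_control(make_trace(i0=40.0, u_end_frac=0.7))
        assert not bad.passed and bad.acquisition_bleaching_pct == pytest.approx(30.0)
        # exactly 25% acquisition: fail (strict bound)
        assert not fr.quality_control(make_trace(i0=40.0, u_end_frac=0.75)).passed


class TestCorrection:
    def test_no_bleach_reduces_to_prebleach_ratio(self):
        tr = make_trace(i_pre=100.0, i0=30.0)
        _, a_post = fr.correct_trace(tr)
        assert np.allclose(a_post, tr.i_post / 100.0)

    def test_multiplicative_decay_cancels_exactly(self, rng):
        n = 33
        t = fr.default_schedule()
        b = 0.99 ** np.arange(n)
        r = 100.0 * (0.4 + 0.6 * 0.8 * (1 - np.exp(-0.02 * t)))
        tr = fr.FrapTrace(
            "p", "r", "PD", t,
            i_pre=np.full(3, 100.0), i_post=b * r,
            u_pre=np.full(3, 100.0), u_post=b * 100.0,
            background=0.0,
        )
        _, a_post = fr.correct_trace(tr)
        assert np.allclose(a_post, r / 100.0, atol=1e-12)

    def test_background_subtraction_exact(self):
        tr0 = make_trace(bg=0.0)
        tr1 = make_trace(bg=0.0)
        tr1.i_pre += 10
        tr1.i_post += 10
        tr1.u_pre += 10
        tr1.u_post += 10
        tr1.background = 10.0
        _, a0 = fr.correct_trace(tr0)
        _, a1 = fr.correct_trace(tr1)
        assert np.allclose(a0, a1)

    def test_scale_invariance(self):
        """Scaling all intensities and background by c > 0 changes nothing."""
        tr = make_trace(bg=5.0, i0=40.0, u_end_frac=0.9)
        for c in (0.25, 7.0):
            trc = make_trace(bg=5.0 * c, i0=40.0 * c, i_pre=100.0 * c, u_end_frac=0.9)
            _, a = fr.correct_trace(tr)
            _, ac = fr.correct_trace(trc)
            assert np.allclose(a, ac)
            assert np.allclose(fr.normalize_trace(a), fr.normalize_trace(ac))


class TestNormalization:
    def test_examples(self):
        a = np.array([0.3, 0.3, 0.65, 1.0])
        n = fr.normalize_trace(a)
        assert n[0] == 0.0
        assert n[2] == pytest.approx(0.5)
        assert n[3] == pytest.approx(1.0)

    def test_no_bleach_depth_rejected(self):
        with pytest.raises(ValueError):
            fr.normalize_trace(np.array([1.0, 1.1]))


class TestOnePhaseFit:
    def test_noiseless_recovery(self):
        t = fr.default_schedule()
        y = 0.8 * (1 - np.exp(-0.02 * t))
        fit = fr.fit_one_phase(y, t)
        assert fit.y_max == pytest.approx(0.8, abs=1e-6)
        assert fit.alpha == pytest.approx(0.02, abs=1e-6)

    def test_half_life_consistency(self):
        t = fr.default_schedule()
        fit = fr.fit_one_phase(0.7 * (1 - np.exp(-0.0231 * t)), t)
        assert fit.half_life == pytest.approx(math.log(2) / fit.alpha, abs=1e-12)
        assert fit.half_life == pytest.approx(30.0, abs=0.01)

    def test_monte_carlo_calibration(self, rng):
        """Bias and CI coverage on self-generated noisy data."""
        t = fr.default_schedule()
        truth = 0.8 * (1 - np.exp(-0.02 * t))
        est, covered = [], 0
        n_rep = 200
        for _ in range(n_rep):
            y = truth + rng.normal(0, 0.05, t.size)
            fit = fr.fit_one_phase(y, t)
            est.append(fit.y_max)
            if fit.y_max_ci[0] <= 0.8 <= fit.y_max_ci[1]:
                covered += 1
        assert abs(np.mean(est) - 0.8) <= 0.02
        assert covered / n_rep >= 0.90

    def test_residuals_mean_zero_and_noise_monotone(self, rng):
        t = fr.default_schedule()
        truth = 0.8 * (1 - np.exp(-0.02 * t))
        errs = []
        for sigma in (0.01, 0.05, 0.15):
            e = []
            for _ in range(60):
                y = truth + rng.normal(0, sigma, t.size)
                fit = fr.fit_one_phase(y, t)
                e.append(abs(fit.y_max - 0.8))
            errs.append(np.mean(e))
        assert errs[0] < errs[1] < errs[2]


class TestTwoPhaseFit:
    def test_exact_two_phase_recovery(self):
        t = fr.default_schedule()
        y = 0.4 * (1 - np.exp(-0.1 * t)) + 0.4 * (1 - np.exp(-0.005 * t))
        fit = fr.fit_two_phase(y, t)
        assert fit.extra["A1"] == pytest.approx(0.4, abs=1e-4)
        assert fit.extra["alpha1"] == pytest.approx(0.1, abs=1e-4)
        assert fit.extra["A2"] == pytest.approx(0.4, abs=1e-4)
        assert fit.extra["alpha2"] == pytest.approx(0.005, abs=1e-4)
        assert fit.extra["alpha1"] > fit.extra["alpha2"]

    def test_one_phase_data_collapses(self):
        t = fr.default_schedule()
        y = 0.8 * (1 - np.exp(-0.02 * t))
        fit = fr.fit_two_phase(y, t)
        a1, a2 = fit.extra["alpha1"], fit.extra["alpha2"]
        collapse = fit.extra["A1"] < 1e-3 or fit.extra["A2"] < 1e-3 or abs(a1 - a2) / a1 < 0.05
        assert collapse
        assert fit.y_max == pytest.approx(0.8, abs=1e-3)


class TestAggregation:
    def test_identical_groups_not_significant(self):
        traces = syn.make_frap(syn.FrapTruth(y_max=0.7, alpha=0.02), n_pupae=3, seed=3)
        rep = fr.aggregate_and_compare(traces, compare_by="orientation")
        (cmp_,) = rep["comparisons"]
        assert cmp_.delta_y_max == pytest.approx(0.0, abs=1e-9)
        assert cmp_.p_value > 0.99

    def test_single_pupa_group_refused(self):
        traces = syn.make_frap(syn.FrapTruth(), n_pupae=1, seed=3)
        with pytest.raises(ValueError):
            fr.aggregate_and_compare(traces, compare_by="orientation")

    def test_t_statistic_matches_textbook_formula(self):
        a = np.array([0.61, 0.64, 0.66])
        b = np.array([0.71, 0.74, 0.78])
        # closed-form pooled two-sample t
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_manual = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        res = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t_manual, rel=1e-12)
        # and the pipeline reports exactly this test on per-pupa plateaus
        tr_a = syn.make_frap(syn.FrapTruth(y_max={"PD": 0.6, "AP": 0.8}, alpha=0.02),
                             n_pupae=3, seed=9)
        rep = fr.aggregate_and_compare(tr_a, compare_by="orientation")
        (cmp_,) = rep["comparisons"]
        ya = rep["per_pupa_fits"].query("orientation == 'AP'")["y_max"].to_numpy()
        yp = rep["per_pupa_fits"].query("orientation == 'PD'")["y_max"].to_numpy()
        expect = stats.ttest_ind(ya, yp, equal_var=True)
        if np.isfinite(expect.statistic):
            assert cmp_.t_statistic == pytest.approx(float(expect.statistic))
        assert cmp_.y_max_a == pytest.approx(0.8, abs=1e-6)
        assert cmp_.y_max_b == pytest.approx(0.6, abs=1e-6)
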