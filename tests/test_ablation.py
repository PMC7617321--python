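"""Ellipse fitting, axis relaxation dynamics, recoil velocities."""

import math

import numpy as np
import pytest

from epipolarity import (
    analyze_recoil,
    compare_axes,
    fit_axis_dynamics,
    fit_ellipse,
    initial_recoil_velocity,
)
from epipolarity import synthetic as syn


def ellipse_points(a, b, theta_deg=0.0, n=12, center=(0.0, 0.0)):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    t = math.radians(theta_deg)
    u = np.array([math.cos(t), -math.sin(t)])
    w = np.array([-math.sin(t), -math.cos(t)])
    return np.asarray(center) + np.outer(a * np.cos(phi), u) + np.outer(b * np.sin(phi), w)


class TestFitEllipse:
    def test_exact_axis_aligned(self):
        f = fit_ellipse(ellipse_points(10, 5))
        assert f.major_length == pytest.approx(20.0, abs=1e-9)
        assert f.minor_length == pytest.approx(10.0, abs=1e-9)
        assert f.orientation == pytest.approx(0.0, abs=1e-6)

    def test_circle_orientation_convention(self):
        f = fit_ellipse(ellipse_points(5, 5))
        assert f.major_length == pytest.approx(10.0, abs=1e-6)
        assert f.orientation == 0.0

    def test_rotation_translation_equivariance(self):
        for theta in (20.0, 77.0, 155.0):
            f = fit_ellipse(ellipse_points(8, 4, theta_deg=theta, center=(33.0, -12.0)))
            d = abs(f.orientation - theta) % 180.0
            assert min(d, 180.0 - d) < 1e-6
            assert f.major_length == pytest.approx(16.0, abs=1e-9)
            assert np.allclose(f.center, [33.0, -12.0], atol=1e-9)

    def test_jittered_points_monte_carlo(self, rng):
        errs = []
        for _ in range(200):
            pts = ellipse_points(10, 5, n=20) + rng.normal(0, 0.05, (20, 2))
            f = fit_ellipse(pts)
            errs.append(abs(f.major_length - 20.0) / 2.0)  # semi-axis error
        assert np.mean(errs) < 0.05

    def test_degenerate_rejected(self):
        line = np.column_stack([np.arange(6.0), np.arange(6.0)])
        with pytest.raises(ValueError):
            fit_ellipse(line)
        with pytest.raises(ValueError):
            fit_ellipse(np.zeros((4, 2)))


class TestAxisDynamics:
    def test_noiseless_recovery(self):
        t = np.arange(1.0, 61.0)
        L = 16.0 - (16.0 - 12.0) * np.exp(-t / 20.0)
        d = fit_axis_dynamics(L, t)
        assert d.L0 == pytest.approx(12.0, abs=1e-6)
        assert d.L_inf == pytest.approx(16.0, abs=1e-6)
        assert d.tau == pytest.approx(20.0, abs=1e-5)

    def test_constant_series_flagged(self):
        t = np.arange(1.0, 11.0)
        d = fit_axis_dynamics(np.full(10, 9.0), t)
        assert "no_recoil" in d.flags
        assert d.L_inf == pytest.approx(d.L0)

    def test_noisy_recovery_within_5pct(self, rng):
        t = np.arange(1.0, 121.0)
        truth = 16.0 - 4.0 * np.exp(-t / 20.0)
        rel = []
        for _ in range(200):
            d = fit_axis_dynamics(truth + rng.normal(0, 0.1, t.size), t)
            rel.append(abs(d.tau - 20.0) / 20.0)
        assert np.mean(rel) < 0.05


class TestRecoilVelocity:
    def test_linear_series(self):
        t = np.arange(0.0, 10.0)
        assert initial_recoil_velocity(10 + 2 * t, t) == pytest.approx(2.0)
        assert initial_recoil_velocity(np.full(10, 4.0), t) == pytest.approx(0.0)

    def test_exponential_matches_closed_form_ols(self):
        tau, Linf, delta = 20.0, 16.0, 4.0
        t = np.arange(0.0, 12.0)
        L = Linf - delta * np.exp(-t / tau)
        tt = np.arange(1.0, 7.0)
        y = Linf - delta * np.exp(-tt / tau)
        tc = tt - tt.mean()
        slope = float((tc * (y - y.mean())).sum() / (tc * tc).sum())
        assert initial_recoil_velocity(L, t) == pytest.approx(slope, abs=1e-9)

    def test_shift_and_scale_behavior(self):
        t = np.arange(0.0, 10.0)
        L = 10 + 1.5 * t + np.sin(t) * 0.0
        v = initial_recoil_velocity(L, t)
        assert initial_recoil_velocity(L + 100.0, t) == pytest.approx(v)
        assert initial_recoil_velocity(3.0 * L, t) == pytest.approx(3.0 * v)

    def test_missing_frames_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        with pytest.raises(ValueError):
            initial_recoil_velocity(np.ones(6), t)


class TestCompareAxes:
    def test_identical_axes_p_near_one(self):
        from epipolarity.ablation import RecoilResult

        results = [
            RecoilResult(pupa_id=f"p{i}", v_major=0.15, v_minor=0.15,
                         major_dynamics=None, minor_dynamics=None, anisotropy=1.0)
            for i in range(3)
        ]
        (rep,) = compare_axes(results)
        assert rep.p_value > 0.99
        assert rep.isotropic

    def test_isotropic_null_mostly_not_significant(self, rng):
        hits = 0
        n_rep = 30
        for i in range(n_rep):
            series = syn.make_recoil(
                syn.RecoilTruth(v_major=0.15, v_minor=0.15, noise_sd=0.03, n_frames=8),
                n_pupae=5, seed=100 + i,
            )
            (rep,) = compare_axes([analyze_recoil(s) for s in series])
            hits += not rep.isotropic
        assert hits / n_rep <= 0.2

    def test_anisotropy_recovered_and_detected(self):
        series = syn.make_recoil(
            syn.RecoilTruth(v_major=0.2, v_minor=0.1, noise_sd=0.02, n_frames=12),
            n_pupae=11, seed=4,
        )
        results = [analyze_recoil(s) for s in series]
        (rep,) = compare_axes(results)
        assert rep.anisotropy == pytest.approx(2.0, rel=0.10)
        assert rep.p_value < 0.05 and not rep.isotropic

    def test_single_pupa_refused(self):
        series = syn.make_recoil(syn.RecoilTruth(n_frames=12), n_pupae=1, seed=2)
        with pytest.raises(ValueError):
            compare_axes([analyze_recoil(s) for s in series])
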