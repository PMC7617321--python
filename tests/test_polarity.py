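"""PCA polarity scoring, coarse-graining and weighted histograms."""

import math

import numpy as np
import pytest

from epipolarity import (
    CellPolarity,
    coarse_grain,
    pca_polarity,
    shape_normalize,
    weighted_angle_histogram,
)
from conftest import circle_boundary


def painted_circle(theta0_deg, m, n=240):
    phi, pts = circle_boundary(n)
    inten = 1.0 + m * np.cos(2.0 * (phi - math.radians(theta0_deg)))
    return pts, inten


def grid_search_polarity_angle(pts, inten, step=0.25):
    """Independent oracle: angle maximizing the intensity-weighted variance
    of projections of whitened displacements, by exhaustive search."""
    u, _ = shape_normalize(pts)
    q = np.column_stack([u[:, 0], -u[:, 1]])
    w = inten / inten.mean()
    best, best_v = 0.0, -1.0
    for ang in np.arange(0.0, 180.0, step):
        t = math.radians(ang)
        proj = q @ np.array([math.cos(t), math.sin(t)])
        v = float(np.sum(w * proj**2) / w.sum())
        if v > best_v:
            best, best_v = ang, v
    return best


class TestShapeNormalize:
    def test_circle_transform_is_pure_scaling(self):
        _, pts = circle_boundary(120)
        out, w = shape_normalize(pts)
        assert abs(w[0, 1]) < 1e-9
        assert w[0, 0] == pytest.approx(w[1, 1], rel=1e-9)

    def test_whitened_moments_are_isotropic(self, rng):
        # random convex-ish polygon boundary + a 2:1 ellipse
        for pts in (
            np.column_stack([10 * np.cos(np.linspace(0, 2 * np.pi, 64, endpoint=False)),
                             5 * np.sin(np.linspace(0, 2 * np.pi, 64, endpoint=False))]),
            rng.normal(size=(40, 2)) @ np.array([[3.0, 1.0], [0.0, 1.0]]),
        ):
            out, _ = shape_normalize(pts)
            d = out - out.mean(axis=0)
            m = d.T @ d / len(d)
            evals = np.linalg.eigvalsh(m)
            assert evals[1] / evals[0] == pytest.approx(1.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            shape_normalize(pts)


class TestPcaPolarity:
    def test_uniform_intensity_is_apolar(self):
        _, pts = circle_boundary()
        p = pca_polarity(pts, np.ones(len(pts)))
        assert p.magnitude < 1e-6

    @pytest.mark.parametrize("theta0", [0.0, 30.0, 90.0, 147.0])
    def test_cosine_pattern_angle_recovered(self, theta0):
        pts, inten = painted_circle(theta0, m=0.5)
        p = pca_polarity(pts, inten)
        d = abs(p.angle - theta0) % 180.0
        assert min(d, 180.0 - d) < 1.0

    def test_matches_grid_search_oracle(self):
        pts, inten = painted_circle(63.0, m=0.3)
        p = pca_polarity(pts, inten)
        oracle = grid_search_polarity_angle(pts, inten)
        d = abs(p.angle - oracle) % 180.0
        assert min(d, 180.0 - d) <= 0.5

    def test_antipodal_bright_arcs_give_axis(self):
        phi, pts = circle_boundary(360)
        deg = np.degrees(phi)
        d90 = np.minimum((deg - 90) % 360, (90 - deg) % 360)
        d270 = np.minimum((deg - 270) % 360, (270 - deg) % 360)
        inten = np.where((d90 < 15) | (d270 < 15), 10.0, 0.1)
        p = pca_polarity(pts, inten)
        assert abs(p.angle - 90.0) < 1.0

    def test_rotation_equivariance(self):
        pts, inten = painted_circle(40.0, m=0.4)
        p0 = pca_polarity(pts, inten)
        delta = 25.0
        t = math.radians(delta)
        # rotate points on screen by +delta (y-down coords)
        rot = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
        p1 = pca_polarity(pts @ rot.T, inten, axis=delta)
        d = abs(p1.angle - p0.angle) % 180.0
        assert min(d, 180.0 - d) < 1e-6
        assert p1.magnitude == pytest.approx(p0.magnitude, rel=1e-9)

    def test_eccentricity_robustness(self):
        """Stretching the cell 2:1 along an axis unrelated to the painted
        pattern barely moves the polarity readout."""
        pts, inten = painted_circle(30.0, m=0.4)
        p0 = pca_polarity(pts, inten)
        stretched = pts @ np.diag([2.0, 1.0])  # stretch along x (0 deg)
        p1 = pca_polarity(stretched, inten)
        d = abs(p1.angle - p0.angle) % 180.0
        assert min(d, 180.0 - d) < 5.0
        assert abs(p1.magnitude - p0.magnitude) / p0.magnitude < 0.10

    def test_magnitude_monotone_in_contrast(self):
        mags = []
        for m in np.linspace(0.0, 0.9, 10):
            pts, inten = painted_circle(30.0, m=m)
            mags.append(pca_polarity(pts, inten).magnitude)
        assert mags[0] < 1e-9
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_input_validation(self):
        _, pts = circle_boundary(6)
        with pytest.raises(ValueError):
            pca_polarity(pts, np.ones(6))  # too few points
        _, pts = circle_boundary(20)
        with pytest.raises(ValueError):
            pca_polarity(pts, np.zeros(20))


class TestCoarseGrain:
    def test_identical_cells_pass_through(self, small_tissue):
        pols = [CellPolarity(c.id, 20.0, 0.4) for c in small_tissue.cells]
        field = coarse_grain(pols, small_tissue)
        for b in field.blocks:
            assert b.mean_angle == pytest.approx(20.0, abs=1e-9)
            assert b.mean_magnitude == pytest.approx(0.4, abs=1e-12)

    def test_orthogonal_mix_cancels(self, small_tissue):
        pols = []
        for i, c in enumerate(small_tissue.cells):
            pols.append(CellPolarity(c.id, 0.0 if i % 2 == 0 else 90.0, 0.5))
        field = coarse_grain(pols, small_tissue, block_cells=100)  # one block
        assert len(field.blocks) == 1
        b = field.blocks[0]
        # equal split up to one odd cell out of n
        assert b.mean_magnitude < 0.5 / len(pols) + 1e-9

    def test_matches_double_angle_sum_oracle(self, small_tissue, rng):
        pols = [
            CellPolarity(c.id, float(rng.uniform(0, 180)), float(rng.uniform(0, 1)))
            for c in small_tissue.cells
        ]
        field = coarse_grain(pols, small_tissue, block_cells=100)
        b = field.blocks[0]
        qx = np.mean([p.magnitude * math.cos(2 * math.radians(p.angle)) for p in pols])
        qy = np.mean([p.magnitude * math.sin(2 * math.radians(p.angle)) for p in pols])
        assert b.mean_magnitude == pytest.approx(math.hypot(qx, qy), abs=1e-12)
        expect = math.degrees(math.atan2(qy, qx)) / 2.0 % 180.0
        assert b.mean_angle == pytest.approx(expect, abs=1e-9)
        assert b.mean_magnitude <= max(p.magnitude for p in pols) + 1e-12


class TestHistogram:
    def test_single_item(self):
        d = weighted_angle_histogram([(12.0, 0.4)])
        assert d.bin_weights[1] == pytest.approx(0.4)
        assert d.bin_weights.sum() == pytest.approx(0.4)

    def test_empty(self):
        d = weighted_angle_histogram([])
        assert d.n_items == 0 and d.bin_weights.sum() == 0

    def test_conservation_and_oracle(self, rng):
        items = [(float(a), float(w)) for a, w in
                 zip(rng.uniform(0, 180, 1000), rng.uniform(0, 2, 1000))]
        d = weighted_angle_histogram(items, "magnitude_sum")
        assert d.bin_weights.sum() == pytest.approx(sum(w for _, w in items), rel=1e-12)
        oracle = np.zeros(18)
        counts = np.zeros(18)
        for a, w in items:
            oracle[int(a // 10)] += w
            counts[int(a // 10)] += 1
        assert np.allclose(d.bin_weights, oracle)
        dm = weighted_angle_histogram(items, "magnitude_mean")
        assert np.allclose(dm.bin_weights, np.where(counts > 0, oracle / np.maximum(counts, 1), 0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            weighted_angle_histogram([(180.0, 1.0)])
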