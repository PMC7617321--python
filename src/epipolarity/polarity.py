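"""Per-cell PCA polarity scoring and nematic coarse-graining.

The polarity of a cell is the axis along which junctional signal,
sampled on the cell outline, is concentrated. The estimator first
whitens the outline (mapping the cell to an isotropic shape, which makes
the score robust to cell eccentricity), normalizes the boundary
intensities by their mean, and then diagonalizes the intensity-weighted
second-moment matrix of boundary displacements from the centroid. The
principal axis is the polarity angle; the normalized eigenvalue
anisotropy (l1 - l2) / (l1 + l2) in [0, 1] is the polarity magnitude.

Polarity is axial (period 180 deg), so spatial averaging uses the
double-angle (nematic) representation throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import ReferenceAxis, normalize_angle
from .tissue import Cell, SegmentedTissue

__all__ = [
    "CellPolarity",
    "CoarsePolarityField",
    "AngularDistribution",
    "shape_normalize",
    "pca_polarity",
    "coarse_grain",
    "weighted_angle_histogram",
    "polarity_table",
]

HIST_BIN_DEG = 10.0
N_BINS = 18


@dataclass
class CellPolarity:
    cell_id: int
    angle: float  # degrees in [0, 180), SOP-normalized
    magnitude: float  # in [0, 1]


@dataclass
class CoarseBlock:
    ix: int
    iy: int
    mean_angle: float
    mean_magnitude: float
    n_cells: int


@dataclass
class CoarsePolarityField:
    blocks: list[CoarseBlock]
    block_size_px: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "block_x": b.ix,
                    "block_y": b.iy,
                    "mean_angle_deg": b.mean_angle,
                    "mean_magnitude": b.mean_magnitude,
                    "n_cells": b.n_cells,
                }
                for b in self.blocks
            ]
        )


@dataclass
class AngularDistribution:
    bin_edges: np.ndarray  # 0, 10, ..., 180
    bin_weights: np.ndarray  # length 18
    n_items: int
    weighting_mode: str  # magnitude_sum | magnitude_mean | count


def shape_normalize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten a boundary point set to isotropic second moments.

    Returns ``(transformed_points, W)`` where W is the inverse principal
    square root of the centered second-moment tensor and the transformed
    points are centered. Raises on rank-deficient (collinear) input.
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    d = p - p.mean(axis=0)
    m = (d.T @ d) / len(d)
    w, v = np.linalg.eigh(m)
    if w[0] <= 1e-12 * max(w[1], 1e-300):
        raise ValueError("rank-deficient second-moment tensor (collinear points)")
    whiten = v @ np.diag(1.0 / np.sqrt(w)) @ v.T
    return d @ whiten.T, whiten


def pca_polarity(
    cell: Cell | np.ndarray,
    boundary_intensities: np.ndarray,
    axis: ReferenceAxis | float = 0.0,
) -> CellPolarity:
    """PCA polarity of one cell from intensities on its outline.

    ``cell`` may be a :class:`Cell` (whose ``boundary_pixels`` are used)
    or a raw (n, 2) array of boundary points. Intensities must be
    nonnegative, with at least 8 finite samples and not all zero.
    """
    if isinstance(cell, Cell):
        pts = cell.boundary_pixels
        cid = cell.id
    else:
        pts = np.asarray(cell, dtype=float)
        cid = -1
    w = np.asarray(boundary_intensities, dtype=float)
    if pts.shape[0] < 8:
        raise ValueError("need at least 8 boundary points")
    if w.shape[0] != pts.shape[0]:
        raise ValueError("intensity count does not match boundary point count")
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("intensities must be finite and nonnegative")
    if np.all(w == 0):
        raise ValueError("all boundary intensities are zero")

    u, _ = shape_normalize(pts)
    w = w / w.mean()
    # screen-math coords (flip y) so the reported angle follows the
    # package-wide convention
    q = np.column_stack([u[:, 0], -u[:, 1]])
    s = (q * w[:, None]).T @ q / w.sum()
    lam, vec = np.linalg.eigh(s)
    l2, l1 = float(lam[0]), float(lam[1])
    mag = (l1 - l2) / (l1 + l2) if (l1 + l2) > 0 else 0.0
    if mag < 1e-9:
        return CellPolarity(cell_id=cid, angle=0.0, magnitude=max(mag, 0.0))
    vx, vy = vec[:, 1]
    raw = math.degrees(math.atan2(vy, vx)) % 180.0
    return CellPolarity(cell_id=cid, angle=normalize_angle(raw, axis), magnitude=mag)


def polarity_table(polarities: list[CellPolarity]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"cell_id": p.cell_id, "angle_deg": p.angle, "magnitude": p.magnitude} for p in polarities]
    )


def coarse_grain(
    polarities: list[CellPolarity],
    tissue: SegmentedTissue,
    block_cells: int = 3,
) -> CoarsePolarityField:
    """Block-average cell polarities as nematic tensors.

    Cells are binned into square spatial tiles whose side is
    ``block_cells`` median cell diameters, approximating averages over
    ``block_cells x block_cells`` groups of cells in an irregular tissue.
    Within a tile, Q = mean of m * (cos 2t, sin 2t); the reported angle is
    arg(Q) / 2 and the magnitude |Q|.
    """
    if not polarities:
        raise ValueError("no polarities to coarse-grain")
    cent = {c.id: c.centroid for c in tissue.cells}
    diam = np.median([2.0 * math.sqrt(c.area / math.pi) for c in tissue.cells])
    side = block_cells * diam
    acc: dict[tuple[int, int], list[CellPolarity]] = {}
    for p in polarities:
        if p.cell_id not in cent:
            raise KeyError(f"cell {p.cell_id} not in tissue")
        x, y = cent[p.cell_id]
        k = (int(x // side), int(y // side))
        acc.setdefault(k, []).append(p)
    blocks = []
    for (ix, iy), members in sorted(acc.items()):
        t = np.radians([m.angle for m in members]) * 2.0
        m = np.array([m.magnitude for m in members])
        qx = float(np.mean(m * np.cos(t)))
        qy = float(np.mean(m * np.sin(t)))
        mag = math.hypot(qx, qy)
        ang = (math.degrees(math.atan2(qy, qx)) / 2.0) % 180.0 if mag > 1e-15 else 0.0
        blocks.append(CoarseBlock(ix=ix, iy=iy, mean_angle=ang, mean_magnitude=mag, n_cells=len(members)))
    return CoarsePolarityField(blocks=blocks, block_size_px=float(side))


def weighted_angle_histogram(
    items: list[tuple[float, float]],
    weighting_mode: str = "magnitude_sum",
) -> AngularDistribution:
    """10-degree-binned axial histogram weighted by polarity magnitude.

    ``magnitude_sum`` increments a bin by each member's weight;
    ``magnitude_mean`` divides each bin by its item count (empty bins
    report 0); ``count`` ignores weights.
    """
    if weighting_mode not in ("magnitude_sum", "magnitude_mean", "count"):
        raise ValueError(f"unknown weighting mode {weighting_mode!r}")
    edges = np.arange(0.0, 180.0 + HIST_BIN_DEG, HIST_BIN_DEG)
    if not items:
        return AngularDistribution(edges, np.zeros(N_BINS), 0, weighting_mode)
    angles = np.array([a for a, _ in items], dtype=float)
    weights = np.array([w for _, w in items], dtype=float)
    if np.any((angles < 0) | (angles >= 180.0)):
        raise ValueError("angles must lie in [0, 180)")
    idx = np.floor(angles / HIST_BIN_DEG).astype(int)
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    if weighting_mode == "count":
        w = counts
    else:
        w = np.bincount(idx, weights=weights, minlength=N_BINS)
        if weighting_mode == "magnitude_mean":
            with np.errstate(invalid="ignore", divide="ignore"):
                w = np.where(counts > 0, w / counts, 0.0)
    return AngularDistribution(edges, w, int(len(items)), weighting_mode)
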