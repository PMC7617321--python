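"""Segmented-tissue data structures and junction-graph construction.

A :class:`SegmentedTissue` wraps one frame's integer label map (0 =
background, k >= 1 = cell k) as produced by a segmentation tool, together
with derived per-cell geometry. :func:`build_junction_graph` turns the
label map into an explicit cell-cell junction graph with chord
orientations and optional junctional intensities, which is the substrate
for polarity scoring and topological-event detection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .angles import ReferenceAxis, axial_angle_deg, classify_orientation, normalize_angle

__all__ = [
    "Cell",
    "SegmentedTissue",
    "Junction",
    "JunctionGraph",
    "TrackingTable",
    "build_junction_graph",
    "classify_junction_orientation",
    "cell_shape",
    "read_label_tiff",
    "write_label_tiff",
    "read_config",
    "write_config",
]


@dataclass
class Cell:
    """One segmented cell: geometry derived from its label-map region."""

    id: int
    centroid: np.ndarray  # (x, y) in pixels
    boundary_pixels: np.ndarray  # (n, 2) array of (x, y), ordered around centroid
    area: float  # pixels^2
    second_moment_tensor: np.ndarray  # 2x2, in screen-math coords (y flipped)
    touches_border: bool = False


@dataclass
class SegmentedTissue:
    label_map: np.ndarray
    pixel_size: float  # um / pixel
    frame_index: int = 0
    cells: list[Cell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @classmethod
    def from_label_map(cls, label_map, pixel_size: float, frame_index: int = 0) -> "SegmentedTissue":
        lm = np.asarray(label_map)
        if lm.ndim != 2:
            raise ValueError("label map must be 2D")
        if not np.issubdtype(lm.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        tissue = cls(label_map=lm, pixel_size=float(pixel_size), frame_index=int(frame_index))
        tissue.cells = _extract_cells(lm)
        return tissue

    def cell(self, cell_id: int) -> Cell:
        for c in self.cells:
            if c.id == cell_id:
                return c
        raise KeyError(cell_id)


def _boundary_mask(lm: np.ndarray) -> np.ndarray:
    """Pixels with a 4-neighbor of a different label, or on the image edge."""
    m = np.zeros(lm.shape, dtype=bool)
    m[:-1, :] |= lm[:-1, :] != lm[1:, :]
    m[1:, :] |= lm[1:, :] != lm[:-1, :]
    m[:, :-1] |= lm[:, :-1] != lm[:, 1:]
    m[:, 1:] |= lm[:, 1:] != lm[:, :-1]
    m[0, :] = m[-1, :] = m[:, 0] = m[:, -1] = True
    return m & (lm > 0)


def _extract_cells(lm: np.ndarray) -> list[Cell]:
    labels = np.unique(lm)
    labels = labels[labels > 0]
    if labels.size == 0:
        return []
    border_labels = set(np.unique(np.concatenate([lm[0, :], lm[-1, :], lm[:, 0], lm[:, -1]])))
    bmask = _boundary_mask(lm)
    rows, cols = np.nonzero(lm > 0)
    vals = lm[rows, cols]
    order = np.argsort(vals, kind="stable")
    rows, cols, vals = rows[order], cols[order], vals[order]
    splits = np.searchsorted(vals, labels, side="left")
    splits = np.append(splits, vals.size)
    on_boundary = bmask[rows, cols]

    cells: list[Cell] = []
    for i, lab in enumerate(labels):
        sl = slice(splits[i], splits[i + 1])
        r, c = rows[sl], cols[sl]
        x, y = c.astype(float), r.astype(float)
        cx, cy = float(x.mean()), float(y.mean())
        # screen-math coordinates: flip y so angle conventions match angles.py
        dx, dyf = x - cx, -(y - cy)
        tensor = np.array(
            [
                [float(np.mean(dx * dx)), float(np.mean(dx * dyf))],
                [float(np.mean(dx * dyf)), float(np.mean(dyf * dyf))],
            ]
        )
        bsel = on_boundary[sl]
        bx, by = x[bsel], y[bsel]
        ang = np.arctan2(-(by - cy), bx - cx)
        bp = np.column_stack([bx, by])[np.argsort(ang, kind="stable")]
        cells.append(
            Cell(
                id=int(lab),
                centroid=np.array([cx, cy]),
                boundary_pixels=bp,
                area=float(x.size),
                second_moment_tensor=tensor,
                touches_border=int(lab) in border_labels,
            )
        )
    return cells


def cell_shape(cell: Cell, axis: ReferenceAxis | float = 0.0) -> tuple[float, float]:
    """Cell elongation axis and magnitude from the second-moment tensor.

    Returns ``(angle_deg, magnitude)`` with the angle SOP-normalized and
    magnitude = (l1 - l2) / (l1 + l2) of the tensor eigenvalues. A
    rotationally symmetric cell reports (0, 0) by convention.
    """
    if cell.area <= 0:
        raise ValueError("degenerate cell with non-positive area")
    w, v = np.linalg.eigh(cell.second_moment_tensor)
    l2, l1 = float(w[0]), float(w[1])
    tot = l1 + l2
    if tot <= 0:
        raise ValueError("degenerate second-moment tensor")
    mag = (l1 - l2) / tot
    if mag < 1e-12:
        return 0.0, 0.0
    vx, vy_math = v[:, 1]
    raw = math.degrees(math.atan2(vy_math, vx)) % 180.0
    return normalize_angle(raw, axis), mag


@dataclass
class Junction:
    """Shared interface between two adjacent cells (or cell and border)."""

    id: int
    cell_a: int
    cell_b: int
    endpoints: np.ndarray  # (2, 2) array of (x, y) chord endpoints, pixels
    length: float  # um (chord length)
    orientation: float  # degrees in [0, 180), SOP-normalized
    mean_intensity: dict[str, float] = field(default_factory=dict)
    n_interface_pixels: int = 0

    @property
    def length_px(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


class JunctionGraph:
    """Cell adjacency graph of one frame with per-junction geometry."""

    def __init__(self, junctions: list[Junction], vertices: np.ndarray | None = None):
        self.junctions = junctions
        self.vertices = vertices if vertices is not None else np.zeros((0, 2))
        self._by_pair: dict[frozenset, Junction] = {
            frozenset((j.cell_a, j.cell_b)): j for j in junctions
        }
        self.graph = nx.Graph()
        for j in junctions:
            self.graph.add_edge(j.cell_a, j.cell_b, junction=j)

    def __len__(self) -> int:
        return len(self.junctions)

    def junction_between(self, a: int, b: int) -> Junction | None:
        return self._by_pair.get(frozenset((a, b)))

    def neighbors(self, cell_id: int) -> set[int]:
        if cell_id not in self.graph:
            return set()
        return set(self.graph.neighbors(cell_id))

    def to_frame(self, frame: int = 0) -> pd.DataFrame:
        rows = []
        for j in self.junctions:
            row = {
                "junction_id": j.id,
                "frame": frame,
                "cell_a": j.cell_a,
                "cell_b": j.cell_b,
                "length_um": j.length,
                "orientation_deg": j.orientation,
            }
            for ch, v in j.mean_intensity.items():
                row[f"intensity_{ch}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _adjacent_pixel_pairs(lm: np.ndarray):
    """All 4-connected pixel pairs with differing positive labels.

    Returns (label_a, label_b, mid_x, mid_y, pix_rows, pix_cols) arrays
    where mid_* are interface midpoints (half-integer coordinates) and the
    pix arrays stack the two contributing integer pixels per contact.
    """
    pairs = []
    # vertical neighbors (along rows)
    a, b = lm[:-1, :], lm[1:, :]
    m = (a != b) & (a > 0) & (b > 0)
    r, c = np.nonzero(m)
    pairs.append((a[m], b[m], c.astype(float), r + 0.5, np.stack([r, r + 1]), np.stack([c, c])))
    # horizontal neighbors (along cols)
    a, b = lm[:, :-1], lm[:, 1:]
    m = (a != b) & (a > 0) & (b > 0)
    r, c = np.nonzero(m)
    pairs.append((a[m], b[m], c + 0.5, r.astype(float), np.stack([r, r]), np.stack([c, c + 1])))
    la = np.concatenate([p[0] for p in pairs])
    lb = np.concatenate([p[1] for p in pairs])
    mx = np.concatenate([p[2] for p in pairs])
    my = np.concatenate([p[3] for p in pairs])
    prow = np.concatenate([p[4] for p in pairs], axis=1)
    pcol = np.concatenate([p[5] for p in pairs], axis=1)
    return la, lb, mx, my, prow, pcol


def brute_force_adjacency(lm: np.ndarray) -> set[frozenset]:
    """Slow reference adjacency by scanning every pixel's 4-neighbors."""
    out: set[frozenset] = set()
    h, w = lm.shape
    for r in range(h):
        for c in range(w):
            v = lm[r, c]
            if v <= 0:
                continue
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr < h and cc < w:
                    u = lm[rr, cc]
                    if u > 0 and u != v:
                        out.add(frozenset((int(v), int(u))))
    return out


def build_junction_graph(
    tissue: SegmentedTissue,
    intensity_images: dict[str, np.ndarray] | None = None,
    axis: ReferenceAxis | float = 0.0,
    band_width: int = 3,
) -> JunctionGraph:
    """Build the cell-cell junction graph of one frame.

    One junction per 4-adjacent cell pair. The junction chord joins the
    two extremal interface points; its angle is SOP-normalized. Mean
    intensities are taken over a ``band_width``-pixel-wide band of cell
    pixels hugging the shared interface, excluding pixels that also touch
    a third cell.
    """
    lm = tissue.label_map
    if lm.size == 0 or not np.any(lm > 0):
        raise ValueError("empty label map")
    if intensity_images:
        for name, img in intensity_images.items():
            if img.shape != lm.shape:
                raise ValueError(f"intensity image {name!r} shape differs from label map")

    la, lb, mx, my, prow, pcol = _adjacent_pixel_pairs(lm)
    if la.size == 0:
        return JunctionGraph([])

    lo = np.minimum(la, lb).astype(np.int64)
    hi = np.maximum(la, lb).astype(np.int64)
    key = lo * (lm.max() + 1) + hi
    order = np.argsort(key, kind="stable")
    key_s = key[order]
    starts = np.nonzero(np.r_[True, key_s[1:] != key_s[:-1]])[0]
    starts = np.append(starts, key_s.size)

    junctions: list[Junction] = []
    jid = 0
    for s, e in zip(starts[:-1], starts[1:]):
        idx = order[s:e]
        a, b = int(lo[idx[0]]), int(hi[idx[0]])
        pts = np.column_stack([mx[idx], my[idx]])
        if pts.shape[0] == 1:
            p0 = p1 = pts[0]
        else:
            ctr = pts.mean(axis=0)
            d = pts - ctr
            # principal interface direction from 2x2 scatter
            cov = d.T @ d
            w, v = np.linalg.eigh(cov)
            u = v[:, -1]
            t = d @ u
            p0, p1 = pts[np.argmin(t)], pts[np.argmax(t)]
        chord = p1 - p0
        if np.allclose(chord, 0):
            ori = 0.0
            length_px = 1.0  # single-contact junction: one pixel edge
        else:
            ori = axial_angle_deg(chord[0], chord[1])
            length_px = float(np.linalg.norm(chord))
        j = Junction(
            id=jid,
            cell_a=a,
            cell_b=b,
            endpoints=np.stack([p0, p1]),
            length=length_px * tissue.pixel_size,
            orientation=normalize_angle(ori, axis),
            n_interface_pixels=int(idx.size),
        )
        if intensity_images:
            j.mean_intensity = _band_intensities(
                lm, prow[:, idx], pcol[:, idx], a, b, intensity_images, band_width
            )
        junctions.append(j)
        jid += 1
    return JunctionGraph(junctions)


def _band_intensities(lm, prow, pcol, a, b, intensity_images, band_width):
    """Mean intensity in a band of {a,b}-pixels around the interface."""
    rows = prow.ravel()
    cols = pcol.ravel()
    pad = max(1, band_width // 2) + 1
    r0, r1 = rows.min() - pad, rows.max() + pad + 1
    c0, c1 = cols.min() - pad, cols.max() + pad + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, lm.shape[0]), min(c1, lm.shape[1])
    patch = lm[r0:r1, c0:c1]
    seed = np.zeros(patch.shape, dtype=bool)
    seed[rows - r0, cols - c0] = True
    if band_width > 2:
        size = band_width if band_width % 2 == 1 else band_width + 1
        band = ndimage.binary_dilation(seed, structure=np.ones((size, size), bool))
    else:
        band = seed
    band &= (patch == a) | (patch == b)
    # exclude pixels 4-adjacent to a third cell
    third = (patch > 0) & (patch != a) & (patch != b)
    near_third = ndimage.binary_dilation(
        third, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    )
    band &= ~near_third
    if not band.any():
        band = seed & ((patch == a) | (patch == b))
    out = {}
    for name, img in intensity_images.items():
        out[name] = float(img[r0:r1, c0:c1][band].mean())
    return out


def classify_junction_orientation(junction: Junction) -> str:
    """PD/AP class of a junction from its normalized chord angle."""
    return classify_orientation(junction.orientation)


class TrackingTable:
    """Lineage bookkeeping across frames: (frame, cell_id, lineage_id, parent).

    The tracking table is the single source of lineage truth; label maps
    are per-frame only. A division appears as two rows whose
    ``parent_lineage_id`` names the mother lineage, in the first frame the
    daughters exist.
    """

    COLUMNS = ["frame", "cell_id", "lineage_id", "parent_lineage_id"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"tracking table missing columns: {missing}")
        df = df[self.COLUMNS].copy()
        dup = df.duplicated(subset=["frame", "cell_id"])
        if dup.any():
            raise ValueError("cell_id not unique within a frame")
        self.df = df.sort_values(["frame", "cell_id"], kind="stable").reset_index(drop=True)
        self._validate_divisions()

    def _validate_divisions(self) -> None:
        kids = self.df.dropna(subset=["parent_lineage_id"])
        if kids.empty:
            return
        first = kids.groupby("lineage_id")["frame"].min().reset_index()
        merged = kids.merge(first, on=["lineage_id", "frame"])
        counts = merged.groupby(["parent_lineage_id", "frame"])["lineage_id"].nunique()
        if (counts > 2).any():
            raise ValueError("a lineage has more than two children in one division event")

    def frames(self) -> list[int]:
        return sorted(self.df["frame"].unique().tolist())

    def lineage_of(self, frame: int) -> dict[int, int]:
        sub = self.df[self.df["frame"] == frame]
        return dict(zip(sub["cell_id"].astype(int), sub["lineage_id"].astype(int)))

    def cell_of(self, frame: int) -> dict[int, int]:
        sub = self.df[self.df["frame"] == frame]
        return dict(zip(sub["lineage_id"].astype(int), sub["cell_id"].astype(int)))

    def divisions(self) -> pd.DataFrame:
        """Rows (frame, parent_lineage_id, child lineage ids) per division."""
        kids = self.df.dropna(subset=["parent_lineage_id"]).copy()
        if kids.empty:
            return pd.DataFrame(columns=["frame", "parent_lineage_id", "children"])
        first = kids.groupby("lineage_id", as_index=False)["frame"].min()
        born = kids.merge(first, on=["lineage_id", "frame"])
        rows = []
        for (parent, frame), grp in born.groupby(["parent_lineage_id", "frame"]):
            rows.append(
                {
                    "frame": int(frame),
                    "parent_lineage_id": int(parent),
                    "children": sorted(int(v) for v in grp["lineage_id"].unique()),
                }
            )
        return pd.DataFrame(rows).sort_values("frame", kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrackingTable":
        return cls(pd.read_csv(path))


def read_label_tiff(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr.astype(np.int64)


def write_label_tiff(path, label_map: np.ndarray) -> None:
    lm = np.asarray(label_map)
    if lm.min() < 0 or lm.max() > np.iinfo(np.uint16).max:
        raise ValueError("label map does not fit in uint16")
    tifffile.imwrite(path, lm.astype(np.uint16))


def read_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")
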