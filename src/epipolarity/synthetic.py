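"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a segmented pupal-wing
field: a ~1000-cell epithelium (seeded Voronoi tessellation with Lloyd
relaxation, optional global stretch for cell elongation), junctional
intensity enriched on PD-oriented junctions (yielding AP-oriented cell
polarity), scripted cell divisions and T1 neighbor exchanges with axial
von Mises-distributed orientations, FRAP traces following
y_max (1 - exp(-a t)) with multiplicative per-frame acquisition
bleaching, and post-ablation elliptical recoil with prescribed initial
axis velocities.

Every generator is a pure function of its parameters and the seed; each
draws from its own sub-stream of the master seed so adding a generator
never perturbs existing outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .angles import axial_angle_deg
from .frap import FrapTrace, default_schedule
from .ablation import AblationSeries, RECOIL_FRAMES
from .tissue import SegmentedTissue, TrackingTable, build_junction_graph, JunctionGraph

__all__ = [
    "PolarityTruth",
    "EventTruth",
    "FrapTruth",
    "RecoilTruth",
    "SyntheticSpec",
    "make_tissue",
    "paint_polarity",
    "make_timelapse",
    "make_frap",
    "make_recoil",
    "sample_axial_von_mises",
]

_SUBKEYS = {
    "tissue": 11,
    "polarity": 23,
    "timelapse": 37,
    "frap": 53,
    "recoil": 71,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _SUBKEYS[stream]])


def sample_axial_von_mises(rng, mu_deg: float, kappa: float, size: int) -> np.ndarray:
    """Axial von Mises sample in [0, 180) via the doubling trick."""
    if math.isinf(kappa):
        return np.full(size, mu_deg % 180.0)
    ang = rng.vonmises(math.radians(2.0 * mu_deg), kappa, size=size)
    return (np.degrees(ang) / 2.0) % 180.0


@dataclass
class PolarityTruth:
    enrichment_axis: float = 0.0  # deg; 0 = PD-junction enrichment
    contrast: float = 0.5  # c in [0, 1)
    base_intensity: float = 100.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.contrast < 1.0):
            raise ValueError("contrast must be in [0, 1)")


@dataclass
class EventTruth:
    n_divisions: int = 50
    n_t1s: int = 30
    mu_deg: float = 90.0  # AP-oriented events, as at 16-18 hAPF
    kappa: float = 4.0


@dataclass
class FrapTruth:
    y_max: float | dict = 0.8
    alpha: float | dict = 0.02  # 1/s
    initial_bleach_pct: float = 60.0
    acquisition_bleach_pct: float = 15.0
    noise_sd: float = 0.0  # in pre-bleach intensity units (relative)
    pre_level: float = 1000.0
    background: float = 50.0

    def value(self, attr: str, orientation: str) -> float:
        v = getattr(self, attr)
        return float(v[orientation]) if isinstance(v, dict) else float(v)


@dataclass
class RecoilTruth:
    v_major: float = 0.2  # um/s over the first 5 s
    v_minor: float = 0.1
    tau: float = 20.0  # s
    L0: float = 24.3  # um, initial (cut) diameter
    major_axis_angle: float = 0.0  # deg; 0 = PD
    noise_sd: float = 0.0  # um, vertex jitter
    n_frames: int = 180
    n_vertices: int = 12


@dataclass
class SyntheticSpec:
    seed: int = 0
    n_cells: int = 1000
    mean_cell_diameter_um: float = 4.0
    pixel_size_um: float = 0.21
    elongation_axis: float = 0.0
    elongation_factor: float = 1.0  # 1 = isotropic
    n_frames: int = 13  # 2 h at 10-min intervals
    polarity_truth: PolarityTruth = field(default_factory=PolarityTruth)
    event_truth: EventTruth = field(default_factory=EventTruth)
    frap_truth: FrapTruth = field(default_factory=FrapTruth)
    recoil_truth: RecoilTruth = field(default_factory=RecoilTruth)
    n_pupae_frap: int = 3
    n_pupae_recoil: int = 3


# ---------------------------------------------------------------- tissue


def make_tissue(
    n_cells: int = 1000,
    mean_cell_diameter_um: float = 4.0,
    pixel_size_um: float = 0.21,
    elongation_axis: float = 0.0,
    elongation_factor: float = 1.0,
    lloyd_iterations: int = 2,
    seed: int = 0,
) -> SegmentedTissue:
    """Seeded Voronoi epithelium rasterized to a label map.

    Lloyd relaxation regularizes cell sizes; an optional anisotropic
    stretch of factor f elongates cells along ``elongation_axis``
    (aspect ratio ~ f). Deterministic given the seed.
    """
    if n_cells < 4:
        raise ValueError("need at least 4 cells")
    rng = _rng(seed, "tissue")
    diam_px = mean_cell_diameter_um / pixel_size_um
    cell_area = math.pi * (diam_px / 2.0) ** 2
    side = int(math.ceil(math.sqrt(n_cells * cell_area)))
    # seeds on a jittered triangular lattice: epithelial packings are
    # near-hexagonal, and Lloyd relaxation then converges quickly
    spacing = math.sqrt(side * side / n_cells / (math.sqrt(3.0) / 2.0))
    xs = np.arange(0.0, side, spacing)
    ys = np.arange(0.0, side, spacing * math.sqrt(3.0) / 2.0)
    gx0, gy0 = np.meshgrid(xs, ys)
    gx0[1::2] += spacing / 2.0
    pts = np.column_stack([gx0.ravel(), gy0.ravel()])
    pts = pts + rng.normal(0.0, 0.15 * spacing, pts.shape)
    if len(pts) >= n_cells:
        keep = rng.permutation(len(pts))[:n_cells]
        pts = pts[np.sort(keep)]
    else:
        extra = rng.uniform(0, side, size=(n_cells - len(pts), 2))
        pts = np.vstack([pts, extra])
    pts = np.clip(pts, 0.0, side - 1.0)

    f = float(elongation_factor)
    t = math.radians(elongation_axis)
    # query-space transform: compress coordinates along the elongation
    # axis so rasterized cells stretch along it (screen-math frame)
    rot = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
    scale = np.diag([1.0 / f, 1.0])
    m = rot.T @ scale @ rot
    flip = np.diag([1.0, -1.0])
    m_img = flip @ m @ flip  # back to y-down image coordinates

    gx, gy = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    grid_q = grid @ m_img.T

    for _ in range(lloyd_iterations + 1):
        tree = cKDTree(pts @ m_img.T)
        _, lab = tree.query(grid_q, workers=1)
        lm = lab.reshape(side, side)
        sums_x = ndimage.sum_labels(gx, labels=lm, index=np.arange(n_cells))
        sums_y = ndimage.sum_labels(gy, labels=lm, index=np.arange(n_cells))
        counts = np.bincount(lm.ravel(), minlength=n_cells).astype(float)
        nonzero = counts > 0
        new_pts = pts.copy()
        new_pts[nonzero, 0] = sums_x[nonzero] / counts[nonzero]
        new_pts[nonzero, 1] = sums_y[nonzero] / counts[nonzero]
        pts = new_pts

    label_map = (lm + 1).astype(np.int32)  # labels 1..n, no background
    return SegmentedTissue.from_label_map(label_map, pixel_size=pixel_size_um, frame_index=0)


# --------------------------------------------------------------- polarity


def paint_polarity(
    tissue: SegmentedTissue,
    truth: PolarityTruth,
    graph: JunctionGraph | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, JunctionGraph]:
    """Paint junctional intensity modulated by junction orientation.

    Each junction's intensity is
    ``base * (1 + c * cos 2(theta - enrichment_axis)) + noise`` painted
    onto the interface pixels of both member cells; non-junction
    boundary pixels (tissue border) carry the base intensity. With
    ``enrichment_axis = 0`` PD-oriented junctions are bright, so
    downstream PCA polarity is AP-oriented (concentrated at 90 deg).
    """
    if graph is None:
        graph = build_junction_graph(tissue)
    rng = _rng(seed, "polarity")
    img = np.full(tissue.label_map.shape, truth.base_intensity, dtype=float)
    lm = tissue.label_map
    for j in graph.junctions:
        theta = j.orientation
        val = truth.base_intensity * (
            1.0 + truth.contrast * math.cos(2.0 * math.radians(theta - truth.enrichment_axis))
        )
        if truth.noise_sd > 0:
            val += rng.normal(0.0, truth.noise_sd)
        val = max(val, 0.0)
        # paint the integer pixels on both sides of each interface contact
        for p0, p1 in _interface_pixels(lm, j):
            img[p0] = val
            img[p1] = val
        j.mean_intensity = {"ch1": val}
    return img, graph


def _interface_pixels(lm, junction):
    """Integer pixel pairs straddling a junction's interface contacts."""
    a, b = junction.cell_a, junction.cell_b
    p0, p1 = junction.endpoints
    r0 = int(max(min(p0[1], p1[1]) - 2, 0))
    r1 = int(min(max(p0[1], p1[1]) + 3, lm.shape[0]))
    c0 = int(max(min(p0[0], p1[0]) - 2, 0))
    c1 = int(min(max(p0[0], p1[0]) + 3, lm.shape[1]))
    patch = lm[r0:r1, c0:c1]
    out = []
    pr, pc = np.nonzero(patch == a)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rr, cc = pr + dr, pc + dc
        ok = (rr >= 0) & (rr < patch.shape[0]) & (cc >= 0) & (cc < patch.shape[1])
        sel = np.zeros(pr.shape, bool)
        sel[ok] = patch[rr[ok], cc[ok]] == b
        for i in np.nonzero(sel)[0]:
            out.append(((pr[i] + r0, pc[i] + c0), (pr[i] + dr + r0, pc[i] + dc + c0)))
    return out


# -------------------------------------------------------------- timelapse


def _split_cell(lm, cell_id, angle_deg, new_ids):
    """Divide a cell along the line through its centroid at angle_deg.

    The daughter-daughter interface lies along ``angle_deg``; returns
    False if either daughter would be empty or disconnected.
    """
    rows, cols = np.nonzero(lm == cell_id)
    if rows.size < 8:
        return False
    cx, cy = cols.mean(), rows.mean()
    t = math.radians(angle_deg)
    dx = cols - cx
    dyf = -(rows - cy)  # screen-math y
    s = dx * (-math.sin(t)) + dyf * math.cos(t)  # signed distance to split line
    side_a = s >= 0
    if side_a.all() or (~side_a).all():
        return False
    trial = lm.copy()
    trial[rows[side_a], cols[side_a]] = new_ids[0]
    trial[rows[~side_a], cols[~side_a]] = new_ids[1]
    for nid in new_ids:
        mask = trial == nid
        _, n_comp = ndimage.label(mask)
        if n_comp != 1:
            return False
    lm[:, :] = trial
    return True


def _rewire_t1(lm, a, b, c, d, junction, angle_deg, band_radius=2.0, half_len=4.0, cutoff=4.0):
    """Rewire the quartet so (a, b) lose contact and (c, d) gain a
    junction along ``angle_deg`` through the old interface midpoint."""
    p0, p1 = junction.endpoints
    v = (p0 + p1) / 2.0
    t = math.radians(angle_deg)
    u = np.array([math.cos(t), -math.sin(t)])  # image coords direction
    r0 = int(max(min(p0[1], p1[1], v[1] - half_len) - band_radius - 2, 0))
    r1 = int(min(max(p0[1], p1[1], v[1] + half_len) + band_radius + 3, lm.shape[0]))
    c0 = int(max(min(p0[0], p1[0], v[0] - half_len) - band_radius - 2, 0))
    c1 = int(min(max(p0[0], p1[0], v[0] + half_len) + band_radius + 3, lm.shape[1]))
    patch = lm[r0:r1, c0:c1]
    pr, pc = np.mgrid[r0:r1, c0:c1]
    px = pc.astype(float)
    py = pr.astype(float)

    # distance to the old interface chord and to the new-junction segment
    def seg_dist(q0, q1):
        seg = q1 - q0
        L2 = float(seg @ seg)
        wx = px - q0[0]
        wy = py - q0[1]
        if L2 == 0:
            return np.hypot(wx, wy)
        tt = np.clip((wx * seg[0] + wy * seg[1]) / L2, 0.0, 1.0)
        return np.hypot(wx - tt * seg[0], wy - tt * seg[1])

    d_old = seg_dist(p0, p1)
    q0 = v - half_len * u
    q1 = v + half_len * u
    d_new = seg_dist(q0, q1)
    region = ((d_old <= band_radius) | (d_new <= band_radius)) & np.isin(patch, [a, b, c, d])
    if not region.any():
        return False

    # side of the new-junction line (screen-math cross product sign)
    sx = px - v[0]
    syf = -(py - v[1])
    uf = np.array([math.cos(t), math.sin(t)])
    side = sx * (-uf[1]) + syf * uf[0]

    def centroid_side(cell):
        rr, cc = np.nonzero(lm == cell)
        scx = cc.mean() - v[0]
        scy = -(rr.mean() - v[1])
        return scx * (-uf[1]) + scy * uf[0]

    sc, sd = centroid_side(c), centroid_side(d)
    if sc == 0 or sd == 0 or (sc > 0) == (sd > 0):
        return False
    trial = lm.copy()
    tpatch = trial[r0:r1, c0:c1]
    c_mask = region & ((side >= 0) == (sc > 0))
    d_mask = region & ~c_mask
    tpatch[c_mask] = c
    tpatch[d_mask] = d

    # validate: a/b separated, c/d joined long enough, all connected
    sub = trial[max(r0 - 4, 0) : min(r1 + 4, lm.shape[0]), max(c0 - 4, 0) : min(c1 + 4, lm.shape[1])]
    if _pair_adjacent(sub, a, b):
        return False
    chord = _pair_chord(sub, c, d)
    if chord is None or chord < cutoff:
        return False
    for cell in (a, b, c, d):
        mask = trial == cell
        if not mask.any():
            return False
        _, n_comp = ndimage.label(mask)
        if n_comp != 1:
            return False
    lm[:, :] = trial
    return True


def _pair_adjacent(lm, a, b):
    m1 = (lm[:-1, :] == a) & (lm[1:, :] == b) | (lm[:-1, :] == b) & (lm[1:, :] == a)
    m2 = (lm[:, :-1] == a) & (lm[:, 1:] == b) | (lm[:, :-1] == b) & (lm[:, 1:] == a)
    return bool(m1.any() or m2.any())


def _pair_chord(lm, a, b):
    pts = []
    m = (lm[:-1, :] == a) & (lm[1:, :] == b) | (lm[:-1, :] == b) & (lm[1:, :] == a)
    r, c = np.nonzero(m)
    pts.append(np.column_stack([c.astype(float), r + 0.5]))
    m = (lm[:, :-1] == a) & (lm[:, 1:] == b) | (lm[:, :-1] == b) & (lm[:, 1:] == a)
    r, c = np.nonzero(m)
    pts.append(np.column_stack([c + 0.5, r.astype(float)]))
    pts = np.vstack(pts)
    if pts.shape[0] == 0:
        return None
    if pts.shape[0] == 1:
        return 1.0
    dif = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((dif**2).sum(-1)).max())


def make_timelapse(
    tissue: SegmentedTissue,
    truth: EventTruth,
    n_frames: int = 13,
    seed: int = 0,
    bond_cutoff: float = 4.0,
) -> tuple[list[SegmentedTissue], TrackingTable, dict]:
    """Scripted time-lapse with planted divisions and T1 exchanges.

    Events are assigned to frames 1..n_frames-1 in rotation; each uses a
    disjoint set of interior cells, so no planted T1 shares a cell with
    a division (divisions elsewhere in the tissue may still share a
    frame). Returns per-frame tissues, the tracking table and the ground
    truth (division and T1 records with planted angles).
    """
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = _rng(seed, "timelapse")
    n_events = truth.n_divisions + truth.n_t1s
    if n_events == 0:
        frames = [tissue] + [
            SegmentedTissue.from_label_map(tissue.label_map.copy(), tissue.pixel_size, f)
            for f in range(1, n_frames)
        ]
        rows = []
        labels = [c.id for c in tissue.cells]
        for f in range(n_frames):
            for lab in labels:
                rows.append({"frame": f, "cell_id": lab, "lineage_id": lab, "parent_lineage_id": None})
        return frames, TrackingTable(pd.DataFrame(rows)), {"divisions": [], "t1s": []}

    # interleave event kinds, then assign frames cyclically
    kinds = ["division"] * truth.n_divisions + ["t1"] * truth.n_t1s
    rng.shuffle(kinds)
    schedule: dict[int, list[str]] = {}
    for i, kind in enumerate(kinds):
        f = 1 + (i % (n_frames - 1))
        schedule.setdefault(f, []).append(kind)

    div_angles = sample_axial_von_mises(rng, truth.mu_deg, truth.kappa, truth.n_divisions)
    t1_angles = sample_axial_von_mises(rng, truth.mu_deg, truth.kappa, truth.n_t1s)
    div_iter = iter(div_angles)
    t1_iter = iter(t1_angles)

    lm = tissue.label_map.astype(np.int32).copy()
    next_id = int(lm.max()) + 1
    used: set[int] = set()
    border = {c.id for c in tissue.cells if c.touches_border}
    parent_of: dict[int, int] = {}
    birth_frame: dict[int, int] = {}
    maps = [lm.copy()]
    truth_div: list[dict] = []
    truth_t1: list[dict] = []

    for f in range(1, n_frames):
        todo = schedule.get(f, [])
        if todo:
            frame_tissue = SegmentedTissue.from_label_map(lm, tissue.pixel_size, f)
            graph = build_junction_graph(frame_tissue)
            cells_by_id = {c.id: c for c in frame_tissue.cells}
        for kind in todo:
            if kind == "division":
                angle = float(next(div_iter))
                placed = False
                candidates = [
                    c.id
                    for c in frame_tissue.cells
                    if c.id not in used and c.id not in border and c.area >= 60
                ]
                rng.shuffle(candidates)
                for cid in candidates:
                    ids = (next_id, next_id + 1)
                    # the daughter interface lies along the sampled
                    # new-junction angle; division axis = angle + 90
                    if _split_cell(lm, cid, angle, ids):
                        parent_of[ids[0]] = cid
                        parent_of[ids[1]] = cid
                        birth_frame[ids[0]] = birth_frame[ids[1]] = f
                        used.update({cid, *ids})
                        next_id += 2
                        truth_div.append(
                            {
                                "frame": f,
                                "mother": cid,
                                "daughters": list(ids),
                                "planted_new_junction_angle": angle,
                                "planted_division_angle": (angle + 90.0) % 180.0,
                            }
                        )
                        placed = True
                        break
                if not placed:
                    raise RuntimeError("could not place a scripted division")
            else:
                angle = float(next(t1_iter))
                if not _place_t1(
                    lm, graph, cells_by_id, used, border, angle, bond_cutoff, truth_t1, f, rng
                ):
                    raise RuntimeError("could not place a scripted T1 exchange")
        maps.append(lm.copy())

    frames = [
        SegmentedTissue.from_label_map(m, tissue.pixel_size, f) for f, m in enumerate(maps)
    ]
    rows = []
    for f, m in enumerate(maps):
        for lab in np.unique(m):
            lab = int(lab)
            if lab <= 0:
                continue
            rows.append(
                {
                    "frame": f,
                    "cell_id": lab,
                    "lineage_id": lab,
                    "parent_lineage_id": parent_of.get(lab),
                }
            )
    tracking = TrackingTable(pd.DataFrame(rows))
    return frames, tracking, {"divisions": truth_div, "t1s": truth_t1}


def _place_t1(lm, graph, cells_by_id, used, border, angle, cutoff, truth_t1, frame, rng):
    """Pick the quartet whose old junction is most perpendicular to the
    target new-junction angle and rewire it."""
    target_old = (angle + 90.0) % 180.0
    candidates = []
    for j in graph.junctions:
        a, b = j.cell_a, j.cell_b
        if a in used or b in used or a in border or b in border:
            continue
        # the pair must count as an effective contact before the exchange
        if j.length_px < cutoff or j.n_interface_pixels < 3:
            continue
        sep = abs((j.orientation - target_old) % 180.0)
        sep = min(sep, 180.0 - sep)
        candidates.append((sep, j.id, j))
    candidates.sort(key=lambda c: (c[0], c[1]))
    for sep, _, j in candidates[:200]:
        a, b = j.cell_a, j.cell_b
        common = sorted(
            (graph.neighbors(a) & graph.neighbors(b)) - used - border - {a, b}
        )
        for i, c in enumerate(common):
            for d in common[i + 1 :]:
                # the gaining pair must not already hold an effective contact
                p0, p1 = j.endpoints
                rr0 = int(max(min(p0[1], p1[1]) - 20, 0))
                rr1 = int(min(max(p0[1], p1[1]) + 21, lm.shape[0]))
                cc0 = int(max(min(p0[0], p1[0]) - 20, 0))
                cc1 = int(min(max(p0[0], p1[0]) + 21, lm.shape[1]))
                prior = _pair_chord(lm[rr0:rr1, cc0:cc1], c, d)
                if prior is not None and prior >= cutoff:
                    continue
                trial_angle = angle if sep <= 25.0 else (j.orientation + 90.0) % 180.0
                if _rewire_t1(lm, a, b, c, d, j, trial_angle, cutoff=cutoff):
                    used.update({a, b, c, d})
                    truth_t1.append(
                        {
                            "frame": frame,
                            "losing_pair": sorted((a, b)),
                            "gaining_pair": sorted((c, d)),
                            "planted_new_junction_angle": trial_angle,
                        }
                    )
                    return True
    return False


# ------------------------------------------------------------------ FRAP


def make_frap(
    truth: FrapTruth,
    n_pupae: int = 3,
    rois_per_orientation: int = 4,
    schedule: np.ndarray | None = None,
    group: str | None = None,
    seed: int = 0,
) -> list[FrapTrace]:
    """FRAP traces whose full-pipeline analysis recovers the truth.

    The underlying recovery is
    R(t) = pre * [(1 - d) + d * y_max * (1 - exp(-a t))] with bleach
    depth d set from the requested initial-bleaching percentage;
    acquisition bleaching multiplies both channels by a geometric
    per-frame decay calibrated so the end-to-end measured acquisition
    bleaching equals the requested percentage. Background is added to
    both channels; Gaussian noise (sd = noise_sd * pre) to all observed
    intensities.
    """
    t = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    rng = _rng(seed, "frap")
    acq = truth.acquisition_bleach_pct
    if acq >= 100.0:
        raise ValueError("acquisition bleaching must be below 100%")
    n_post = t.size
    decay = (1.0 - acq / 100.0) ** (1.0 / (n_post - 1)) if n_post > 1 else 1.0
    b = decay ** np.arange(n_post)
    pre = truth.pre_level
    bg = truth.background
    traces = []
    for p in range(n_pupae):
        pupa = f"{group or 'wt'}_p{p:02d}"
        for orientation in ("PD", "AP"):
            y_max = truth.value("y_max", orientation)
            alpha = truth.value("alpha", orientation)
            ini = truth.initial_bleach_pct
            d = (ini / 100.0) * (pre + bg) / pre
            if not (0.0 < d <= 1.0):
                raise ValueError("requested initial bleaching infeasible for pre/background levels")
            recovery = pre * ((1.0 - d) + d * y_max * (1.0 - np.exp(-alpha * t)))
            for r in range(rois_per_orientation):
                sd = truth.noise_sd * pre
                noise = (lambda n: rng.normal(0.0, sd, n)) if sd > 0 else (lambda n: np.zeros(n))
                i_pre = np.maximum(pre + bg + noise(3), 0.0)
                u_pre = np.maximum(pre + bg + noise(3), 0.0)
                i_post = np.maximum(b * recovery + bg + noise(n_post), 0.0)
                u_post = np.maximum(b * pre + bg + noise(n_post), 0.0)
                traces.append(
                    FrapTrace(
                        pupa_id=pupa,
                        roi_id=f"{pupa}_{orientation}_roi{r}",
                        orientation_class=orientation,
                        t_post=t.copy(),
                        i_pre=i_pre,
                        i_post=i_post,
                        u_pre=u_pre,
                        u_post=u_post,
                        background=bg,
                        group=group,
                    )
                )
    return traces


# ---------------------------------------------------------------- recoil


def _ols_slope_factor(tau: float) -> float:
    """OLS slope of -exp(-t/tau) over the recoil frames t = 1..6."""
    t = RECOIL_FRAMES
    y = -np.exp(-t / tau)
    tc = t - t.mean()
    return float((tc * y).sum() / (tc * tc).sum())


def make_recoil(
    truth: RecoilTruth,
    n_pupae: int = 1,
    group: str | None = None,
    seed: int = 0,
) -> list[AblationSeries]:
    """Post-ablation vertex tracks whose recoil analysis recovers the truth.

    Axis lengths follow L(t) = L_inf - (L_inf - L0) exp(-t / tau) with
    L_inf per axis chosen so the OLS slope over frames 1..6 equals the
    requested initial velocity exactly (before noise). Vertices are
    sampled on the ellipse at fixed polar angles with Gaussian jitter.
    """
    rng = _rng(seed, "recoil")
    s = _ols_slope_factor(truth.tau)
    d_major = truth.v_major / s
    d_minor = truth.v_minor / s
    t = np.arange(1.0, truth.n_frames + 1.0)
    theta = math.radians(truth.major_axis_angle)
    u = np.array([math.cos(theta), -math.sin(theta)])
    w = np.array([-math.sin(theta), -math.cos(theta)])
    center = np.array([50.0, 50.0])
    series = []
    for p in range(n_pupae):
        pupa = f"{group or 'wt'}_p{p:02d}"
        phis = np.linspace(0, 2 * math.pi, truth.n_vertices, endpoint=False)
        phis = phis + rng.uniform(-0.08, 0.08, truth.n_vertices)
        L_maj = (truth.L0 + d_major) - d_major * np.exp(-t / truth.tau)
        L_min = (truth.L0 + d_minor) - d_minor * np.exp(-t / truth.tau)
        rows = []
        for fi, (tt, lm_, ln_) in enumerate(zip(t, L_maj, L_min), start=1):
            a_, b_ = lm_ / 2.0, ln_ / 2.0
            pts = (
                center[None, :]
                + np.outer(a_ * np.cos(phis), u)
                + np.outer(b_ * np.sin(phis), w)
            )
            if truth.noise_sd > 0:
                pts = pts + rng.normal(0.0, truth.noise_sd, pts.shape)
            for vid, (x, y) in enumerate(pts):
                rows.append(
                    {"frame": fi, "t_s": tt, "vertex_id": vid, "x_um": x, "y_um": y}
                )
        series.append(
            AblationSeries(
                pupa_id=pupa,
                frames=pd.DataFrame(rows),
                geometry_diameter_um=truth.L0,
                group=group,
            )
        )
    return series
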