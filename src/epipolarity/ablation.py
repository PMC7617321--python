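"""Tissue-tension anisotropy from circular laser-ablation recoil.

After a circular cut the wound edge recoils into an ellipse whose axis
lengths report the tension borne along each axis. Tracked vertices on
the wound edge are fitted with a direct least-squares ellipse per frame;
each axis-length series is fitted with a saturating exponential
L(t) = L_inf - (L_inf - L0) exp(-t / tau) (a Kelvin-Voigt-type
relaxation), and the initial recoil velocity is the ordinary
least-squares slope of the length over the first five seconds of recoil
(frames t = 1..6 at 1 frame/s). Major- and minor-axis velocities are
compared per genotype with an unpaired Student's t-test across pupae.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.measure import EllipseModel

from .angles import ReferenceAxis, normalize_angle

__all__ = [
    "AblationSeries",
    "EllipseFrame",
    "EllipseTimeSeries",
    "RecoilResult",
    "AnisotropyReport",
    "fit_ellipse",
    "fit_ellipse_series",
    "fit_axis_dynamics",
    "initial_recoil_velocity",
    "analyze_recoil",
    "compare_axes",
]

RECOIL_FRAMES = np.arange(1.0, 7.0)  # t = 1..6 s at 1 frame/s


@dataclass
class AblationSeries:
    """Tracked wound-edge vertices around one ablation, per frame."""

    pupa_id: str
    frames: pd.DataFrame  # columns: frame, t_s, vertex_id, x_um, y_um
    geometry_diameter_um: float = 24.3
    frame_rate_hz: float = 1.0
    group: str | None = None

    def __post_init__(self) -> None:
        needed = {"frame", "t_s", "vertex_id", "x_um", "y_um"}
        missing = needed - set(self.frames.columns)
        if missing:
            raise ValueError(f"ablation series missing columns: {sorted(missing)}")
        per_frame = self.frames.groupby("frame")["vertex_id"].count()
        if (per_frame < 5).any():
            raise ValueError("need at least 5 tracked vertices per frame")
        if per_frame.size < 6:
            raise ValueError("need at least 6 post-ablation frames")


@dataclass
class EllipseFrame:
    t_s: float
    center: np.ndarray
    major_length: float  # full axis length, um
    minor_length: float
    orientation: float  # degrees [0, 180), SOP-normalized


@dataclass
class EllipseTimeSeries:
    frames: list[EllipseFrame]

    def axis_lengths(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = np.array([f.t_s for f in self.frames])
        return t, np.array([f.major_length for f in self.frames]), np.array(
            [f.minor_length for f in self.frames]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_s": f.t_s,
                    "center_x": f.center[0],
                    "center_y": f.center[1],
                    "major_um": f.major_length,
                    "minor_um": f.minor_length,
                    "orientation_deg": f.orientation,
                }
                for f in self.frames
            ]
        )


@dataclass
class AxisDynamics:
    L0: float
    L_inf: float
    tau: float
    flags: list[str]


@dataclass
class RecoilResult:
    pupa_id: str
    v_major: float  # um/s
    v_minor: float
    major_dynamics: AxisDynamics | None
    minor_dynamics: AxisDynamics | None
    anisotropy: float  # v_major / v_minor
    group: str | None = None


def fit_ellipse(points: np.ndarray, axis: ReferenceAxis | float = 0.0) -> EllipseFrame:
    """Direct least-squares ellipse through wound-edge vertices.

    Returns full major/minor axis lengths (a >= b) and the
    SOP-normalized major-axis orientation; a circle reports orientation
    0 by convention. Requires >= 5 non-collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (x, y) points")
    d = pts - pts.mean(axis=0)
    if np.linalg.eigvalsh(d.T @ d)[0] <= 1e-12 * max(np.linalg.eigvalsh(d.T @ d)[1], 1e-300):
        raise ValueError("degenerate (collinear) points")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not np.all(np.isfinite([xc, yc, a, b, theta])):
        raise ValueError("ellipse fit failed")
    if a < b:
        a, b = b, a
        theta += math.pi / 2.0
    # EllipseModel's theta is math-convention on raw (x, y); with y down
    # the on-screen angle is its negation
    raw = (-math.degrees(theta)) % 180.0
    if (a - b) / max(a, 1e-300) < 1e-9:
        ori = 0.0
    else:
        ori = normalize_angle(raw, axis)
    return EllipseFrame(
        t_s=math.nan,
        center=np.array([xc, yc]),
        major_length=2.0 * a,
        minor_length=2.0 * b,
        orientation=ori,
    )


def fit_ellipse_series(series: AblationSeries, axis: ReferenceAxis | float = 0.0) -> EllipseTimeSeries:
    frames = []
    for frame, sub in series.frames.groupby("frame", sort=True):
        ell = fit_ellipse(sub[["x_um", "y_um"]].to_numpy(), axis=axis)
        ell.t_s = float(sub["t_s"].iloc[0])
        frames.append(ell)
    return EllipseTimeSeries(frames=frames)


def _relaxation(t, L0, L_inf, tau):
    return L_inf - (L_inf - L0) * np.exp(-t / tau)


def fit_axis_dynamics(lengths: np.ndarray, t: np.ndarray) -> AxisDynamics:
    """NLS fit of L(t) = L_inf - (L_inf - L0) exp(-t / tau).

    A flat series is flagged ``no_recoil`` (tau is then unidentifiable
    and reported as fitted, with L_inf ~= L0).
    """
    L = np.asarray(lengths, dtype=float)
    t = np.asarray(t, dtype=float)
    if L.size < 6:
        raise ValueError("need at least 6 post-ablation frames")
    flags: list[str] = []
    span = float(L.max() - L.min())
    if span < 1e-9 * max(abs(L).max(), 1.0):
        return AxisDynamics(L0=float(L[0]), L_inf=float(L[0]), tau=math.inf, flags=["no_recoil"])
    p0 = [float(L[0]), float(L[-1]), max((t[-1] - t[0]) / 3.0, 1e-3)]
    try:
        popt, _ = optimize.curve_fit(
            _relaxation,
            t,
            L,
            p0=p0,
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"axis-dynamics fit did not converge: {err}") from err
    L0, L_inf, tau = (float(v) for v in popt)
    if tau <= 0:
        raise ValueError("fitted relaxation time is not positive")
    if abs(L_inf - L0) < 1e-6 * max(abs(L0), 1.0):
        flags.append("no_recoil")
    return AxisDynamics(L0=L0, L_inf=L_inf, tau=tau, flags=flags)


def initial_recoil_velocity(lengths: np.ndarray, t: np.ndarray) -> float:
    """OLS slope of axis length over frames t = 1..6 s (first 5 s)."""
    L = np.asarray(lengths, dtype=float)
    t = np.asarray(t, dtype=float)
    sel = []
    for target in RECOIL_FRAMES:
        hits = np.nonzero(np.isclose(t, target, atol=1e-6))[0]
        if hits.size == 0:
            raise ValueError(f"missing frame at t = {target:g} s")
        sel.append(hits[0])
    tt, ll = t[sel], L[sel]
    slope = float(np.polyfit(tt, ll, 1)[0])
    return slope


def analyze_recoil(series: AblationSeries, axis: ReferenceAxis | float = 0.0) -> RecoilResult:
    ets = fit_ellipse_series(series, axis=axis)
    t, major, minor = ets.axis_lengths()
    v_maj = initial_recoil_velocity(major, t)
    v_min = initial_recoil_velocity(minor, t)
    dyn_maj = fit_axis_dynamics(major, t) if t.size >= 6 else None
    dyn_min = fit_axis_dynamics(minor, t) if t.size >= 6 else None
    return RecoilResult(
        pupa_id=series.pupa_id,
        v_major=v_maj,
        v_minor=v_min,
        major_dynamics=dyn_maj,
        minor_dynamics=dyn_min,
        anisotropy=v_maj / v_min if v_min != 0 else math.inf,
        group=series.group,
    )


@dataclass
class AnisotropyReport:
    group: str | None
    n_pupae: int
    mean_v_major: float
    mean_v_minor: float
    anisotropy: float
    t_statistic: float
    p_value: float
    isotropic: bool  # True when the axis difference is not significant

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "n_pupae": self.n_pupae,
            "mean_v_major_um_s": self.mean_v_major,
            "mean_v_minor_um_s": self.mean_v_minor,
            "anisotropy": self.anisotropy,
            "t": self.t_statistic,
            "p": self.p_value,
            "isotropic": self.isotropic,
        }


def compare_axes(results: list[RecoilResult], alpha: float = 0.05) -> list[AnisotropyReport]:
    """Per-group comparison of major vs minor initial recoil velocities.

    Unpaired Student's t-test on per-pupa velocities; a group with a
    single pupa is refused. ``isotropic`` is True when p >= alpha.
    """
    by_group: dict = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)
    reports = []
    for group, rs in sorted(by_group.items(), key=lambda kv: str(kv[0])):
        if len(rs) < 2:
            raise ValueError(f"group {group!r} has a single pupa; comparison refused")
        vmaj = np.array([r.v_major for r in rs])
        vmin = np.array([r.v_minor for r in rs])
        if vmaj.var() == 0 and vmin.var() == 0 and vmaj.mean() == vmin.mean():
            # degenerate but well-defined: identical constant samples
            tt = type("TT", (), {"statistic": 0.0, "pvalue": 1.0})()
        else:
            tt = stats.ttest_ind(vmaj, vmin, equal_var=True)
        mean_min = float(vmin.mean())
        reports.append(
            AnisotropyReport(
                group=group,
                n_pupae=len(rs),
                mean_v_major=float(vmaj.mean()),
                mean_v_minor=mean_min,
                anisotropy=float(vmaj.mean() / mean_min) if mean_min != 0 else math.inf,
                t_statistic=float(tt.statistic),
                p_value=float(tt.pvalue),
                isotropic=bool(tt.pvalue >= alpha),
            )
        )
    return reports
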