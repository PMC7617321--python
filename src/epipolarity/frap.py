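"""FRAP recovery analysis: QC gates, bleaching correction, curve fits.

The chain mirrors a standard junctional-FRAP workflow on an epithelium:

1. quality control — initial bleach depth must lie in [50, 75] % and
   cumulative acquisition bleaching (measured on paired unbleached
   control ROIs) must stay below 25 %;
2. correction — each bleached-ROI series is divided by its control's
   relative decay and referenced to the pre-bleach mean, cancelling any
   multiplicative imaging-induced bleaching and background offset;
3. normalization — corrected intensities are mapped so the first
   post-bleach point is 0 and full pre-bleach recovery is 1;
4. fitting — one-phase recovery y = y_max (1 - exp(-a t)), where y_max
   is the mobile fraction (plateau) and ln 2 / a the half-life; an
   optional two-phase variant tests for fast + slow recovery modes;
5. aggregation — per-pupa mean curves are fitted (ROIs are technical
   replicates, pupae biological ones) and plateaus compared between
   groups with an unpaired Student's t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FrapTrace",
    "FrapQC",
    "FrapFit",
    "default_schedule",
    "initial_bleaching",
    "acquisition_bleaching",
    "quality_control",
    "correct_trace",
    "normalize_trace",
    "fit_one_phase",
    "fit_two_phase",
    "pupa_mean_curves",
    "aggregate_and_compare",
    "traces_from_frame",
    "traces_to_frame",
    "INITIAL_BLEACH_BOUNDS",
    "ACQ_BLEACH_MAX",
]

INITIAL_BLEACH_BOUNDS = (50.0, 75.0)  # percent, inclusive
ACQ_BLEACH_MAX = 25.0  # percent, exclusive upper gate


def default_schedule() -> np.ndarray:
    """Post-bleach acquisition times (s): immediate frame, then
    5 frames every 5 s, 10 every 10 s, 10 every 15 s and 7 every 30 s."""
    t = [0.0]
    for n, dt in ((5, 5.0), (10, 10.0), (10, 15.0), (7, 30.0)):
        for _ in range(n):
            t.append(t[-1] + dt)
    return np.array(t)


@dataclass
class FrapTrace:
    """One bleached ROI with its paired unbleached control series."""

    pupa_id: str
    roi_id: str
    orientation_class: str  # "PD" or "AP"
    t_post: np.ndarray  # seconds, first entry immediately post-bleach
    i_pre: np.ndarray  # >= 3 pre-bleach intensities of the bleached ROI
    i_post: np.ndarray
    u_pre: np.ndarray  # control ROI, pre-bleach
    u_post: np.ndarray
    background: float = 0.0
    group: str | None = None  # genotype / condition label

    def __post_init__(self) -> None:
        for name in ("t_post", "i_pre", "i_post", "u_pre", "u_post"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.i_pre.size < 3:
            raise ValueError("need at least 3 pre-bleach points")
        if np.any(np.diff(self.t_post) <= 0):
            raise ValueError("post-bleach times must be strictly increasing")
        if self.i_post.shape != self.t_post.shape or self.u_post.shape != self.t_post.shape:
            raise ValueError("post-bleach series lengths must match the schedule")
        if min(self.i_pre.min(), self.i_post.min(), self.u_pre.min(), self.u_post.min()) < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass
class FrapQC:
    initial_bleaching_pct: float
    acquisition_bleaching_pct: float
    passed: bool


@dataclass
class FrapFit:
    y_max: float
    alpha: float  # 1/s
    half_life: float  # s = ln2 / alpha
    y_max_ci: tuple[float, float]
    alpha_ci: tuple[float, float]
    model: str  # "one_phase" | "two_phase"
    n_points: int
    converged: bool = True
    extra: dict = field(default_factory=dict)  # two-phase: A1, A2, alpha1, alpha2, ...


def _as_traces(traces) -> list[FrapTrace]:
    return [traces] if isinstance(traces, FrapTrace) else list(traces)


def initial_bleaching(traces) -> float:
    """Percent bleach depth: 100 - 100 * (mean first post-bleach / mean
    pre-bleach), averaged over the supplied same-orientation ROIs."""
    ts = _as_traces(traces)
    i_pre = float(np.mean([t.i_pre.mean() for t in ts]))
    i_0 = float(np.mean([t.i_post[0] for t in ts]))
    if i_pre <= 0:
        raise ValueError("mean pre-bleach intensity must be positive")
    return 100.0 - 100.0 * i_0 / i_pre


def acquisition_bleaching(traces) -> float:
    """Percent signal loss of the unbleached controls over the run:
    100 * (U_pre - U_end) / (U_pre - background)."""
    ts = _as_traces(traces)
    u_pre = float(np.mean([t.u_pre.mean() for t in ts]))
    u_end = float(np.mean([t.u_post[-1] for t in ts]))
    bg = float(np.mean([t.background for t in ts]))
    if u_pre <= bg:
        raise ValueError("mean control pre-bleach intensity must exceed background")
    return 100.0 * (u_pre - u_end) / (u_pre - bg)


def quality_control(traces) -> FrapQC:
    ini = initial_bleaching(traces)
    acq = acquisition_bleaching(traces)
    ok = INITIAL_BLEACH_BOUNDS[0] <= ini <= INITIAL_BLEACH_BOUNDS[1] and acq < ACQ_BLEACH_MAX
    return FrapQC(initial_bleaching_pct=ini, acquisition_bleaching_pct=acq, passed=ok)


def correct_trace(trace: FrapTrace, reference: str = "pre_bleach") -> tuple[np.ndarray, np.ndarray]:
    """Bleaching- and background-corrected series.

    A_n = [(U_pre - bg) / (U_n - bg)] * [(I_n - bg) / (ref - bg)] where
    the reference is the pre-bleach mean of the bleached ROI (pre-bleach
    points then map to ~1 and the bleach floor to the bleach depth). The
    ``"post_bleach"`` reference instead divides by the first post-bleach
    intensity, the literal alternative reading; it is provided for
    comparison but breaks the 0-to-1 normalization convention.

    Returns ``(a_pre, a_post)``.
    """
    bg = trace.background
    u_ref = trace.u_pre.mean() - bg
    if u_ref <= 0:
        raise ValueError("control pre-bleach mean must exceed background")
    if reference == "pre_bleach":
        ref = trace.i_pre.mean() - bg
    elif reference == "post_bleach":
        ref = trace.i_post[0] - bg
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if ref <= 0:
        raise ValueError("reference intensity must exceed background")
    out = []
    for i_arr, u_arr in ((trace.i_pre, trace.u_pre), (trace.i_post, trace.u_post)):
        u = u_arr - bg
        bad = np.nonzero(u <= 0)[0]
        if bad.size:
            raise ValueError(f"control intensity at/below background at timepoint index {bad[0]}")
        out.append((u_ref / u) * ((i_arr - bg) / ref))
    return out[0], out[1]


def normalize_trace(a_post: np.ndarray) -> np.ndarray:
    """Map the corrected post-bleach series to [0, 1]:
    N(n) = (A_n - A_0) / (1 - A_0), so N(0) = 0 and full recovery is 1."""
    a = np.asarray(a_post, dtype=float)
    a0 = a[0]
    if a0 >= 1.0:
        raise ValueError("no bleach depth: first corrected post-bleach value >= 1")
    return (a - a0) / (1.0 - a0)


def _one_phase(t, y_max, alpha):
    return y_max * (1.0 - np.exp(-alpha * t))


def _ci_from_cov(popt, pcov, dof, level=0.95):
    if pcov is None or not np.all(np.isfinite(pcov)):
        return [(math.nan, math.nan)] * len(popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    q = stats.t.ppf(0.5 + level / 2.0, max(dof, 1))
    return [(p - q * s, p + q * s) for p, s in zip(popt, se)]


def fit_one_phase(n_series: np.ndarray, t: np.ndarray) -> FrapFit:
    """Nonlinear least-squares fit of y = y_max (1 - exp(-a t)).

    Starting values: y_max from the last observation, alpha from the
    time to half-plateau; bounds y_max in (0, 1.5], alpha in (0, 10] 1/s.
    95 % CIs come from the asymptotic covariance of the estimate.
    """
    y = np.asarray(n_series, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 post-bleach points")
    y_max0 = max(float(y[-1]), 1e-3)
    half_idx = np.nonzero(y >= 0.5 * y_max0)[0]
    t_half = t[half_idx[0]] if half_idx.size and t[half_idx[0]] > 0 else max(t[-1] / 4.0, 1e-6)
    alpha0 = min(max(math.log(2.0) / t_half, 1e-6), 10.0)
    try:
        popt, pcov = optimize.curve_fit(
            _one_phase,
            t,
            y,
            p0=[min(y_max0, 1.5), alpha0],
            bounds=([1e-12, 1e-12], [1.5, 10.0]),
            xtol=1e-10,
            ftol=1e-10,
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"one-phase FRAP fit did not converge: {err}") from err
    y_max, alpha = float(popt[0]), float(popt[1])
    if alpha <= 0:
        raise ValueError("fitted rate constant is not positive")
    cis = _ci_from_cov(popt, pcov, dof=y.size - 2)
    return FrapFit(
        y_max=y_max,
        alpha=alpha,
        half_life=math.log(2.0) / alpha,
        y_max_ci=cis[0],
        alpha_ci=cis[1],
        model="one_phase",
        n_points=int(y.size),
    )


def _two_phase(t, a1, k1, a2, k2):
    return a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def fit_two_phase(n_series: np.ndarray, t: np.ndarray) -> FrapFit:
    """Two-phase fit y = A1 (1 - e^{-a1 t}) + A2 (1 - e^{-a2 t}), a1 > a2.

    On non-convergence or an ill-conditioned covariance (near-equal
    rates), confidence intervals are reported as NaN rather than raising;
    plateau = A1 + A2 and the reported rate is the slow phase's.
    """
    y = np.asarray(n_series, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 post-bleach points")
    y_end = max(float(y[-1]), 1e-3)
    p0 = [0.5 * y_end, 0.1, 0.5 * y_end, 0.01]
    converged = True
    try:
        popt, pcov = optimize.curve_fit(
            _two_phase,
            t,
            y,
            p0=p0,
            bounds=([0.0, 1e-12, 0.0, 1e-12], [1.5, 10.0, 1.5, 10.0]),
            xtol=1e-10,
            ftol=1e-10,
            maxfev=20000,
        )
    except RuntimeError:
        popt = np.full(4, math.nan)
        pcov = None
        converged = False
    if converged and popt[1] < popt[3]:  # order phases fast-first
        popt = np.array([popt[2], popt[3], popt[0], popt[1]])
        if pcov is not None:
            perm = [2, 3, 0, 1]
            pcov = pcov[np.ix_(perm, perm)]
    cis = _ci_from_cov(popt, pcov, dof=y.size - 4) if converged else [(math.nan, math.nan)] * 4
    a1, k1, a2, k2 = (float(v) for v in popt)
    plateau = a1 + a2 if converged else math.nan
    slow = k2 if converged else math.nan
    return FrapFit(
        y_max=plateau,
        alpha=slow,
        half_life=(math.log(2.0) / slow) if converged and slow > 0 else math.nan,
        y_max_ci=(math.nan, math.nan),
        alpha_ci=cis[3],
        model="two_phase",
        n_points=int(y.size),
        converged=converged,
        extra={
            "A1": a1,
            "alpha1": k1,
            "A2": a2,
            "alpha2": k2,
            "A1_ci95": cis[0],
            "alpha1_ci95": cis[1],
            "A2_ci95": cis[2],
            "alpha2_ci95": cis[3],
        },
    )


def pupa_mean_curves(
    traces: list[FrapTrace],
    reference: str = "pre_bleach",
    by_orientation: bool = True,
) -> dict[tuple, tuple[np.ndarray, np.ndarray]]:
    """Average normalized recovery per (group, pupa[, orientation]).

    Each ROI is corrected and normalized individually; the per-pupa curve
    is the mean across its (typically four) same-orientation ROIs, or
    across all of the pupa's ROIs when ``by_orientation`` is False.
    """
    buckets: dict[tuple, list[FrapTrace]] = {}
    for tr in traces:
        key = (tr.group, tr.pupa_id, tr.orientation_class if by_orientation else "all")
        buckets.setdefault(key, []).append(tr)
    out = {}
    for key, members in sorted(buckets.items(), key=lambda kv: tuple(str(x) for x in kv[0])):
        t = members[0].t_post
        curves = []
        for tr in members:
            if tr.t_post.shape != t.shape or not np.allclose(tr.t_post, t):
                raise ValueError("ROIs of one pupa must share the acquisition schedule")
            _, a_post = correct_trace(tr, reference=reference)
            curves.append(normalize_trace(a_post))
        out[key] = (t, np.mean(curves, axis=0))
    return out


@dataclass
class FrapComparison:
    group_a: str
    group_b: str
    y_max_a: float
    y_max_b: float
    delta_y_max: float
    t_statistic: float
    p_value: float
    n_pupae: tuple[int, int]


def aggregate_and_compare(
    traces: list[FrapTrace],
    compare_by: str = "orientation",
    model: str = "one_phase",
    reference: str = "pre_bleach",
) -> dict:
    """Per-pupa fits, group-level fits and plateau comparison.

    ``compare_by`` is ``"orientation"`` (PD vs AP junctions) or
    ``"group"`` (genotype/condition label). Statistical comparison uses
    the per-pupa plateau values (pupae are the biological replicates)
    with an unpaired Student's t-test; groups with fewer than two pupae
    are refused.
    """
    fitter = fit_one_phase if model == "one_phase" else fit_two_phase
    curves = pupa_mean_curves(
        traces, reference=reference, by_orientation=(compare_by == "orientation")
    )

    def cmp_key(key):
        group, pupa, orientation = key
        return orientation if compare_by == "orientation" else (group or "all")

    per_pupa: dict[str, list[tuple[str, FrapFit]]] = {}
    fits_rows = []
    for key, (t, n) in curves.items():
        fit = fitter(n, t)
        label = cmp_key(key)
        per_pupa.setdefault(label, []).append((key[1], fit))
        fits_rows.append(
            {
                "comparison_group": label,
                "group": key[0],
                "pupa": key[1],
                "orientation": key[2],
                "y_max": fit.y_max,
                "y_max_lo": fit.y_max_ci[0],
                "y_max_hi": fit.y_max_ci[1],
                "alpha": fit.alpha,
                "half_life": fit.half_life,
                "model": fit.model,
            }
        )
    labels = sorted(per_pupa)
    for lab in labels:
        if len(per_pupa[lab]) < 2:
            raise ValueError(f"group {lab!r} has a single pupa; comparison refused")

    # group-level fit on the cross-pupa mean curve
    group_fits: dict[str, FrapFit] = {}
    for lab in labels:
        keys = [k for k in curves if cmp_key(k) == lab]
        t = curves[keys[0]][0]
        mean_curve = np.mean([curves[k][1] for k in keys], axis=0)
        group_fits[lab] = fitter(mean_curve, t)

    comparisons = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            ya = np.array([f.y_max for _, f in per_pupa[la]])
            yb = np.array([f.y_max for _, f in per_pupa[lb]])
            if ya.var() == 0 and yb.var() == 0 and ya.mean() == yb.mean():
                # identical constant groups: no evidence of a difference
                tt = type("TT", (), {"statistic": 0.0, "pvalue": 1.0})()
            else:
                tt = stats.ttest_ind(ya, yb, equal_var=True)
            comparisons.append(
                FrapComparison(
                    group_a=la,
                    group_b=lb,
                    y_max_a=float(ya.mean()),
                    y_max_b=float(yb.mean()),
                    delta_y_max=float(ya.mean() - yb.mean()),
                    t_statistic=float(tt.statistic),
                    p_value=float(tt.pvalue),
                    n_pupae=(ya.size, yb.size),
                )
            )
    return {
        "per_pupa_fits": pd.DataFrame(fits_rows),
        "group_fits": group_fits,
        "comparisons": comparisons,
    }


def traces_to_frame(traces: list[FrapTrace]) -> pd.DataFrame:
    """Long-format table: one row per (trace, timepoint); pre-bleach
    timepoints carry negative pseudo-times -3, -2, -1."""
    rows = []
    for tr in traces:
        pre_t = -np.arange(tr.i_pre.size, 0, -1, dtype=float)
        for t, i, u in zip(pre_t, tr.i_pre, tr.u_pre):
            rows.append((tr.pupa_id, tr.roi_id, tr.orientation_class, tr.group, t, i, u, tr.background))
        for t, i, u in zip(tr.t_post, tr.i_post, tr.u_post):
            rows.append((tr.pupa_id, tr.roi_id, tr.orientation_class, tr.group, t, i, u, tr.background))
    return pd.DataFrame(
        rows,
        columns=[
            "pupa_id",
            "roi_id",
            "orientation",
            "group",
            "timepoint_s",
            "intensity",
            "control_intensity",
            "background",
        ],
    )


def traces_from_frame(df: pd.DataFrame) -> list[FrapTrace]:
    traces = []
    group_col = "group" if "group" in df.columns else None
    for (pupa, roi), sub in df.groupby(["pupa_id", "roi_id"], sort=True):
        sub = sub.sort_values("timepoint_s", kind="stable")
        pre = sub[sub["timepoint_s"] < 0]
        post = sub[sub["timepoint_s"] >= 0]
        traces.append(
            FrapTrace(
                pupa_id=str(pupa),
                roi_id=str(roi),
                orientation_class=str(sub["orientation"].iloc[0]),
                t_post=post["timepoint_s"].to_numpy(),
                i_pre=pre["intensity"].to_numpy(),
                i_post=post["intensity"].to_numpy(),
                u_pre=pre["control_intensity"].to_numpy(),
                u_post=post["control_intensity"].to_numpy(),
                background=float(sub["background"].iloc[0]),
                group=str(sub[group_col].iloc[0]) if group_col else None,
            )
        )
    return traces
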