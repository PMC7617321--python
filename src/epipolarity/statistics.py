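"""Distribution comparisons and group tests for the pipeline's outputs.

Angle distributions (division axes, T1 new-junction angles, polarity
angles) are compared with a two-sample Kolmogorov-Smirnov test on the
raw angles treated as linear data on [0, 180) with the origin fixed at
the SOP axis (note: for circular data this makes D origin-dependent; the
fixed anatomical origin makes it well-defined here). Scalar per-pupa
quantities (e.g. AP:PD ratios) are compared with an unpaired Student's
t-test for two groups, or one-way ANOVA with Tukey-Kramer-adjusted
pairwise comparisons for three or more.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .polarity import AngularDistribution

__all__ = [
    "KSResult",
    "GroupComparison",
    "ks_two_sample",
    "compare_groups",
    "circular_histogram_table",
    "EXACT_KS_MAX_PRODUCT",
]

EXACT_KS_MAX_PRODUCT = 10_000  # exact p-value below this n1*n2, else asymptotic


@dataclass
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(angles1, angles2) -> KSResult:
    """Two-sample KS test on angle samples in [0, 180).

    D is the maximum absolute difference between the two empirical CDFs;
    the p-value is exact for small samples (n1*n2 <= 10^4) and
    asymptotic otherwise.
    """
    a1 = np.asarray(angles1, dtype=float)
    a2 = np.asarray(angles2, dtype=float)
    if a1.size == 0 or a2.size == 0:
        raise ValueError("both samples must be nonempty")
    for a in (a1, a2):
        if np.any((a < 0) | (a >= 180.0)):
            raise ValueError("angles must lie in [0, 180)")
    pooled = np.concatenate([a1, a2])
    has_ties = np.unique(pooled).size < pooled.size
    # scipy's exact p-value is unavailable with ties; D is exact either way
    method = "exact" if (a1.size * a2.size <= EXACT_KS_MAX_PRODUCT and not has_ties) else "asymp"
    res = stats.ks_2samp(a1, a2, method=method)
    return KSResult(D=float(res.statistic), p_value=float(res.pvalue), n1=a1.size, n2=a2.size)


@dataclass
class GroupComparison:
    test: str  # "t_test" | "anova_tukey"
    groups: list[str]
    statistic: float  # t or F
    p_value: float  # overall test p
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_raw, p_adjusted


def _pooled_pairwise_p(values: dict[str, np.ndarray]) -> pd.DataFrame:
    """Unadjusted pairwise t-tests using the pooled ANOVA error variance."""
    labels = sorted(values)
    n_tot = sum(v.size for v in values.values())
    k = len(labels)
    dof = n_tot - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in values.values())
    mse = sse / dof if dof > 0 else np.nan
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        va, vb = values[la], values[lb]
        diff = float(va.mean() - vb.mean())
        se = np.sqrt(mse * (1.0 / va.size + 1.0 / vb.size))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            tstat = 0.0 if diff == 0 else np.inf
        else:
            tstat = diff / se
            p = 2.0 * float(stats.t.sf(abs(tstat), dof))
        rows.append({"group_a": la, "group_b": lb, "diff": diff, "t": tstat, "p_raw": p})
    return pd.DataFrame(rows)


def compare_groups(values: dict[str, list | np.ndarray]) -> GroupComparison:
    """Compare scalar values across labelled groups.

    Two groups: unpaired Student's t-test. Three or more: one-way ANOVA
    plus Tukey-Kramer multiple-comparison-adjusted pairwise p-values.
    Every group needs at least two values.
    """
    vals = {str(k): np.asarray(v, dtype=float) for k, v in values.items()}
    if len(vals) < 2:
        raise ValueError("need at least two groups")
    for k, v in vals.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than two values; comparison refused")
    labels = sorted(vals)
    if len(labels) == 2:
        va, vb = vals[labels[0]], vals[labels[1]]
        if va.var() == 0 and vb.var() == 0 and va.mean() == vb.mean():
            tstat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(va, vb, equal_var=True)
            tstat, p = float(res.statistic), float(res.pvalue)
        pairwise = pd.DataFrame(
            [
                {
                    "group_a": labels[0],
                    "group_b": labels[1],
                    "diff": float(va.mean() - vb.mean()),
                    "p_raw": p,
                    "p_adjusted": p,
                }
            ]
        )
        return GroupComparison(
            test="t_test", groups=labels, statistic=tstat, p_value=p, pairwise=pairwise
        )

    arrays = [vals[k] for k in labels]
    f_res = stats.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    grp = np.concatenate([[k] * vals[k].size for k in labels])
    tukey = pairwise_tukeyhsd(flat, grp)
    tk = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    tk = tk.rename(columns={"group1": "group_a", "group2": "group_b", "p-adj": "p_adjusted"})
    tk["p_adjusted"] = np.asarray(tukey.pvalues, dtype=float)
    raw = _pooled_pairwise_p(vals)
    pairwise = raw.merge(
        tk[["group_a", "group_b", "p_adjusted"]], on=["group_a", "group_b"], how="left"
    )
    return GroupComparison(
        test="anova_tukey",
        groups=labels,
        statistic=float(f_res.statistic),
        p_value=float(f_res.pvalue),
        pairwise=pairwise[["group_a", "group_b", "diff", "p_raw", "p_adjusted"]],
    )


def circular_histogram_table(dist: AngularDistribution) -> pd.DataFrame:
    """Plot-ready 18-row table with bin bounds and normalized weights."""
    total = float(dist.bin_weights.sum())
    norm = dist.bin_weights / total if total > 0 else np.zeros_like(dist.bin_weights)
    return pd.DataFrame(
        {
            "bin_start": dist.bin_edges[:-1],
            "bin_end": dist.bin_edges[1:],
            "weight": dist.bin_weights,
            "normalized_weight": norm,
        }
    )
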