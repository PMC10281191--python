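"""Group-level statistics: baseline tables, AUC comparisons, clinical correlation.

Baseline demographic and clinical characteristics are compared with a pooled
equal-variance two-sample t-test (computable from printed ``mean ± SD``
summaries alone) for continuous variables and a Yates-corrected χ² (or
Fisher's exact test) for 2×2 categorical tables. The primary outcome
(pre/post motor score) is handled by a repeated-measures-style ANOVA:
between-group one-way F at each timepoint — for two groups, ``F = t²`` —
plus within-group F from raw paired scores. Topology is compared as one
two-sample t-test per network × metric on sparsity-AUC values, flagged at an
uncorrected α (0.05 by default); metric–clinical association uses Pearson
product-moment correlation.

No multiple-testing correction is applied by default; Bonferroni and
Benjamini–Hochberg adjustments can be requested, with the caveat that the
default matches the uncorrected convention of the original screening design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStat",
    "GroupComparisonResult",
    "CorrelationResult",
    "two_sample_t_summary",
    "two_sample_t_raw",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "anova_pre_post",
    "pearson_correlation",
    "compare_networks",
]


@dataclass
class SummaryStat:
    """n, mean, SD — one printed table cell."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")

    @classmethod
    def from_values(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=np.float64)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass
class GroupComparisonResult:
    statistic: str  # one of t, chi2, F, Z
    value: float
    df: float | tuple[float, float]
    p: float
    context: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass
class CorrelationResult:
    R: float
    p: float
    n: int


def two_sample_t_summary(
    a: SummaryStat, b: SummaryStat, context: str = ""
) -> GroupComparisonResult:
    """Pooled equal-variance two-sample t from summary statistics.

    df = n_a + n_b − 2; two-sided p. When both SDs are zero and the means
    equal, t = 0 by convention (identical degenerate samples).
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return GroupComparisonResult("t", 0.0, a.n + b.n - 2, 1.0, context)
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return GroupComparisonResult("t", float(t), a.n + b.n - 2, float(p), context)


def two_sample_t_raw(x, y, context: str = "") -> GroupComparisonResult:
    """Pooled two-sample t on raw values; identical to the summary path."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    return two_sample_t_summary(
        SummaryStat.from_values(x), SummaryStat.from_values(y), context
    )


def chi_square_2x2(
    table, yates: bool = True, context: str = ""
) -> GroupComparisonResult:
    """χ² test on a 2×2 contingency table, Yates-corrected by default."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be nonnegative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return GroupComparisonResult("chi2", float(chi2), float(df), float(p), context)


def fisher_exact_2x2(table, context: str = "") -> GroupComparisonResult:
    """Fisher's exact test (two-sided) as the small-count alternative."""
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    odds, p = sps.fisher_exact(t)
    return GroupComparisonResult("chi2", float(odds), 1.0, float(p),
                                 context or "fisher_exact")


def anova_pre_post(
    pre_a: SummaryStat | None = None,
    pre_b: SummaryStat | None = None,
    post_a: SummaryStat | None = None,
    post_b: SummaryStat | None = None,
    raw: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict[str, GroupComparisonResult]:
    """Pre/post two-group ANOVA decomposition.

    Summary path: between-group one-way F at each timepoint (for two groups
    ``F = t²``, p from ``F(1, n−2)``). Raw path (``raw`` maps group name to
    ``(pre, post)`` paired arrays): additionally the within-group
    repeated-measures F — for two timepoints the squared paired t — and a
    Tukey HSD comparison of post scores.

    The within-group F cannot be recovered from summaries alone (it depends
    on the unreported pre–post correlation); asking for it without raw data
    raises.
    """
    results: dict[str, GroupComparisonResult] = {}

    def _between(a: SummaryStat, b: SummaryStat, label: str) -> None:
        t = two_sample_t_summary(a, b, context=label)
        f = t.value ** 2
        dfd = a.n + b.n - 2
        p = float(sps.f.sf(f, 1, dfd)) if f > 0 else 1.0
        results[f"between_{label}"] = GroupComparisonResult("F", f, (1.0, float(dfd)), p, label)

    if pre_a and pre_b:
        _between(pre_a, pre_b, "pre")
    if post_a and post_b:
        _between(post_a, post_b, "post")

    if raw is None:
        if not results:
            raise ValueError(
                "within-group F requires raw paired scores; summaries alone "
                "cannot recover the pre-post correlation"
            )
        return results

    post_by_group = {}
    for group, (pre, post) in raw.items():
        pre = np.asarray(pre, dtype=np.float64)
        post = np.asarray(post, dtype=np.float64)
        if pre.size != post.size or pre.size < 2:
            raise ValueError(f"group {group!r}: paired pre/post arrays required")
        t, p = sps.ttest_rel(post, pre)
        f = float(t**2)
        results[f"within_{group}"] = GroupComparisonResult(
            "F", f, (1.0, float(pre.size - 1)), float(p), f"within_{group}"
        )
        post_by_group[group] = post
    if len(post_by_group) == 2:
        (ga, xa), (gb, xb) = post_by_group.items()
        hsd = sps.tukey_hsd(xa, xb)
        results["tukey_post"] = GroupComparisonResult(
            "F", float(hsd.statistic[0, 1]), float(xa.size + xb.size - 2),
            float(hsd.pvalue[0, 1]), f"tukey_post_{ga}_vs_{gb}",
        )
    return results


def pearson_correlation(x, y, context: str = "") -> CorrelationResult:
    """Product-moment correlation with two-sided p via the t transform (df = n−2)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(R=float(res.statistic), p=float(res.pvalue), n=x.size)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * p.size / (np.arange(p.size) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError(f"unknown correction {method!r}")


def compare_networks(
    auc_table: pd.DataFrame,
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Per network × metric two-sample t-test on sparsity-AUC values.

    ``auc_table`` must have columns ``subject, group, network, metric, auc``
    with exactly two groups. Returns the full result table (never only the
    significant rows) with columns ``network, metric, mean_<g1>, mean_<g2>,
    t, df, p, p_adj, significant``. Cells where a metric is entirely missing
    in one group are skipped with a warning.
    """
    required = {"subject", "group", "network", "metric", "auc"}
    missing = required - set(auc_table.columns)
    if missing:
        raise ValueError(f"auc_table missing columns: {sorted(missing)}")
    if correction == "none":
        pass
    else:
        warnings.warn(
            f"multiple-testing correction {correction!r} differs from the "
            "uncorrected screening convention", stacklevel=2,
        )
    groups = sorted(auc_table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups

    rows = []
    for (network, metric), cell in auc_table.groupby(["network", "metric"], sort=True):
        x = cell.loc[cell["group"] == g1, "auc"].dropna().to_numpy()
        y = cell.loc[cell["group"] == g2, "auc"].dropna().to_numpy()
        if x.size < 2 or y.size < 2:
            warnings.warn(
                f"{network}/{metric}: insufficient defined AUCs "
                f"({x.size} vs {y.size}); skipped", stacklevel=2,
            )
            continue
        res = two_sample_t_raw(x, y, context=f"{network}/{metric}")
        rows.append({
            "network": network,
            "metric": metric,
            f"mean_{g1}": x.mean(),
            f"mean_{g2}": y.mean(),
            "n_1": x.size,
            "n_2": y.size,
            "t": res.value,
            "df": res.df,
            "p": res.p,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no testable network × metric cells")
    out["p_adj"] = _adjust(out["p"].to_numpy(), correction)
    out["significant"] = out["p_adj"] < alpha
    return out
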