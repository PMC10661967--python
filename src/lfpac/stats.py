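"""Group-comparison statistics for subject-level band powers and MI values.

Band powers are compared with one-way ANOVA preceded by distributional
checks (Shapiro-Wilk normality per group, Bartlett's chi-square test of
variance homogeneity), followed by Tamhane's T2 post hoc pairwise
comparisons, which do not assume equal variances: each pair gets a Welch
t statistic with Satterthwaite degrees of freedom and a Sidak-type
multiplicity adjustment ``p_adj = 1 - (1 - p)^k`` over the ``k`` pairs.

Modulation-index values are compared with the one-tailed Wilcoxon rank-sum
test: exact by enumeration for small tie-free samples (total n <= 12),
normal approximation with tie and continuity corrections otherwise.

The experimental unit throughout is the subject (channel-averaged metrics).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .io import ResultTable

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "normality_test",
    "variance_homogeneity_test",
    "one_way_anova",
    "tamhane_t2",
    "wilcoxon_rank_sum_one_tailed",
    "compare_metric_across_groups",
    "comparison_frame",
]

EXACT_RANKSUM_MAX_N = 12


@dataclass
class GroupSample:
    """Subject-level measurements for one group."""

    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("group values must be one-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.group} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ComparisonResult:
    """Outcome of one statistical test, with an optional pairwise table."""

    test_name: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_groups(groups: Sequence[GroupSample], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < min_n:
            raise ValueError(f"group {g.group} has {g.n} < {min_n} values")


def normality_test(values: Iterable[float]) -> float:
    """Shapiro-Wilk p-value (null: the sample is Gaussian)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise ValueError("normality test requires at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("normality test undefined for a constant sample")
    return float(sst.shapiro(v).pvalue)


def variance_homogeneity_test(groups: Sequence[GroupSample]) -> ComparisonResult:
    """Bartlett's test of equal variances (chi-square statistic under H0)."""
    _check_groups(groups)
    for g in groups:
        if np.var(g.values, ddof=1) == 0:
            raise ValueError(f"group {g.group} has zero variance")
    stat, p = sst.bartlett(*(g.values for g in groups))
    return ComparisonResult("bartlett", float(stat), float(p))


def one_way_anova(groups: Sequence[GroupSample]) -> ComparisonResult:
    """One-way fixed-effects ANOVA F test across groups."""
    _check_groups(groups)
    all_values = np.concatenate([g.values for g in groups])
    if np.ptp(all_values) == 0:
        raise ValueError("ANOVA undefined: all values identical")
    stat, p = sst.f_oneway(*(g.values for g in groups))
    return ComparisonResult("anova", float(stat), float(p))


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df and two-sided p for one pair."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        raise ValueError("zero variance in both samples of a pair")
    t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sst.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def tamhane_t2(groups: Sequence[GroupSample], alpha: float = 0.05) -> ComparisonResult:
    """Tamhane T2 pairwise comparisons for groups with unequal variances.

    Each pair uses the Welch t statistic with Satterthwaite df; per-pair
    p-values are Sidak-adjusted over the ``k = m(m-1)/2`` pairs
    (``p_adj = 1 - (1 - p)^k``).  With a single pair this reduces exactly to
    Welch's t-test.
    """
    _check_groups(groups)
    pairs = list(itertools.combinations(range(len(groups)), 2))
    k = len(pairs)
    rows = []
    for i, j in pairs:
        a, b = groups[i], groups[j]
        t, df, p = _welch_pair(a.values, b.values)
        p_adj = float(min(1.0 - (1.0 - p) ** k, 1.0))
        rows.append({"group_a": a.group, "group_b": b.group, "statistic": t,
                     "df": df, "p_raw": p, "p_adj": p_adj,
                     "significant": p_adj < alpha})
    table = pd.DataFrame(rows)
    best = table.loc[table["p_adj"].idxmin()]
    return ComparisonResult("tamhane_t2", float(best["statistic"]),
                            float(best["p_adj"]), pairwise=table,
                            extra={"alpha": alpha, "n_pairs": k})


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """P(rank sum of a sample like ``a`` <= observed) by full enumeration.

    Valid only for tie-free pooled samples; cost C(na+nb, na) combinations.
    """
    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    w_obs = ranks[:a.size].sum()
    n = pooled.size
    count = sum(1 for c in itertools.combinations(range(1, n + 1), a.size)
                if sum(c) <= w_obs + 1e-9)
    return count / comb(n, a.size)


def wilcoxon_rank_sum_one_tailed(a: Iterable[float], b: Iterable[float],
                                 alternative: str = "less") -> ComparisonResult:
    """One-tailed Wilcoxon rank-sum test of ``a`` against ``b``.

    ``alternative="less"`` tests whether ``a`` is stochastically smaller than
    ``b``.  Exact enumeration of all rank assignments when the pooled sample
    is tie-free with n <= 12; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if alternative == "greater":
        # symmetry: a > b  <=>  b < a
        res = wilcoxon_rank_sum_one_tailed(b, a, "less")
        return ComparisonResult("wilcoxon_rank_sum", -res.statistic, res.p_value,
                                extra=res.extra)
    pooled = np.concatenate([a, b])
    ranks = sst.rankdata(pooled)
    w = float(ranks[:a.size].sum())
    ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_RANKSUM_MAX_N and not ties:
        p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        na, nb = a.size, b.size
        mu = na * (na + nb + 1) / 2.0
        tie_counts = np.array([c for c in
                               pd.Series(pooled).value_counts().to_numpy()])
        tie_term = np.sum(tie_counts ** 3 - tie_counts)
        n = na + nb
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var == 0:
            p = 1.0
        else:
            z = (w - mu + 0.5) / np.sqrt(var)  # continuity-corrected lower tail
            p = float(sst.norm.cdf(z))
        method = "normal_approx"
    return ComparisonResult("wilcoxon_rank_sum", w, float(min(max(p, 0.0), 1.0)),
                            extra={"method": method, "alternative": alternative})


def compare_metric_across_groups(table: ResultTable | pd.DataFrame, metric: str,
                                 procedure: str, alpha: float = 0.05,
                                 control: str | None = None,
                                 alternative: str = "less") -> dict:
    """Run the full comparison battery for one metric of a result table.

    Uses only channel-averaged (``channel == "avg"``) subject-level rows.
    ``procedure="anova+posthoc"`` (band powers): per band, Shapiro-Wilk per
    group and Bartlett homogeneity are logged, then one-way ANOVA and Tamhane
    T2 pairwise comparisons.  ``procedure="ranksum"`` (MI values): each
    non-control group is compared against the control group (the first group
    by appearance unless named) with the one-tailed rank-sum test, default
    alternative "less" (treatment below control).

    Returns ``{band: {test_name: ComparisonResult, ...}, ...}``.
    """
    df = table.df if isinstance(table, ResultTable) else table
    sub = df[(df["metric"] == metric) & (df["channel"] == "avg")]
    if sub.empty:
        raise ValueError(f"no channel-averaged rows for metric {metric!r}")
    results: dict[str, dict[str, ComparisonResult]] = {}
    for band, band_df in sub.groupby("band", sort=False):
        group_names = list(dict.fromkeys(band_df["group"]))
        if len(group_names) < 2:
            raise ValueError(f"metric {metric!r}, band {band!r}: need >= 2 groups")
        groups = [GroupSample(g, band_df.loc[band_df["group"] == g, "value"].to_numpy())
                  for g in group_names]
        out: dict[str, ComparisonResult] = {}
        if procedure == "anova+posthoc":
            norm_p = {g.group: normality_test(g.values) for g in groups}
            out["normality"] = ComparisonResult("shapiro_min", float("nan"),
                                                min(norm_p.values()),
                                                extra={"per_group": norm_p})
            out["homogeneity"] = variance_homogeneity_test(groups)
            out["anova"] = one_way_anova(groups)
            out["posthoc"] = tamhane_t2(groups, alpha=alpha)
        elif procedure == "ranksum":
            ctrl = control if control is not None else group_names[0]
            ctrl_vals = next(g.values for g in groups if g.group == ctrl)
            rows = []
            for g in groups:
                if g.group == ctrl:
                    continue
                res = wilcoxon_rank_sum_one_tailed(g.values, ctrl_vals,
                                                   alternative=alternative)
                rows.append({"group_a": g.group, "group_b": ctrl,
                             "statistic": res.statistic, "p_raw": res.p_value,
                             "p_adj": res.p_value,
                             "significant": res.p_value < alpha})
            table_pw = pd.DataFrame(rows)
            best = table_pw.loc[table_pw["p_raw"].idxmin()]
            out["ranksum"] = ComparisonResult("wilcoxon_rank_sum",
                                              float(best["statistic"]),
                                              float(best["p_raw"]),
                                              pairwise=table_pw,
                                              extra={"control": ctrl,
                                                     "alternative": alternative,
                                                     "alpha": alpha})
        else:
            raise ValueError(f"unknown procedure {procedure!r}")
        results[str(band)] = out
    return results


def comparison_frame(results: dict, metric: str) -> pd.DataFrame:
    """Flatten ``compare_metric_across_groups`` output into an exportable table."""
    rows = []
    for band, tests in results.items():
        for name, res in tests.items():
            if res.pairwise is not None:
                for _, pw in res.pairwise.iterrows():
                    rows.append({"metric": metric, "band": band, "test": res.test_name,
                                 "group_a": pw["group_a"], "group_b": pw["group_b"],
                                 "statistic": pw["statistic"], "p": pw["p_raw"],
                                 "p_adj": pw["p_adj"],
                                 "significant": bool(pw["significant"])})
            else:
                rows.append({"metric": metric, "band": band, "test": res.test_name,
                             "group_a": "", "group_b": "",
                             "statistic": res.statistic, "p": res.p_value,
                             "p_adj": res.p_value,
                             "significant": bool(res.p_value < 0.05)})
    return pd.DataFrame(rows)
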