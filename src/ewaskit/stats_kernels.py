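"""Shared statistical primitives used across the pipeline.

Contingency-table chi-square tests (no continuity correction, matching the
cohort-table and enrichment arithmetic), ordinal trend tests, Benjamini-
Hochberg FDR, the genomic-control inflation factor lambda, the Wallenius
noncentral hypergeometric gene-set test, and a cohort descriptive-summary
table with per-covariate tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# median of the chi-square distribution with 1 df; denominator of lambda
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.45493642...

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "trend_test",
    "bh_fdr",
    "inflation_lambda",
    "wallenius_test",
    "summarize_cohort",
    "CHI2_1DF_MEDIAN",
]


@dataclass
class ContingencyTable:
    """An r-by-c table of nonnegative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (self.counts < 0).any():
            raise ValueError("contingency table counts must be nonnegative")
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise ValueError("contingency table needs at least 2 rows and 2 columns")
        if not self.row_labels:
            self.row_labels = [f"r{i}" for i in range(r)]
        if not self.col_labels:
            self.col_labels = [f"c{j}" for j in range(c)]


def chi_square_test(
    table: ContingencyTable | np.ndarray, continuity: bool = False
) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square test of independence.

    Returns ``(chi2, df, p, expected)``. Expected counts are the product of
    margins over the grand total. No continuity correction by default.

    Raises ``ValueError`` on a zero row or column margin.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, float)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("chi-square test requires positive row and column margins")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=continuity)
    return float(chi2), int(df), float(p), expected


def trend_test(group_scores: np.ndarray, variable: np.ndarray) -> float:
    """Linear trend test of a variable against ordinal group scores.

    For a binary 0/1 variable this is the Cochran-Armitage linear-by-linear
    association test; for a continuous variable it is the slope t-test of
    the value on the group score. Missing values are dropped pairwise.
    Returns the two-sided p-value; a constant variable gives p = 1.
    """
    scores = np.asarray(group_scores, dtype=float)
    values = np.asarray(variable, dtype=float)
    keep = np.isfinite(scores) & np.isfinite(values)
    scores, values = scores[keep], values[keep]
    if len(scores) < 3 or np.ptp(values) == 0 or np.ptp(scores) == 0:
        return 1.0
    uniq = np.unique(values)
    if set(uniq).issubset({0.0, 1.0}):
        # Cochran-Armitage as the linear-by-linear (Mantel-Haenszel) statistic:
        # M^2 = (n-1) r^2 ~ chi-square(1)
        r = np.corrcoef(scores, values)[0, 1]
        m2 = (len(scores) - 1) * r * r
        return float(stats.chi2.sf(m2, 1))
    res = stats.linregress(scores, values)
    return float(res.pvalue)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1. Missing (NaN)
    p-values are propagated as NaN and excluded from m.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.clip(ranked, 0, 1)
    q[ok] = qv
    return q


def inflation_lambda(p: np.ndarray) -> float:
    """Genomic-control inflation factor from two-sided p-values.

    lambda = median( chi2_1df quantile of (1 - p) ) / 0.4549364. A value of
    1.0 indicates calibrated tests; >1 inflation, <1 deflation.
    """
    p = np.asarray(p, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 2:
        raise ValueError("inflation lambda needs at least 2 finite p-values")
    chi2_obs = stats.chi2.isf(p, 1)  # upper-tail quantile of p == ppf(1-p)
    chi2_obs = chi2_obs[np.isfinite(chi2_obs)]
    return float(np.median(chi2_obs) / CHI2_1DF_MEDIAN)


def wallenius_test(
    category_in_selected: int,
    category_total: int,
    universe_selected: int,
    universe_total: int,
    odds: float = 1.0,
) -> float:
    """Upper-tail Wallenius noncentral hypergeometric gene-set p-value.

    Probability of drawing >= ``category_in_selected`` category genes when
    ``universe_selected`` genes are sampled without replacement from a
    universe of ``universe_total`` containing ``category_total`` category
    genes, each category gene carrying sampling ``odds`` relative to the
    rest. With odds = 1 this reduces to the central hypergeometric
    (one-sided Fisher) p-value.
    """
    k, K, n, N = category_in_selected, category_total, universe_selected, universe_total
    if not (0 <= k <= min(K, n)):
        raise ValueError("observed overlap inconsistent with margins")
    if K > N or n > N:
        raise ValueError("category/selection cannot exceed the universe")
    if not np.isfinite(odds) or odds <= 0:
        raise ValueError("odds must be a positive finite number")
    if k == 0:
        return 1.0
    if odds == 1.0:
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    return float(stats.nchypergeom_wallenius.sf(k - 1, N, K, n, odds))


def _is_numeric_continuous(series: pd.Series) -> bool:
    vals = pd.to_numeric(series, errors="coerce").dropna()
    if len(vals) < len(series.dropna()):
        return False
    return vals.nunique() > 5


def summarize_cohort(
    sheet: pd.DataFrame,
    outcome_col: str = "outcome",
    outcome_order: tuple[str, ...] = ("TD", "nonTD", "ASD"),
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive cohort table with a per-covariate test against the outcome.

    Nominal covariates get N (%) per outcome group and a Pearson chi-square
    p-value (complete-case; missing counted in a separate row). Continuous
    covariates get mean (SD) and a linear trend test p-value with outcome
    groups scored 0/1/2 in ``outcome_order``.
    """
    if outcome_col not in sheet.columns:
        raise ValueError(f"sample sheet has no '{outcome_col}' column")
    if covariates is None:
        covariates = [c for c in sheet.columns if c not in (outcome_col, "sample_id")]
    score_map = {g: i for i, g in enumerate(outcome_order)}
    scores_all = sheet[outcome_col].map(score_map)
    rows = []
    for cov in covariates:
        col = sheet[cov]
        n_missing = int(col.isna().sum())
        if _is_numeric_continuous(col):
            vals = pd.to_numeric(col, errors="coerce")
            p = trend_test(scores_all.to_numpy(float), vals.to_numpy(float))
            cells = {
                g: f"{vals[sheet[outcome_col] == g].mean():.1f} ({vals[sheet[outcome_col] == g].std():.2f})"
                for g in outcome_order
            }
            rows.append({"covariate": cov, "level": "continuous", **cells, "p": p})
        else:
            tab = pd.crosstab(col, sheet[outcome_col])
            tab = tab.reindex(columns=[g for g in outcome_order if g in tab.columns])
            try:
                _, _, p, _ = chi_square_test(tab.to_numpy())
            except ValueError:
                p = np.nan
            for i, (level, counts) in enumerate(tab.iterrows()):
                tot = counts.sum()
                cells = {
                    g: f"{counts.get(g, 0)} ({100 * counts.get(g, 0) / max(tot, 1):.1f}%)"
                    for g in outcome_order
                }
                rows.append(
                    {"covariate": cov, "level": str(level), **cells, "p": p if i == 0 else np.nan}
                )
        if n_missing:
            rows.append(
                {"covariate": cov, "level": "Missing", **{g: "" for g in outcome_order},
                 "p": np.nan, "n_missing": n_missing}
            )
    return pd.DataFrame(rows)
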