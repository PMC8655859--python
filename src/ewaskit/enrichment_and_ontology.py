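"""Risk-gene enrichment curves and probe-bias-adjusted ontology testing.

CpG-level association results are lifted to the gene level: a gene is
"nominal" at a threshold when any of its CpGs has p strictly below it. At
each threshold of the significance grid a 2x2 gene-level table (risk vs
non-risk x selected vs not) is tested with a Pearson chi-square (no
continuity correction), with the expected risk-gene overlap reported as the
margins product over the universe size. Permutation controls repeat the
curve with random gene sets the size of the risk set. Ontology categories
are tested with the Wallenius noncentral hypergeometric distribution, with
each category's sampling odds derived from the smoothed relationship
between a gene's probe count and its chance of selection (genes with many
probes are more likely to be nominal by chance alone).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CpGAnnotation, GeneSet
from .stats_kernels import chi_square_test, wallenius_test

__all__ = [
    "GeneUniverse",
    "EnrichmentCurve",
    "build_universe",
    "nominal_gene_set",
    "expected_overlap",
    "enrichment_curve",
    "cross_tissue_overlap",
    "ontology_enrichment",
    "rank_sum_across_tissues",
]


@dataclass
class GeneUniverse:
    """Genes with at least one analysed CpG, and their per-gene probe counts."""

    cpgs_per_gene: dict[str, int]

    @property
    def genes(self) -> set[str]:
        return set(self.cpgs_per_gene)

    def __len__(self) -> int:
        return len(self.cpgs_per_gene)

    def overlap_stats(self, risk: GeneSet, selected: set[str]) -> dict[str, float]:
        """Observed and expected risk-gene overlap plus the percent of risk
        genes selected, from the universe margins."""
        universe = self.genes
        risk_in = risk.genes & universe
        sel = selected & universe
        observed = len(risk_in & sel)
        expected = len(risk_in) * len(sel) / len(universe)
        return {
            "risk_in_universe": len(risk_in),
            "selected": len(sel),
            "universe": len(universe),
            "observed": observed,
            "expected": expected,
            "percent_of_risk": 100.0 * observed / len(risk_in) if risk_in else np.nan,
        }


def build_universe(res: pd.DataFrame, ann: CpGAnnotation) -> GeneUniverse:
    """Count analysed CpGs per gene (symbols deduplicated within a probe).

    Probes absent from the annotation are excluded; probes without gene
    symbols contribute to no gene. An empty universe is an error.
    """
    counts: dict[str, int] = {}
    ann_genes = ann.table["genes"]
    for probe in res.index:
        if probe not in ann_genes.index:
            continue
        for g in set(ann_genes[probe]):
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        raise ValueError("no annotated probes: gene universe is empty")
    return GeneUniverse(counts)


def nominal_gene_set(
    res: pd.DataFrame, ann: CpGAnnotation, threshold: float
) -> set[str]:
    """Genes with at least one CpG at p strictly below the threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    hits = res.index[res["p_value"] < threshold]
    genes: set[str] = set()
    ann_genes = ann.table["genes"]
    for probe in hits:
        if probe in ann_genes.index:
            genes.update(ann_genes[probe])
    return genes


def expected_overlap(n_risk: int, n_selected: int, n_universe: int) -> float:
    """Expected risk-gene overlap under independence: margins product / N."""
    return n_risk * n_selected / n_universe


def _table_for(universe: set[str], risk_in: set[str], selected: set[str]) -> np.ndarray:
    a = len(risk_in & selected)
    b = len(risk_in) - a
    c = len(selected) - a
    d = len(universe) - a - b - c
    return np.array([[a, b], [c, d]], dtype=float)


@dataclass
class EnrichmentCurve:
    """Per-threshold enrichment results plus permutation-null replicates."""

    table: pd.DataFrame                       # indexed by threshold
    permutation_p: pd.DataFrame | None = None  # n_perm x thresholds
    restricted: bool = False
    seed: int | None = None
    risk_name: str = ""


def enrichment_curve(
    res: pd.DataFrame,
    ann: CpGAnnotation,
    risk: GeneSet,
    grid=None,
    n_perm: int = 10,
    seed: int = 0,
    restrict_cpgs: list[str] | None = None,
    match_probe_counts: bool = False,
) -> EnrichmentCurve:
    """Risk-gene enrichment of nominal genes over a p-threshold grid.

    Per threshold: gene-level 2x2 chi-square (via the shared kernel),
    observed and expected overlap. ``n_perm`` negative-control curves use
    random gene sets of size |risk in universe| drawn without replacement
    from the universe; with ``match_probe_counts`` the draw is stratified
    on per-gene probe count. ``restrict_cpgs`` (e.g. meQTL-target CpGs)
    first subsets the result probes, then rebuilds the universe.
    """
    from .data_model import DEFAULT_THRESHOLD_GRID

    grid = tuple(grid) if grid is not None else DEFAULT_THRESHOLD_GRID
    restricted = restrict_cpgs is not None
    if restricted:
        keep = [p for p in res.index if p in set(restrict_cpgs)]
        res = res.loc[keep]
    uni = build_universe(res, ann)
    universe = uni.genes
    risk_in = risk.genes & universe
    if not risk_in:
        raise ValueError("risk gene set does not intersect the gene universe")

    rows = []
    selected_by_t = {}
    for t in grid:
        sel = nominal_gene_set(res, ann, t) & universe
        selected_by_t[t] = sel
        tab = _table_for(universe, risk_in, sel)
        if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
            chi2, _, p, _ = chi_square_test(tab)
        else:
            chi2, p = np.nan, np.nan
        rows.append(
            {
                "threshold": t,
                "selected_gene_count": len(sel),
                "risk_overlap_observed": int(tab[0, 0]),
                "risk_overlap_expected": expected_overlap(
                    len(risk_in), len(sel), len(universe)
                ),
                "chi2": chi2,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("threshold")

    perm_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        genes_arr = np.array(sorted(universe))
        counts = np.array([uni.cpgs_per_gene[g] for g in genes_arr])
        perm_rows = []
        for _ in range(n_perm):
            if match_probe_counts:
                # stratified draw: within probe-count quintiles, sample the
                # same number of genes as the risk set contributes there
                qs = np.quantile(counts, [0.2, 0.4, 0.6, 0.8])
                strat = np.searchsorted(qs, counts)
                risk_strat = np.searchsorted(
                    qs, [uni.cpgs_per_gene[g] for g in sorted(risk_in)]
                )
                fake: list[str] = []
                for s in range(5):
                    pool = genes_arr[strat == s]
                    need = int((risk_strat == s).sum())
                    if need:
                        fake.extend(rng.choice(pool, size=min(need, len(pool)), replace=False))
                fake_set = set(fake)
            else:
                fake_set = set(rng.choice(genes_arr, size=len(risk_in), replace=False))
            pvals = []
            for t in grid:
                tab = _table_for(universe, fake_set, selected_by_t[t])
                if tab.sum(axis=1).min() > 0 and tab.sum(axis=0).min() > 0:
                    _, _, p, _ = chi_square_test(tab)
                else:
                    p = np.nan
                pvals.append(p)
            perm_rows.append(pvals)
        perm_p = pd.DataFrame(perm_rows, columns=list(grid))
        perm_p.index.name = "permutation"
    return EnrichmentCurve(
        table=table,
        permutation_p=perm_p,
        restricted=restricted,
        seed=seed,
        risk_name=risk.name,
    )


def cross_tissue_overlap(
    nominal_sets: dict[str, set[str]], risk: GeneSet
) -> pd.DataFrame:
    """Inclusion-exclusion partition of nominal genes across tissues.

    Returns one row per membership pattern (a tissue -> bool mapping encoded
    in the columns) with counts of risk genes and non-risk genes carrying
    exactly that pattern, plus the all-tissue intersection.
    """
    if len(nominal_sets) < 2:
        raise ValueError("need at least 2 tissues")
    tissues = list(nominal_sets)
    all_genes = set().union(*nominal_sets.values())
    patterns: dict[tuple[bool, ...], dict[str, int]] = {}
    for g in all_genes:
        pat = tuple(g in nominal_sets[t] for t in tissues)
        cell = patterns.setdefault(pat, {"risk": 0, "non_risk": 0})
        cell["risk" if g in risk else "non_risk"] += 1
    rows = []
    for pat, cell in sorted(patterns.items(), reverse=True):
        rows.append(
            {**{t: m for t, m in zip(tissues, pat)}, **cell, "n_tissues": sum(pat)}
        )
    df = pd.DataFrame(rows)
    df.attrs["all_tissue_risk"] = int(
        df.loc[df["n_tissues"] == len(tissues), "risk"].sum()
    )
    df.attrs["all_tissue_non_risk"] = int(
        df.loc[df["n_tissues"] == len(tissues), "non_risk"].sum()
    )
    return df


def _selection_bias(uni: GeneUniverse, selected: set[str]) -> pd.Series:
    """Smoothed probability of selection as a function of per-gene probe count.

    Genes are ordered by probe count and the selection indicator is averaged
    in a moving window (the standard probe-number bias estimate for array
    gene-set testing); returns a per-gene probability.
    """
    genes = sorted(uni.genes)
    counts = np.array([uni.cpgs_per_gene[g] for g in genes], dtype=float)
    sel = np.array([g in selected for g in genes], dtype=float)
    order = np.argsort(counts, kind="mergesort")
    window = max(5, len(genes) // 20)
    kernel = np.ones(window) / window
    smoothed = np.convolve(
        np.pad(sel[order], (window // 2, window - 1 - window // 2), mode="edge"),
        kernel,
        mode="valid",
    )
    prob = np.empty(len(genes))
    prob[order] = smoothed
    # genes with identical probe counts are exchangeable: average their
    # probabilities so the estimate does not depend on sort order
    s = pd.Series(prob, index=genes)
    grouped = s.groupby(counts).transform("mean")
    return np.clip(grouped, 1e-6, 1 - 1e-6)


def ontology_enrichment(
    res: pd.DataFrame,
    ann: CpGAnnotation,
    go_map: pd.DataFrame,
    threshold: float = 0.05,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Per-category Wallenius noncentral hypergeometric enrichment p-values.

    ``go_map`` is a two-column table (gene, category). Categories with fewer
    than ``min_genes`` universe genes are skipped. Each category's odds are
    the mean smoothed selection probability of its genes relative to the
    rest (probe-count bias adjustment); when every gene has the same probe
    count the odds are 1 and the test is the central hypergeometric.
    """
    uni = build_universe(res, ann)
    universe = uni.genes
    selected = nominal_gene_set(res, ann, threshold) & universe
    bias = _selection_bias(uni, selected)
    gene_col, cat_col = go_map.columns[:2]
    rows = []
    for cat, grp in go_map.groupby(cat_col):
        members = set(grp[gene_col]) & universe
        if len(members) < min_genes:
            continue
        k = len(members & selected)
        in_mean = bias[sorted(members)].mean()
        rest = universe - members
        out_mean = bias[sorted(rest)].mean() if rest else in_mean
        odds = float(
            (in_mean / (1 - in_mean)) / (out_mean / (1 - out_mean))
        )
        p = wallenius_test(k, len(members), len(selected), len(universe), odds)
        rows.append(
            {
                "category": cat,
                "n_genes": len(members),
                "n_selected": k,
                "odds": odds,
                "p_value": p,
            }
        )
    if not rows:
        raise ValueError("no categories meet the minimum gene count")
    return pd.DataFrame(rows).set_index("category").sort_values("p_value")


def rank_sum_across_tissues(per_tissue_go_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Sum each category's p-value rank across tissues (average ranks on ties).

    Categories missing from a tissue get a missing rank there and are
    flagged ``incomplete``. The result is sorted by ascending rank sum.
    """
    ranks = {}
    for tissue, tab in per_tissue_go_tables.items():
        ranks[tissue] = tab["p_value"].rank(method="average")
    rk = pd.DataFrame(ranks)
    out = pd.DataFrame(
        {
            "rank_sum": rk.sum(axis=1, skipna=True),
            "n_tissues": rk.notna().sum(axis=1),
            "incomplete": rk.isna().any(axis=1),
        }
    )
    return out.sort_values("rank_sum")
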