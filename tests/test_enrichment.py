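import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ewaskit import (
    GeneSet,
    build_universe,
    cross_tissue_overlap,
    enrichment_curve,
    nominal_gene_set,
    ontology_enrichment,
    rank_sum_across_tissues,
)
from ewaskit.data_model import CpGAnnotation
from ewaskit.enrichment_and_ontology import expected_overlap


def _ann(gene_lists, chroms=None):
    n = len(gene_lists)
    return CpGAnnotation(
        pd.DataFrame(
            {
                "chrom": chroms or ["chr1"] * n,
                "pos": np.arange(1, n + 1),
                "genes": gene_lists,
                "region_class": ["open_sea"] * n,
                "enhancer": [False] * n,
            },
            index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"),
        )
    )


def _res(pvals):
    return pd.DataFrame(
        {"p_value": pvals, "effect_percent": np.zeros(len(pvals))},
        index=[f"cg{i}" for i in range(len(pvals))],
    )


class TestUniverse:
    def test_semicolon_genes_deduplicated_per_probe(self):
        ann = _ann([["A", "B"], ["A"], []])
        uni = build_universe(_res([0.1, 0.2, 0.3]), ann)
        assert uni.cpgs_per_gene == {"A": 2, "B": 1}

    def test_empty_universe_rejected(self):
        ann = _ann([[], []])
        with pytest.raises(ValueError, match="empty"):
            build_universe(_res([0.1, 0.2]), ann)

    def test_counts_match_known_construction(self, small_dataset):
        beta, _, ann, _, _, _ = small_dataset
        res = _res(np.full(len(ann.probe_ids), 0.5))
        res.index = ann.probe_ids
        uni = build_universe(res, ann)
        # independent bookkeeping: tally by brute force
        tally: dict = {}
        for p in ann.probe_ids:
            for g in set(ann.table.loc[p, "genes"]):
                tally[g] = tally.get(g, 0) + 1
        assert uni.cpgs_per_gene == tally

    def test_overlap_percentage_matches_reported_arithmetic(self):
        # 488 of 839 risk genes selected = 58.2%
        uni_genes = {f"G{i}" for i in range(19013)}
        uni = type(build_universe(_res([0.5]), _ann([["G0"]])))(
            {g: 1 for g in uni_genes}
        )
        risk = GeneSet.from_iterable("risk", [f"G{i}" for i in range(839)])
        selected = {f"G{i}" for i in range(488)} | {
            f"G{i}" for i in range(839, 839 + 7742)
        }
        stats_ = uni.overlap_stats(risk, selected)
        assert stats_["observed"] == 488
        assert round(stats_["percent_of_risk"], 1) == 58.2
        assert round(stats_["expected"]) == 363


class TestNominalGeneSet:
    def test_hand_built_six_probe_example(self):
        ann = _ann([["A"], ["A"], ["B"], ["B"], ["C"], ["C"]])
        res = _res([0.001, 0.8, 0.04, 0.9, 0.6, 0.7])
        assert nominal_gene_set(res, ann, 0.05) == {"A", "B"}
        assert nominal_gene_set(res, ann, 0.0005) == set()

    def test_threshold_is_strict(self):
        ann = _ann([["A"]])
        res = _res([0.05])
        assert nominal_gene_set(res, ann, 0.05) == set()

    def test_saturating_threshold_selects_all_genes(self, small_dataset):
        beta, _, ann, _, _, _ = small_dataset
        rng = np.random.default_rng(0)
        res = _res(rng.uniform(0.0001, 0.9, len(ann.probe_ids)))
        res.index = ann.probe_ids
        uni = build_universe(res, ann)
        sel = nominal_gene_set(res, ann, 0.99)
        assert sel >= uni.genes  # every universe gene has a p<0.99 CpG here


class TestEnrichmentCurve:
    def test_expected_overlap_margins_arithmetic(self):
        assert expected_overlap(839, 8230, 19013) == pytest.approx(363.17, abs=0.01)

    def test_table_cells_partition_universe(self, spiked_dataset):
        from ewaskit import fit_sitewise

        beta, _, ann, sheet, risk, _ = spiked_dataset
        res = fit_sitewise(beta, sheet, None)
        curve = enrichment_curve(res, ann, risk, grid=(0.01, 0.05, 0.5), n_perm=0)
        uni = build_universe(res, ann)
        risk_in = risk.genes & uni.genes
        for t, row in curve.table.iterrows():
            sel = nominal_gene_set(res, ann, t) & uni.genes
            assert row["risk_overlap_observed"] <= min(len(risk_in), len(sel))
            assert row["selected_gene_count"] == len(sel)
            assert row["risk_overlap_expected"] == pytest.approx(
                len(risk_in) * len(sel) / len(uni.genes)
            )
        counts = curve.table["selected_gene_count"].to_numpy()
        assert (np.diff(counts) >= 0).all()  # nondecreasing in threshold

    def test_spiked_simulation_enriched_with_quiet_permutations(self, spiked_dataset):
        from ewaskit import fit_sitewise

        beta, _, ann, sheet, risk, _ = spiked_dataset
        res = fit_sitewise(beta, sheet, None)
        curve = enrichment_curve(res, ann, risk, grid=(0.05,), n_perm=10, seed=1)
        assert curve.table.loc[0.05, "p_value"] < 1e-6
        assert (curve.permutation_p[0.05] > 0.01).all()

    def test_restriction_to_all_probes_is_identity(self, spiked_dataset):
        from ewaskit import fit_sitewise

        beta, _, ann, sheet, risk, _ = spiked_dataset
        res = fit_sitewise(beta, sheet, None)
        full = enrichment_curve(res, ann, risk, grid=(0.05, 0.2), n_perm=0)
        restricted = enrichment_curve(
            res, ann, risk, grid=(0.05, 0.2), n_perm=0,
            restrict_cpgs=list(res.index),
        )
        pd.testing.assert_frame_equal(full.table, restricted.table)

    def test_null_enrichment_level_calibrated(self, null_dataset):
        from ewaskit import fit_sitewise

        beta, _, ann, sheet, risk, _ = null_dataset
        res = fit_sitewise(beta, sheet, None)
        curve = enrichment_curve(res, ann, risk, grid=(0.05,), n_perm=200, seed=7)
        pp = curve.permutation_p[0.05].dropna().to_numpy()
        rate = (pp < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(pp))
        assert rate < 0.05 + 3 * se

    def test_disjoint_risk_set_rejected(self, small_dataset):
        from ewaskit import fit_sitewise

        beta, _, ann, sheet, _, _ = small_dataset
        res = fit_sitewise(beta, sheet, None)
        alien = GeneSet.from_iterable("alien", ["NO_SUCH_GENE"])
        with pytest.raises(ValueError, match="intersect"):
            enrichment_curve(res, ann, alien, grid=(0.05,), n_perm=0)


class TestCrossTissueOverlap:
    def test_identical_sets_fully_intersect(self):
        sets = {t: {"A", "B", "C"} for t in ("t1", "t2", "t3")}
        risk = GeneSet.from_iterable("risk", ["A", "B"])
        df = cross_tissue_overlap(sets, risk)
        assert df.attrs["all_tissue_risk"] == 2
        assert df.attrs["all_tissue_non_risk"] == 1

    def test_disjoint_sets_have_empty_intersection(self):
        sets = {"t1": {"A"}, "t2": {"B"}}
        risk = GeneSet.from_iterable("risk", ["A", "B"])
        df = cross_tissue_overlap(sets, risk)
        assert df.attrs["all_tissue_risk"] == 0

    def test_partition_matches_brute_force_tabulation(self):
        rng = np.random.default_rng(13)
        universe = [f"G{i}" for i in range(1000)]
        sets = {
            f"t{j}": set(rng.choice(universe, size=300, replace=False))
            for j in range(5)
        }
        risk = GeneSet.from_iterable("risk", rng.choice(universe, 100, replace=False))
        df = cross_tissue_overlap(sets, risk)
        tissues = [f"t{j}" for j in range(5)]
        # brute force every pattern
        for _, row in df.iterrows():
            pat = tuple(bool(row[t]) for t in tissues)
            expect_risk = expect_non = 0
            for g in set().union(*sets.values()):
                if tuple(g in sets[t] for t in tissues) == pat:
                    if g in risk:
                        expect_risk += 1
                    else:
                        expect_non += 1
            assert row["risk"] == expect_risk
            assert row["non_risk"] == expect_non


class TestOntology:
    def _uniform_probe_setup(self, selected_genes, n_genes=40, per_cat=8):
        genes = [f"G{i}" for i in range(n_genes)]
        ann = _ann([[g] for g in genes])
        pvals = [0.01 if g in selected_genes else 0.5 for g in genes]
        res = _res(pvals)
        cats = pd.DataFrame(
            {
                "gene": genes,
                "category": [f"cat{i // per_cat}" for i in range(n_genes)],
            }
        )
        return res, ann, cats

    def test_no_probe_bias_reduces_to_hypergeometric(self):
        selected = {f"G{i}" for i in range(10)}
        res, ann, cats = self._uniform_probe_setup(selected)
        tab = ontology_enrichment(res, ann, cats, threshold=0.05, min_genes=5)
        k = tab.loc["cat0", "n_selected"]
        p_ref = float(sps.hypergeom.sf(k - 1, 40, 8, 10))
        assert tab.loc["cat0", "odds"] == pytest.approx(1.0, abs=0.15)
        assert tab.loc["cat0", "p_value"] == pytest.approx(p_ref, rel=0.3)

    def test_whole_universe_category_gives_p_one(self):
        selected = {f"G{i}" for i in range(10)}
        genes = [f"G{i}" for i in range(20)]
        ann = _ann([[g] for g in genes])
        res = _res([0.01 if g in selected else 0.5 for g in genes])
        cats = pd.DataFrame({"gene": genes, "category": ["all"] * 20})
        tab = ontology_enrichment(res, ann, cats, threshold=0.05, min_genes=5)
        assert tab.loc["all", "p_value"] == pytest.approx(1.0)

    def test_small_categories_skipped(self):
        res, ann, cats = self._uniform_probe_setup(set(), per_cat=3)
        with pytest.raises(ValueError, match="minimum gene count"):
            ontology_enrichment(res, ann, cats, min_genes=5)

    def test_planted_category_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"G{i}" for i in range(100)]
            ann = _ann([[g] for g in genes])
            target = {f"G{i}" for i in range(10)}       # cat0 genes
            pvals = [
                0.001 if (g in target and rng.random() < 0.8)
                else float(rng.uniform(0.05, 1))
                for g in genes
            ]
            res = _res(pvals)
            cats = pd.DataFrame(
                {"gene": genes, "category": [f"cat{i // 10}" for i in range(100)]}
            )
            tab = ontology_enrichment(res, ann, cats, threshold=0.05, min_genes=5)
            hits += tab.index[0] == "cat0"
        assert hits >= 9


class TestRankSum:
    def test_unanimous_winner_has_rank_sum_equal_to_tissue_count(self):
        tabs = {}
        for t in range(5):
            tabs[f"t{t}"] = pd.DataFrame(
                {"p_value": [0.001, 0.5, 0.9]}, index=["win", "mid", "lose"]
            )
        out = rank_sum_across_tissues(tabs)
        assert out.index[0] == "win"
        assert out.loc["win", "rank_sum"] == 5

    def test_identical_pvalues_tie_to_equal_rank_sums(self):
        tabs = {
            "t1": pd.DataFrame({"p_value": [0.5, 0.5]}, index=["a", "b"]),
            "t2": pd.DataFrame({"p_value": [0.5, 0.5]}, index=["a", "b"]),
        }
        out = rank_sum_across_tissues(tabs)
        assert out["rank_sum"].nunique() == 1

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(14)
        cats = [f"c{i}" for i in range(20)]
        tabs = {
            f"t{j}": pd.DataFrame({"p_value": rng.uniform(size=20)}, index=cats)
            for j in range(3)
        }
        out = rank_sum_across_tissues(tabs)
        for c in cats:
            brute = sum(
                1 + sum(tabs[t].loc[o, "p_value"] < tabs[t].loc[c, "p_value"] for o in cats)
                for t in tabs
            )
            assert out.loc[c, "rank_sum"] == pytest.approx(brute)

    def test_missing_category_flagged(self):
        tabs = {
            "t1": pd.DataFrame({"p_value": [0.1, 0.2]}, index=["a", "b"]),
            "t2": pd.DataFrame({"p_value": [0.1]}, index=["a"]),
        }
        out = rank_sum_across_tissues(tabs)
        assert bool(out.loc["b", "incomplete"]) is True
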