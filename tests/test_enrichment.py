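"""Enrichment-score, permutation-null and integration behavior."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from padnet.enrichment import (
    CASE,
    CONTROL,
    EnrichmentResult,
    ExpressionDataset,
    GeneSetCollection,
    NoOverlapError,
    RankedGeneList,
    collapse_probes,
    enrich_dataset,
    enrichment_score,
    integrate_disease_pathways,
    nominal_p,
    rank_genes,
)

from .conftest import null_dataset
from .oracles import brute_force_es

LABELS_2X2 = [CASE, CASE, CONTROL, CONTROL]


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------


class TestCollapseProbes:
    def test_probes_for_same_gene_are_averaged(self):
        mat = pd.DataFrame([[2.0, 2.0], [4.0, 4.0]], index=["P1", "P2"], columns=["s1", "s2"])
        ds = collapse_probes(mat, {"P1": "G", "P2": "G"}, [CASE, CONTROL])
        assert ds.gene_ids == ["G"]
        np.testing.assert_allclose(ds.values, [[3.0, 3.0]])

    def test_unmapped_probe_is_dropped(self):
        mat = pd.DataFrame([[1.0], [9.0]], index=["P1", "P3"], columns=["s1"])
        ds = collapse_probes(mat, {"P1": "G1"}, [CASE])
        assert ds.gene_ids == ["G1"]

    def test_identity_when_one_probe_per_gene(self):
        mat = pd.DataFrame(np.arange(6.0).reshape(3, 2), index=["P1", "P2", "P3"], columns=["a", "b"])
        ds = collapse_probes(mat, {"P1": "GA", "P2": "GB", "P3": "GC"}, [CASE, CONTROL])
        assert ds.gene_ids == ["GA", "GB", "GC"]
        np.testing.assert_allclose(ds.values, mat.values)

    def test_empty_mapping_raises(self):
        mat = pd.DataFrame([[1.0]], index=["P1"], columns=["s1"])
        with pytest.raises(ValueError, match="unusable mapping"):
            collapse_probes(mat, {"Q9": "G"}, [CASE])

    def test_missing_values_rejected_or_imputed(self):
        mat = pd.DataFrame(
            [[1.0, np.nan], [2.0, 4.0]], index=["P1", "P2"], columns=["s1", "s2"]
        )
        mapping = {"P1": "G1", "P2": "G2"}
        ds = collapse_probes(mat, mapping, [CASE, CONTROL], missing="reject")
        assert ds.gene_ids == ["G2"]
        ds2 = collapse_probes(mat, mapping, [CASE, CONTROL], missing="impute")
        assert ds2.gene_ids == ["G1", "G2"]
        np.testing.assert_allclose(ds2.values[0], [1.0, 1.0])  # row mean fill


# ---------------------------------------------------------------------------
# gene ranking
# ---------------------------------------------------------------------------


class TestRankGenes:
    def test_hand_computed_signal_to_noise(self):
        # per-gene values: two case then two control samples
        data = {
            "A": ([2.0, 4.0], [0.0, 2.0]),  # (3-1)/(sqrt2+sqrt2) = 1/sqrt(2)
            "B": ([0.0, 0.0], [0.0, 0.0]),  # 0
            "C": ([10.0, 10.0], [0.0, 0.0]),  # sd floors: 10/(2+eps) ~= 5
            "D": ([0.0, 2.0], [4.0, 6.0]),  # (1-5)/(2 sqrt2) = -sqrt(2)
            "E": ([1.0, 3.0], [1.0, 3.0]),  # 0
        }
        genes = list(data)
        values = np.array([data[g][0] + data[g][1] for g in genes])
        ds = ExpressionDataset(genes, values, LABELS_2X2)
        ranked = rank_genes(ds)
        assert ranked.gene_ids == ["C", "A", "B", "E", "D"]  # ties B/E lexicographic
        expected = [5.0, 1 / np.sqrt(2), 0.0, 0.0, -np.sqrt(2)]
        np.testing.assert_allclose(ranked.metric_values, expected, rtol=1e-6)

    def test_zero_sd_gene_ranks_above_equal_means(self):
        ds = ExpressionDataset(
            ["up", "flat"],
            np.array([[1.0, 3.0, 0.0, 0.0], [1.0, 2.0, 1.0, 2.0]]),
            LABELS_2X2,
        )
        ranked = rank_genes(ds)
        assert ranked.gene_ids[0] == "up"
        assert ranked.metric_values[0] > 0

    def test_all_identical_gives_lexicographic_order(self):
        ds = ExpressionDataset(
            ["z", "a", "m"], np.tile([1.0, 2.0, 1.0, 2.0], (3, 1)), LABELS_2X2
        )
        ranked = rank_genes(ds)
        assert ranked.gene_ids == ["a", "m", "z"]
        np.testing.assert_array_equal(ranked.metric_values, 0.0)

    def test_small_class_errors_name_the_class(self):
        ds = ExpressionDataset(["g"], np.array([[1.0, 2.0, 3.0]]), [CASE, CONTROL, CONTROL])
        with pytest.raises(ValueError, match="'case'"):
            rank_genes(ds)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


class TestEnrichmentScore:
    @pytest.mark.parametrize("exponent", [0.0, 1.0, 1.5, 2.0])
    def test_top_block_scores_one(self, exponent):
        ranked = RankedGeneList([f"g{i}" for i in range(10)], np.linspace(3, -3, 10))
        assert enrichment_score(ranked, {"g0", "g1", "g2"}, exponent) == pytest.approx(1.0)

    def test_four_gene_alternating_set(self):
        ranked = RankedGeneList(["g1", "g2", "g3", "g4"], [4.0, 3.0, 2.0, 1.0])
        # running sum at p=0: +0.5, 0, +0.5, 0 -> max deviation 0.5
        assert enrichment_score(ranked, {"g1", "g3"}, 0.0) == pytest.approx(0.5)

    def test_bottom_block_scores_minus_one(self):
        ranked = RankedGeneList(["a", "b", "c", "d"], [2.0, 1.0, -1.0, -2.0])
        assert enrichment_score(ranked, {"c", "d"}, 1.0) == pytest.approx(-1.0)

    def test_no_overlap_is_an_error_not_zero(self):
        ranked = RankedGeneList(["a", "b"], [1.0, -1.0])
        with pytest.raises(NoOverlapError):
            enrichment_score(ranked, {"zzz"})

    def test_set_genes_absent_from_ranking_are_ignored(self):
        ranked = RankedGeneList(["a", "b", "c", "d"], [4.0, 3.0, 2.0, 1.0])
        assert enrichment_score(ranked, {"a", "b"}, 1.0) == enrichment_score(
            ranked, {"a", "b", "missing"}, 1.0
        )

    @pytest.mark.parametrize("exponent", [0.0, 1.0, 1.5, 2.0])
    def test_matches_brute_force_oracle(self, rng, exponent):
        for _ in range(25):
            n = int(rng.integers(10, 60))
            ids = [f"g{i:03d}" for i in range(n)]
            metric = np.sort(rng.normal(size=n))[::-1]
            gene_set = set(rng.choice(ids, size=int(rng.integers(2, 9)), replace=False))
            ranked = RankedGeneList(ids, metric)
            expected = brute_force_es(ids, metric, gene_set, exponent)
            assert enrichment_score(ranked, gene_set, exponent) == pytest.approx(expected, abs=1e-12)

    def test_rank_only_dependence_at_exponent_zero(self, rng):
        n = 40
        ids = [f"g{i}" for i in range(n)]
        metric = np.sort(rng.normal(size=n))[::-1]
        gene_set = set(rng.choice(ids, 7, replace=False))
        base = enrichment_score(RankedGeneList(ids, metric), gene_set, 0.0)
        for transform in (lambda x: 3 * x + 5, np.exp, lambda x: x**3 + x):
            warped = transform(metric)
            assert enrichment_score(RankedGeneList(ids, warped), gene_set, 0.0) == pytest.approx(base)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(5, 50),
        k=st.integers(1, 5),
        exponent=st.sampled_from([0.0, 1.0, 2.0]),
        seed=st.integers(0, 10_000),
    )
    def test_score_always_in_unit_interval(self, n, k, exponent, seed):
        local = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n)]
        metric = np.sort(local.normal(size=n))[::-1]
        gene_set = set(local.choice(ids, size=min(k, n), replace=False))
        es = enrichment_score(RankedGeneList(ids, metric), gene_set, exponent)
        assert -1.0 <= es <= 1.0


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


class TestNominalP:
    def test_deterministic_given_seed(self, rng):
        ds = null_dataset(rng)
        gene_set = set(ds.gene_ids[:15])
        a = nominal_p(ds, gene_set, n_perm=100, seed=7)
        b = nominal_p(ds, gene_set, n_perm=100, seed=7)
        assert (a.nominal_p, a.nes, a.es) == (b.nominal_p, b.nes, b.es)

    def test_planted_set_attains_minimum_achievable_p(self):
        rng = np.random.default_rng(101)
        ds = null_dataset(rng, n_genes=300, n_per_class=15)
        planted = ds.gene_ids[:20]
        values = ds.values.copy()
        values[:20, ds.case_mask] += 2.0  # +2 sd shift in cases
        shifted = ExpressionDataset(ds.gene_ids, values, ds.sample_labels)
        res = nominal_p(shifted, set(planted), n_perm=1000, seed=11)
        assert res.nominal_p == pytest.approx(1.0 / (1.0 + res.n_same_sign))
        assert res.nes > 1.0

    def test_p_in_half_open_interval_and_sign_consistency(self, rng):
        ds = null_dataset(rng)
        for start in range(0, 60, 12):
            res = nominal_p(ds, set(ds.gene_ids[start : start + 12]), n_perm=50, seed=start)
            assert 0.0 < res.nominal_p <= 1.0
            if not np.isnan(res.nes):
                assert np.sign(res.nes) == np.sign(res.es)

    def test_geneset_fallback_below_seven_per_class(self, rng):
        values = rng.standard_normal((100, 8))
        ds = ExpressionDataset([f"g{i}" for i in range(100)], values, [CASE] * 4 + [CONTROL] * 4)
        res = nominal_p(ds, set(ds.gene_ids[:10]), n_perm=50, seed=1)  # auto -> geneset
        assert 0.0 < res.nominal_p <= 1.0

    def test_null_p_distribution_roughly_uniform(self):
        # light version of the large-simulation check in the acceptance suite
        from scipy.stats import kstest

        rng = np.random.default_rng(102)
        pvals = []
        for rep in range(50):
            ds = null_dataset(rng, n_genes=120, n_per_class=8)
            pvals.append(nominal_p(ds, set(ds.gene_ids[:12]), n_perm=100, seed=rep).nominal_p)
        assert kstest(pvals, "uniform").statistic < 0.2


# ---------------------------------------------------------------------------
# dataset-level enrichment and integration
# ---------------------------------------------------------------------------


class TestEnrichDataset:
    def test_planted_pathways_rank_lowest_p(self):
        rng = np.random.default_rng(20260101)
        n_genes, size = 2000, 20
        genes = [f"G{i:05d}" for i in range(n_genes)]
        sets = {f"NULL{i:03d}": set(rng.choice(genes, 25, replace=False)) for i in range(100)}
        planted_names = []
        for i in range(3):
            members = genes[i * size : (i + 1) * size]
            sets[f"PLANTED{i}"] = set(members)
            planted_names.append(f"PLANTED{i}")
        values = rng.standard_normal((n_genes, 30))
        labels = [CASE] * 15 + [CONTROL] * 15
        values[: 3 * size, :15] += 2.0
        ds = ExpressionDataset(genes, values, labels)
        results = enrich_dataset(ds, GeneSetCollection(sets), n_perm=1000, seed=3)
        by_p = sorted(results, key=lambda r: (r.nominal_p, r.pathway_name))
        top3 = {r.pathway_name for r in by_p[:3]}
        assert top3 == set(planted_names)

    def test_pathway_below_min_overlap_is_skipped(self, rng):
        ds = null_dataset(rng, n_genes=50)
        sets = GeneSetCollection({"tiny": {ds.gene_ids[0], "absent1", "absent2"}, "ok": set(ds.gene_ids[:10])})
        results = enrich_dataset(ds, sets, n_perm=20, seed=0, min_overlap=5)
        assert [r.pathway_name for r in results] == ["ok"]

    def test_pathway_with_no_matching_genes_yields_no_row(self, rng):
        ds = null_dataset(rng, n_genes=50)
        sets = GeneSetCollection({"ghost": {"X1", "X2", "X3", "X4", "X5"}})
        assert enrich_dataset(ds, sets, n_perm=20, seed=0) == []

    def test_empty_collection_is_an_error(self, rng):
        ds = null_dataset(rng, n_genes=20)
        with pytest.raises(ValueError):
            enrich_dataset(ds, GeneSetCollection({}), n_perm=10, seed=0)


def _result(name: str, p: float) -> EnrichmentResult:
    return EnrichmentResult(name, es=0.5, nes=1.2, nominal_p=p, n_genes_matched=10)


class TestIntegrateDiseasePathways:
    def test_union_with_provenance(self):
        d1 = [_result("A", 0.001), _result("B", 0.005), _result("C", 0.5)]
        d2 = [_result("B", 0.002), _result("C", 0.009)]
        union = integrate_disease_pathways([d1, d2], 0.01, ["ds1", "ds2"])
        assert union.pathway_names == {"A", "B", "C"}
        assert union.provenance["B"] == ["ds1", "ds2"]
        assert union.provenance["A"] == ["ds1"]

    def test_single_dataset_union_is_its_selection(self):
        d1 = [_result("A", 0.001), _result("B", 0.05)]
        union = integrate_disease_pathways([d1], 0.01)
        assert union.pathway_names == {"A"}

    def test_union_size_equals_sum_minus_overlaps(self):
        # four selections sized 109/7/17/21 with 11 overlapping picks -> 143
        d1 = [_result(f"P{i:04d}", 0.001) for i in range(109)]
        d2 = [_result(f"P{i:04d}", 0.001) for i in range(3)] + [_result(f"Q{i}", 0.001) for i in range(4)]
        d3 = [_result(f"P{i:04d}", 0.001) for i in range(4)] + [_result(f"R{i}", 0.001) for i in range(13)]
        d4 = [_result(f"P{i:04d}", 0.001) for i in range(4)] + [_result(f"S{i}", 0.001) for i in range(17)]
        union = integrate_disease_pathways([d1, d2, d3, d4], 0.01)
        sizes = [109, 7, 17, 21]
        assert len(union) == sum(sizes) - 11 == 143
        assert len(union) <= sum(sizes)
        for results in (d1, d2, d3, d4):
            assert {r.pathway_name for r in results} <= union.pathway_names

    def test_empty_union_allowed(self):
        union = integrate_disease_pathways([[_result("A", 0.5)]], 0.01)
        assert len(union) == 0
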