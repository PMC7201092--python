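"""Downstream subtype-comparison statistics."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernanet import (
    cerna_partners,
    classify_network_genes,
    degree_ratio,
    edge_subnetwork,
    expression_variability,
    group_difference_test,
    log2_fold_change,
    matched_null_similarity,
    overrepresentation,
    recurrent_apa,
    set_overlap_significance,
    subsample_experiment,
)
from cernanet.cerna import build_cerna_network

from conftest import expression_from_array


def calls_frame(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "event"])


class TestRecurrentApa:
    samples = [f"s{i}" for i in range(10)]

    def test_strictly_above_fraction_included(self):
        calls = calls_frame([(f"s{i}", "g", "3US") for i in range(3)])
        assert recurrent_apa(calls, self.samples, "3US") == {"g"}

    def test_boundary_excluded(self):
        calls = calls_frame([(f"s{i}", "g", "3US") for i in range(2)])
        assert recurrent_apa(calls, self.samples, "3US") == set()

    def test_no_calls_empty(self):
        assert recurrent_apa(calls_frame([]), self.samples, "3US") == set()

    def test_kind_filtering(self):
        calls = calls_frame([(f"s{i}", "g", "3UL") for i in range(5)])
        assert recurrent_apa(calls, self.samples, "3US") == set()
        assert recurrent_apa(calls, self.samples, "3UL") == {"g"}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            recurrent_apa(calls_frame([]), self.samples, "3US", fraction=1.0)


class TestPartnersAndSubnetworks:
    def test_partners_of_star_center(self):
        star = nx.star_graph(5)
        assert cerna_partners(star, {0}) == {1, 2, 3, 4, 5}

    def test_isolated_seeds_have_no_partners(self):
        assert cerna_partners(nx.star_graph(3), {"missing"}) == set()

    def test_shared_neighbor_counted_once(self):
        g = nx.Graph([("a", "x"), ("b", "x")])
        assert cerna_partners(g, {"a", "b"}) == {"x"}

    def test_edge_subnetwork_incidence_rule(self, path3):
        sub = edge_subnetwork(path3, {"b"})
        assert set(sub.edges) == {("a", "b"), ("b", "c")}

    def test_edge_subnetwork_all_and_none(self, path3):
        assert set(edge_subnetwork(path3, set(path3.nodes)).edges) == set(path3.edges)
        assert edge_subnetwork(path3, set()).number_of_edges() == 0


class TestDegreeRatio:
    def test_fully_retained(self, path3):
        assert degree_ratio(path3, path3, "b") == 1.0

    def test_absent_from_tumor_is_zero(self, path3):
        assert degree_ratio(path3, nx.Graph([("x", "y")]), "b") == 0.0

    def test_gains_ignored(self):
        normal = nx.star_graph(10)  # center 0 with 10 neighbors
        tumor = nx.Graph([(0, 1), (0, 2), (0, 3), (0, 4), (0, "n1"), (0, "n2"), (0, "n3")])
        assert degree_ratio(normal, tumor, 0) == pytest.approx(0.4)

    def test_absent_from_normal_rejected(self, path3):
        with pytest.raises(ValueError):
            degree_ratio(path3, path3, "zzz")


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        assert log2_fold_change([2.0, 4.0], [4.0, 2.0]) == 0.0

    def test_pseudocount_example(self):
        assert log2_fold_change([3.0, 3.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change([-1.0], [1.0])


class TestGroupDifferenceTest:
    def test_identical_multisets_not_significant(self):
        assert group_difference_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) > 0.9

    def test_complete_separation_matches_exact_enumeration(self):
        # with complete separation the two-sided exact p is 2 / C(40, 20)
        a = np.arange(20.0)
        b = np.arange(100.0, 120.0)
        assert group_difference_test(a, b) == pytest.approx(
            2 / math.comb(40, 20), rel=1e-9
        )

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            hits += group_difference_test(a, b) < 0.01
        assert hits >= 19

    def test_all_tied_signalled(self):
        with pytest.raises(ValueError):
            group_difference_test([1.0, 1.0], [1.0, 1.0])


class TestSetOverlap:
    def test_disjoint_small_sets_not_significant(self):
        u = [f"g{i}" for i in range(30)]
        assert set_overlap_significance({"g0"}, {"g1"}, u) > 0.9

    def test_half_universe_full_overlap_closed_form(self):
        u = [f"g{i}" for i in range(12)]
        half = set(u[:6])
        assert set_overlap_significance(half, half, u) == pytest.approx(
            1 / math.comb(12, 6)
        )

    def test_symmetry(self):
        u = [f"g{i}" for i in range(15)]
        a, b = set(u[:5]), set(u[3:10])
        assert set_overlap_significance(a, b, u) == pytest.approx(
            set_overlap_significance(b, a, u)
        )

    def test_containment_enforced(self):
        with pytest.raises(ValueError):
            set_overlap_significance({"x"}, set(), {"a"})


class TestOverrepresentation:
    universe = [f"g{i}" for i in range(40)]
    collection = {
        "hit": set(universe[:8]),
        "half": set(universe[4:12]),
        "miss": set(universe[20:30]),
    }

    def test_whole_set_query_ranks_first(self):
        table = overrepresentation(self.collection["hit"], self.collection, self.universe)
        assert table.iloc[0]["set"] == "hit"
        assert table["p"].is_monotonic_increasing

    def test_empty_query_all_one(self):
        table = overrepresentation(set(), self.collection, self.universe)
        assert (table["p"] == 1.0).all()

    def test_null_queries_give_valid_pvalues(self):
        # random queries against random sets: the discrete hypergeometric
        # p-values must be valid (super-uniform), i.e. P(p <= a) <= a up to
        # Monte Carlo error, and not concentrated near zero
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(60)]
        ps = []
        for _ in range(400):
            query = set(rng.choice(universe, size=rng.integers(5, 20), replace=False))
            members = set(rng.choice(universe, size=rng.integers(5, 25), replace=False))
            ps.append(
                overrepresentation(query, {"s": members}, universe)["p"].iloc[0]
            )
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.2, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se
        assert ps.mean() > 0.45

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation({"g1"}, {}, self.universe)


class TestClassifyNetworkGenes:
    annotation = pd.DataFrame(
        {"HK": [True, False, False, False], "TA": False, "TF": False},
        index=["hub", "l1", "l2", "l3"],
    )

    def test_no_apa_genes_all_unconnected(self):
        star = nx.Graph([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        table = classify_network_genes(star, set(), self.annotation)
        assert (table["category"] == "unconnected").all()

    def test_star_center_makes_leaves_partners(self):
        star = nx.Graph([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
        table = classify_network_genes(star, {"hub"}, self.annotation)
        assert table.loc["hub", "category"] == "3US"
        assert (table.loc[["l1", "l2", "l3"], "category"] == "3US_partner").all()
        assert table.loc["hub", "HK"]

    def test_counts_match_planted_truth(self, small_dataset):
        # on the target-share graph implied by the generator's ground truth,
        # the classification recovers the planted 3'US genes and partners
        share = nx.Graph(sorted(small_dataset.truth.cerna_pairs))
        table = classify_network_genes(
            share, small_dataset.truth.us_genes, small_dataset.annotations
        )
        got_us = set(table.index[table["category"] == "3US"])
        got_partners = set(table.index[table["category"] == "3US_partner"])
        assert got_us == small_dataset.truth.us_genes & set(share.nodes)
        assert got_partners == small_dataset.truth.partners & set(share.nodes)


class TestMatchedNullSimilarity:
    def test_deterministic_under_seed(self, small_dataset, small_backbone):
        net_a = build_cerna_network(
            small_dataset.condition("A", "normal"), small_backbone, 0.4
        )
        net_b = build_cerna_network(
            small_dataset.condition("A", "tumor"), small_backbone, 0.4
        )
        hk = set(small_dataset.annotations.index[small_dataset.annotations["HK"]])
        focal = set(sorted(hk)[:10])
        c1 = matched_null_similarity(net_a, net_b, focal, reps=20, seed=4)
        c2 = matched_null_similarity(net_a, net_b, focal, reps=20, seed=4)
        assert np.array_equal(c1.null_ps, c2.null_ps)
        assert c1.empirical_p == c2.empirical_p
        assert c1.empirical_p > 0  # add-one rule forbids zero

    def test_empty_focal_rejected(self, path3):
        with pytest.raises(ValueError):
            matched_null_similarity(path3, path3, set(), reps=5, seed=0)

    def test_insufficient_nonfocal_edges_rejected(self, path3):
        with pytest.raises(ValueError, match="non-focal"):
            matched_null_similarity(path3, path3, {"b"}, reps=5, seed=0)


class TestSubsampleExperiment:
    def test_full_size_reproduces_full_network(self, small_dataset, small_backbone):
        matrix = small_dataset.condition("B", "normal")
        full = build_cerna_network(matrix, small_backbone, 0.6)
        res = subsample_experiment(
            matrix, small_backbone, [matrix.n_samples], cutoff=0.6, reps=5, seed=0
        )
        assert (res.edge_counts["n_edges"] == full.number_of_edges()).all()
        occ = res.occurrence[matrix.n_samples]
        assert (occ == 5).all() and len(occ) == full.number_of_edges()

    def test_seeded_reproducibility(self, small_dataset, small_backbone):
        matrix = small_dataset.condition("A", "normal")
        r1 = subsample_experiment(matrix, small_backbone, [10], cutoff=0.6, reps=6, seed=2)
        r2 = subsample_experiment(matrix, small_backbone, [10], cutoff=0.6, reps=6, seed=2)
        assert r1.edge_counts.equals(r2.edge_counts)
        assert r1.occurrence[10].equals(r2.occurrence[10])

    def test_size_bounds_enforced(self, small_dataset, small_backbone):
        matrix = small_dataset.condition("B", "normal")
        with pytest.raises(ValueError):
            subsample_experiment(matrix, small_backbone, [2], cutoff=0.6, reps=2, seed=0)
        with pytest.raises(ValueError):
            subsample_experiment(matrix, small_backbone, [999], cutoff=0.6, reps=2, seed=0)


class TestExpressionVariability:
    def test_constant_genes_have_zero_sd(self):
        arr = np.vstack([np.full(6, 5.0), np.arange(6.0)])
        matrix = expression_from_array(arr)
        sd_a, sd_b, _ = expression_variability(matrix, ["g0", "g1"], ["g0", "g1"])
        assert sd_a["g0"] == 0.0

    def test_identical_groups_not_significant(self, small_dataset):
        genes = small_dataset.condition("A", "normal").genes[:50]
        _, _, p = expression_variability(
            small_dataset.condition("A", "normal"), genes, genes
        )
        assert p > 0.9

    def test_missing_gene_rejected(self, small_dataset):
        with pytest.raises(KeyError):
            expression_variability(
                small_dataset.condition("A", "normal"), ["nope"], ["alsonope"]
            )
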