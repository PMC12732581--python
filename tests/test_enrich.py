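"""Hypergeometric tail, BH adjustment, enrichment, and pathway connectivity."""

import itertools
import math

import numpy as np
import pytest

from netprior.core import GeneSet, GeneSetCollection
from netprior.enrich import (
    bh_adjust,
    enrich_gene_list,
    hypergeom_right_tail,
    pathway_connectivity,
)


def enumeration_right_tail(k, n, K, N):
    """Brute-force oracle: enumerate every draw of n items from N."""
    items = list(range(N))
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(items, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomRightTail:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_right_tail(0, 3, 5, 10) == 1.0

    def test_full_overlap_worked_example(self):
        # all 3 draws marked out of 5 marked in 10: C(5,3)/C(10,3)
        assert hypergeom_right_tail(3, 3, 5, 10) == pytest.approx(10 / 120)

    def test_degenerate_everything_equal(self):
        assert hypergeom_right_tail(4, 4, 4, 4) == 1.0

    def test_matches_enumeration_small_configs(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_right_tail(k, n, K, N) == pytest.approx(
                            enumeration_right_tail(k, n, K, N), abs=1e-12
                        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_right_tail(4, 3, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_right_tail(1, 3, 11, 10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.01, 0.04, 0.03, 0.005]) == pytest.approx(
            [0.02, 0.04, 0.04, 0.02]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_monotone_in_raw_p_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 30)))
            adjusted = np.asarray(bh_adjust(p))
            order = np.argsort(p)
            assert np.all(np.diff(adjusted[order]) >= -1e-12)
            assert np.all(adjusted <= 1.0)
            assert np.all(adjusted >= p - 1e-12)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected.tolist())


def make_collection(sets):
    return GeneSetCollection(
        sets=tuple(
            GeneSet(name=name, category="pathway", members=frozenset(genes))
            for name, genes in sets
        )
    )


class TestEnrichGeneList:
    def test_query_equal_to_single_pathway_is_degenerate(self):
        pathway_genes = {"A", "B", "C"}
        collection = make_collection([("P", pathway_genes)])
        query = GeneSet(name="q", category="q", members=frozenset(pathway_genes))
        (result,) = enrich_gene_list(query, collection, universe=pathway_genes)
        assert result.p == 1.0
        assert result.k == result.n == result.K == result.N == 3

    def test_planted_enriched_pathway_ranks_first(self):
        from netprior.synthetic import gen_universe

        rng = np.random.default_rng(3)
        universe = gen_universe(300)
        planted = universe[:40]
        decoys = [universe[40 + 30 * i : 70 + 30 * i] for i in range(5)]
        collection = make_collection(
            [("PLANTED", planted)] + [(f"D{i}", d) for i, d in enumerate(decoys)]
        )
        # query drawn 80% from the planted pathway, 20% uniform background
        query_genes = set(rng.choice(planted, size=16, replace=False)) | set(
            rng.choice(universe, size=4, replace=False)
        )
        query = GeneSet(name="q", category="q", members=frozenset(query_genes))
        results = enrich_gene_list(query, collection, universe=set(universe))
        assert results[0].pathway == "PLANTED"

    def test_genes_outside_universe_dropped_with_warning(self, caplog):
        collection = make_collection([("P", {"A", "B"}), ("Q", {"B", "C"})])
        query = GeneSet(name="q", category="q", members=frozenset({"A", "ZZZ"}))
        with caplog.at_level("WARNING"):
            with_stray = enrich_gene_list(query, collection)
        assert "ZZZ" in caplog.text
        clean_query = GeneSet(name="q", category="q", members=frozenset({"A"}))
        clean = enrich_gene_list(clean_query, collection)
        assert [(r.pathway, r.p) for r in with_stray] == [(r.pathway, r.p) for r in clean]

    def test_zero_overlap_pathways_count_toward_bh_denominator(self):
        collection = make_collection([("P", {"A", "B"}), ("FAR", {"X", "Y", "Z"})])
        query = GeneSet(name="q", category="q", members=frozenset({"A", "B"}))
        results = enrich_gene_list(query, collection)
        (hit,) = [r for r in results if r.pathway == "P"]
        # m = 2 tested pathways even though only one is reported
        assert hit.fdr == pytest.approx(min(1.0, hit.p * 2 / 1))

    def test_panel_fully_covered_by_reference_pathways(self):
        from netprior import datasets

        panel = GeneSet(name="panel", category="panel", members=datasets.PANEL_GENES)
        results = enrich_gene_list(panel, datasets.pathway_collection())
        covered = set().union(*(r.overlap_genes for r in results))
        assert datasets.PANEL_GENES <= covered

    def test_null_calibration(self):
        """Uniform null queries reject at the exact super-uniform rate ~alpha."""
        N, K, n, alpha, reps = 20000, 2000, 1000, 0.05, 2000
        rng = np.random.default_rng(17)
        # drawing the query uniformly makes the overlap hypergeometric
        ks = rng.hypergeometric(K, N - K, n, size=reps)
        fraction = np.mean([hypergeom_right_tail(int(k), n, K, N) < alpha for k in ks])
        assert fraction == pytest.approx(alpha, abs=0.015)


class TestPathwayConnectivity:
    def test_shared_pair_weight(self):
        from netprior import datasets

        panel = GeneSet(name="panel", category="panel", members=datasets.PANEL_GENES)
        results = enrich_gene_list(panel, datasets.pathway_collection())
        graph = pathway_connectivity(results)
        edge = graph.edges["TCR signaling", "Interleukin-1 family signaling"]
        assert edge["weight"] == 2
        assert edge["shared"] == ["NFKBIA", "PSME3"]

    def test_disjoint_overlaps_give_no_edges(self):
        collection = make_collection([("P", {"A"}), ("Q", {"B"})])
        query = GeneSet(name="q", category="q", members=frozenset({"A", "B"}))
        graph = pathway_connectivity(enrich_gene_list(query, collection))
        assert graph.number_of_edges() == 0
        assert graph.number_of_nodes() == 2

    def test_weights_match_brute_force_intersections(self):
        rng = np.random.default_rng(21)
        universe = [f"G{i:03d}" for i in range(60)]
        sets = [
            (f"P{i}", set(rng.choice(universe, size=15, replace=False))) for i in range(6)
        ]
        query = GeneSet(
            name="q", category="q",
            members=frozenset(rng.choice(universe, size=30, replace=False)),
        )
        results = enrich_gene_list(query, make_collection(sets), universe=set(universe))
        graph = pathway_connectivity(results)
        overlap = {r.pathway: r.overlap_genes for r in results}
        for a, b in itertools.combinations(overlap, 2):
            shared = overlap[a] & overlap[b]
            if shared:
                assert graph.edges[a, b]["weight"] == len(shared)
            else:
                assert not graph.has_edge(a, b)
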