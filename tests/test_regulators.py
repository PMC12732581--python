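"""Activation z-score, overlap p-value, regulator calls, and exports."""

import itertools
import math

import numpy as np
import pytest

from netprior.core import CausalEdge, GeneSet
from netprior.expression import ExpressionChange
from netprior.regulators import (
    RegulatorState,
    activation_zscore,
    annotate_biomarkers,
    call_regulators,
    consensus_regulators,
    export_signature_network,
    overlap_pvalue,
)
from netprior import io as npio


def edges_for(regulator, expected_signs):
    return [
        CausalEdge(regulator=regulator, target=f"T{i:02d}", expected_sign=s)
        for i, s in enumerate(expected_signs)
    ]


def observed(signs):
    return {f"T{i:02d}": s for i, s in enumerate(signs)}


class TestActivationZscore:
    def test_three_consistent_targets(self):
        res = activation_zscore(edges_for("R", [1, 1, 1]), observed([1, 1, 1]))
        assert round(res.z, 2) == 1.73
        assert (res.n_used, res.n_consistent, res.n_inconsistent) == (3, 3, 0)

    def test_five_inconsistent_targets(self):
        res = activation_zscore(edges_for("R", [1] * 5), observed([-1] * 5))
        assert round(res.z, 2) == -2.24

    def test_four_consistent_is_exactly_two(self):
        res = activation_zscore(edges_for("R", [1, -1, 1, -1]), observed([1, -1, 1, -1]))
        assert res.z == pytest.approx(2.0)

    def test_even_split_is_zero(self):
        res = activation_zscore(edges_for("R", [1, 1]), observed([1, -1]))
        assert res.z == 0.0

    def test_antisymmetry_under_observation_flip(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(1, 10))
            expected = rng.choice([-1, 1], size=n).tolist()
            obs = rng.choice([-1, 1], size=n).tolist()
            forward = activation_zscore(edges_for("R", expected), observed(obs))
            flipped = activation_zscore(
                edges_for("R", expected), observed([-s for s in obs])
            )
            assert flipped.z == pytest.approx(-forward.z)

    def test_bounded_by_sqrt_n_with_equality_iff_unanimous(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            expected = rng.choice([-1, 1], size=n).tolist()
            obs = rng.choice([-1, 1], size=n).tolist()
            res = activation_zscore(edges_for("R", expected), observed(obs))
            assert abs(res.z) <= math.sqrt(res.n_used) + 1e-12
            unanimous = res.n_consistent in (0, res.n_used)
            assert math.isclose(abs(res.z), math.sqrt(res.n_used)) == unanimous

    def test_zero_expected_signs_and_flat_observations_excluded(self):
        edges = edges_for("R", [1, 0, 1, 1])
        signs = observed([1, 1, 0, 1])
        res = activation_zscore(edges, signs)
        assert res.n_used == 2  # T01 has unknown sign, T02 is flat
        # permutation invariance
        res2 = activation_zscore(list(reversed(edges)), signs)
        assert res2 == res

    def test_no_evidence_is_an_error(self):
        with pytest.raises(ValueError, match="no usable evidence"):
            activation_zscore(edges_for("R", [0, 0]), observed([1, 1]))

    def test_duplicate_targets_rejected(self):
        edges = [
            CausalEdge(regulator="R", target="T00", expected_sign=1),
            CausalEdge(regulator="R", target="T00", expected_sign=-1),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            activation_zscore(edges, observed([1]))

    def test_reference_z_values_reproduced_per_compound(
        self, causal_network, regulator_reference
    ):
        """Every reference z value follows from the network + observed directions."""
        from netprior.datasets import expression_changes

        changes = expression_changes()
        by_regulator = {}
        for edge in causal_network:
            by_regulator.setdefault(edge.regulator, []).append(edge)
        checked = 0
        for row in regulator_reference:
            for compound in row["z_compounds"]:
                signs = {
                    c.gene: c.direction.sign for c in changes if c.compound == compound
                }
                res = activation_zscore(by_regulator[row["regulator"]], signs)
                assert round(res.z, 2) == row["z"], (row["regulator"], compound)
                assert res.n_used == row["n_used"]
                assert res.n_consistent == row["n_consistent"]
                checked += 1
        assert checked == 50  # 21 z values over their compound scopes


class TestOverlapPvalue:
    def test_no_overlap_gives_one(self):
        assert overlap_pvalue({"A"}, {"B"}, {"A", "B", "C"}) == 1.0

    def test_everything_equal_gives_one(self):
        universe = {"A", "B", "C"}
        assert overlap_pvalue(universe, universe, universe) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # N=20, K=6, n=5, k=4: enumerate all C(20,5) draws
        N, K, n, k = 20, 6, 5, 4
        universe = {f"G{i}" for i in range(N)}
        targets = {f"G{i}" for i in range(K)}
        changed = {f"G{i}" for i in list(range(k)) + list(range(K, K + n - k))}
        hits = total = 0
        for draw in itertools.combinations(sorted(universe), n):
            total += 1
            if len(targets.intersection(draw)) >= k:
                hits += 1
        assert overlap_pvalue(targets, changed, universe) == pytest.approx(hits / total)


class TestCallRegulators:
    def test_reference_anchor_row(self, causal_network, gene_universe):
        from netprior.datasets import expression_changes

        changes = [c for c in expression_changes() if c.compound == "C1"]
        calls = call_regulators(causal_network, changes, gene_universe)
        anchor = next(c for c in calls if c.regulator == "MMP12")
        assert round(anchor.z, 2) == 1.73
        assert anchor.n_used == 3
        assert anchor.state is RegulatorState.INDETERMINATE  # 1.73 < 2
        # ranked by overlap p-value ascending
        ps = [c.p_overlap for c in calls]
        assert ps == sorted(ps)

    def test_all_flat_changes_give_empty_call_list(self, causal_network, gene_universe):
        flat = [
            ExpressionChange.from_fold_change(g, "C1", 1.0)
            for g in ("MMP12", "CD44", "NFKBIA")
        ]
        assert call_regulators(causal_network, flat, gene_universe) == []

    def test_planted_activated_regulator_is_unique_activated_call(self):
        from netprior.synthetic import (
            RegulatorSpec,
            SyntheticSpec,
            gen_causal_network,
            gen_universe,
        )

        spec = SyntheticSpec(
            seed=6,
            universe_size=60,
            regulator_specs=(
                RegulatorSpec("PLANT", 6, "active", 1.0),
                RegulatorSpec("NULL1", 4, "null"),
                RegulatorSpec("NULL2", 4, "null"),
            ),
        )
        universe = gen_universe(spec.universe_size)
        edges, changes, truth = gen_causal_network(spec, universe)
        calls = call_regulators(edges, changes, set(universe), p_max=1.1)
        activated = [c for c in calls if c.state is RegulatorState.ACTIVATED]
        assert [c.regulator for c in activated] == ["PLANT"]
        assert activated[0].z == pytest.approx(math.sqrt(6))

    def test_category_filter(self, causal_network, gene_universe):
        from netprior.datasets import expression_changes

        changes = [c for c in expression_changes() if c.compound == "C1"]
        calls = call_regulators(
            causal_network, changes, gene_universe, category_filter={"kinase"}
        )
        assert calls and all(c.category == "kinase" for c in calls)


class TestConsensusRegulators:
    def test_shared_across_four_compounds(self, causal_network, gene_universe):
        from netprior.datasets import expression_changes

        changes = expression_changes()
        calls = {
            comp: call_regulators(
                causal_network,
                [c for c in changes if c.compound == comp],
                gene_universe,
            )
            for comp in ("C1", "C7", "C10", "C15")
        }
        rows = {r["regulator"]: r for r in consensus_regulators(calls)}
        akt = rows["AKT family"]
        assert akt["compounds"] == ["C1", "C10", "C15", "C7"]
        assert akt["status"] == "shared"

    def test_single_compound_makes_everything_unique(self):
        calls = {
            "C9": [
                type("Call", (), {"regulator": "EGFR", "z": -0.82})(),
            ]
        }
        rows = consensus_regulators(calls)
        assert rows[0]["status"] == "unique"

    def test_grouping_equals_map_inversion(self):
        rng = np.random.default_rng(12)
        regs = [f"R{i}" for i in range(8)]
        calls = {}
        for comp in ("A", "B", "C"):
            chosen = rng.choice(regs, size=4, replace=False)
            calls[comp] = [
                type("Call", (), {"regulator": r, "z": 0.0})() for r in chosen
            ]
        rows = consensus_regulators(calls)
        inverted = {}
        for comp, comp_calls in calls.items():
            for call in comp_calls:
                inverted.setdefault(call.regulator, []).append(comp)
        assert {r["regulator"]: sorted(r["compounds"]) for r in rows} == {
            k: sorted(v) for k, v in inverted.items()
        }


class TestAnnotateBiomarkers:
    def test_three_of_eight_panel_genes_annotated(self):
        from netprior import datasets

        panel = GeneSet(name="panel", category="panel", members=datasets.PANEL_GENES)
        annotation = annotate_biomarkers(panel, datasets.biomarker_catalog_path())
        annotated = {g for g, roles in annotation.items() if roles is not None}
        assert annotated == {"ADAM9", "CD44", "MMP12"}
        assert annotation["CD44"] == ["diagnosis", "prognosis", "progression"]
        # rows failing species/disease/context filters never join
        assert annotation["NFKBIA"] is None
        assert annotation["SPARCL1"] is None

    def test_empty_catalog_maps_everything_to_none(self, tmp_path):
        path = tmp_path / "catalog.tsv"
        path.write_text("gene\tspecies\tdisease\tcontext\tbiomarker_roles\n")
        panel = GeneSet(name="p", category="p", members=frozenset({"MMP12"}))
        assert annotate_biomarkers(panel, path) == {"MMP12": None}


class TestSignatureNetworkExport:
    def test_round_trip_recovers_edge_multiset(self, causal_network, tmp_path):
        from netprior.datasets import expression_changes

        changes = [c for c in expression_changes() if c.compound == "C10"]
        sif = tmp_path / "net.sif"
        export_signature_network(
            causal_network, changes, sif, tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        )
        relation_sign = {"activates": 1, "inhibits": -1, "regulates": 0}
        parsed = {
            (src, tgt, relation_sign[rel]) for src, rel, tgt in npio.read_sif(sif)
        }
        assert parsed == {
            (e.regulator, e.target, e.expected_sign) for e in causal_network
        }

    def test_empty_inputs_give_headers_only(self, tmp_path):
        export_signature_network(
            [], [], tmp_path / "net.sif", tmp_path / "nodes.tsv", tmp_path / "edges.tsv"
        )
        assert (tmp_path / "net.sif").read_text() == ""
        assert (tmp_path / "nodes.tsv").read_text() == "node\tdirection\n"
        assert (tmp_path / "edges.tsv").read_text() == "regulator\ttarget\texpected_sign\n"
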