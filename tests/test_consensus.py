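"""Consensus scoring, table assembly and algorithm selection."""

import numpy as np
import pytest

from smmbn.bn_core import Dag, Pdag, DiscreteDataset, VariableSpec
from smmbn.ensemble_consensus import (
    build_consensus,
    consensus_skeleton,
    constrained_cpdag,
    run_replicates,
    score_algorithm_arcs,
    select_algorithms,
)
from smmbn.structure_learning import AlgorithmConfig, ConstraintSet
from smmbn.exceptions import ContractError


def _pdag(directed=(), undirected=(), nodes=("a", "b", "c")):
    return Pdag(nodes, directed, undirected)


class TestScoreAlgorithmArcs:
    def test_unanimous_directed_scores_one(self):
        structures = [_pdag(directed=[("a", "b")])] * 100
        assert score_algorithm_arcs(structures) == {("a", "b"): 1.0}

    def test_split_directions_score_half(self):
        # a->b at 0.40, b->a at 0.40, absent 0.20: edge 0.8 > 0.7, no
        # single direction above threshold
        structures = (
            [_pdag(directed=[("a", "b")])] * 40
            + [_pdag(directed=[("b", "a")])] * 40
            + [_pdag()] * 20
        )
        assert score_algorithm_arcs(structures, 0.7) == {("a", "b"): 0.5}

    def test_strict_threshold(self):
        structures = [_pdag(directed=[("a", "b")])] * 60 + [_pdag()] * 40
        assert score_algorithm_arcs(structures, 0.7) == {}

    def test_undirected_counts_toward_edge(self):
        structures = [_pdag(undirected=[("a", "b")])] * 80 + [_pdag()] * 20
        assert score_algorithm_arcs(structures, 0.7) == {("a", "b"): 0.5}

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(0)
        structures = (
            [_pdag(directed=[("a", "b")])] * 50
            + [_pdag(undirected=[("b", "c")])] * 50
        )
        shuffled = list(structures)
        rng.shuffle(shuffled)
        assert score_algorithm_arcs(structures) == score_algorithm_arcs(shuffled)

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            score_algorithm_arcs([])


class TestConsensusTable:
    def test_single_algorithm_single_arc(self):
        table = build_consensus({"alg": {("a", "b"): 1.0}}, ["alg"])
        assert table.occurrence == {("a", "b"): 1.0}
        assert table.total_arcs == {"alg": 1.0}

    def test_unanimous_eleven_algorithms(self):
        algs = [f"alg{i}" for i in range(11)]
        table = build_consensus(
            {alg: {("hdp", "smm"): 1.0} for alg in algs}, algs
        )
        assert table.occurrence[("hdp", "smm")] == 11.0

    def test_mixed_entries_sum(self):
        table = build_consensus(
            {
                "x": {("a", "b"): 1.0},
                "y": {("a", "b"): 1.0},
                "z": {("a", "b"): 0.5},
            },
            ["x", "y", "z"],
        )
        assert table.occurrence[("a", "b")] == pytest.approx(2.5)

    def test_row_and_column_sums_recompute(self):
        scores = {
            "x": {("a", "b"): 1.0, ("b", "c"): 0.5},
            "y": {("a", "b"): 0.5},
        }
        table = build_consensus(scores, ["x", "y"])
        assert sum(table.occurrence.values()) == pytest.approx(
            sum(table.total_arcs.values())
        )
        for arc in table.arcs:
            assert table.occurrence[arc] == pytest.approx(
                sum(table.entry(arc, alg) for alg in table.algorithms)
            )

    def test_opposite_directions_merge_to_one_row(self):
        table = build_consensus(
            {"x": {("a", "b"): 1.0}, "y": {("b", "a"): 1.0}, "z": {("b", "a"): 1.0}},
            ["x", "y", "z"],
        )
        assert table.arcs == [("b", "a")]  # majority direction labels the row
        assert table.occurrence[("b", "a")] == 3.0

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        table = build_consensus(
            {"x": {("a", "b"): 1.0, ("b", "c"): 0.5}}, ["x"]
        )
        path = tmp_path / "consensus.csv"
        table.to_csv(path)
        frame = pd.read_csv(path, index_col=0)
        assert list(frame.columns) == ["x", "occurrence"]
        assert frame.loc["a -> b", "x"] == 1.0
        assert frame.loc["total_arcs", "x"] == 1.5


class TestSelectAlgorithms:
    # column totals of the published consensus table, in roster order
    ROSTER = [
        "HC-BIC", "HC-AIC", "TS-BIC", "TS-AIC", "GS", "IAMB",
        "Fast-IAMB", "Inter-IAMB", "MMHC", "hybrid H2PC", "rmax2",
    ]
    TOTALS = [29, 29, 28, 29, 8, 20, 16.5, 20, 28, 28, 26]

    def _table(self):
        # one synthetic arc per half-point of each column total
        scores = {}
        for alg, total in zip(self.ROSTER, self.TOTALS):
            entries = {}
            full, half = int(total), total % 1 != 0
            for i in range(full):
                entries[(f"n{i:02d}", f"m{i:02d}")] = 1.0
            if half:
                entries[(f"n{full:02d}", f"m{full:02d}")] = 0.5
            scores[alg] = entries
        return build_consensus(scores, self.ROSTER)

    def test_published_totals_select_top_three(self):
        table = self._table()
        assert table.total_arcs == dict(zip(self.ROSTER, map(float, self.TOTALS)))
        assert select_algorithms(table, 3) == ["HC-BIC", "HC-AIC", "TS-AIC"]

    def test_k_equals_roster(self):
        table = self._table()
        ranked = select_algorithms(table, len(self.ROSTER))
        assert sorted(ranked) == sorted(self.ROSTER)
        totals = table.total_arcs
        assert all(
            totals[ranked[i]] >= totals[ranked[i + 1]]
            for i in range(len(ranked) - 1)
        )

    def test_all_equal_totals_gives_roster_prefix(self):
        algs = ["one", "two", "three"]
        table = build_consensus(
            {alg: {("a", "b"): 1.0} for alg in algs}, algs
        )
        assert select_algorithms(table, 2) == ["one", "two"]

    def test_k_too_large(self):
        with pytest.raises(ContractError):
            select_algorithms(self._table(), 12)


class TestRunReplicates:
    def _planted_data(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, n)
        b = np.where(rng.random(n) < 0.95, a, 1 - a)
        specs = [VariableSpec("a", ("0", "1")), VariableSpec("b", ("0", "1"))]
        return DiscreteDataset(specs, np.column_stack([a, b]))

    def test_single_replicate_matches_direct_learning(self):
        from smmbn.structure_learning import hill_climb
        from smmbn.bn_core import to_cpdag

        data = self._planted_data()
        cfg = AlgorithmConfig("hc", score="bic")
        [structure] = run_replicates(data, cfg, 1, seed=5)
        rows = np.random.default_rng(5).integers(0, data.n_records, data.n_records)
        direct = to_cpdag(hill_climb(data.take(rows), cfg))
        assert structure == direct

    def test_seed_reproducibility(self):
        data = self._planted_data(seed=1)
        cfg = AlgorithmConfig("hc", score="bic")
        assert run_replicates(data, cfg, 5, seed=9) == run_replicates(
            data, cfg, 5, seed=9
        )

    def test_planted_arc_appears_in_every_replicate(self):
        data = self._planted_data(seed=2)
        cfg = AlgorithmConfig("hc", score="bic")
        structures = run_replicates(data, cfg, 50, seed=3)
        pair = frozenset(("a", "b"))
        assert all(pair in s.skeleton() for s in structures)


class TestConstrainedCpdag:
    def test_forced_direction_restored(self):
        dag = Dag(["race", "anemia"], [("race", "anemia")])
        constraints = ConstraintSet(blacklist=frozenset({("anemia", "race")}))
        pdag = constrained_cpdag(dag, constraints)
        assert pdag.directed_arcs == {("race", "anemia")}

    def test_without_constraints_stays_undirected(self):
        from smmbn.structure_learning import EMPTY_CONSTRAINTS

        dag = Dag(["a", "b"], [("a", "b")])
        pdag = constrained_cpdag(dag, EMPTY_CONSTRAINTS)
        assert pdag.undirected_edges == {frozenset(("a", "b"))}


def test_consensus_skeleton_threshold():
    scores = {
        "x": {("a", "b"): 1.0, ("c", "d"): 0.5},
        "y": {("a", "b"): 1.0},
    }
    table = build_consensus(scores, ["x", "y"])
    assert consensus_skeleton(table, min_fraction=0.75) == {frozenset(("a", "b"))}
    assert consensus_skeleton(table, min_fraction=0.25) == {
        frozenset(("a", "b")),
        frozenset(("c", "d")),
    }
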