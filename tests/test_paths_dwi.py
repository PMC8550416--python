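"""Unblocked path enumeration and distance-weighted influence."""

import itertools

import pytest

from smmbn.bn_core import Dag
from smmbn.ensemble_consensus import ArcStrengthTable
from smmbn.influence_queries import (
    dwi,
    dwi_weighted,
    rank_influence,
    unblocked_paths,
)
from smmbn.exceptions import ConfigurationError, ContractError, IdentifierError


def _strengths(mapping, nodes):
    return ArcStrengthTable(
        dict(mapping),
        replicates=1,
        sample_size=1,
        nodes=tuple(nodes),
        check_fractions=False,
    )


def brute_force_unblocked(dag: Dag, x: str, y: str):
    """Oracle: enumerate all simple skeleton paths, filter colliders."""
    adjacency = {n: set(dag.neighbours(n)) for n in dag.nodes}
    out = []

    def walk(path):
        if path[-1] == y:
            ok = True
            for i in range(1, len(path) - 1):
                if dag.has_arc(path[i - 1], path[i]) and dag.has_arc(
                    path[i + 1], path[i]
                ):
                    ok = False
                    break
            if ok:
                out.append(tuple(path))
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in path:
                walk(path + [nxt])

    walk([x])
    return sorted(out, key=lambda p: (len(p), p))


class TestUnblockedPaths:
    def test_direct_and_mediated(self):
        dag = Dag(["X", "Y", "Z"], [("X", "Y"), ("X", "Z"), ("Z", "Y")])
        paths = unblocked_paths(dag, "X", "Y")
        assert [p.nodes for p in paths] == [("X", "Y"), ("X", "Z", "Y")]
        assert [p.length for p in paths] == [1, 2]

    def test_collider_blocks(self):
        dag = Dag(["X", "Y", "C"], [("X", "C"), ("Y", "C")])
        assert unblocked_paths(dag, "X", "Y") == []

    def test_matches_brute_force_on_mixed7(self, mixed7):
        dag, _ = mixed7
        for x, y in itertools.combinations(dag.nodes, 2):
            got = [p.nodes for p in unblocked_paths(dag, x, y)]
            assert got == brute_force_unblocked(dag, x, y), (x, y)

    def test_mixed7_documented_paths(self, mixed7):
        dag, _ = mixed7
        got = [p.nodes for p in unblocked_paths(dag, "x", "y")]
        assert got == [("x", "u", "y"), ("x", "v", "y"), ("x", "w", "y")]

    def test_directed_only_mode(self, mixed7):
        dag, _ = mixed7
        got = [p.nodes for p in unblocked_paths(dag, "x", "y", directed_only=True)]
        assert got == [("x", "u", "y"), ("x", "v", "y")]

    def test_unknown_node(self, mixed7):
        with pytest.raises(IdentifierError):
            unblocked_paths(mixed7[0], "x", "nope")


class TestDwi:
    def test_single_arc(self):
        dag = Dag(["X", "Y"], [("X", "Y")])
        assert dwi(dag, "X", "Y", 0.8) == pytest.approx(0.8)

    def test_two_paths_powers(self):
        dag = Dag(["X", "Y", "Z"], [("X", "Y"), ("X", "Z"), ("Z", "Y")])
        assert dwi(dag, "X", "Y", 0.5) == pytest.approx(0.75)

    def test_w_one_counts_paths(self, mixed7):
        dag, _ = mixed7
        for x, y in itertools.combinations(dag.nodes, 2):
            assert dwi(dag, x, y, 1.0) == len(unblocked_paths(dag, x, y))

    def test_w_zero(self):
        dag = Dag(["X", "Y"], [("X", "Y")])
        assert dwi(dag, "X", "Y", 0.0) == 0.0

    def test_monotone_in_w(self, mixed7):
        dag, _ = mixed7
        values = [dwi(dag, "x", "y", w) for w in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert values == sorted(values)

    def test_w_out_of_range(self):
        with pytest.raises(ContractError):
            dwi(Dag(["X", "Y"], [("X", "Y")]), "X", "Y", 1.5)


class TestDwiWeighted:
    def test_single_arc_strength(self):
        dag = Dag(["X", "Y"], [("X", "Y")])
        table = _strengths({("X", "Y"): 0.9}, dag.nodes)
        assert dwi_weighted(dag, table, "X", "Y") == pytest.approx(0.9)

    def test_two_path_products(self):
        dag = Dag(["X", "Y", "Z"], [("X", "Y"), ("X", "Z"), ("Z", "Y")])
        table = _strengths(
            {("X", "Y"): 0.9, ("X", "Z"): 0.8, ("Z", "Y"): 0.7}, dag.nodes
        )
        assert dwi_weighted(dag, table, "X", "Y") == pytest.approx(0.9 + 0.56)

    def test_all_ones_equals_path_count(self, mixed7):
        dag, _ = mixed7
        table = _strengths({a: 1.0 for a in dag.arcs()}, dag.nodes)
        for x, y in itertools.combinations(dag.nodes, 2):
            assert dwi_weighted(dag, table, x, y) == pytest.approx(
                dwi(dag, x, y, 1.0)
            )

    def test_missing_strength_rejected(self):
        dag = Dag(["X", "Y"], [("X", "Y")])
        table = _strengths({}, dag.nodes)
        with pytest.raises(ConfigurationError):
            dwi_weighted(dag, table, "X", "Y")


class TestRankInfluence:
    def test_star_ranking(self):
        dag = Dag(["A", "B", "T"], [("A", "T"), ("B", "T")])
        table = _strengths({("A", "T"): 0.9, ("B", "T"): 0.4}, dag.nodes)
        result = rank_influence(dag, "T", strengths=table)
        assert result.ranking == ("A", "B")
        assert result.scores == {"A": pytest.approx(0.9), "B": pytest.approx(0.4)}

    def test_collider_only_node_scores_zero_and_ranks_last(self):
        dag = Dag(
            ["A", "T", "Z", "C"], [("A", "T"), ("Z", "C"), ("T", "C")]
        )
        table = _strengths(
            {("A", "T"): 0.9, ("Z", "C"): 0.8, ("T", "C"): 0.7}, dag.nodes
        )
        result = rank_influence(dag, "T", strengths=table)
        assert result.scores["Z"] == 0.0
        assert result.ranking[-1] == "Z"

    def test_exclusions_remove_arcs(self):
        dag = Dag(["A", "B", "T"], [("A", "T"), ("B", "T")])
        table = _strengths({("A", "T"): 0.9, ("B", "T"): 0.4}, dag.nodes)
        result = rank_influence(
            dag, "T", strengths=table, exclusions=(("A", "T"),)
        )
        assert result.scores["A"] == 0.0

    def test_constant_w_mode(self):
        dag = Dag(["A", "B", "T"], [("A", "B"), ("B", "T")])
        result = rank_influence(dag, "T", w=0.5)
        assert result.scores == {"B": pytest.approx(0.5), "A": pytest.approx(0.25)}
        assert result.mode == "constant-w"

    def test_exactly_one_mode_required(self):
        dag = Dag(["A", "T"], [("A", "T")])
        with pytest.raises(ConfigurationError):
            rank_influence(dag, "T")

    def test_tie_broken_by_path_distance(self):
        # parent and grandparent tie in score when the upstream arc has
        # strength 1; the direct parent must rank first
        dag = Dag(["G", "P", "T"], [("G", "P"), ("P", "T")])
        table = _strengths({("G", "P"): 1.0, ("P", "T"): 0.9}, dag.nodes)
        result = rank_influence(dag, "T", strengths=table)
        assert result.ranking == ("P", "G")

    def test_collider_arc_addition_leaves_scores_unchanged(self):
        """An extra arc into an existing collider only creates blocked
        paths to the target, so all other influence scores are unchanged."""
        nodes = ["A", "B", "C", "D", "T"]
        base = {("A", "T"): 0.9, ("A", "B"): 0.8, ("C", "B"): 0.7}
        dag = Dag(nodes, list(base))
        before = rank_influence(dag, "T", strengths=_strengths(base, nodes))
        extra = {**base, ("D", "B"): 0.6}
        dag2 = Dag(nodes, list(extra))
        after = rank_influence(dag2, "T", strengths=_strengths(extra, nodes))
        for node in ("A", "B", "C"):
            assert after.scores[node] == before.scores[node]
        assert after.scores["D"] == 0.0
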