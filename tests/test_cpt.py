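"""CPT fitting, joint probabilities, exact queries and ancestral sampling."""

import numpy as np
import pytest

from smmbn.bn_core import (
    CptSet,
    Dag,
    DiscreteDataset,
    VariableSpec,
    ancestral_sample,
    exact_query,
    fit_cpts,
    joint_probability,
)
from smmbn.exceptions import ContractError, UndefinedConditionalError

from conftest import enumerate_assignments, oracle_joint, oracle_query


def _binary_data(columns: dict[str, list[int]]) -> DiscreteDataset:
    specs = [VariableSpec(n, ("0", "1")) for n in columns]
    codes = np.array(list(columns.values())).T
    return DiscreteDataset(specs, codes)


class TestFitCpts:
    def test_parentless_frequency(self):
        data = _binary_data({"x": [1, 0, 0, 1, 0, 0, 0, 1, 0, 0]})
        cpts = fit_cpts(Dag(["x"]), data, smoothing=0.0)
        assert cpts.prob("x", 1, {}) == pytest.approx(0.3)

    def test_conditional_frequency(self):
        x = [1] * 10 + [0] * 5
        y = [1] * 8 + [0] * 2 + [0] * 5
        data = _binary_data({"x": x, "y": y})
        cpts = fit_cpts(Dag(["x", "y"], [("x", "y")]), data, smoothing=0.0)
        assert cpts.prob("y", 1, {"x": 1}) == pytest.approx(0.8)

    def test_smoothing_arithmetic(self):
        # counts (0, 4) with smoothing 1 -> (1/6, 5/6)
        data = _binary_data({"x": [1, 1, 1, 1]})
        cpts = fit_cpts(Dag(["x"]), data, smoothing=1.0)
        assert cpts.table("x")[0] == pytest.approx([1 / 6, 5 / 6])

    def test_unseen_parent_config_uniform(self):
        data = _binary_data({"x": [1, 1, 1], "y": [0, 1, 1]})
        cpts = fit_cpts(Dag(["x", "y"], [("x", "y")]), data, smoothing=0.0)
        assert cpts.table("y")[0] == pytest.approx([0.5, 0.5])

    def test_rows_normalized(self, mixed7):
        dag, cpts = mixed7
        data = ancestral_sample(dag, cpts, 500, seed=0)
        fitted = fit_cpts(dag, data, smoothing=0.5)
        for n in fitted.nodes:
            assert fitted.table(n).sum(axis=1) == pytest.approx(
                np.ones(fitted.table(n).shape[0]), abs=1e-9
            )

    def test_mle_loglik_cannot_be_improved(self, chain3):
        """Perturbing any fitted CPT row lowers training log-likelihood."""
        dag, gen = chain3
        data = ancestral_sample(dag, gen, 400, seed=7)
        cpts = fit_cpts(dag, data, smoothing=0.0)

        def loglik(c: CptSet) -> float:
            total = 0.0
            for i in range(data.n_records):
                rec = {n: int(data.column(n)[i]) for n in c.nodes}
                total += np.log(joint_probability(dag, c, rec))
            return total

        base = loglik(cpts)
        rng = np.random.default_rng(0)
        for node in cpts.nodes:
            table = cpts.table(node).copy()
            for row in range(table.shape[0]):
                perturbed = table.copy()
                shift = 0.08 * (rng.random(table.shape[1]) - 0.5)
                perturbed[row] = np.clip(perturbed[row] + shift, 0.01, None)
                perturbed[row] /= perturbed[row].sum()
                other = CptSet(
                    cpts.variables,
                    {n: cpts.parents(n) for n in cpts.nodes},
                    {
                        n: (perturbed if n == node else cpts.table(n))
                        for n in cpts.nodes
                    },
                )
                assert loglik(other) <= base + 1e-9


class TestJointProbability:
    def test_two_node_product(self):
        specs = [VariableSpec("A", ("0", "1")), VariableSpec("B", ("0", "1"))]
        cpts = CptSet(
            specs,
            {"A": (), "B": ("A",)},
            {"A": [[0.5, 0.5]], "B": [[0.9, 0.1], [0.2, 0.8]]},
        )
        dag = Dag(["A", "B"], [("A", "B")])
        assert joint_probability(dag, cpts, {"A": 1, "B": 1}) == pytest.approx(0.4)

    @pytest.mark.parametrize("fixture", ["chain3", "collider3", "diamond4", "mixed7"])
    def test_normalization(self, fixture, request):
        dag, cpts = request.getfixturevalue(fixture)
        total = sum(
            joint_probability(dag, cpts, a) for a in enumerate_assignments(cpts)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_manual_oracle(self, mixed7):
        dag, cpts = mixed7
        for a in enumerate_assignments(cpts):
            assert joint_probability(dag, cpts, a) == pytest.approx(
                oracle_joint(cpts, a), abs=1e-12
            )

    def test_incomplete_assignment_rejected(self, chain3):
        dag, cpts = chain3
        with pytest.raises(ContractError):
            joint_probability(dag, cpts, {"A": 0})

    def test_sampling_frequencies_match_joint(self, collider3):
        """Empirical assignment frequencies agree within 4 binomial SEs."""
        dag, cpts = collider3
        n = 200_000
        data = ancestral_sample(dag, cpts, n, seed=123)
        key = data.codes @ np.array([4, 2, 1])
        freq = np.bincount(key, minlength=8) / n
        for i, a in enumerate(enumerate_assignments(cpts)):
            p = joint_probability(dag, cpts, a)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(freq[i] - p) <= 4 * se + 1e-12


class TestExactQuery:
    def test_event_equals_evidence_variable(self, chain3):
        dag, cpts = chain3
        assert exact_query(dag, cpts, {"A": 1}, {}) == pytest.approx(0.3)

    def test_hand_computed_chain(self, chain3):
        dag, cpts = chain3
        # P(C=1 | A=1) = 0.8 * 0.9 + 0.2 * 0.1 = 0.74
        assert exact_query(dag, cpts, {"C": "1"}, {"A": "1"}) == pytest.approx(
            0.74, abs=1e-12
        )

    def test_empty_evidence_is_marginal(self, diamond4):
        dag, cpts = diamond4
        marg = sum(
            joint_probability(dag, cpts, a)
            for a in enumerate_assignments(cpts)
            if a["Y"] == 1
        )
        assert exact_query(dag, cpts, {"Y": 1}, {}) == pytest.approx(marg, abs=1e-12)

    def test_matches_enumeration_oracle(self, mixed7):
        dag, cpts = mixed7
        got = exact_query(dag, cpts, {"y": 1}, {"x": 1, "w": 0})
        want = oracle_query(cpts, {"y": 1}, {"x": 1, "w": 0})
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_probability_evidence(self):
        specs = [VariableSpec("A", ("0", "1")), VariableSpec("B", ("0", "1"))]
        cpts = CptSet(
            specs,
            {"A": (), "B": ("A",)},
            {"A": [[1.0, 0.0]], "B": [[0.5, 0.5], [0.5, 0.5]]},
        )
        dag = Dag(["A", "B"], [("A", "B")])
        with pytest.raises(UndefinedConditionalError):
            exact_query(dag, cpts, {"B": 1}, {"A": 1})

    def test_overlapping_event_evidence_rejected(self, chain3):
        dag, cpts = chain3
        with pytest.raises(ContractError):
            exact_query(dag, cpts, {"A": 1}, {"A": 0})


class TestAncestralSample:
    def test_n_validation(self, chain3):
        dag, cpts = chain3
        with pytest.raises(ContractError):
            ancestral_sample(dag, cpts, 0, seed=1)
        assert ancestral_sample(dag, cpts, 1, seed=1).n_records == 1

    def test_determinism(self, mixed7):
        dag, cpts = mixed7
        a = ancestral_sample(dag, cpts, 500, seed=42)
        b = ancestral_sample(dag, cpts, 500, seed=42)
        assert a == b

    def test_different_seeds_differ(self, mixed7):
        dag, cpts = mixed7
        a = ancestral_sample(dag, cpts, 500, seed=1)
        b = ancestral_sample(dag, cpts, 500, seed=2)
        assert a != b

    def test_marginals_converge(self, diamond4):
        dag, cpts = diamond4
        n = 100_000
        data = ancestral_sample(dag, cpts, n, seed=9)
        for node in dag.nodes:
            p = exact_query(dag, cpts, {node: 1}, {})
            se = np.sqrt(p * (1 - p) / n)
            emp = float((data.column(node) == 1).mean())
            assert abs(emp - p) <= 4 * se
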