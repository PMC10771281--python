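"""F81 ancestral reconstruction against independent oracles.

The oracle computes transition matrices by numerical matrix exponential of
the F81 rate matrix (scipy), and likelihoods / marginals / joint scores by
exhaustive enumeration over all internal-state assignments — sharing no
code path with the pruning, up-down, or dynamic-programming implementations
it checks.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from phylocarto import (
    F81Model,
    cluster_pie_counts,
    f81_transition_prob,
    fit_scale,
    joint_ml,
    marginal_posteriors,
    pruning_log_likelihood,
    reconstruct,
    retain_modalities,
)
from phylocarto.asr import f81_matrix
from phylocarto.errors import DataError, ParameterError

from conftest import build_tree, random_annotated_tree


def expm_transition(model, t):
    return expm(model.rate_matrix() * model.scale * t)


def enumerate_likelihoods(tree, tip_state_idx, model):
    """Oracle: joint probability of each full internal assignment, using
    matrix-exponential transition probabilities."""
    internal = [nid for nid in tree.postorder() if tree.nodes[nid].children]
    pmats = {
        nid: expm_transition(model, tree.nodes[nid].branch_length or 0.0)
        for nid in tree.nodes
        if tree.nodes[nid].parent is not None
    }
    table = {}
    for assignment in itertools.product(range(model.m), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        state.update(tip_state_idx)
        p = model.pi[state[tree.root_id]]
        for nid, node in tree.nodes.items():
            if node.parent is not None:
                p *= pmats[nid][state[node.parent], state[nid]]
        table[assignment] = (internal, p)
    return internal, {a: p for a, (_, p) in table.items()}


def tip_index_map(tree, tip_states, model):
    return {
        t.id: model.index(tip_states[t.taxon_label]) for t in tree.tips()
    }


def random_case(rng, n_tips, m):
    tree, _ = random_annotated_tree(n_tips=n_tips, seed=int(rng.integers(1 << 30)))
    states = [f"S{i}" for i in range(m)]
    pi = rng.dirichlet(np.ones(m) * 2)
    pi = np.clip(pi, 0.05, None)
    pi = pi / pi.sum()
    scale = float(rng.uniform(0.1, 3.0))
    model = F81Model(states=states, pi=pi, scale=scale)
    tip_states = {
        t.taxon_label: states[int(rng.integers(m))] for t in tree.tips()
    }
    return tree, model, tip_states


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        model = F81Model(["a", "b", "c"], np.array([0.2, 0.3, 0.5]))
        assert np.allclose(f81_matrix(model, 0.0), np.eye(3))

    def test_infinite_time_rows_equal_pi(self):
        model = F81Model(["a", "b"], np.array([0.7, 0.3]))
        p = f81_matrix(model, 1e6)
        assert np.allclose(p, np.tile(model.pi, (2, 1)), atol=1e-9)

    def test_two_state_closed_form_matches_matrix_exponential(self):
        model = F81Model(["a", "b"], np.array([0.5, 0.5]), scale=1.0)
        stay = f81_transition_prob(model, 0, 0, 0.5)
        assert stay == pytest.approx(0.5 + 0.5 * math.exp(-1.0), abs=1e-12)
        assert stay == pytest.approx(0.68394, abs=1e-5)
        assert np.allclose(f81_matrix(model, 0.5), expm_transition(model, 0.5), atol=1e-10)

    def test_rows_sum_to_one_fuzz(self, rng):
        for _ in range(1000):
            m = int(rng.integers(2, 6))
            pi = rng.dirichlet(np.ones(m))
            pi = np.clip(pi, 1e-6, None)
            pi /= pi.sum()
            model = F81Model([str(i) for i in range(m)], pi, scale=float(rng.uniform(0.01, 10)))
            t = float(rng.uniform(0, 50))
            assert np.allclose(f81_matrix(model, t).sum(axis=1), 1.0, atol=1e-12)

    def test_negative_time_rejected(self):
        model = F81Model(["a", "b"], np.array([0.5, 0.5]))
        with pytest.raises(ParameterError):
            f81_matrix(model, -1.0)


class TestPruningLikelihood:
    def test_single_tip_tree_is_log_pi(self):
        tree = build_tree(("A", None, 0.0, 0.0, []))
        model = F81Model(["x", "y"], np.array([0.3, 0.7]))
        ll = pruning_log_likelihood(tree, {"A": "y"}, model)
        assert ll == pytest.approx(math.log(0.7), abs=1e-12)

    def test_long_branch_limit_factorizes(self):
        tree = build_tree(
            (None, None, 0.0, 0.0, [
                ("A", 1e7, 0.0, 0.0, []),
                ("B", 1e7, 0.0, 0.0, []),
            ])
        )
        model = F81Model(["x", "y"], np.array([0.25, 0.75]))
        ll = pruning_log_likelihood(tree, {"A": "x", "B": "y"}, model)
        assert ll == pytest.approx(math.log(0.25) + math.log(0.75), abs=1e-9)

    def test_unknown_state_label_raises(self, two_tip_tree):
        model = F81Model(["x", "y"], np.array([0.5, 0.5]))
        with pytest.raises(DataError):
            pruning_log_likelihood(two_tip_tree, {"A": "zzz", "B": "x"}, model)

    def test_missing_tip_raises(self, two_tip_tree):
        model = F81Model(["x", "y"], np.array([0.5, 0.5]))
        with pytest.raises(DataError):
            pruning_log_likelihood(two_tip_tree, {"A": "x"}, model)

    def test_ambiguous_tip_sums_states(self, two_tip_tree):
        model = F81Model(["x", "y"], np.array([0.4, 0.6]))
        both = pruning_log_likelihood(two_tip_tree, {"A": {"x", "y"}, "B": "x"}, model)
        parts = [
            pruning_log_likelihood(two_tip_tree, {"A": s, "B": "x"}, model)
            for s in ("x", "y")
        ]
        assert math.exp(both) == pytest.approx(sum(math.exp(p) for p in parts), abs=1e-12)

    def test_label_permutation_invariance(self):
        tree, _ = random_annotated_tree(n_tips=10, seed=21)
        pi = np.array([0.2, 0.3, 0.5])
        model = F81Model(["a", "b", "c"], pi, scale=0.8)
        tips = {t.taxon_label: ["a", "b", "c"][t.id % 3] for t in tree.tips()}
        ll = pruning_log_likelihood(tree, tips, model)
        perm = [2, 0, 1]
        model_p = F81Model(["c", "a", "b"], pi[perm], scale=0.8)
        assert pruning_log_likelihood(tree, tips, model_p) == pytest.approx(ll, abs=1e-10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n_tips,m", [(2, 2), (3, 2), (3, 3), (4, 3), (5, 3)])
    def test_pruning_marginals_joint_match_enumeration(self, n_tips, m):
        rng = np.random.default_rng(100 + n_tips * 10 + m)
        for _ in range(8):
            tree, model, tip_states = random_case(rng, n_tips, m)
            tip_idx = tip_index_map(tree, tip_states, model)
            internal, table = enumerate_likelihoods(tree, tip_idx, model)
            total = sum(table.values())

            ll = pruning_log_likelihood(tree, tip_states, model)
            assert ll == pytest.approx(math.log(total), abs=1e-10)

            marg = marginal_posteriors(tree, tip_states, model)
            for pos, nid in enumerate(internal):
                for s in range(model.m):
                    expected = sum(
                        p for a, p in table.items() if a[pos] == s
                    ) / total
                    assert marg[nid][s] == pytest.approx(expected, abs=1e-10)

            joint, joint_ll = joint_ml(tree, tip_states, model)
            best_assignment = max(table, key=table.get)
            assert joint_ll == pytest.approx(math.log(table[best_assignment]), abs=1e-10)
            assert joint_ll <= ll + 1e-12
            # the DP's assignment must reach the same maximal probability
            dp_prob = table[tuple(model.index(joint[nid]) for nid in internal)]
            assert math.log(dp_prob) == pytest.approx(math.log(table[best_assignment]), abs=1e-10)

    def test_tip_marginals_are_point_masses(self):
        tree, model, tip_states = random_case(np.random.default_rng(0), 4, 2)
        marg = marginal_posteriors(tree, tip_states, model)
        for t in tree.tips():
            vec = marg[t.id]
            assert vec[model.index(tip_states[t.taxon_label])] == pytest.approx(1.0)

    def test_marginals_sum_to_one(self):
        tree, model, tip_states = random_case(np.random.default_rng(1), 5, 3)
        for vec in marginal_posteriors(tree, tip_states, model).values():
            assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_tips_identical_joint_is_constant(self):
        tree, _ = random_annotated_tree(n_tips=6, seed=33)
        model = F81Model(["p", "q"], np.array([0.5, 0.5]), scale=0.5)
        tips = {t.taxon_label: "q" for t in tree.tips()}
        joint, _ = joint_ml(tree, tips, model)
        assert set(joint.values()) == {"q"}


class TestScaleFitting:
    def test_fitted_value_beats_grid(self):
        tree, states = random_annotated_tree(n_tips=40, seed=50, scale=1.0)
        tips = {t.taxon_label: t.discrete_trait for t in tree.tips()}
        pi = np.full(3, 1 / 3)
        scale, ll = fit_scale(tree, tips, pi, ["A", "B", "C"])
        model = F81Model(["A", "B", "C"], pi)
        for grid in np.logspace(-3, 2, 10):
            assert ll >= pruning_log_likelihood(tree, tips, model, scale=float(grid)) - 1e-9

    def test_invariant_character_drives_scale_to_lower_bound(self):
        tree, _ = random_annotated_tree(n_tips=10, seed=51)
        tips = {t.taxon_label: "A" for t in tree.tips()}
        pi = np.array([0.5, 0.5])
        scale, ll = fit_scale(tree, tips, pi, ["A", "B"], bracket=(1e-4, 10.0))
        assert scale == pytest.approx(1e-4, rel=0.01)

    def test_bad_bracket_rejected(self, two_tip_tree):
        with pytest.raises(ParameterError):
            fit_scale(two_tip_tree, {"A": "x", "B": "y"}, np.array([0.5, 0.5]),
                      ["x", "y"], bracket=(1.0, 0.5))


class TestModalityRetention:
    @pytest.mark.parametrize(
        "vector,percent,expected",
        [
            ((0.6, 0.3, 0.1), 20, ["S0"]),
            ((0.5, 0.45, 0.05), 20, ["S0", "S1"]),
            ((0.4, 0.4, 0.2), 0, ["S0", "S1"]),
            ((1.0, 0.0, 0.0), 0, ["S0"]),
            ((0.2, 0.3, 0.5), 100, ["S0", "S1", "S2"]),
        ],
    )
    def test_threshold_rule(self, vector, percent, expected):
        states = ["S0", "S1", "S2"]
        assert retain_modalities(np.array(vector), percent, states) == expected

    def test_always_contains_majority(self, rng):
        states = ["S0", "S1", "S2"]
        for _ in range(200):
            vec = rng.dirichlet(np.ones(3))
            p = float(rng.uniform(0, 100))
            retained = retain_modalities(vec, p, states)
            assert states[int(np.argmax(vec))] in retained
            assert retained

    def test_out_of_range_percent_rejected(self):
        with pytest.raises(ParameterError):
            retain_modalities(np.array([1.0, 0.0]), 150, ["a", "b"])


class TestPieCounts:
    def test_single_cluster_tally(self):
        retained = {0: ["S4"], 1: ["S4"], 2: ["S4"]}
        counts = cluster_pie_counts(retained, {0: 0, 1: 0, 2: 0})
        assert counts == {0: {"S4": 3}}

    def test_multi_retention_increments_both(self):
        counts = cluster_pie_counts({0: ["S4", "S5"]}, {0: 0})
        assert counts == {0: {"S4": 1, "S5": 1}}

    def test_matches_brute_force_tally(self, rng):
        states = ["a", "b", "c"]
        retained = {
            i: [s for s in states if rng.uniform() < 0.5] or ["a"] for i in range(50)
        }
        grouping = {i: int(rng.integers(2)) for i in range(50)}
        counts = cluster_pie_counts(retained, grouping)
        for group in (0, 1):
            for s in states:
                expected = sum(
                    1 for i in range(50) if grouping[i] == group and s in retained[i]
                )
                assert counts.get(group, {}).get(s, 0) == expected


class TestReconstructDriver:
    def test_end_to_end_on_simulated_data(self):
        tree, truth = random_annotated_tree(n_tips=40, seed=77, states=("A", "B", "C"))
        tips = {t.taxon_label: t.discrete_trait for t in tree.tips()}
        result = reconstruct(tree, tips, threshold_percent=20)
        assert set(result.marginals) == set(tree.nodes)
        assert result.joint_log_likelihood <= result.log_likelihood + 1e-12
        for t in tree.tips():
            assert result.joint[t.id] == tips[t.taxon_label]
        for nid, kept in result.retained.items():
            assert kept
            assert result.model.states[int(np.argmax(result.marginals[nid]))] in kept
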