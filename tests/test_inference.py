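"""Likelihood engine: closed forms, oracles, fitting, marginals, aggregation."""

import itertools

import numpy as np
import pytest

from spiculate import inference
from spiculate.inference import (
    aggregate_display,
    enumeration_loglik,
    fit_ml,
    marginal_ancestral,
    minimum_across_runs,
    pruning_loglik,
    transition_matrix,
    transition_matrices,
)
from spiculate.phylo_io import parse_tree
from spiculate.trait_model import (
    Component,
    build_model,
    kronecker_amalgamate,
)

from conftest import make_matrix, random_instance, random_rates, random_tree


def binary_er(q: float, name: str = "c") -> object:
    Q = np.array([[-q, q], [q, -q]])
    return kronecker_amalgamate([Component(name, ("0", "1"), Q, (name,))])


def binary_matrix(states: dict, char: str = "c"):
    from spiculate.phylo_io import CharacterMatrix

    return CharacterMatrix(
        taxa=list(states),
        characters=[char],
        state_spaces={char: ("0", "1")},
        observations={(t, char): frozenset(v) for t, v in states.items()},
    )


class TestTransitionMatrix:
    def test_identity_at_t0(self, rng):
        m = build_model("D", random_rates(rng, "D"))
        assert np.allclose(transition_matrix(m.Q, 0.0), np.eye(16), atol=1e-14)

    def test_closed_form_symmetric_binary(self):
        for q in (1e-3, 0.05, 0.5, 2.0):
            for t in (0.01, 0.1, 1.0, 10.0, 100.0):
                P = transition_matrix(np.array([[-q, q], [q, -q]]), t)
                expect = (1.0 + np.exp(-2 * q * t)) / 2.0
                assert P[0, 0] == pytest.approx(expect, abs=1e-12)
                assert P[0, 1] == pytest.approx(1 - expect, abs=1e-12)

    def test_stationary_limit(self):
        P = transition_matrix(np.array([[-0.5, 0.5], [0.5, -0.5]]), 1e6)
        assert np.allclose(P, 0.5, atol=1e-9)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(np.array([[-1.0, 1.0], [1.0, -1.0]]), -0.1)

    def test_eig_and_pade_agree_on_random_generators(self, rng):
        for _ in range(10):
            m = build_model(str(rng.choice(["A", "B", "C", "D"])),
                            random_rates(rng, "D"))
            t = float(rng.uniform(0.01, 50))
            P1 = transition_matrix(m.Q, t, method="eig")
            P2 = transition_matrix(m.Q, t, method="pade")
            assert np.max(np.abs(P1 - P2)) < 1e-10


class TestPruning:
    def test_two_tip_closed_form(self):
        tree = parse_tree("(A:1,B:1);")
        model = binary_er(0.5)
        data = binary_matrix({"A": "0", "B": "0"})
        P00 = (1 + np.exp(-1.0)) / 2
        P10 = 1 - P00
        expect = np.log(0.5 * (P00**2 + P10**2))
        assert pruning_loglik(tree, model, data) == pytest.approx(expect, abs=1e-12)

    def test_all_missing_gives_loglik_zero(self):
        tree = parse_tree("((A:1,B:1):1,C:2);")
        model = binary_er(0.3)
        data = binary_matrix({"A": "01", "B": "01", "C": "01"})
        assert pruning_loglik(tree, model, data) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_on_random_instances(self, rng):
        for _ in range(25):
            tree, model, matrix = random_instance(rng, max_tips=6)
            prior = str(rng.choice(["flat", "fitzjohn"]))
            ll_p = pruning_loglik(tree, model, matrix, root_prior=prior)
            ll_e = enumeration_loglik(tree, model, matrix, root_prior=prior)
            if np.isfinite(ll_p) or np.isfinite(ll_e):
                assert ll_p == pytest.approx(ll_e, abs=1e-10)

    def test_polytomy_likelihood_matches_enumeration(self, rng):
        tree = parse_tree("((A:1,B:1,C:1):1,D:2,E:2);")
        model = build_model("C", random_rates(rng, "C"))
        from conftest import random_observations

        matrix = make_matrix({t: random_observations(rng, model) for t in "ABCDE"})
        assert pruning_loglik(tree, model, matrix) == pytest.approx(
            enumeration_loglik(tree, model, matrix), abs=1e-10
        )

    def test_shuffled_taxon_order_same_likelihood(self, rng):
        tree, model, matrix = random_instance(rng, max_tips=6)
        ll1 = pruning_loglik(tree, model, matrix)
        shuffled = type(matrix)(
            taxa=list(reversed(matrix.taxa)),
            characters=matrix.characters,
            state_spaces=matrix.state_spaces,
            observations=matrix.observations,
        )
        assert pruning_loglik(tree, model, shuffled) == pytest.approx(ll1, abs=1e-12)

    def test_unmatched_tip_raises(self):
        tree = parse_tree("(A:1,Zed:1);")
        model = binary_er(0.5)
        data = binary_matrix({"A": "0", "B": "0"})
        with pytest.raises(Exception, match="Zed"):
            pruning_loglik(tree, model, data)

    def test_impossible_data_returns_minus_inf(self):
        # zero-length cherry with contradictory fixed tips under a frozen chain
        tree = parse_tree("(A:0,B:0);")
        model = binary_er(0.0)
        data = binary_matrix({"A": "0", "B": "1"})
        assert pruning_loglik(tree, model, data) == -np.inf

    def test_root_position_invariance_time_reversible(self):
        """For a symmetric chain the likelihood must not depend on where
        along the central edge the root is placed."""
        model = binary_er(0.23)
        data = binary_matrix({"A": "0", "B": "1", "C": "0"})
        lls = []
        for a in (0.25, 1.0, 2.5):
            tree = parse_tree(f"((A:1,B:1):{a},C:{3 - a});")
            lls.append(pruning_loglik(tree, model, data, root_prior="flat"))
        assert np.ptp(lls) < 1e-8

    def test_enumeration_refuses_large_instances(self, rng):
        tree = random_tree(rng, 12)
        model = binary_er(0.5)
        data = binary_matrix({f"T{i}": "0" for i in range(12)})
        with pytest.raises(ValueError, match="limited"):
            enumeration_loglik(tree, model, data)

    def test_single_tip_tree_is_root_prior_mass(self):
        tree = parse_tree("(A:1);")
        model = binary_er(0.4)
        data = binary_matrix({"A": "0"})
        ll = enumeration_loglik(tree, model, data)
        # root--A edge of 1 Myr under a flat root: 0.5*(P00 + P10) = 0.5
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)


class TestFitML:
    def test_same_seed_reproduces_bitwise(self, rng):
        tree = random_tree(rng, 16, bl_range=(1, 30))
        model = build_model("A", {"calcareous.gain": 0.02, "calcareous.loss": 0.02,
                                  "siliceous.gain": 0.02, "siliceous.loss": 0.02})
        from spiculate.simulate import simulate_traits

        ds = simulate_traits(tree, model, seed=7)
        f1 = fit_ml(tree, "A", ds.matrix, seed=11, n_restarts=4)
        f2 = fit_ml(tree, "A", ds.matrix, seed=11, n_restarts=4)
        assert f1.loglik == f2.loglik
        assert f1.params == f2.params

    def test_constant_character_drives_gain_to_lower_bound(self, rng):
        tree = random_tree(rng, 8, bl_range=(1, 10))
        cells = {t: {"calcareous": "0", "siliceous": "0"} for t in tree.tip_labels}
        data = make_matrix(cells)
        fit = fit_ml(
            tree,
            "A",
            data,
            free_params=["calcareous.gain", "siliceous.gain"],
            fixed_params={"calcareous.loss": 1e-3, "siliceous.loss": 1e-3},
            seed=5,
            n_restarts=4,
        )
        assert fit.params["calcareous.gain"] <= 2e-8
        assert fit.params["siliceous.gain"] <= 2e-8
        # no-change data: likelihood approaches the root-prior mass of the
        # all-absent state (slightly above, since a root with minerals can
        # still lose them)
        assert fit.loglik >= np.log(0.25) - 1e-6
        assert fit.loglik <= np.log(0.3)

    def test_recovers_rates_within_factor_two_mostly(self, rng):
        """Moderate-size simulation check; the full-size recovery study is
        exercised by the acceptance suite."""
        from spiculate.simulate import SimulationConfig, simulate_tree, simulate_traits

        truth = 0.05
        hits = 0
        n_rep = 6
        for r in range(n_rep):
            cfg = SimulationConfig(
                seed=100 + r, birth=0.3, death=0.05, n_extant=96, fossil_rate=0.0,
                model_id="A",
                rates={"calcareous.gain": truth, "calcareous.loss": truth,
                       "siliceous.gain": truth, "siliceous.loss": truth},
            )
            tree = simulate_tree(cfg)
            model = build_model("A", cfg.rates)
            ds = simulate_traits(tree, model, seed=100 + r)
            fit = fit_ml(tree, "A", ds.matrix, seed=100 + r, n_restarts=3)
            errs = [abs(np.log10(fit.params[k] / truth)) for k in fit.free_names]
            if np.median(errs) < np.log10(2):
                hits += 1
        assert hits >= n_rep - 2


def enumeration_marginals(tree, model, matrix, root_prior="flat"):
    """Brute-force joint enumeration oracle for node marginals."""
    from spiculate.inference import tip_partials, _root_prior_vector

    k = model.n_states
    tips = tip_partials(tree, model, matrix)
    P = transition_matrices(model.Q, tree.branch_lengths)
    interior = tree.internal_nodes
    pos = {v: j for j, v in enumerate(interior)}
    weights = {}
    total = 0.0
    D_root = np.zeros(k)
    for assign in itertools.product(range(k), repeat=len(interior)):
        w = 1.0
        for v in interior:
            sv = assign[pos[v]]
            for c in tree.children[v]:
                if tree.is_tip(c):
                    w *= float(P[c][sv] @ tips[c])
                else:
                    w *= float(P[c][sv, assign[pos[c]]])
        D_root[assign[pos[tree.root]]] += w
        weights[assign] = w
    pi = _root_prior_vector(root_prior, model, D_root)
    marg = np.zeros((len(interior), k))
    for assign, w in weights.items():
        w *= pi[assign[pos[tree.root]]]
        for v in interior:
            marg[pos[v], assign[pos[v]]] += w
    marg /= marg.sum(axis=1, keepdims=True)
    return {v: marg[pos[v]] for v in interior}


class TestMarginalAncestral:
    def test_matches_enumeration_on_model_c(self, rng):
        for trial in range(4):
            tree = random_tree(rng, 5, bl_range=(0.5, 40))
            model = build_model("C", random_rates(rng, "C"))
            from conftest import random_observations

            matrix = make_matrix(
                {t: random_observations(rng, model) for t in tree.tip_labels}
            )
            recon = marginal_ancestral(tree, model, {}, matrix)
            oracle = enumeration_marginals(tree, model, matrix)
            for v, expect in oracle.items():
                assert np.max(np.abs(recon.probs[v] - expect)) < 1e-9

    def test_rows_sum_to_one(self, rng):
        tree, model, matrix = random_instance(rng, max_tips=6)
        recon = marginal_ancestral(tree, model, {}, matrix)
        assert np.allclose(recon.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_length_branch_pins_node_to_tip_state(self):
        tree = parse_tree("((A:0,B:2):1,C:2);")
        model = binary_er(0.3)
        data = binary_matrix({"A": "1", "B": "0", "C": "0"})
        recon = marginal_ancestral(tree, model, {}, data)
        cherry = tree.parent[[i for i in tree.tips if tree.labels[i] == "A"][0]]
        assert recon.probs[cherry, 1] == pytest.approx(1.0, abs=1e-12)

    def test_frozen_chain_inherits_tip_state_everywhere(self):
        tree = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        model = binary_er(0.0)
        data = binary_matrix({t: "0" for t in "ABCD"})
        recon = marginal_ancestral(tree, model, {}, data)
        for v in tree.internal_nodes:
            assert recon.probs[v, 0] == pytest.approx(1.0, abs=1e-12)


class TestAggregateDisplay:
    def test_concentrated_state_maps_to_single_category(self, rng):
        model = build_model("D", random_rates(rng, "D"))
        tree = parse_tree("(A:1,B:1);")
        data = make_matrix(
            {
                "A": {"calcareous": "0", "siliceous": "1", "pathway": "1", "spicules": "1"},
                "B": {"calcareous": "0", "siliceous": "1", "pathway": "1", "spicules": "1"},
            }
        )
        # frozen chain so every node matches the tips exactly
        frozen = build_model(
            "D",
            {k: 0.0 for k in (
                "calcareous.gain", "calcareous.loss", "siliceous.gain",
                "siliceous.loss", "spicules.gain", "spicules.loss")},
        )
        recon = marginal_ancestral(tree, frozen, {}, data)
        agg = aggregate_display(recon)
        root_row = agg[agg["node"] == tree.root].iloc[0]
        assert root_row["siliceous"] == pytest.approx(1.0, abs=1e-12)
        assert root_row["spicules_present"] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_vector_gives_quarter_each(self, rng):
        model = build_model("A", random_rates(rng, "A"))
        tree = parse_tree("(A:1,B:1);")
        data = make_matrix({"A": {"calcareous": "?", "siliceous": "?"},
                            "B": {"calcareous": "?", "siliceous": "?"}})
        recon = marginal_ancestral(tree, model, {}, data)
        agg = aggregate_display(recon)
        root_row = agg[agg["node"] == tree.root].iloc[0]
        for cat in ("none", "siliceous", "calcareous", "biminerallic"):
            assert root_row[cat] == pytest.approx(0.25, abs=1e-9)

    def test_categories_partition_probability_mass(self, rng):
        for _ in range(5):
            tree, model, matrix = random_instance(rng, max_tips=5)
            recon = marginal_ancestral(tree, model, {}, matrix)
            agg = aggregate_display(recon)
            total = agg[["none", "siliceous", "calcareous", "biminerallic"]].sum(axis=1)
            assert np.allclose(total, 1.0, atol=1e-9)

    def test_minimum_across_runs_is_elementwise(self, rng):
        tree, model, matrix = random_instance(rng, max_tips=5)
        r1 = aggregate_display(marginal_ancestral(tree, model, {}, matrix))
        r2 = aggregate_display(
            marginal_ancestral(tree, model, {}, matrix, root_prior="fitzjohn")
        )
        mins = minimum_across_runs([r1, r2])
        for _, row in mins.iterrows():
            for cat in ("none", "siliceous"):
                a = float(r1.loc[r1["clade"] == row["clade"], cat].iloc[0])
                b = float(r2.loc[r2["clade"] == row["clade"], cat].iloc[0])
                assert row[cat] == pytest.approx(min(a, b), abs=1e-15)
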