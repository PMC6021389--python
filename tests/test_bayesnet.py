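"""Bayesian-network scores, constrained hill climbing, CPTs, likelihood,
inference and arc strength."""

import numpy as np
import pandas as pd
import pytest

from adbn.bayesnet import (
    BayesianNetworkModel,
    StructureConstraints,
    arc_strength,
    encode_data,
    family_score,
    fit_cpts,
    hill_climb,
    loglik_loss,
    network_score,
    predict_class,
    select_scoring_function,
)
from adbn.errors import ConstraintError, GraphError, InputError

from conftest import brute_force_posterior, random_network


def _enc(df, cats):
    return encode_data(df, cats)


class TestFamilyScore:
    """Worked closed-form values use a binary node observed (T, T, F)."""

    @pytest.fixture()
    def ttf(self):
        df = pd.DataFrame({"x": ["T", "T", "F"]})
        return _enc(df, {"x": ["F", "T"]}), {"x": 2}

    def test_k2_closed_form(self, ttf):
        enc, cards = ttf
        # (r-1)! * prod N_k! / (N+r-1)! = (1 * 2 * 1) / 4! = 2/24
        assert family_score(enc, "x", [], cards, "k2") == \
            pytest.approx(np.log(2 / 24), abs=1e-9)

    def test_bic_closed_form(self, ttf):
        enc, cards = ttf
        expected = 2 * np.log(2 / 3) + np.log(1 / 3) - 0.5 * np.log(3)
        assert family_score(enc, "x", [], cards, "bic") == \
            pytest.approx(expected, abs=1e-9)

    def test_counting_oracle_no_parents(self, ttf):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.choice(["a", "b", "c"], size=40)})
        cats = {"x": ["a", "b", "c"]}
        enc = _enc(df, cats)
        # independent counting route
        counts = np.array([(df["x"] == c).sum() for c in cats["x"]])
        from scipy.special import gammaln
        n = counts.sum()
        k2_direct = (gammaln(3) - gammaln(n + 3)
                     + gammaln(counts + 1).sum())
        assert family_score(enc, "x", [], {"x": 3}, "k2") == \
            pytest.approx(float(k2_direct), abs=1e-10)

    def test_bad_arguments(self, ttf):
        enc, cards = ttf
        with pytest.raises(InputError):
            family_score(enc, "x", [], cards, "aic")
        with pytest.raises(InputError):
            family_score(enc, "x", [], cards, "bde", ess=0.0)


class TestNetworkScore:
    def _random_discrete(self, rng, n=200):
        return pd.DataFrame({
            "a": rng.choice(["0", "1"], size=n),
            "b": rng.choice(["0", "1", "2"], size=n),
            "c": rng.choice(["0", "1"], size=n),
        })

    def test_empty_graph_is_sum_of_singletons(self):
        rng = np.random.default_rng(1)
        df = self._random_discrete(rng)
        total = network_score(set(), df, "bic")
        cats = {c: sorted(df[c].unique()) for c in df}
        enc = _enc(df, cats)
        cards = {c: len(v) for c, v in cats.items()}
        parts = sum(family_score(enc, v, [], cards, "bic", n_records=len(df))
                    for v in df.columns)
        assert total == pytest.approx(parts, abs=1e-9)

    def test_covered_edge_reversal_bde_score_equivalent(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            df = self._random_discrete(rng, n=100)[["a", "b"]]
            s_ab = network_score({("a", "b")}, df, "bde", ess=10.0)
            s_ba = network_score({("b", "a")}, df, "bde", ess=10.0)
            assert s_ab == pytest.approx(s_ba, abs=1e-9)

    def test_three_node_decomposability_oracle(self):
        rng = np.random.default_rng(3)
        df = self._random_discrete(rng)
        edges = {("a", "b"), ("b", "c")}
        cats = {c: sorted(df[c].unique()) for c in df}
        enc = _enc(df, cats)
        cards = {c: len(v) for c, v in cats.items()}
        for score in ("k2", "bde", "mbde", "bic"):
            direct = (
                family_score(enc, "a", [], cards, score, n_records=len(df))
                + family_score(enc, "b", ["a"], cards, score,
                               n_records=len(df))
                + family_score(enc, "c", ["b"], cards, score,
                               n_records=len(df))
            )
            assert network_score(edges, df, score) == \
                pytest.approx(direct, abs=1e-9)

    def test_cycle_rejected(self):
        rng = np.random.default_rng(4)
        df = self._random_discrete(rng)
        with pytest.raises(GraphError):
            network_score({("a", "b"), ("b", "a")}, df, "bic")


class TestHillClimb:
    def _dependent_pair(self, rng, n=2000):
        a = rng.choice(["0", "1"], size=n)
        flip = rng.random(n) < 0.1
        b = np.where(flip, np.where(a == "0", "1", "0"), a)
        return pd.DataFrame({"a": a, "b": b})

    def test_recovers_strong_dependence(self):
        rng = np.random.default_rng(5)
        df = self._dependent_pair(rng)
        m = hill_climb(df, score="bic")
        assert {frozenset(e) for e in m.edges} == {frozenset(("a", "b"))}

    def test_independent_columns_empty_graph(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "a": rng.choice(["0", "1"], size=2000),
            "b": rng.choice(["0", "1"], size=2000),
            "c": rng.choice(["0", "1", "2"], size=2000),
        })
        m = hill_climb(df, score="bic")
        assert m.edges == set()

    def test_all_forbidden_returns_required_graph(self):
        rng = np.random.default_rng(7)
        df = self._dependent_pair(rng, n=200)
        cons = StructureConstraints(
            required_edges={("a", "b")},
            forbidden_edges={("b", "a")},
        )
        # forbid everything else: only a->b exists, nothing else possible
        m = hill_climb(df, cons, score="bic")
        assert ("a", "b") in m.edges

    def test_tier_constraints_respected(self):
        rng = np.random.default_rng(8)
        df = self._dependent_pair(rng)
        cons = StructureConstraints(tier_order=[["b"], ["a"]])
        m = hill_climb(df, cons, score="bic")
        assert ("a", "b") not in m.edges  # a is in the later tier
        assert ("b", "a") in m.edges

    def test_inconsistent_constraints_rejected_before_search(self):
        with pytest.raises(ConstraintError):
            StructureConstraints(required_edges={("a", "b")},
                                 forbidden_edges={("a", "b")})
        with pytest.raises(ConstraintError):
            StructureConstraints(required_edges={("a", "b")},
                                 tier_order=[["b"], ["a"]])

    def test_score_of_result_not_less_than_start(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({
            c: rng.choice(["0", "1"], size=300) for c in "abcd"
        })
        m = hill_climb(df, score="bic")
        empty = network_score(set(), df, "bic")
        assert m.score_value >= empty - 1e-9


class TestFitCptsAndLoss:
    def test_empirical_and_laplace_rows(self):
        df = pd.DataFrame({"x": ["T", "T", "F"]})
        cats = {"x": ["F", "T"]}
        m0 = fit_cpts(set(), df, smoothing=0.0, categories=cats)
        np.testing.assert_allclose(m0.cpts["x"][0], [1 / 3, 2 / 3])
        m1 = fit_cpts(set(), df, smoothing=1.0, categories=cats)
        np.testing.assert_allclose(m1.cpts["x"][0], [2 / 5, 3 / 5])

    def test_unseen_parent_configuration_uniform(self):
        df = pd.DataFrame({"p": ["0", "0"], "c": ["a", "b"]})
        cats = {"p": ["0", "1"], "c": ["a", "b"]}
        m = fit_cpts({("p", "c")}, df, smoothing=0.0, categories=cats)
        np.testing.assert_allclose(m.cpts["c"][1], [0.5, 0.5])

    def test_uniform_single_node_loss_is_log2(self):
        df = pd.DataFrame({"x": ["a", "b", "a", "b"]})
        m = fit_cpts(set(), df, smoothing=0.0)
        assert loglik_loss(m, df) == pytest.approx(np.log(2))

    def test_mle_minimizes_loss_on_training_data(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "a": rng.choice(["0", "1"], size=100),
            "b": rng.choice(["0", "1"], size=100),
        })
        m = fit_cpts({("a", "b")}, df, smoothing=0.0)
        base = loglik_loss(m, df)
        for _ in range(20):
            perturbed = fit_cpts({("a", "b")}, df, smoothing=0.0)
            t = np.asarray(perturbed.cpts["b"], dtype=float).copy()
            t += rng.uniform(0, 0.2, size=t.shape)
            t /= t.sum(axis=1, keepdims=True)
            perturbed.cpts["b"] = t
            assert loglik_loss(perturbed, df) >= base - 1e-12

    def test_two_node_chain_hand_computed_loss(self):
        # P(a=0)=0.5; P(b=0|a=0)=1, P(b=0|a=1)=0.5 on the worked 4-row table
        df = pd.DataFrame({"a": ["0", "0", "1", "1"],
                           "b": ["0", "0", "0", "1"]})
        m = fit_cpts({("a", "b")}, df, smoothing=0.0)
        # record probabilities: 0.5*1, 0.5*1, 0.5*0.5, 0.5*0.5
        expected = -np.mean(np.log([0.5, 0.5, 0.25, 0.25]))
        assert loglik_loss(m, df) == pytest.approx(expected, abs=1e-12)


class TestScoreSelection:
    def test_chosen_attains_minimal_mean_loss(self, ground_truth_net):
        from adbn.simulate import sample_from_network

        df = sample_from_network(ground_truth_net, 400, seed=0)
        res = select_scoring_function(df, folds=3, seed=1)
        assert res.chosen in res.mean_losses
        assert res.mean_losses[res.chosen] == min(res.mean_losses.values())

    def test_deterministic(self, ground_truth_net):
        from adbn.simulate import sample_from_network

        df = sample_from_network(ground_truth_net, 200, seed=2)
        r1 = select_scoring_function(df, folds=3, seed=4)
        r2 = select_scoring_function(df, folds=3, seed=4)
        assert r1.mean_losses == r2.mean_losses and r1.chosen == r2.chosen


class TestPredictClass:
    def test_two_node_chain_posterior(self):
        net = BayesianNetworkModel(
            nodes=["A", "B"],
            categories={"A": ["0", "1"], "B": ["0", "1"]},
            edges={("A", "B")},
            cpts={"A": np.array([[0.7, 0.3]]),
                  "B": np.array([[0.8, 0.2], [0.1, 0.9]])},
            parent_order={"A": [], "B": ["A"]},
        )
        post = predict_class(net, {"B": "1"}, "A")
        assert post["1"] == pytest.approx(0.27 / 0.41, abs=1e-12)

    def test_no_evidence_gives_prior_marginal(self):
        net = BayesianNetworkModel(
            nodes=["A"], categories={"A": ["x", "y"]}, edges=set(),
            cpts={"A": np.array([[0.25, 0.75]])}, parent_order={"A": []},
        )
        post = predict_class(net, {}, "A")
        assert post == {"x": 0.25, "y": 0.75}

    def test_evidence_on_target_rejected(self):
        net = BayesianNetworkModel(
            nodes=["A"], categories={"A": ["x", "y"]}, edges=set(),
            cpts={"A": np.array([[0.5, 0.5]])}, parent_order={"A": []},
        )
        with pytest.raises(InputError):
            predict_class(net, {"A": "x"}, "A")

    def test_matches_enumeration_oracle_on_random_networks(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            net = random_network(rng, max_nodes=7)
            target = net.nodes[int(rng.integers(len(net.nodes)))]
            ev_nodes = [v for v in net.nodes
                        if v != target and rng.random() < 0.5]
            ev = {v: net.categories[v][
                int(rng.integers(len(net.categories[v])))]
                for v in ev_nodes}
            post = predict_class(net, ev, target)
            oracle = brute_force_posterior(net, ev, target)
            got = np.array([post[s] for s in net.categories[target]])
            np.testing.assert_allclose(got, oracle, atol=1e-10)


class TestArcStrength:
    def test_ci_test_flags_strong_dependence(self):
        rng = np.random.default_rng(14)
        n = 2000
        a = rng.choice(["0", "1"], size=n)
        b = np.where(rng.random(n) < 0.15,
                     np.where(a == "0", "1", "0"), a)
        df = pd.DataFrame({"a": a, "b": b})
        m = hill_climb(df, score="bic")
        m = fit_cpts(m, df)
        rep = arc_strength(m, df, method="ci_test")
        (_, stats_), = rep.arcs.items()
        assert stats_["p_value"] < 1e-3

    def test_score_delta_positive_for_learned_arc(self):
        rng = np.random.default_rng(15)
        n = 1500
        a = rng.choice(["0", "1"], size=n)
        b = np.where(rng.random(n) < 0.1, np.where(a == "0", "1", "0"), a)
        df = pd.DataFrame({"a": a, "b": b})
        m = fit_cpts(hill_climb(df, score="bic"), df)
        rep = arc_strength(m, df, method="score_delta")
        assert all(v["strength"] > 0 for v in rep.arcs.values())

    def test_bootstrap_on_forced_independent_edge_is_low(self):
        rng = np.random.default_rng(16)
        df = pd.DataFrame({
            "a": rng.choice(["0", "1"], size=400),
            "b": rng.choice(["0", "1"], size=400),
        })
        cons = StructureConstraints(required_edges=set())
        m = fit_cpts(hill_climb(df, cons, score="bic"), df)
        m.edges = {("a", "b")}   # force-report an arc the data do not support
        m.parent_order = {"a": [], "b": ["a"]}
        rep = arc_strength(m, df, method="bootstrap", replicates=40, seed=0,
                           constraints=cons)
        assert rep.arcs[("a", "b")]["strength"] <= 0.5

    def test_unknown_method_rejected(self):
        df = pd.DataFrame({"a": ["0", "1"]})
        m = fit_cpts(set(), df)
        with pytest.raises(InputError):
            arc_strength(m, df, method="magic")
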