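import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecodbn.dbn_core import (
    HIDDEN,
    CLGNodeParams,
    FittedModel,
    HiddenChainParams,
    NetworkStructure,
    NodeSpec,
    clg_logdensity,
    forward_filter,
    infer_hidden,
    joint_loglik_complete,
    predict_one_step,
    sample_model,
)

from conftest import enumerate_paths, make_table


class TestStructureValidation:
    def test_intra_cycle_rejected(self):
        nodes = (NodeSpec("a"), NodeSpec("b"))
        with pytest.raises(ValueError, match="cycle"):
            NetworkStructure(nodes=nodes, intra_edges=(("a", "b"), ("b", "a")))

    def test_hidden_cross_links_rejected(self):
        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("G", HIDDEN, 2))
        with pytest.raises(ValueError, match="self-link"):
            NetworkStructure(nodes=nodes, inter_edges=(("H", "G"),))

    def test_observed_to_hidden_rejected(self):
        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"))
        with pytest.raises(ValueError, match="hidden"):
            NetworkStructure(nodes=nodes, intra_edges=(("a", "H"),))

    def test_hidden_must_be_binary(self):
        with pytest.raises(ValueError, match="binary"):
            NodeSpec("H", HIDDEN, cardinality=3)


class TestCLGLogDensity:
    def test_standard_normal_at_mode(self):
        p = CLGNodeParams("y", (), (), (), mu=[0.0], W=np.zeros((1, 0)), sigma2=[1.0])
        assert clg_logdensity(0.0, [], 0, p) == pytest.approx(-0.9189385, abs=1e-6)

    def test_shifted_mode_through_regression(self):
        p = CLGNodeParams(
            "y", (("x", 1),), (), (), mu=[1.0], W=[[2.0]], sigma2=[1.0]
        )
        assert clg_logdensity(2.0, [0.5], 0, p) == pytest.approx(-0.9189385, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_normal_density(self, seed):
        rng = np.random.default_rng(seed)
        mu = rng.normal(size=2)
        W = rng.normal(size=(2, 3))
        s2 = rng.uniform(0.1, 2.0, size=2)
        p = CLGNodeParams(
            "y", tuple((f"x{i}", 1) for i in range(3)), ("H",), (2,),
            mu=mu, W=W, sigma2=s2,
        )
        x = rng.normal(size=3)
        y = rng.normal()
        q = int(rng.integers(2))
        expected = stats.norm.logpdf(y, loc=mu[q] + W[q] @ x, scale=math.sqrt(s2[q]))
        assert clg_logdensity(y, x, q, p) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = CLGNodeParams("y", (("x", 1),), (), (), mu=[0.0], W=[[1.0]], sigma2=[1.0])
        with pytest.raises(ValueError):
            clg_logdensity(0.0, [1.0, 2.0], 0, p)
        with pytest.raises(ValueError):
            clg_logdensity(0.0, [1.0], 5, p)


class TestCompleteLogLik:
    def test_no_parent_no_hidden_reduces_to_iid_normals(self):
        nodes = (NodeSpec("a"),)
        s = NetworkStructure(nodes=nodes)
        m = FittedModel(
            s,
            {"a": CLGNodeParams("a", (), (), (), mu=[0.3], W=np.zeros((1, 0)), sigma2=[2.0])},
            {},
        )
        df = pd.DataFrame({"a": [0.1, -0.5, 1.2]}, index=pd.Index(range(3), name="year"))
        data = make_table(df)
        expected = stats.norm.logpdf(df["a"], loc=0.3, scale=math.sqrt(2.0)).sum()
        assert joint_loglik_complete(m, data, {}) == pytest.approx(expected, abs=1e-10)

    def test_two_year_toy_hand_computed(self, toy_model):
        df = pd.DataFrame(
            {"a": [0.5, -0.2, 0.0], "b": [1.0, 0.3, 0.0]},
            index=pd.Index(range(3), name="year"),
        )
        data = make_table(df)
        path = {"H": [0, 1, 1]}
        # chain: log pi_0 + log A_01 + log A_11
        expected = math.log(0.6) + math.log(0.2) + math.log(0.7)
        # t=0 emissions are skipped (lag-1 parents unavailable)
        expected += stats.norm.logpdf(-0.2, loc=1 + 0.3 * 0.5, scale=math.sqrt(0.8))
        expected += stats.norm.logpdf(0.3, loc=-0.4 - 0.2 * 0.5, scale=math.sqrt(0.3))
        expected += stats.norm.logpdf(0.0, loc=1 + 0.3 * -0.2, scale=math.sqrt(0.8))
        expected += stats.norm.logpdf(0.0, loc=-0.4 - 0.2 * -0.2, scale=math.sqrt(0.3))
        got = joint_loglik_complete(toy_model, data, path)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_probability_transition_is_minus_inf(self, toy_model, toy_data):
        m = FittedModel(
            toy_model.structure,
            toy_model.node_params,
            {"H": HiddenChainParams(pi=[1.0, 0.0], A=[[1.0, 0.0], [0.0, 1.0]])},
        )
        assert joint_loglik_complete(m, toy_data, {"H": [0, 1, 1, 1, 1]}) == -np.inf


class TestForwardFilter:
    def test_loglik_matches_path_enumeration(self, toy_model, toy_data):
        brute, _ = enumerate_paths(toy_model, toy_data)
        _, ll, _ = forward_filter(toy_model, toy_data)
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_uninformative_emissions_leave_prior(self):
        # identical emissions in both states + uniform transitions: the
        # filtered posterior equals the initial distribution at every year
        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"))
        s = NetworkStructure(
            nodes=nodes, intra_edges=(("H", "a"),), inter_edges=(("H", "H"),)
        )
        m = FittedModel(
            s,
            {"a": CLGNodeParams("a", (), ("H",), (2,), mu=[0.0, 0.0], W=np.zeros((2, 0)), sigma2=[1.0, 1.0])},
            {"H": HiddenChainParams(pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]])},
        )
        df = pd.DataFrame({"a": [0.3, -1.0, 0.7]}, index=pd.Index(range(3), name="year"))
        marg, _, _ = forward_filter(m, make_table(df))
        assert np.allclose(marg["H"], 0.5)

    def test_all_missing_gives_zero_loglik_and_prior_chain(self, toy_model):
        df = pd.DataFrame(
            {"a": [np.nan] * 4, "b": [np.nan] * 4},
            index=pd.Index(range(4), name="year"),
        )
        marg, ll, _ = forward_filter(toy_model, make_table(df))
        assert ll == 0.0
        pi = np.array([0.6, 0.4])
        A = np.array([[0.8, 0.2], [0.3, 0.7]])
        expect = pi
        for t in range(4):
            assert np.allclose(marg["H"][t], expect, atol=1e-12)
            expect = expect @ A

    def test_matches_hmmlearn_on_pure_gaussian_hmm(self):
        # independent cross-check: no regression parents, so the model is a
        # plain Gaussian HMM that hmmlearn can score with fixed parameters
        from hmmlearn import hmm

        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"), NodeSpec("b"))
        s = NetworkStructure(
            nodes=nodes,
            intra_edges=(("H", "a"), ("H", "b")),
            inter_edges=(("H", "H"),),
        )
        mus = {"a": [-1.0, 2.0], "b": [0.5, -0.5]}
        s2s = {"a": [0.7, 1.3], "b": [0.4, 0.9]}
        m = FittedModel(
            s,
            {
                n: CLGNodeParams(n, (), ("H",), (2,), mu=mus[n], W=np.zeros((2, 0)), sigma2=s2s[n])
                for n in ("a", "b")
            },
            {"H": HiddenChainParams(pi=[0.3, 0.7], A=[[0.9, 0.1], [0.2, 0.8]])},
        )
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        df = pd.DataFrame(X, columns=["a", "b"], index=pd.Index(range(6), name="year"))
        _, ll, _ = forward_filter(m, make_table(df))
        ref = hmm.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = np.array([0.3, 0.7])
        ref.transmat_ = np.array([[0.9, 0.1], [0.2, 0.8]])
        ref.means_ = np.array([[-1.0, 0.5], [2.0, -0.5]])
        ref.covars_ = np.array([[0.7, 0.4], [1.3, 0.9]])
        assert ll == pytest.approx(ref.score(X), abs=1e-8)


class TestSmoothing:
    def test_matches_enumeration_posterior(self, toy_model, toy_data):
        _, expected = enumerate_paths(toy_model, toy_data)
        post = infer_hidden(toy_model, toy_data)["H"]
        assert np.allclose(post, expected, atol=1e-8)

    def test_posteriors_are_distributions(self, toy_model, toy_data):
        post = infer_hidden(toy_model, toy_data)["H"]
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_chain_forces_path(self, toy_model, toy_data):
        m = FittedModel(
            toy_model.structure,
            toy_model.node_params,
            {"H": HiddenChainParams(pi=[1.0, 0.0], A=[[1.0, 0.0], [0.0, 1.0]])},
        )
        post = infer_hidden(m, toy_data)["H"]
        assert np.allclose(post[:, 0], 1.0)

    def test_smoothed_equals_filtered_at_final_year(self, toy_model, toy_data):
        filt, _, _ = forward_filter(toy_model, toy_data)
        post = infer_hidden(toy_model, toy_data)["H"]
        assert np.allclose(post[-1], filt["H"][-1], atol=1e-10)


class TestPredictOneStep:
    def test_pure_linear_case_is_exact(self):
        nodes = (NodeSpec("x"), NodeSpec("y"))
        s = NetworkStructure(nodes=nodes, inter_edges=(("x", "x"), ("x", "y")))
        m = FittedModel(
            s,
            {
                "x": CLGNodeParams("x", (("x", 1),), (), (), mu=[0.1], W=[[0.8]], sigma2=[1.0]),
                "y": CLGNodeParams("y", (("x", 1),), (), (), mu=[0.5], W=[[2.0]], sigma2=[1.0]),
            },
            {},
        )
        pred = predict_one_step(m, {"x": 0.25, "y": 9.9})
        assert pred["y"][0] == pytest.approx(0.5 + 2.0 * 0.25, abs=1e-12)
        assert pred["x"][0] == pytest.approx(0.1 + 0.8 * 0.25, abs=1e-12)

    def test_symmetric_mixture_moments(self):
        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"))
        s = NetworkStructure(
            nodes=nodes, intra_edges=(("H", "a"),), inter_edges=(("H", "H"),)
        )
        m = FittedModel(
            s,
            {"a": CLGNodeParams("a", (), ("H",), (2,), mu=[-1.0, 1.0], W=np.zeros((2, 0)), sigma2=[0.5, 0.5])},
            {"H": HiddenChainParams(pi=[0.5, 0.5], A=np.eye(2))},
        )
        pred = predict_one_step(m, {}, {"H": np.array([0.5, 0.5])})
        assert pred["a"][0] == pytest.approx(0.0, abs=1e-12)
        # law of total variance: sigma2 + spread of the two means
        assert pred["a"][1] == pytest.approx(0.5 + 1.0, abs=1e-12)

    def test_matches_monte_carlo(self, toy_model):
        rng = np.random.default_rng(11)
        prior = {"H": np.array([0.5, 0.5])}
        ev = {"a": 0.7, "b": -0.3}
        pred = predict_one_step(toy_model, ev, prior)
        N = 200_000
        hs = rng.choice(2, p=[0.5, 0.5], size=N)
        stay = np.array([0.8, 0.7])
        ht = np.where(rng.random(N) < stay[hs], hs, 1 - hs)
        mu = np.where(ht == 0, -1 + 0.5 * 0.7, 1 + 0.3 * 0.7)
        sd = np.where(ht == 0, math.sqrt(0.5), math.sqrt(0.8))
        a = mu + sd * rng.normal(size=N)
        assert pred["a"][0] == pytest.approx(a.mean(), abs=4 * a.std() / math.sqrt(N))
        assert pred["a"][1] == pytest.approx(a.var(), rel=0.02)


class TestSampling:
    def test_same_seed_reproduces(self, toy_model):
        t1, h1 = sample_model(toy_model, 10, seed=42)
        t2, h2 = sample_model(toy_model, 10, seed=42)
        assert t1.data.equals(t2.data)
        assert np.array_equal(h1["H"], h2["H"])

    def test_identity_transitions_freeze_hidden_state(self, toy_model):
        m = FittedModel(
            toy_model.structure,
            toy_model.node_params,
            {"H": HiddenChainParams(pi=[0.5, 0.5], A=np.eye(2))},
        )
        for seed in range(5):
            _, h = sample_model(m, 20, seed=seed)
            assert len(np.unique(h["H"])) == 1

    def test_no_parent_node_mean_follows_mixture(self):
        nodes = (NodeSpec("H", HIDDEN, 2), NodeSpec("a"))
        s = NetworkStructure(
            nodes=nodes, intra_edges=(("H", "a"),), inter_edges=(("H", "H"),)
        )
        m = FittedModel(
            s,
            {"a": CLGNodeParams("a", (), ("H",), (2,), mu=[-2.0, 1.0], W=np.zeros((2, 0)), sigma2=[0.3, 0.3])},
            {"H": HiddenChainParams(pi=[0.25, 0.75], A=[[0.25, 0.75], [0.25, 0.75]])},
        )
        # stationary distribution equals (0.25, 0.75) by construction
        t, _ = sample_model(m, 50_000, seed=7)
        expect = 0.25 * -2.0 + 0.75 * 1.0
        se = t.data["a"].std() / math.sqrt(len(t.data))
        assert t.data["a"].mean() == pytest.approx(expect, abs=4 * se)


def test_model_json_roundtrip(toy_model, tmp_path):
    p = tmp_path / "m.json"
    toy_model.to_json(p)
    back = FittedModel.from_json(p)
    assert back.structure == toy_model.structure
    for n in ("a", "b"):
        assert np.allclose(back.node_params[n].mu, toy_model.node_params[n].mu)
        assert np.allclose(back.node_params[n].W, toy_model.node_params[n].W)
    assert np.allclose(back.chain_params["H"].A, toy_model.chain_params["H"].A)
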