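"""Estimation core: likelihood oracles, gradients, decoding, inference."""

import itertools
import json

import numpy as np
import pytest
from scipy import stats

import switchssa as sw
from switchssa._core import viterbi
from switchssa.msclogit import (
    _Layout,
    _design,
    _nll_grad,
    choice_log_probabilities,
    fit_to_dict,
    log_likelihood,
    save_fit_json,
)


def _random_choice_data(rng, S, M, pZ=1, angle_model="von_mises"):
    lengths = rng.gamma(2.0, 1.0, size=(S, M + 1)) + 0.1
    angles = rng.uniform(-np.pi, np.pi, size=(S, M + 1))
    if angle_model == "von_mises":
        C = np.stack(
            [np.column_stack([np.log(l), -l, np.cos(a)]) for l, a in zip(lengths, angles)]
        )
    else:
        C = np.stack([np.column_stack([np.log(l), -l]) for l in lengths])
    Z = rng.normal(size=(S, M + 1, pZ))
    return sw.CaseControlData(
        C=C,
        Z=Z,
        endpoints=np.zeros((S, M + 1, 2)),
        t_index=np.arange(1, S + 1),
        proposal=sw.ProposalDistribution(2.0, 1.0),
        angle_model=angle_model,
    )


def _random_model(rng, N, pZ=1):
    states = [
        sw.StateParameters(
            shape=rng.uniform(0.8, 3.0),
            rate=rng.uniform(0.3, 1.5),
            concentration=rng.uniform(-1.0, 1.5),
            beta=rng.uniform(-1.5, 1.5, size=pZ),
        )
        for _ in range(N)
    ]
    tpm = rng.uniform(0.2, 1.0, size=(N, N)) + np.eye(N) * 3
    tpm /= tpm.sum(axis=1, keepdims=True)
    return sw.HMMiSSAModel(tpm=tpm, states=states)


def _enumerate_loglik_and_argmax(model, data):
    """Brute force over all state sequences (the independent oracle)."""
    logp = choice_log_probabilities(data, model)
    S, N = logp.shape
    total = -np.inf
    best = (-np.inf, None)
    for seq in itertools.product(range(N), repeat=S):
        lp = np.log(model.delta[seq[0]]) + logp[0, seq[0]]
        for t in range(1, S):
            lp += np.log(model.tpm[seq[t - 1], seq[t]]) + logp[t, seq[t]]
        total = np.logaddexp(total, lp)
        if lp > best[0]:
            best = (lp, seq)
    return total, np.asarray(best[1])


class TestChoiceProbabilities:
    def test_identical_rows_give_uniform_choice(self):
        rng = np.random.default_rng(0)
        M = 4
        row_c = np.array([0.3, -1.4, 0.2])
        C = np.tile(row_c, (2, M + 1, 1))
        Z = np.tile(rng.normal(), (2, M + 1, 1))
        data = sw.CaseControlData(
            C=C, Z=Z, endpoints=np.zeros((2, M + 1, 2)), t_index=np.array([1, 2]),
            proposal=sw.ProposalDistribution(2.0, 1.0),
        )
        model = _random_model(np.random.default_rng(1), N=2)
        logp = choice_log_probabilities(data, model)
        assert np.allclose(logp, np.log(1.0 / (M + 1)))

    def test_zero_coefficients_give_uniform_choice_for_any_covariates(self):
        rng = np.random.default_rng(2)
        data = _random_choice_data(rng, S=5, M=7)
        # state equal to the proposal and beta = 0 -> all weights are zero
        model = sw.HMMiSSAModel(
            tpm=[[1.0]], states=[sw.StateParameters(2.0, 1.0, 0.0, [0.0])]
        )
        logp = choice_log_probabilities(data, model)
        assert np.allclose(logp, -np.log(8.0))

    def test_two_row_logistic_arithmetic(self):
        # M=1 with weight difference 0.5 -> p = logistic(0.5)
        C = np.zeros((1, 2, 3))
        Z = np.array([[[0.25], [0.0]]])  # beta=2 -> w0 - w1 = 0.5
        data = sw.CaseControlData(
            C=C + [[0.0, -1.0, 0.0], [0.0, -1.0, 0.0]],
            Z=Z, endpoints=np.zeros((1, 2, 2)), t_index=np.array([1]),
            proposal=sw.ProposalDistribution(1.0, 1.0),
        )
        model = sw.HMMiSSAModel(
            tpm=[[1.0]], states=[sw.StateParameters(1.0, 1.0, 0.0, [2.0])]
        )
        p = float(np.exp(choice_log_probabilities(data, model)[0, 0]))
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-0.5)), abs=1e-12)

    def test_choice_probabilities_normalise(self, toy_choice_data):
        model = _random_model(np.random.default_rng(3), N=2)
        # independent softmax recomputation per state and set
        logp = choice_log_probabilities(toy_choice_data, model)
        for i, st in enumerate(model.states):
            w = sw.log_step_weight(
                toy_choice_data.C.reshape(-1, 3),
                toy_choice_data.Z.reshape(-1, 1),
                st,
                proposal=toy_choice_data.proposal,
            ).reshape(4, 4)
            p = np.exp(w - stats.logistic().logcdf(0) * 0)  # plain exponent
            p /= p.sum(axis=1, keepdims=True)
            assert np.allclose(np.exp(logp[:, i]), p[:, 0], atol=1e-12)
            assert np.allclose(p.sum(axis=1), 1.0)


class TestForwardAndViterbiOracles:
    @pytest.mark.parametrize("N,S,seed", [(2, 4, 0), (2, 6, 1), (3, 5, 2), (1, 6, 3)])
    def test_forward_equals_enumeration(self, N, S, seed):
        rng = np.random.default_rng(seed)
        data = _random_choice_data(rng, S=S, M=3)
        model = _random_model(rng, N=N)
        oracle, _ = _enumerate_loglik_and_argmax(model, data)
        assert log_likelihood(model, data) == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("N,S,seed", [(2, 4, 4), (2, 6, 5), (3, 5, 6)])
    def test_viterbi_equals_enumeration_argmax(self, N, S, seed):
        rng = np.random.default_rng(seed)
        data = _random_choice_data(rng, S=S, M=3)
        model = _random_model(rng, N=N)
        _, best_seq = _enumerate_loglik_and_argmax(model, data)
        logp = choice_log_probabilities(data, model)
        path = viterbi(logp, model.tpm, model.delta, data.segments)
        assert np.array_equal(path, best_seq)

    def test_viterbi_ties_break_toward_lower_state_index(self):
        logp = np.zeros((4, 3))
        tpm = np.full((3, 3), 1.0 / 3.0)
        delta = np.full(3, 1.0 / 3.0)
        assert np.array_equal(viterbi(logp, tpm, delta, [(0, 4)]), np.zeros(4, dtype=int))

    def test_bursts_multiply_independent_forward_passes(self):
        rng = np.random.default_rng(7)
        data = _random_choice_data(rng, S=6, M=3)
        model = _random_model(rng, N=2)
        joint = log_likelihood(model, data)
        data.segments = [(0, 3), (3, 6)]
        split = log_likelihood(model, data)
        assert split != pytest.approx(joint)
        # the split likelihood equals the sum over separately enumerated bursts
        front = _random_choice_data(np.random.default_rng(7), S=6, M=3)
        front.segments = [(0, 3), (3, 6)]
        tot = 0.0
        for a, b in front.segments:
            sub = sw.CaseControlData(
                C=data.C[a:b], Z=data.Z[a:b], endpoints=data.endpoints[a:b],
                t_index=data.t_index[a:b], proposal=data.proposal,
            )
            tot += _enumerate_loglik_and_argmax(model, sub)[0]
        assert split == pytest.approx(tot, abs=1e-10)


class TestLikelihoodInvariances:
    def test_label_permutation_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(8)
        data = _random_choice_data(rng, S=8, M=4)
        model = _random_model(rng, N=3)
        perm = [2, 0, 1]
        permuted = sw.HMMiSSAModel(
            tpm=model.tpm[np.ix_(perm, perm)],
            states=[model.states[j] for j in perm],
            delta=model.delta[perm],
        )
        assert log_likelihood(permuted, data) == pytest.approx(
            log_likelihood(model, data), abs=1e-10
        )

    def test_two_identical_states_equal_single_state(self):
        rng = np.random.default_rng(9)
        data = _random_choice_data(rng, S=10, M=4)
        st = sw.StateParameters(2.2, 0.7, 0.5, [1.0])
        one = sw.HMMiSSAModel(tpm=[[1.0]], states=[st])
        two = sw.HMMiSSAModel(tpm=[[0.7, 0.3], [0.2, 0.8]], states=[st, st])
        assert log_likelihood(two, data) == pytest.approx(
            log_likelihood(one, data), abs=1e-10
        )

    def test_single_state_likelihood_is_sum_of_choice_logprobs(self):
        rng = np.random.default_rng(10)
        data = _random_choice_data(rng, S=12, M=5)
        model = _random_model(rng, N=1)
        logp = choice_log_probabilities(data, model)
        assert log_likelihood(model, data) == pytest.approx(float(logp.sum()), abs=1e-10)


class TestGradient:
    @pytest.mark.parametrize(
        "N,angle_model,pZ",
        [(1, "von_mises", 1), (2, "von_mises", 1), (2, "uniform", 1), (2, "von_mises", 0), (3, "von_mises", 2)],
    )
    def test_analytic_gradient_matches_finite_differences(self, N, angle_model, pZ):
        rng = np.random.default_rng(11)
        data = _random_choice_data(rng, S=15, M=4, pZ=max(pZ, 1), angle_model=angle_model)
        data.segments = [(0, 9), (9, 15)]
        layout = _Layout(N, angle_model == "von_mises", pZ)
        X = _design(data, layout)
        x0 = rng.normal(scale=0.4, size=layout.n_free)
        _, g = _nll_grad(x0, layout, X, data)
        for j in range(x0.size):
            h = 1e-6 * (1 + abs(x0[j]))
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            fd = (_nll_grad(xp, layout, X, data)[0] - _nll_grad(xm, layout, X, data)[0]) / (2 * h)
            assert g[j] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestFitting:
    def test_single_state_fit_matches_independent_clogit(self, scenario1_data):
        cc = scenario1_data["cc"]
        est = sw.HMMiSSA(n_states=1, n_starts=2, seed=0).fit(cc)
        st = est.model_.states[0]
        ours = np.array(
            [
                st.shape - cc.proposal.shape0,
                st.rate - cc.proposal.rate0,
                st.concentration,
                st.beta[0],
            ]
        )
        from statsmodels.discrete.conditional_models import ConditionalLogit

        S, Mp1, _ = cc.C.shape
        X = np.concatenate([cc.C, cc.Z], axis=-1).reshape(S * Mp1, 4)
        y = np.zeros(S * Mp1)
        y[::Mp1] = 1.0
        groups = np.repeat(np.arange(S), Mp1)
        ref = ConditionalLogit(y, X, groups=groups).fit(
            disp=0, method="newton", tol=1e-10
        )
        assert np.allclose(ours, ref.params, atol=1e-4)

    def test_fit_is_deterministic_given_seed(self, toy_choice_data):
        a = sw.HMMiSSA(n_states=1, n_starts=2, seed=3).fit(toy_choice_data)
        b = sw.HMMiSSA(n_states=1, n_starts=2, seed=3).fit(toy_choice_data)
        assert np.array_equal(a.working_, b.working_)

    def test_permuting_fitted_state_labels_keeps_likelihood(self, scenario1_data):
        est = sw.HMMiSSA(n_states=2, n_starts=3, seed=1).fit(scenario1_data["cc"])
        m = est.model_
        perm = [1, 0]
        swapped = sw.HMMiSSAModel(
            tpm=m.tpm[np.ix_(perm, perm)],
            states=[m.states[1], m.states[0]],
            angle_model=m.angle_model,
        )
        assert log_likelihood(swapped, scenario1_data["cc"]) == pytest.approx(
            est.loglik_, abs=1e-8
        )

    def test_information_criteria_and_parameter_count(self, scenario1_data):
        est = sw.HMMiSSA(n_states=2, n_starts=3, seed=1).fit(scenario1_data["cc"])
        # N * dim(theta) + N * dim(beta) + N (N - 1): 2*3 + 2*1 + 2 = 10
        assert est.n_parameters_ == 10
        aic, bic = sw.information_criteria(est)
        assert aic == pytest.approx(-2 * est.loglik_ + 2 * 10)
        assert bic == pytest.approx(-2 * est.loglik_ + 10 * np.log(est.n_obs_))
        nosel = sw.HMMiSSA(
            n_states=2, include_selection=False, n_starts=3, seed=1
        ).fit(scenario1_data["cc"])
        assert nosel.n_parameters_ == 8


class TestWaldInference:
    def test_duplicated_data_shrinks_standard_errors_by_sqrt2(self, toy_choice_data):
        rng = np.random.default_rng(20)
        data = _random_choice_data(rng, S=60, M=6)
        est1 = sw.HMMiSSA(n_states=1, n_starts=2, seed=0).fit(data)
        doubled = sw.CaseControlData(
            C=np.concatenate([data.C, data.C]),
            Z=np.concatenate([data.Z, data.Z]),
            endpoints=np.concatenate([data.endpoints, data.endpoints]),
            t_index=np.concatenate([data.t_index, data.t_index + 100]),
            proposal=data.proposal,
            segments=[(0, 60), (60, 120)],
        )
        est2 = sw.HMMiSSA(n_states=1, n_starts=2, seed=0).fit(doubled)
        se1 = sw.wald_inference(est1)["se"].to_numpy()
        se2 = sw.wald_inference(est2)["se"].to_numpy()
        assert np.allclose(se2, se1 / np.sqrt(2.0), rtol=0.02)

    def test_p_values_follow_the_normal_approximation(self, scenario1_data):
        est = sw.HMMiSSA(n_states=1, n_starts=2, seed=0).fit(scenario1_data["cc"])
        tab = sw.wald_inference(est)
        row = tab[tab["parameter"] == "beta1"].iloc[0]
        assert row["z"] == pytest.approx(row["estimate"] / row["se"])
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["z"])))
        # movement parameters carry no p-values by default
        assert tab[tab["parameter"] == "shape"]["p"].isna().all()


class TestSerialization:
    def test_json_roundtrip(self, tmp_path, scenario1_data):
        est = sw.HMMiSSA(n_states=1, n_starts=2, seed=0).fit(scenario1_data["cc"])
        path = tmp_path / "fit.json"
        save_fit_json(est, path)
        loaded = json.loads(path.read_text())
        assert loaded["n_states"] == 1
        assert loaded["loglik"] == pytest.approx(est.loglik_)
        assert loaded["states"][0]["shape"] == pytest.approx(est.model_.states[0].shape)
        assert fit_to_dict(est)["aic"] == pytest.approx(est.aic_)
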