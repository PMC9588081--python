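import numpy as np
import pytest

from _oracles import classic_hmm_posteriors, enumerate_posteriors, random_model
from samgep.io_data import LabelSeries
from samgep.mgp import (
    GPParams,
    MarkovParams,
    MGPModel,
    conditional_covariance,
    em_one_step,
    emission_logdensity,
    fit_gp,
    fit_markov,
    fit_supervised,
    forward_backward,
    gp_mean,
    init_prob,
    model_from_dict,
    model_to_dict,
    predict,
    trans_prob,
    tune_r,
)
from samgep.simulate import simulate_mgp_series
from samgep.weights import EmbeddingSeries


def _gp(m=2, **kw):
    base = dict(
        mu0=np.zeros(m), mu1=np.zeros(m), mu2=np.zeros(m), mu3=np.zeros(m),
        mu4=np.zeros(m), mu5=np.zeros(m), muH=np.zeros(m), muYH=np.zeros(m),
        sigma=np.ones(m), alpha=np.zeros(m), tau=np.zeros(m),
        rho=np.eye(m), r=0.0,
    )
    base.update(kw)
    return GPParams(**base)


def _markov(**kw):
    base = dict(lambda_init=0.0, lambda_H0=0.0, lambda_0=0.0, lambda_1=0.0,
                lambda_2=0.0, lambda_3=0.0, lambda_H=0.0)
    base.update(kw)
    return MarkovParams(**base)


class TestChainPrimitives:
    def test_init_prob_expit_forms(self):
        assert init_prob(0.0, _markov()) == 0.5
        assert init_prob(0.0, _markov(lambda_init=np.log(3))) == pytest.approx(0.75)
        assert init_prob(0.5, _markov(lambda_init=1.0, lambda_H0=-2.0)) == pytest.approx(0.5)

    def test_trans_prob_selects_one_intercept(self):
        mk = _markov(lambda_0=-1.0, lambda_2=0.1)
        assert trans_prob(0, 10, 0.0, mk) == pytest.approx(0.5)  # -1 + 1 = 0
        assert trans_prob(1, 10, 0.0, mk) == pytest.approx(1 / (1 + np.exp(-1.0)))

    def test_trans_prob_absorbing_limit_and_t_guard(self):
        mk = _markov(lambda_1=50.0)
        assert trans_prob(1, 5, 0.0, mk) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            trans_prob(0, 1, 0.0, mk)


class TestGPMean:
    def test_state_selects_baseline_at_t1(self, rng):
        gp = _gp(m=3, mu0=rng.normal(size=3), mu1=rng.normal(size=3))
        np.testing.assert_allclose(gp_mean(0, 0.0, 1, gp), gp.mu0)
        np.testing.assert_allclose(gp_mean(1, 0.0, 1, gp), gp.mu1)

    def test_generic_eight_term_sum(self, rng):
        vs = {k: rng.normal(size=2) for k in
              ("mu0", "mu1", "mu2", "mu3", "mu4", "mu5", "muH", "muYH")}
        gp = _gp(m=2, **vs)
        y, H, t = 1, 2.0, 3
        expected = (vs["mu1"] + vs["muH"] * H + vs["muYH"] * H
                    + vs["mu2"] * t + vs["mu3"] * np.log(t)
                    + vs["mu4"] * t + vs["mu5"] * np.log(t))
        np.testing.assert_allclose(gp_mean(y, H, t, gp), expected)


class TestEmission:
    def test_r_zero_is_memoryless(self, rng):
        gp = _gp(m=2, sigma=np.array([1.0, 2.0]), tau=np.array([0.5, 0.5]), r=0.0)
        x, xp = rng.normal(size=2), rng.normal(size=2)
        cond = emission_logdensity(x, xp, 1, 0, 0.3, 4, gp)
        marg = emission_logdensity(x, None, 1, None, 0.3, 1, gp)
        # same state/time mean here (all mu zero), so densities coincide
        assert cond == pytest.approx(marg)

    def test_standard_normal_at_origin(self):
        gp = _gp(m=1)
        ld = emission_logdensity(np.zeros(1), None, 0, None, 0.0, 1, gp)
        assert ld == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_ar_deflated_conditional_covariance(self):
        gp = _gp(m=2, tau=np.array([0.5, 0.5]), r=1.0)
        np.testing.assert_allclose(
            conditional_covariance(0.0, gp), np.diag([0.75, 0.75])
        )
        # matches a long-hand bivariate normal evaluation
        x = np.array([0.3, -0.2])
        xp = np.array([1.0, 0.5])
        shift = 0.5 * xp
        resid = x - shift
        expected = (-np.log(2 * np.pi) - 0.5 * np.log(0.75 ** 2)
                    - 0.5 * (resid ** 2 / 0.75).sum())
        got = emission_logdensity(x, xp, 0, 0, 0.0, 2, gp)
        assert got == pytest.approx(expected)


class TestForwardBackward:
    def test_single_bin_is_bayes_rule(self, rng):
        model = random_model(rng, m=2)
        x = rng.normal(size=(1, 2))
        H = 0.4
        pi, F, ll = forward_backward(x, H, model)
        p1 = init_prob(H, model.markov)
        phi0 = np.exp(emission_logdensity(x[0], None, 0, None, H, 1, model.gp))
        phi1 = np.exp(emission_logdensity(x[0], None, 1, None, H, 1, model.gp))
        expected = p1 * phi1 / (p1 * phi1 + (1 - p1) * phi0)
        assert pi[0] == pytest.approx(expected)
        assert F[0] == pytest.approx(expected)

    def test_uninformative_emission_returns_prior_marginals(self):
        # identical state means: posteriors reduce to the chain's priors
        mk = _markov(lambda_init=-1.0, lambda_0=-0.5, lambda_1=1.0)
        gp = _gp(m=2)
        model = MGPModel(markov=mk, gp=gp)
        T, H = 5, 0.0
        x = np.random.default_rng(1).normal(size=(T, 2))
        pi, _, _ = forward_backward(x, H, model)
        prior = np.empty((T, 2))
        p1 = init_prob(H, mk)
        prior[0] = [1 - p1, p1]
        for t in range(2, T + 1):
            p01 = trans_prob(0, t, H, mk)
            p11 = trans_prob(1, t, H, mk)
            prior[t - 1, 1] = prior[t - 2, 0] * p01 + prior[t - 2, 1] * p11
            prior[t - 1, 0] = 1 - prior[t - 1, 1]
        np.testing.assert_allclose(pi, prior[:, 1], atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_on_random_models(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 4))
        T = int(rng.integers(2, 7))
        model = random_model(rng, m=m)
        H = float(rng.uniform(0, 1.5))
        x = rng.normal(0, 1.5, size=(T, m))
        pi, F, ll = forward_backward(x, H, model)
        marg, zero_path, ll_ref = enumerate_posteriors(x, H, model)
        assert ll == pytest.approx(ll_ref, abs=1e-8)
        np.testing.assert_allclose(pi, marg, atol=1e-8)
        np.testing.assert_allclose(1 - F, zero_path, atol=1e-8)

    def test_nan_input_rejected(self, rng):
        model = random_model(rng, m=1)
        with pytest.raises(ValueError, match="NaN"):
            forward_backward(np.array([[np.nan]]), 0.0, model)

    def test_cdf_nondecreasing(self, rng):
        model = random_model(rng, m=2)
        x = rng.normal(size=(10, 2))
        _, F, _ = forward_backward(x, 0.5, model)
        assert (np.diff(F) >= -1e-12).all()


class TestFitMarkov:
    def test_hard_equals_soft_with_degenerate_weights(self, rng):
        ys, Hs = {}, {}
        for i in range(40):
            ys[i] = (rng.random(10) < 0.3).astype(float)
            Hs[i] = float(rng.uniform(0, 2))
        hard = fit_markov({k: v for k, v in ys.items()}, Hs)
        soft = fit_markov(
            {k: ys[k] for k in list(ys)[:20]}, Hs,
            posteriors={k: ys[k] for k in list(ys)[20:]},  # 0/1 posteriors
        )
        for name in ("lambda_init", "lambda_0", "lambda_1", "lambda_H"):
            assert getattr(soft, name) == pytest.approx(getattr(hard, name), abs=1e-5)

    def test_all_one_class_rejected(self):
        with pytest.raises(ValueError):
            fit_markov({0: np.zeros(5), 1: np.zeros(5)}, {0: 0.1, 1: 0.2})


class TestFitGP:
    def test_constant_H_zeroes_alpha(self, rng):
        X = {i: rng.normal(size=(6, 2)) for i in range(10)}
        H = {i: 1.0 for i in range(10)}
        ys = {i: (rng.random(6) < 0.5).astype(float) for i in range(10)}
        ys[0][:] = [1, 1, 0, 0, 1, 0]  # both classes guaranteed
        gp = fit_gp(EmbeddingSeries(X=X, H=H), ys)
        np.testing.assert_array_equal(gp.alpha, np.zeros(2))

    def test_zero_residual_variance_flagged(self):
        # X exactly equal to the design prediction -> degenerate emission
        X = {0: np.tile([1.0, 2.0], (5, 1))}
        ys = {0: np.array([0, 1, 0, 1, 0], dtype=float)}
        with pytest.raises(ValueError, match="degenerate"):
            fit_gp(EmbeddingSeries(X=X, H={0: 0.5}), ys)

    def test_recovers_known_parameters(self):
        mk = _markov(lambda_init=-1.0, lambda_0=-1.5, lambda_1=1.0)
        gp_true = _gp(
            m=3,
            mu0=np.array([0.0, 0.5, -0.5]), mu1=np.array([1.0, -0.2, 0.8]),
            muH=np.array([0.3, 0.0, -0.3]),
            sigma=np.array([0.8, 1.0, 1.2]), alpha=np.array([0.2, -0.1, 0.0]),
            tau=np.array([0.5, 0.3, 0.6]), r=1.0,
            rho=np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]]),
        )
        series, labels = simulate_mgp_series(mk, gp_true, 500, mean_T=25, seed=4)
        gp_hat = fit_gp(series, labels.y)
        np.testing.assert_allclose(gp_hat.sigma, gp_true.sigma, rtol=0.10)
        np.testing.assert_allclose(gp_hat.tau, gp_true.tau, rtol=0.10, atol=0.03)
        np.testing.assert_allclose(gp_hat.alpha, gp_true.alpha, atol=0.08)
        np.testing.assert_allclose(gp_hat.rho, gp_true.rho, atol=0.05)


class TestTuneRAndSupervised:
    def test_single_value_grid_short_circuits(self, rng):
        series = EmbeddingSeries(X={0: rng.normal(size=(3, 1))}, H={0: 0.0})
        labels = LabelSeries(y={0: np.array([0, 1, 0])})
        assert tune_r(series, labels, r_grid=[0.3]) == 0.3

    def test_r_changes_posteriors_on_autocorrelated_data(self):
        mk = _markov(lambda_init=-0.5, lambda_0=-1.0, lambda_1=1.0)
        gp = _gp(m=2, mu1=np.array([0.5, 0.5]), tau=np.array([0.7, 0.7]), r=1.0)
        series, _ = simulate_mgp_series(mk, gp, 1, mean_T=15, seed=2)
        pid = series.patient_ids[0]
        x, H = series.X[pid], series.H[pid]
        gp0 = _gp(m=2, mu1=np.array([0.5, 0.5]), tau=np.array([0.7, 0.7]), r=0.0)
        pi0, _, _ = forward_backward(x, H, MGPModel(markov=mk, gp=gp0))
        pi1, _, _ = forward_backward(x, H, MGPModel(markov=mk, gp=gp))
        assert np.abs(pi0 - pi1).max() > 1e-3

    def test_supervised_fit_beats_chance_on_informative_data(self):
        mk = _markov(lambda_init=-1.0, lambda_0=-1.5, lambda_1=1.0)
        gp = _gp(m=2, mu1=np.array([1.0, -0.8]), tau=np.array([0.4, 0.4]), r=1.0)
        series, labels = simulate_mgp_series(mk, gp, 60, mean_T=12, seed=9)
        model = fit_supervised(series, labels, r=0.5)
        post = predict(model, series)
        from samgep.metrics import auc
        y = np.concatenate([labels.y[p] for p in labels.patient_ids])
        assert auc(y, post.pooled()) > 0.8


class TestOneStepEM:
    def test_empty_unlabeled_returns_model_unchanged(self):
        mk = _markov(lambda_init=-1.0, lambda_0=-1.5, lambda_1=1.0)
        gp = _gp(m=2, mu1=np.array([1.0, -0.8]))
        series, labels = simulate_mgp_series(mk, gp, 20, mean_T=8, seed=3)
        model = fit_supervised(series, labels, r=0.0)
        assert em_one_step(model, series, labels) is model

    def test_em_refit_moves_parameters_toward_truth(self):
        mk = _markov(lambda_init=-1.0, lambda_0=-1.5, lambda_1=1.0)
        gp = _gp(m=2, mu1=np.array([1.5, -1.2]), tau=np.array([0.3, 0.3]), r=1.0)
        series, labels = simulate_mgp_series(mk, gp, 400, mean_T=15, seed=6)
        few = LabelSeries(y={p: labels.y[p] for p in labels.patient_ids[:40]})
        sup = fit_supervised(series.subset(few.patient_ids), few, r=0.3)
        semi = em_one_step(sup, series, few)
        assert semi.provenance == "one-step-em"

        def mu_rmse(model):
            return np.sqrt(np.mean(
                (model.gp.mu1 - gp.mu1) ** 2 + (model.gp.mu0 - gp.mu0) ** 2
            ))
        # strong, well-specified signal: imputation-based refit sharpens means
        assert mu_rmse(semi) <= mu_rmse(sup) + 0.02

    def test_iteration_count_default_is_one(self):
        # n_iter governs refits: 1 E/M pass by default
        import inspect
        sig = inspect.signature(em_one_step)
        assert sig.parameters["n_iter"].default == 1


class TestSerialization:
    def test_model_dict_round_trip(self, rng):
        model = random_model(rng, m=3)
        back = model_from_dict(model_to_dict(model))
        assert back.markov.as_dict() == pytest.approx(model.markov.as_dict())
        np.testing.assert_allclose(back.gp.rho, model.gp.rho)
        np.testing.assert_allclose(back.gp.tau, model.gp.tau)
        assert back.gp.r == model.gp.r


class TestHMMReduction:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_r_zero_matches_classic_forward_backward(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, m=2)
        model.gp.r = 0.0
        T = 12
        x = rng.normal(0, 1.2, size=(T, 2))
        H = float(rng.uniform(0, 1))
        pi, _, ll = forward_backward(x, H, model)
        pi_ref, ll_ref = classic_hmm_posteriors(x, H, model)
        np.testing.assert_allclose(pi, pi_ref, atol=1e-10)
        assert ll == pytest.approx(ll_ref, abs=1e-10)
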