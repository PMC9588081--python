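"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own recursion code paths: the
enumeration oracle sums over all 2^T label sequences with per-term density
calls, and the classic HMM forward-backward is the textbook scaled
(non-log) recursion with per-bin (state-only) emissions.
"""

from itertools import product

import numpy as np
from scipy.stats import multivariate_normal

from samgep.mgp import (
    MGPModel,
    emission_logdensity,
    gp_mean,
    init_prob,
    marginal_covariance,
    trans_prob,
)


def enumerate_posteriors(x: np.ndarray, H: float, model: MGPModel):
    """Brute-force marginals, all-zero-path probabilities, log-likelihood."""
    T = x.shape[0]
    mk, gp = model.markov, model.gp
    logjoint = {}
    for ys in product((0, 1), repeat=T):
        p1 = init_prob(H, mk)
        lp = np.log(p1 if ys[0] else 1 - p1)
        lp += emission_logdensity(x[0], None, ys[0], None, H, 1, gp)
        for t in range(2, T + 1):
            pt = trans_prob(ys[t - 2], t, H, mk)
            lp += np.log(pt if ys[t - 1] else 1 - pt)
            lp += emission_logdensity(x[t - 1], x[t - 2], ys[t - 1], ys[t - 2], H, t, gp)
        logjoint[ys] = lp
    lps = np.array(list(logjoint.values()))
    mx = lps.max()
    loglik = mx + np.log(np.exp(lps - mx).sum())
    marg = np.zeros(T)
    zero_path = np.zeros(T)
    for ys, lp in logjoint.items():
        w = np.exp(lp - loglik)
        for t in range(T):
            if ys[t]:
                marg[t] += w
            if not any(ys[: t + 1]):
                zero_path[t] += w
    return marg, zero_path, loglik


def classic_hmm_posteriors(x: np.ndarray, H: float, model: MGPModel):
    """Scaled forward-backward for a Gaussian-emission HMM (no AR memory)."""
    T = x.shape[0]
    mk, gp = model.markov, model.gp
    S = marginal_covariance(H, gp)
    dens = np.empty((T, 2))
    for t in range(1, T + 1):
        for y in (0, 1):
            dens[t - 1, y] = multivariate_normal.pdf(
                x[t - 1], mean=gp_mean(y, H, t, gp), cov=S
            )
    p1 = init_prob(H, mk)
    alpha = np.empty((T, 2))
    scale = np.empty(T)
    alpha[0] = np.array([1 - p1, p1]) * dens[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    A = np.empty((T, 2, 2))
    for t in range(2, T + 1):
        for yp in (0, 1):
            pt = trans_prob(yp, t, H, mk)
            A[t - 1, yp] = [1 - pt, pt]
        alpha[t - 1] = (alpha[t - 2] @ A[t - 1]) * dens[t - 1]
        scale[t - 1] = alpha[t - 1].sum()
        alpha[t - 1] /= scale[t - 1]
    beta = np.ones((T, 2))
    for t in range(T - 2, -1, -1):
        beta[t] = (A[t + 1] * (dens[t + 1] * beta[t + 1])[None, :]).sum(axis=1)
        beta[t] /= scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 1], float(np.log(scale).sum())


def random_model(rng, m: int, spread: float = 0.6) -> MGPModel:
    """A random, well-conditioned small MGP for oracle comparisons."""
    from samgep.mgp import GPParams, MarkovParams, nearest_correlation

    mk = MarkovParams(*rng.normal(0, spread, 7))
    R = nearest_correlation(np.corrcoef(rng.normal(0, 1, (m + 3, m)).T)) \
        if m > 1 else np.ones((1, 1))
    gp = GPParams(
        mu0=rng.normal(0, spread, m), mu1=rng.normal(0, spread, m),
        mu2=rng.normal(0, 0.05, m), mu3=rng.normal(0, spread, m),
        mu4=rng.normal(0, 0.05, m), mu5=rng.normal(0, spread, m),
        muH=rng.normal(0, spread, m), muYH=rng.normal(0, spread, m),
        sigma=rng.uniform(0.6, 1.4, m), alpha=rng.normal(0, 0.2, m),
        tau=rng.uniform(-0.6, 0.8, m), rho=R, r=float(rng.uniform(0, 1)),
    )
    return MGPModel(markov=mk, gp=gp)
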