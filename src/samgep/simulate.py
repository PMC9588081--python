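"""Synthetic longitudinal cohort generator.

Emulates the structure of a binned coded-record cohort: p = 150 count
features per patient-bin, a mean of 25 bins per patient, a per-patient
utilization covariate, latent binary phenotype states generated by a
two-state Markov chain (with configurable dependence on time), and feature
counts whose log1p transform is linear in the state and utilization with
within-patient AR(1) noise that is marginally Gaussian (lognormal counts)
or Student-t with 5 df (log-t counts).  Only a small set of "informative"
features carries state signal; the remainder are heavily zero-inflated
noise, mirroring the sparsity of real coded data.

A companion stand-in generator produces an embedding matrix whose
informative columns share a low-rank signal component, so that cosine
screening and discriminant weighting have structure to find.  A separate
model-based generator draws embedding series directly from given chain and
emission parameters for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .io_data import FeaturePanel, LabelSeries
from .mgp import (
    GPParams,
    MarkovParams,
    _mean_matrix,
    _psd_floor,
    marginal_covariance,
)
from .weights import EmbeddingSeries

_MODES = ("independent", "correct", "complex")
_DISTS = ("lognormal", "log_t5")


@dataclass
class SimConfig:
    """Generative configuration; defaults follow the reference study design."""

    N_unlabeled: int = 1000
    n_labeled: int = 100
    p: int = 150
    m: int = 10
    mean_T: float = 25.0
    n_informative: int = 20
    y_given_t_mode: str = "correct"
    feature_dist: str = "lognormal"
    seed: int = 0

    # latent chain (logit scale)
    lambda_init: float = -2.5
    lambda_H0: float = 0.3
    lambda_0: float = -3.0
    lambda_1: float = 0.5
    lambda_2: float = 0.002
    lambda_3: float = 0.2
    lambda_H: float = 0.2

    # utilization: truncated normal on the log scale
    mu_H: float = 1.0
    sigma_H: float = 0.5

    # informative-feature log-count model: a_j + b_j Y + c_j H + noise
    effect_loc: float = 0.3          # mean of state effects b_j
    effect_scale: float = 0.1
    baseline_loc: float = 0.8        # mean of intercepts a_j
    baseline_scale: float = 0.2
    util_loc: float = 0.2            # mean of utilization slopes c_j
    util_scale: float = 0.1
    noise_sd: float = 0.8
    ar_coef: float = 0.4             # within-patient AR(1) of the noise
    zero_inflation: float = 0.85     # P(structural zero) for noise features
    noise_baseline: float = 0.3

    def validate(self) -> None:
        if self.y_given_t_mode not in _MODES:
            raise ValueError(f"y_given_t_mode must be one of {_MODES}")
        if self.feature_dist not in _DISTS:
            raise ValueError(f"feature_dist must be one of {_DISTS}")
        if not (0 <= self.n_informative <= self.p):
            raise ValueError("n_informative must lie in [0, p]")
        if self.mean_T < 2:
            raise ValueError("mean_T must be >= 2")


def _simulate_states(cfg: SimConfig, T: int, H: float, rng) -> np.ndarray:
    y = np.empty(T, dtype=np.int8)
    if cfg.y_given_t_mode == "independent":
        # start at the stationary law of the time-free chain so the
        # marginal P(Y_t = 1) is exactly flat in t
        p01 = expit(cfg.lambda_0 + cfg.lambda_H * H)
        p10 = 1.0 - expit(cfg.lambda_1 + cfg.lambda_H * H)
        p1 = p01 / max(p01 + p10, 1e-12)
    else:
        p1 = expit(cfg.lambda_init + cfg.lambda_H0 * H)
    y[0] = rng.random() < p1
    for t in range(2, T + 1):
        eta = cfg.lambda_0 * (1 - y[t - 2]) + cfg.lambda_1 * y[t - 2] + cfg.lambda_H * H
        if cfg.y_given_t_mode == "correct":
            eta += cfg.lambda_2 * t + cfg.lambda_3 * np.log(t)
        elif cfg.y_given_t_mode == "complex":
            eta += (cfg.lambda_2 * t + cfg.lambda_3 * np.log(t)
                    + 1e-3 * t ** 2 + 0.3 * np.sin(2 * np.pi * t / 12.0))
        y[t - 1] = rng.random() < expit(eta)
    return y


def _ar1_noise(cfg: SimConfig, T: int, p: int, rng) -> np.ndarray:
    """Within-patient AR(1) noise with stationary marginal SD noise_sd."""
    phi = cfg.ar_coef
    if cfg.feature_dist == "lognormal":
        innov = rng.standard_normal((T, p))
    else:  # marginally t with 5 df, scaled to unit variance (var = 5/3)
        innov = rng.standard_t(5, size=(T, p)) / np.sqrt(5.0 / 3.0)
    e = np.empty((T, p))
    e[0] = innov[0]
    for t in range(1, T):
        e[t] = phi * e[t - 1] + np.sqrt(1 - phi ** 2) * innov[t]
    return cfg.noise_sd * e


def simulate_cohort(cfg: SimConfig):
    """Draw a full cohort under the configuration.

    Returns ``(panel, labels, V, truth)``: the feature panel for all
    patients, the complete label series (the truth record lists which
    patients' labels are revealed), the stand-in embedding matrix, and a
    record of all generative parameters.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    N = cfg.N_unlabeled + cfg.n_labeled

    informative = np.arange(cfg.n_informative)
    a = rng.normal(cfg.baseline_loc, cfg.baseline_scale, size=cfg.p)
    b = np.zeros(cfg.p)
    b[informative] = rng.normal(cfg.effect_loc, cfg.effect_scale,
                                size=cfg.n_informative)
    c = np.zeros(cfg.p)
    c[informative] = rng.normal(cfg.util_loc, cfg.util_scale,
                                size=cfg.n_informative)
    a_noise = np.full(cfg.p, cfg.noise_baseline)
    a_noise[informative] = a[informative]

    feature_ids = [f"F{j + 1:03d}" for j in range(cfg.p)]
    raw, C, H, yall = {}, {}, {}, {}
    for i in range(N):
        pid = f"P{i + 1:05d}"
        T = 1 + rng.poisson(cfg.mean_T - 1)
        h = max(0.0, rng.normal(cfg.mu_H, cfg.sigma_H))
        y = _simulate_states(cfg, T, h, rng)
        e = _ar1_noise(cfg, T, cfg.p, rng)
        logc = a_noise[None, :] + b[None, :] * y[:, None] + c[None, :] * h + e
        counts = np.maximum(0, np.round(np.expm1(logc))).astype(np.int64)
        # heavy zero-inflation on the uninformative background
        mask = rng.random((T, cfg.p)) < cfg.zero_inflation
        mask[:, informative] = False
        counts[mask] = 0
        raw[pid] = counts
        C[pid] = np.log1p(counts.astype(float))
        H[pid] = h
        yall[pid] = y

    panel = FeaturePanel(feature_ids=feature_ids, raw=raw, C=C, H=H)
    labels = LabelSeries(y=yall)
    V = make_embedding_matrix(cfg.p, cfg.m, informative, seed=cfg.seed + 1)
    labeled_ids = sorted(
        rng.choice(panel.patient_ids, size=cfg.n_labeled, replace=False)
    )
    truth = {
        "config": cfg,
        "a": a_noise, "b": b, "c": c,
        "informative_ids": [feature_ids[j] for j in informative],
        "labeled_ids": labeled_ids,
        "markov": MarkovParams(
            lambda_init=cfg.lambda_init, lambda_H0=cfg.lambda_H0,
            lambda_0=cfg.lambda_0, lambda_1=cfg.lambda_1,
            lambda_2=cfg.lambda_2, lambda_3=cfg.lambda_3,
            lambda_H=cfg.lambda_H,
        ),
    }
    return panel, labels, V, truth


def make_embedding_matrix(p: int, m: int, informative, seed: int = 0) -> np.ndarray:
    """Stand-in m x p embedding matrix.

    Informative features share a common low-rank signal direction plus
    idiosyncratic noise, so their pairwise cosines exceed those of
    informative-noise pairs; all columns are unit-normalized.  Deterministic
    given the seed.
    """
    if m > p:
        raise ValueError("m must be <= p")
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((m, p)) / np.sqrt(m)
    u = rng.standard_normal(m)
    u /= np.linalg.norm(u)
    informative = np.asarray(informative, dtype=int)
    V[:, informative] = (
        0.75 * u[:, None]
        + 0.35 * rng.standard_normal((m, len(informative))) / np.sqrt(m)
    )
    V /= np.linalg.norm(V, axis=0, keepdims=True)
    return V


def simulate_mgp_series(
    markov: MarkovParams,
    gp: GPParams,
    n_patients: int,
    mean_T: float = 25.0,
    mu_H: float = 1.0,
    sigma_H: float = 0.5,
    seed: int = 0,
):
    """Draw (X, Y, H) directly from given chain and emission parameters.

    Residuals follow the stationary AR(1) law implied by the emission model
    with coefficient gp.r * gp.tau and stationary covariance Sigma(H).
    Used for parameter-recovery checks against fit_markov / fit_gp.
    """
    rng = np.random.default_rng(seed)
    X, yd, Hd = {}, {}, {}
    for i in range(n_patients):
        pid = f"P{i + 1:05d}"
        T = 1 + rng.poisson(mean_T - 1)
        h = max(0.0, rng.normal(mu_H, sigma_H))
        y = np.empty(T, dtype=np.int8)
        y[0] = rng.random() < expit(markov.lambda_init + markov.lambda_H0 * h)
        for t in range(2, T + 1):
            eta = (markov.lambda_0 * (1 - y[t - 2]) + markov.lambda_1 * y[t - 2]
                   + markov.lambda_2 * t + markov.lambda_3 * np.log(t)
                   + markov.lambda_H * h)
            y[t - 1] = rng.random() < expit(eta)
        S = marginal_covariance(h, gp)
        A = gp.r * gp.tau
        L = np.linalg.cholesky(S + 1e-10 * np.eye(gp.m))
        # PSD-projected, mirroring the model's conditional covariance: the
        # diagonal-AR law need not leave S - A S A positive definite
        innov_cov = _psd_floor(S - (S * np.outer(A, A)))
        Li = np.linalg.cholesky(innov_cov + 1e-10 * np.eye(gp.m))
        eps = np.empty((T, gp.m))
        eps[0] = L @ rng.standard_normal(gp.m)
        for t in range(1, T):
            eps[t] = A * eps[t - 1] + Li @ rng.standard_normal(gp.m)
        M0 = _mean_matrix(0, h, T, gp)
        M1 = _mean_matrix(1, h, T, gp)
        mean = np.where(y[:, None] == 1, M1, M0)
        X[pid] = mean + eps
        yd[pid] = y
        Hd[pid] = h
    return EmbeddingSeries(X=X, H=Hd), LabelSeries(y=yd)
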