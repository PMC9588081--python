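"""Markov Gaussian Process (MGP) latent-state model.

The phenotype state sequence Y_i = (Y_{i,1}, ..., Y_{i,T_i}) follows a
two-state discrete-time Markov chain whose initial and transition
probabilities are logistic in the utilization covariate H_i and (for t >= 2)
in linear and log time:

    P(Y_1 = 1 | H)            = expit(lambda_init + lambda_H0 H)
    P(Y_t = 1 | Y_{t-1}, H)   = expit(lambda_0 (1 - y_{t-1}) + lambda_1 y_{t-1}
                                      + lambda_2 t + lambda_3 log t + lambda_H H)

Conditional on Y, the patient-timepoint embedding series X_i is a Gaussian
process.  Its mean at bin t is linear in Y, H, t and log t (with Y
interactions); its within-bin covariance is Sigma(H) = D rho D with
D = diag(sigma_k exp(alpha_k H)); and its residuals carry first-order
autoregressive memory damped by a hyperparameter r in [0, 1]:

    E[eps_t | eps_{t-1}] = r tau_k eps_{t-1,k}.

Bin-level posteriors P(Y_t = 1 | X) and the joint no-event probabilities
P(Y_1 = ... = Y_t = 0 | X) are computed exactly by a log-space
forward-backward recursion over the pairwise chain.  Fitting is supervised
(logistic regression for the chain, weighted least squares plus moment
estimators for the emission) optionally followed by a single EM step that
re-fits on observed labels plus soft posterior labels of the unlabeled set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .io_data import LabelSeries
from .weights import EmbeddingSeries

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-8
_TAU_CLIP = 0.99


@dataclass
class MarkovParams:
    lambda_init: float
    lambda_H0: float
    lambda_0: float
    lambda_1: float
    lambda_2: float
    lambda_3: float
    lambda_H: float
    se: dict = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        return {
            k: float(getattr(self, k))
            for k in (
                "lambda_init", "lambda_H0", "lambda_0", "lambda_1",
                "lambda_2", "lambda_3", "lambda_H",
            )
        }


@dataclass
class GPParams:
    mu0: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    mu4: np.ndarray
    mu5: np.ndarray
    muH: np.ndarray
    muYH: np.ndarray
    sigma: np.ndarray            # baseline SDs, > 0
    alpha: np.ndarray            # utilization variance slopes
    tau: np.ndarray              # lag-1 autocorrelations, |tau| < 1
    rho: np.ndarray              # m x m correlation matrix
    r: float = 0.0               # autoregression dampener in [0, 1]
    se: dict = field(default_factory=dict, repr=False)

    @property
    def m(self) -> int:
        return len(self.sigma)

    def validate(self) -> None:
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be positive")
        if (np.abs(self.tau) >= 1).any():
            raise ValueError("|tau| must be < 1")
        if not (0.0 <= self.r <= 1.0):
            raise ValueError("r must lie in [0, 1]")
        if not np.allclose(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")


@dataclass
class MGPModel:
    markov: MarkovParams
    gp: GPParams
    provenance: str = "supervised"   # or "one-step-em"

    @property
    def m(self) -> int:
        return self.gp.m


@dataclass
class PosteriorSeries:
    """Per-patient marginal posteriors and derived joint quantities."""

    pi: dict          # pid -> length-T vector of P(Y_t = 1 | X)
    F: dict           # pid -> 1 - P(Y_1 = ... = Y_t = 0 | X)
    loglik: dict      # pid -> total log-likelihood of X_i

    @property
    def patient_ids(self) -> list:
        return list(self.pi.keys())

    def pooled(self, patient_ids=None) -> np.ndarray:
        pids = patient_ids if patient_ids is not None else self.patient_ids
        return np.concatenate([self.pi[pid] for pid in pids])


# ---------------------------------------------------------------------------
# Chain and emission primitives


def init_prob(H: float, markov: MarkovParams) -> float:
    """P(Y_1 = 1 | H)."""
    return float(expit(markov.lambda_init + markov.lambda_H0 * H))


def trans_prob(y_prev: int, t: int, H: float, markov: MarkovParams) -> float:
    """P(Y_t = 1 | Y_{t-1} = y_prev, H) for t >= 2."""
    if t < 2:
        raise ValueError("trans_prob requires t >= 2; bin 1 uses init_prob")
    eta = (
        markov.lambda_0 * (1 - y_prev)
        + markov.lambda_1 * y_prev
        + markov.lambda_2 * t
        + markov.lambda_3 * np.log(t)
        + markov.lambda_H * H
    )
    return float(expit(eta))


def gp_mean(y: int, H: float, t: int, gp: GPParams) -> np.ndarray:
    """Mean embedding vector at state y, utilization H, bin t (1-based)."""
    if t < 1:
        raise ValueError("t must be >= 1")
    logt = np.log(t)
    return (
        gp.mu0 * (1 - y)
        + gp.mu1 * y
        + gp.muH * H
        + gp.muYH * H * y
        + gp.mu2 * t
        + gp.mu3 * logt
        + gp.mu4 * y * t
        + gp.mu5 * y * logt
    )


def _mean_matrix(y: int, H: float, T: int, gp: GPParams) -> np.ndarray:
    """T x m matrix of gp_mean over bins 1..T at a fixed state."""
    t = np.arange(1, T + 1, dtype=float)[:, None]
    logt = np.log(t)
    base = gp.mu0 * (1 - y) + gp.mu1 * y + gp.muH * H + gp.muYH * H * y
    return base + gp.mu2 * t + gp.mu3 * logt + gp.mu4 * y * t + gp.mu5 * y * logt


def _psd_floor(S: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= floor:
        return S
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def nearest_correlation(R: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Eigenvalue-clipped PSD projection followed by diagonal renormalization."""
    S = _psd_floor(R, floor)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)

def marginal_covariance(H: float, gp: GPParams) -> np.ndarray:
    """Sigma(H) = D rho D with D = diag(sigma_k exp(alpha_k H))."""
    d = gp.sigma * np.exp(gp.alpha * H)
    return gp.rho * np.outer(d, d)


def conditional_covariance(H: float, gp: GPParams) -> np.ndarray:
    """Sigma(H) - A Sigma(H) A with A = diag(r tau_k), floored to PSD."""
    S = marginal_covariance(H, gp)
    a = gp.r * gp.tau
    Sc = S - (S * np.outer(a, a))
    return _psd_floor(Sc)


def emission_logdensity(
    x_t: np.ndarray,
    x_prev: np.ndarray | None,
    y_t: int,
    y_prev: int | None,
    H: float,
    t: int,
    gp: GPParams,
) -> float:
    """Log emission density of one bin given the previous bin's residual.

    For t = 1 this is the marginal Gaussian; for t > 1 the conditional
    Gaussian whose mean is shifted by diag(r tau) times the previous
    residual and whose covariance is the AR(1)-deflated Sigma_c(H).
    """
    mean = gp_mean(y_t, H, t, gp)
    if t == 1 or x_prev is None:
        S = marginal_covariance(H, gp)
    else:
        if y_prev is None:
            raise ValueError("y_prev required for t > 1")
        mean = mean + (gp.r * gp.tau) * (x_prev - gp_mean(y_prev, H, t - 1, gp))
        S = conditional_covariance(H, gp)
    resid = np.asarray(x_t, float) - mean
    c, lower = cho_factor(S, lower=True)
    quad = resid @ cho_solve((c, lower), resid)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    m = len(resid)
    return float(-0.5 * (m * np.log(2 * np.pi) + logdet + quad))


# ---------------------------------------------------------------------------
# Forward-backward over the pairwise chain


def _emission_tables(x: np.ndarray, H: float, gp: GPParams):
    """Log emission arrays for one patient.

    Returns (e1, epair) with e1[y] the bin-1 log density at state y and
    epair[t-2, yp, y] the conditional log density of bin t (t >= 2) given
    (Y_{t-1} = yp, Y_t = y).  Choleskys of the two covariances are shared
    across bins since they depend only on H.
    """
    T, m = x.shape
    M = [_mean_matrix(0, H, T, gp), _mean_matrix(1, H, T, gp)]
    S1 = marginal_covariance(H, gp)
    L1 = np.linalg.cholesky(_psd_floor(S1))

    def _logdens(resid, L):
        z = solve_triangular(L, resid.T, lower=True)
        quad = (z * z).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        return -0.5 * (m * np.log(2 * np.pi) + logdet + quad)

    e1 = np.array([_logdens(x[:1] - M[y][:1], L1)[0] for y in (0, 1)])
    if T == 1:
        return e1, np.zeros((0, 2, 2))
    Sc = conditional_covariance(H, gp)
    Lc = np.linalg.cholesky(_psd_floor(Sc))
    a = gp.r * gp.tau
    epair = np.empty((T - 1, 2, 2))
    for yp in (0, 1):
        shift = a * (x[:-1] - M[yp][:-1])
        for y in (0, 1):
            resid = x[1:] - M[y][1:] - shift
            epair[:, yp, y] = _logdens(resid, Lc)
    return e1, epair


def forward_backward(
    x: np.ndarray, H: float, model: MGPModel
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact posteriors for one patient under the pairwise chain.

    Returns (pi, F, loglik): the marginal posteriors P(Y_t = 1 | X_{1:T}),
    the first-event CDF F_t = 1 - P(Y_1 = ... = Y_t = 0 | X_{1:T}), and the
    total log-likelihood of the series.  All computation is in log space.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.isnan(x).any():
        raise ValueError("NaN in embedding series")
    T = x.shape[0]
    mk = model.markov
    e1, epair = _emission_tables(x, H, model.gp)

    p1 = init_prob(H, mk)
    log_init = np.log(np.array([1.0 - p1, p1]))
    # log transition matrices ltr[t-2, yp, y] for t = 2..T
    if T > 1:
        ts = np.arange(2, T + 1)
        ltr = np.empty((T - 1, 2, 2))
        for yp in (0, 1):
            p = expit(
                mk.lambda_0 * (1 - yp) + mk.lambda_1 * yp
                + mk.lambda_2 * ts + mk.lambda_3 * np.log(ts) + mk.lambda_H * H
            )
            ltr[:, yp, 1] = np.log(p)
            ltr[:, yp, 0] = np.log1p(-p)

    def _lse(a, axis):
        # logsumexp over one axis of a 2x2 block; scipy's version carries
        # array-API dispatch overhead that dominates at this size
        mx = a.max(axis=axis)
        return mx + np.log(np.exp(a - np.expand_dims(mx, axis)).sum(axis=axis))

    la = np.empty((T, 2))
    la[0] = log_init + e1
    for t in range(1, T):
        step = la[t - 1][:, None] + ltr[t - 1] + epair[t - 1]
        la[t] = _lse(step, 0)
    mx = la[-1].max()
    loglik = float(mx + np.log(np.exp(la[-1] - mx).sum()))

    lb = np.zeros((T, 2))
    for t in range(T - 2, -1, -1):
        step = ltr[t] + epair[t] + lb[t + 1][None, :]
        lb[t] = _lse(step, 1)

    post = np.exp(la + lb - loglik)
    post /= post.sum(axis=1, keepdims=True)
    pi = post[:, 1]

    # all-zero-path: P(Y_1..t = 0 | X_{1:T}) = exp(lz_t + lb[t,0] - loglik)
    lz = np.empty(T)
    lz[0] = log_init[0] + e1[0]
    for t in range(1, T):
        lz[t] = lz[t - 1] + ltr[t - 1, 0, 0] + epair[t - 1, 0, 0]
    F = 1.0 - np.exp(lz + lb[:, 0] - loglik)
    F = np.clip(F, 0.0, 1.0)
    return pi, F, loglik


def predict(model: MGPModel, series: EmbeddingSeries) -> PosteriorSeries:
    """Run forward-backward over every patient in the series."""
    pi, F, ll = {}, {}, {}
    for pid in series.patient_ids:
        pi[pid], F[pid], ll[pid] = forward_backward(
            series.X[pid], series.H[pid], model
        )
    return PosteriorSeries(pi=pi, F=F, loglik=ll)


# ---------------------------------------------------------------------------
# Supervised fitting


def _weighted_logistic(Z, y, w, names):
    """Weighted logistic regression without intercept; returns (coef, se).

    Falls back to a lightly L2-stabilized fit when the unpenalized problem
    fails to converge (e.g. complete separation).
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    Z = np.asarray(Z, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    keep = w > 0
    Z, y, w = Z[keep], y[keep], w[keep]
    if (y * w).sum() <= 0 or ((1 - y) * w).sum() <= 0:
        raise ValueError("logistic fit needs both outcome classes with weight")
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(
                C=np.inf, fit_intercept=False, solver="lbfgs", max_iter=2000
            ).fit(Z, y.round().astype(int), sample_weight=w)
            coef = clf.coef_.ravel()
            if np.abs(coef).max() > 30:
                raise ConvergenceWarning("coefficients diverging")
        except (ConvergenceWarning, np.linalg.LinAlgError) as exc:
            logger.warning("logistic fit unstable (%s); adding small ridge", exc)
            clf = LogisticRegression(
                C=1e3, fit_intercept=False, solver="lbfgs", max_iter=2000,
            ).fit(Z, y.round().astype(int), sample_weight=w)
            coef = clf.coef_.ravel()
    p = expit(Z @ coef)
    info = Z.T @ (Z * (w * p * (1 - p))[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(len(coef), np.nan)
    return dict(zip(names, coef)), dict(zip(names, se))


def _soft_rows(y_or_pi, hard: bool):
    """Expand a label/posterior vector into (state, weight) rows per bin."""
    v = np.asarray(y_or_pi, float)
    if hard:
        return [(v.astype(int), np.ones_like(v))]
    return [(np.zeros(len(v), dtype=int), 1.0 - v), (np.ones(len(v), dtype=int), v)]


def fit_markov(
    labels: dict,
    H: dict,
    posteriors: dict | None = None,
) -> MarkovParams:
    """Fit the chain parameters by (weighted) logistic regression.

    ``labels`` maps patient_id -> hard 0/1 vectors (weight 1).  ``posteriors``
    maps additional patients to marginal posterior vectors; each such
    initial state contributes its two configurations weighted by the
    marginal, and each transition contributes the four (y_{t-1}, y_t)
    configurations weighted by the product of adjacent marginals.
    """
    init_Z, init_y, init_w = [], [], []
    tr_Z, tr_y, tr_w = [], [], []

    def _add(pid, v, hard):
        h = H[pid]
        v = np.asarray(v, float)
        T = len(v)
        if hard:
            w1 = np.array([1.0])
            init_y.append(np.array([v[0]]))
            init_Z.append(np.array([[1.0, h]]))
            init_w.append(w1)
            if T > 1:
                ts = np.arange(2, T + 1, dtype=float)
                yp = v[:-1]
                tr_Z.append(
                    np.column_stack([1 - yp, yp, ts, np.log(ts), np.full(T - 1, h)])
                )
                tr_y.append(v[1:])
                tr_w.append(np.ones(T - 1))
        else:
            for s in (0, 1):
                init_y.append(np.array([float(s)]))
                init_Z.append(np.array([[1.0, h]]))
                init_w.append(np.array([v[0] if s else 1 - v[0]]))
            if T > 1:
                ts = np.arange(2, T + 1, dtype=float)
                for yp in (0, 1):
                    wp = v[:-1] if yp else 1 - v[:-1]
                    row = np.column_stack(
                        [np.full(T - 1, 1.0 - yp), np.full(T - 1, float(yp)),
                         ts, np.log(ts), np.full(T - 1, h)]
                    )
                    for y in (0, 1):
                        wy = v[1:] if y else 1 - v[1:]
                        tr_Z.append(row)
                        tr_y.append(np.full(T - 1, float(y)))
                        tr_w.append(wp * wy)

    for pid, v in labels.items():
        _add(pid, v, hard=True)
    if posteriors:
        for pid, v in posteriors.items():
            _add(pid, v, hard=False)

    if not tr_Z:
        raise ValueError("no transitions observed")
    init_coef, init_se = _weighted_logistic(
        np.vstack(init_Z), np.concatenate(init_y), np.concatenate(init_w),
        ["lambda_init", "lambda_H0"],
    )
    tr_coef, tr_se = _weighted_logistic(
        np.vstack(tr_Z), np.concatenate(tr_y), np.concatenate(tr_w),
        ["lambda_0", "lambda_1", "lambda_2", "lambda_3", "lambda_H"],
    )
    return MarkovParams(**init_coef, **tr_coef, se={**init_se, **tr_se})


_MU_NAMES = ["mu0", "mu1", "muH", "muYH", "mu2", "mu3", "mu4", "mu5"]


def _gp_design(y_state, H, T):
    t = np.arange(1, T + 1, dtype=float)
    logt = np.log(t)
    y = np.asarray(y_state, float)
    h = np.full(T, H)
    return np.column_stack([1 - y, y, h, h * y, t, logt, y * t, y * logt])


def fit_gp(
    series: EmbeddingSeries,
    labels: dict,
    posteriors: dict | None = None,
    r: float = 0.0,
) -> GPParams:
    """Fit the emission parameters by weighted least squares and moments.

    Mean coefficients come from per-component WLS of X on the state/time
    design.  Residuals then yield the variance model: alpha_k from the slope
    of log eps^2 on 2H, sigma_k from the H-standardized second moment, rho
    from the correlation of standardized residuals (PSD-projected), and
    tau_k as the pooled lag-1 autoregression coefficient of within-patient
    standardized residuals.  Soft labels contribute a weighted pair of rows
    per bin.
    """
    Zs, Xs, ws, row_pids = [], [], [], []
    pid_rows = {}  # pid -> (soft) marginal vector used for residual means

    def _add(pid, v, hard):
        T = series.T(pid)
        v = np.asarray(v, float)
        if len(v) != T:
            raise ValueError(f"label length mismatch for patient {pid!r}")
        for states, wv in _soft_rows(v, hard):
            Zs.append(_gp_design(states, series.H[pid], T))
            Xs.append(series.X[pid])
            ws.append(np.asarray(wv, float))
            row_pids.append(pid)
        pid_rows[pid] = v

    for pid, v in labels.items():
        _add(pid, v, hard=True)
    if posteriors:
        for pid, v in posteriors.items():
            _add(pid, v, hard=False)

    Z = np.vstack(Zs)
    X = np.vstack(Xs)
    w = np.concatenate(ws)
    m = X.shape[1]

    sw = np.sqrt(w)
    ZW = Z * sw[:, None]
    XW = X * sw[:, None]
    ZtZ = ZW.T @ ZW
    B, *_ = np.linalg.lstsq(ZtZ, ZW.T @ XW, rcond=None)  # 8 x m
    mus = {name: B[i].copy() for i, name in enumerate(_MU_NAMES)}

    # patient-clustered sandwich SEs for the mean coefficients: residuals
    # are AR(1)-correlated within patient, so plain WLS errors undersell
    # the uncertainty
    resid_rows = XW - ZW @ B
    try:
        Cinv = np.linalg.inv(ZtZ)
        G_by_pid: dict = {}
        row0 = 0
        for block_Z, block_pid in zip(Zs, row_pids):
            nrows = block_Z.shape[0]
            G = ZW[row0:row0 + nrows].T @ resid_rows[row0:row0 + nrows]  # 8 x m
            if block_pid in G_by_pid:
                G_by_pid[block_pid] += G
            else:
                G_by_pid[block_pid] = G
            row0 += nrows
        meat = np.zeros((Z.shape[1], Z.shape[1], m))
        for G in G_by_pid.values():
            meat += np.einsum("ak,bk->abk", G, G)
        var = np.einsum("ab,bck,cd->adk", Cinv, meat, Cinv)
        mu_se = {name: np.sqrt(np.maximum(var[i, i, :], 0))
                 for i, name in enumerate(_MU_NAMES)}
    except np.linalg.LinAlgError:
        mu_se = {}

    # expected residual per patient-bin (exact for hard labels)
    eps, Hs, pids_order = [], [], []
    for pid, v in pid_rows.items():
        T = series.T(pid)
        m0 = _gp_design(np.zeros(T), series.H[pid], T) @ B
        m1 = _gp_design(np.ones(T), series.H[pid], T) @ B
        mean = m0 * (1 - v[:, None]) + m1 * v[:, None]
        eps.append(series.X[pid] - mean)
        Hs.append(np.full(T, series.H[pid]))
        pids_order.append(pid)
    E = np.vstack(eps)
    Hvec = np.concatenate(Hs)

    if (E ** 2).mean() < 1e-12:
        raise ValueError("zero residual variance; emission model is degenerate")

    h_sd = Hvec.std()
    if h_sd < 1e-8:
        alpha = np.zeros(m)
    else:
        # slope of log eps^2 on 2H recovers alpha_k
        D = np.column_stack([np.ones(len(Hvec)), 2.0 * Hvec])
        logE2 = np.log(E ** 2 + 1e-12)
        coefs, *_ = np.linalg.lstsq(D, logE2, rcond=None)
        alpha = coefs[1]
    # H-standardized second moment recovers sigma (bias-free, unlike the
    # log-scale intercept which absorbs E[log chi2_1])
    scale = np.exp(alpha[None, :] * Hvec[:, None])
    sigma = np.sqrt((E / scale).var(axis=0) + ((E / scale).mean(axis=0)) ** 2)
    sigma = np.maximum(sigma, 1e-8)

    Zstd = E / (sigma[None, :] * scale)
    rho = nearest_correlation(np.corrcoef(Zstd.T)) if m > 1 else np.ones((1, 1))

    num = np.zeros(m)
    den = np.zeros(m)
    row0 = 0
    for pid in pids_order:
        T = series.T(pid)
        z = Zstd[row0:row0 + T]
        row0 += T
        if T > 1:
            num += (z[1:] * z[:-1]).sum(axis=0)
            den += (z[:-1] ** 2).sum(axis=0)
    tau = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    tau = np.clip(tau, -_TAU_CLIP, _TAU_CLIP)

    gp = GPParams(
        **mus, sigma=sigma, alpha=np.asarray(alpha, float), tau=tau,
        rho=rho, r=float(r), se=mu_se,
    )
    gp.validate()
    return gp


# ---------------------------------------------------------------------------
# Hyperparameter tuning and the supervised / semi-supervised estimators

DEFAULT_R_GRID = np.round(np.arange(0.0, 1.01, 0.1), 10)


def tune_r(
    series: EmbeddingSeries,
    labels: LabelSeries,
    r_grid=None,
    n_folds: int = 5,
    seed: int = 0,
) -> float:
    """Choose the AR dampener r by patient-level CV maximizing AUROC.

    Chain and emission parameters do not depend on r, so each training fold
    is fit once and scored at every grid value; ties break toward smaller r.
    """
    from sklearn.metrics import roc_auc_score

    from .weights import _patient_folds

    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, float)
    if len(r_grid) == 1:
        return float(r_grid[0])
    folds = _patient_folds(labels, n_folds, seed)
    scores = np.zeros(len(r_grid))
    counts = np.zeros(len(r_grid))
    for train_ids, test_ids in folds:
        y_true = np.concatenate([np.asarray(labels.y[pid]) for pid in test_ids])
        if y_true.min() == y_true.max():
            logger.warning("held-out fold has one class; skipped")
            continue
        try:
            mk = fit_markov({pid: labels.y[pid] for pid in train_ids}, series.H)
            gp = fit_gp(series.subset(train_ids),
                        {pid: labels.y[pid] for pid in train_ids})
        except ValueError as exc:
            logger.warning("fold fit failed (%s); skipped", exc)
            continue
        for ri, r in enumerate(r_grid):
            gp_r = GPParams(**{k: getattr(gp, k) for k in
                               _MU_NAMES}, sigma=gp.sigma, alpha=gp.alpha,
                            tau=gp.tau, rho=gp.rho, r=float(r))
            model = MGPModel(markov=mk, gp=gp_r)
            post = predict(model, series.subset(test_ids))
            scores[ri] += roc_auc_score(y_true, post.pooled(test_ids))
            counts[ri] += 1
    if counts.max() == 0:
        logger.warning("all CV folds failed; defaulting to r = 0")
        return 0.0
    mean_scores = scores / np.maximum(counts, 1)
    best = int(np.argmax(mean_scores))  # argmax returns first max -> smaller r
    return float(r_grid[best])


def fit_supervised(
    series: EmbeddingSeries,
    labels: LabelSeries,
    r: float | None = None,
    r_grid=None,
    n_folds: int = 5,
    seed: int = 0,
) -> MGPModel:
    """Tune r (unless given) and fit the MGP on hard labels."""
    labels.validate()
    if r is None:
        r = tune_r(series, labels, r_grid=r_grid, n_folds=n_folds, seed=seed)
    hard = {pid: labels.y[pid] for pid in labels.patient_ids}
    mk = fit_markov(hard, series.H)
    gp = fit_gp(series.subset(labels.patient_ids), hard, r=r)
    return MGPModel(markov=mk, gp=gp, provenance="supervised")


def em_one_step(
    model: MGPModel,
    series: EmbeddingSeries,
    labels: LabelSeries,
    soft: bool = True,
    n_iter: int = 1,
) -> MGPModel:
    """One EM iteration: impute unlabeled states, refit on the union.

    The E-step scores every unlabeled patient with the supervised model's
    marginal posteriors; the M-step refits chain and emission on hard labels
    (weight 1) plus the imputed soft labels.  ``soft=False`` thresholds the
    posteriors at 0.5 instead.  ``n_iter`` defaults to a single step: the
    supervised initializer is consistent, so one step suffices and limits
    the influence of the unlabeled pool.
    """
    labeled = set(labels.patient_ids)
    unlabeled = [pid for pid in series.patient_ids if pid not in labeled]
    if not unlabeled:
        return model
    hard = {pid: labels.y[pid] for pid in labels.patient_ids}
    current = model
    for _ in range(n_iter):
        post = predict(current, series.subset(unlabeled))
        imputed = {pid: post.pi[pid] for pid in unlabeled}
        if not soft:
            imputed = {pid: (v >= 0.5).astype(float) for pid, v in imputed.items()}
        mk = fit_markov(hard, series.H, posteriors=imputed)
        gp = fit_gp(series, hard, posteriors=imputed, r=current.gp.r)
        current = MGPModel(markov=mk, gp=gp, provenance="one-step-em")
    return current


# ---------------------------------------------------------------------------
# Serialization


def model_to_dict(model: MGPModel) -> dict:
    gp = model.gp
    return {
        "markov": model.markov.as_dict(),
        "gp": {
            **{k: getattr(gp, k).tolist() for k in _MU_NAMES},
            "sigma": gp.sigma.tolist(),
            "alpha": gp.alpha.tolist(),
            "tau": gp.tau.tolist(),
            "rho": gp.rho.tolist(),
            "r": gp.r,
        },
        "m": gp.m,
        "provenance": model.provenance,
    }


def model_from_dict(d: dict) -> MGPModel:
    mk = MarkovParams(**d["markov"])
    g = d["gp"]
    gp = GPParams(
        **{k: np.asarray(g[k], float) for k in _MU_NAMES},
        sigma=np.asarray(g["sigma"], float),
        alpha=np.asarray(g["alpha"], float),
        tau=np.asarray(g["tau"], float),
        rho=np.asarray(g["rho"], float),
        r=float(g["r"]),
    )
    return MGPModel(markov=mk, gp=gp, provenance=d.get("provenance", "supervised"))
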