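"""Discriminant feature weighting and patient-timepoint embeddings.

Each bin's count vector is compressed to a dense m-dimensional embedding

    X_{i,t} = C_{i,t} diag(W) V',

where V (m x p) holds pre-trained feature embeddings and W is a sparse
diagonal weight vector learned by maximizing the L1-penalized linear
discriminant objective

    D(W) = (mu_1 - mu_0)' Sigma_X^{-1} (mu_1 - mu_0) - lambda ||W||_1,

with mu_y the label-stratified embedding means and Sigma_X the pooled
within-class covariance over labeled patient-bins.  The first ("anchor")
feature is a known highly predictive code whose weight is pinned at 1 for
identifiability; all other weights are free in sign and shrunk toward zero
by the L1 term.  Optimization is proximal gradient ascent (soft-thresholding
the non-anchor coordinates) with backtracking line search; the penalty
lambda is chosen by patient-level five-fold cross-validation maximizing the
held-out objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_data import FeaturePanel, LabelSeries

logger = logging.getLogger(__name__)

_RIDGE_COND = 1e10
_RIDGE_SCALE = 1e-6


@dataclass
class EmbeddingModel:
    """Learned diagonal feature weights plus class moments at the optimum."""

    V: np.ndarray                 # m x p
    W: np.ndarray                 # length p, W[anchor_index] == 1
    anchor_index: int
    lambda_l1: float
    mu0: np.ndarray
    mu1: np.ndarray
    Sigma_X: np.ndarray
    objective_value: float
    cv_path: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.V.shape[0]


@dataclass
class EmbeddingSeries:
    """Per-patient T_i x m embedding matrices, with utilization carried along."""

    X: dict
    H: dict

    @property
    def patient_ids(self) -> list:
        return list(self.X.keys())

    def T(self, pid) -> int:
        return self.X[pid].shape[0]

    def subset(self, patient_ids) -> "EmbeddingSeries":
        return EmbeddingSeries(
            X={pid: self.X[pid] for pid in patient_ids},
            H={pid: self.H[pid] for pid in patient_ids},
        )


def compute_patient_embeddings(
    panel: FeaturePanel, W: np.ndarray, V: np.ndarray
) -> EmbeddingSeries:
    """Map every patient-bin count vector to X = C diag(W) V'."""
    W = np.asarray(W, dtype=float)
    V = np.asarray(V, dtype=float)
    if V.shape[1] != panel.p or W.shape[0] != panel.p:
        raise ValueError(
            f"dimension mismatch: panel has p={panel.p}, V is {V.shape}, "
            f"W has length {W.shape[0]}"
        )
    M = (V * W).T  # p x m; rows scaled by W
    X = {pid: panel.C[pid] @ M for pid in panel.patient_ids}
    return EmbeddingSeries(X=X, H=dict(panel.H))


# ---------------------------------------------------------------------------
# Discriminant objective.  Because X is linear in W, the class moments of X
# reduce to count-space moments:  mu_1 - mu_0 = M'(cbar_1 - cbar_0) and
# Sigma_X = M' S_C M with M = diag(W) V' and S_C the pooled within-class
# covariance of C.  S_C and the class mean difference are computed once.


def _count_moments(panel: FeaturePanel, labels: LabelSeries, patient_ids=None):
    pids = patient_ids if patient_ids is not None else labels.patient_ids
    Cs, ys = [], []
    for pid in pids:
        Cs.append(panel.C[pid])
        ys.append(np.asarray(labels.y[pid]))
    C = np.vstack(Cs)
    y = np.concatenate(ys)
    if not (y == 0).any() or not (y == 1).any():
        raise ValueError("both classes must be present among labeled bins")
    cbar0 = C[y == 0].mean(axis=0)
    cbar1 = C[y == 1].mean(axis=0)
    resid = C - np.where(y[:, None] == 1, cbar1, cbar0)
    S_C = resid.T @ resid / len(y)
    return cbar1 - cbar0, S_C


def _mahalanobis(delta_C, S_C, V, W):
    """Unpenalized term and its gradient in W."""
    d = V @ (W * delta_C)                       # m-vector
    VW = V * W                                  # m x p
    Sigma_X = VW @ S_C @ VW.T
    Sigma_inv_d = _solve_spd(Sigma_X, d)
    f = float(d @ Sigma_inv_d)
    g = V.T @ Sigma_inv_d                       # p-vector, g_j = V_j' u
    grad = 2.0 * g * delta_C - 2.0 * g * (S_C @ (W * g))
    return f, grad, Sigma_X


_warned_ill_conditioned = False


def _solve_spd(A, b):
    global _warned_ill_conditioned
    A = np.asarray(A)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > _RIDGE_COND:
        ridge = _RIDGE_SCALE * np.trace(A) / A.shape[0]
        log = logger.debug if _warned_ill_conditioned else logger.warning
        log("pooled covariance ill-conditioned (cond=%.2e); adding ridge %.2e",
            cond, ridge)
        _warned_ill_conditioned = True
        A = A + ridge * np.eye(A.shape[0])
    return np.linalg.solve(A, b)


def discriminant_objective(
    W: np.ndarray,
    embeddings_or_panel,
    labels: LabelSeries,
    lambda_l1: float,
    V: np.ndarray | None = None,
) -> float:
    """Evaluate D(W) on labeled bins.

    Accepts either a FeaturePanel together with V, or a precomputed
    EmbeddingSeries (in which case W enters only through the penalty and the
    series is taken as the embedding at that W).
    """
    W = np.asarray(W, dtype=float)
    if isinstance(embeddings_or_panel, FeaturePanel):
        if V is None:
            raise ValueError("V required when passing a FeaturePanel")
        delta_C, S_C = _count_moments(embeddings_or_panel, labels)
        f, _, _ = _mahalanobis(delta_C, S_C, np.asarray(V, float), W)
        return f - lambda_l1 * float(np.abs(W).sum())
    series: EmbeddingSeries = embeddings_or_panel
    Xs, ys = [], []
    for pid in labels.patient_ids:
        Xs.append(series.X[pid])
        ys.append(np.asarray(labels.y[pid]))
    X = np.vstack(Xs)
    y = np.concatenate(ys)
    if not (y == 0).any() or not (y == 1).any():
        raise ValueError("both classes must be present among labeled bins")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    resid = X - np.where(y[:, None] == 1, mu1, mu0)
    Sigma_X = resid.T @ resid / len(y)
    d = mu1 - mu0
    f = float(d @ _solve_spd(Sigma_X, d))
    return f - lambda_l1 * float(np.abs(W).sum())


# ---------------------------------------------------------------------------
# Proximal gradient ascent


def _optimize_W(
    delta_C,
    S_C,
    V,
    anchor_index: int,
    lambda_l1: float,
    W0=None,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    p = V.shape[1]
    W = np.ones(p) if W0 is None else np.asarray(W0, float).copy()
    W[anchor_index] = 1.0

    def penalized(Wv):
        f, _, _ = _mahalanobis(delta_C, S_C, V, Wv)
        return f - lambda_l1 * np.abs(Wv).sum()

    def prox_step(Wv, grad, s):
        # ascent step then soft-threshold; anchor coordinate pinned, not shrunk
        Wn = Wv + s * grad
        Wn = np.sign(Wn) * np.maximum(np.abs(Wn) - s * lambda_l1, 0.0)
        Wn[anchor_index] = 1.0
        return Wn

    obj = penalized(W)
    _, grad, _ = _mahalanobis(delta_C, S_C, V, W)
    step = 1.0 / max(np.abs(grad).max(), 1.0)
    prev_W = prev_grad = None
    converged = False
    slow = 0
    for _ in range(max_iter):
        if prev_W is not None:
            # Barzilai-Borwein spectral step, clipped for safety
            dw = W - prev_W
            dg = grad - prev_grad
            denom = abs(float(dw @ dg))
            if denom > 1e-30:
                step = float(np.clip(float(dw @ dw) / denom, 1e-12, 1e6))
        s = step
        accepted = False
        while s >= 1e-14:
            Wnew = prox_step(W, grad, s)
            obj_new = penalized(Wnew)
            if obj_new > obj:  # strict ascent only
                accepted = True
                break
            s *= 0.5
        if not accepted:
            converged = True  # no ascent step found: stationary
            break
        rel = (obj_new - obj) / max(abs(obj), 1e-12)
        prev_W, prev_grad = W, grad
        W, obj = Wnew, obj_new
        _, grad, _ = _mahalanobis(delta_C, S_C, V, W)
        # BB steps progress unevenly: require sustained stalling, not one
        # slow iteration, before declaring convergence
        slow = slow + 1 if rel < tol else 0
        if slow >= 5:
            converged = True
            break
    if not converged:
        logger.warning("weight optimization hit the iteration cap; "
                       "returning the best iterate")
    return W, obj


def fit_weights(
    panel: FeaturePanel,
    labels: LabelSeries,
    V: np.ndarray,
    anchor_feature,
    lambda_grid=None,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EmbeddingModel:
    """Fit the sparse diagonal weights W on the labeled panel.

    lambda is selected by patient-level ``n_folds``-fold cross-validation
    maximizing the held-out discriminant objective (moments recomputed on the
    held-out fold); ties break toward the larger (sparser) lambda.  Folds are
    stratified by each patient's any-event indicator.
    """
    V = np.asarray(V, dtype=float)
    if anchor_feature not in panel.feature_ids:
        raise ValueError(f"anchor feature {anchor_feature!r} not in panel")
    anchor_index = panel.feature_ids.index(anchor_feature)
    labeled_pids = labels.patient_ids
    if not any(np.asarray(labels.y[pid]).any() for pid in labeled_pids):
        raise ValueError("no labeled positives")

    delta_C, S_C = _count_moments(panel, labels)
    f0, _, _ = _mahalanobis(delta_C, S_C, V, np.ones(panel.p))
    if lambda_grid is None:
        lambda_grid = f0 * np.logspace(-4, 1, 20)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))

    cv_scores = np.zeros(len(lambda_grid))
    if len(lambda_grid) > 1:
        folds = _patient_folds(labels, n_folds, seed)
        for train_ids, test_ids in folds:
            try:
                dC_tr, SC_tr = _count_moments(panel, labels, train_ids)
                dC_te, SC_te = _count_moments(panel, labels, test_ids)
            except ValueError:
                logger.warning("CV fold lacks a class; skipped")
                continue
            W_warm = None
            for li in range(len(lambda_grid) - 1, -1, -1):  # warm-start from sparse end
                W_l, _ = _optimize_W(
                    dC_tr, SC_tr, V, anchor_index, lambda_grid[li],
                    W0=W_warm, max_iter=max_iter, tol=tol,
                )
                W_warm = W_l
                f_te, _, _ = _mahalanobis(dC_te, SC_te, V, W_l)
                cv_scores[li] += f_te - lambda_grid[li] * np.abs(W_l).sum()
        # ties toward larger lambda
        best = len(lambda_grid) - 1 - int(np.argmax(cv_scores[::-1]))
    else:
        best = 0
    lam = float(lambda_grid[best])

    W, obj = _optimize_W(
        delta_C, S_C, V, anchor_index, lam, max_iter=max_iter, tol=tol
    )
    f, _, Sigma_X = _mahalanobis(delta_C, S_C, V, W)
    d = V @ (W * delta_C)
    series = compute_patient_embeddings(panel, W, V)
    Xs = np.vstack([series.X[pid] for pid in labeled_pids])
    ys = np.concatenate([np.asarray(labels.y[pid]) for pid in labeled_pids])
    return EmbeddingModel(
        V=V,
        W=W,
        anchor_index=anchor_index,
        lambda_l1=lam,
        mu0=Xs[ys == 0].mean(axis=0),
        mu1=Xs[ys == 1].mean(axis=0),
        Sigma_X=Sigma_X,
        objective_value=obj,
        cv_path={"lambda_grid": lambda_grid, "cv_scores": cv_scores},
    )


def _patient_folds(labels: LabelSeries, n_folds: int, seed: int):
    """Patient-level folds stratified by the any-event indicator."""
    from sklearn.model_selection import StratifiedKFold

    pids = np.array(labels.patient_ids, dtype=object)
    strata = np.array([int(np.asarray(labels.y[pid]).any()) for pid in pids])
    n_folds = min(n_folds, *np.bincount(strata, minlength=2)[np.bincount(strata, minlength=2) > 0])
    n_folds = max(2, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    out = []
    for train_idx, test_idx in skf.split(pids, strata):
        out.append((list(pids[train_idx]), list(pids[test_idx])))
    return out


def screen_features_by_cosine(
    V: np.ndarray, feature_ids, target_feature, threshold: float = 0.1
):
    """Retain features whose embedding cosine with the target is >= threshold.

    The default threshold of 0.1 matches the screening rule used to select
    candidate codes around a sentinel diagnosis code.  Zero-norm embedding
    columns are treated as similarity 0; the target itself is always kept.
    """
    V = np.asarray(V, dtype=float)
    j = list(feature_ids).index(target_feature)
    target = V[:, j]
    tnorm = np.linalg.norm(target)
    if tnorm == 0:
        raise ValueError("target feature has a zero embedding column")
    norms = np.linalg.norm(V, axis=0)
    if (norms == 0).any():
        warnings.warn("zero-norm embedding columns treated as cosine 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(norms > 0, (target @ V) / (tnorm * norms), 0.0)
    keep = [f for f, c in zip(feature_ids, cos) if c >= threshold]
    if target_feature not in keep:
        keep.append(target_feature)
    return keep
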