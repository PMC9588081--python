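"""Adaptive blending of supervised and semi-supervised posteriors.

The final prediction is the convex combination

    p_hat = alpha * p_semisup + (1 - alpha) * p_sup,

with alpha chosen by patient-level five-fold cross-validation maximizing
the pooled AUROC of bin-level predictions.  The semi-supervised member
gains efficiency from the unlabeled pool when the generative model is
right; the supervised member is the safe fallback under misspecification,
and the adaptive weight interpolates between the two.  First-event CDFs
are blended with the same alpha, each member contributing its own joint
all-zero-path CDF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import mgp
from .io_data import LabelSeries
from .weights import EmbeddingSeries, _patient_folds

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class EnsembleModel:
    alpha: float
    cv_grid: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_auroc: np.ndarray = field(default_factory=lambda: np.array([]))
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def member_auroc(self) -> dict:
        """CV AUROC of the pure members (grid endpoints), when tuned."""
        out = {}
        for name, a in (("sup", 0.0), ("semisup", 1.0)):
            hit = np.isclose(self.cv_grid, a)
            if hit.any():
                out[name] = float(self.cv_auroc[hit][0])
        return out


def combine(
    p_sup: mgp.PosteriorSeries, p_semisup: mgp.PosteriorSeries, alpha: float
) -> mgp.PosteriorSeries:
    """Elementwise convex combination of two aligned posterior series."""
    if set(p_sup.patient_ids) != set(p_semisup.patient_ids):
        raise ValueError("posterior series are not aligned on the same patients")
    pi, F, ll = {}, {}, {}
    for pid in p_sup.patient_ids:
        if len(p_sup.pi[pid]) != len(p_semisup.pi[pid]):
            raise ValueError(f"posterior series misaligned for patient {pid!r}")
        pi[pid] = alpha * p_semisup.pi[pid] + (1 - alpha) * p_sup.pi[pid]
        F[pid] = alpha * p_semisup.F[pid] + (1 - alpha) * p_sup.F[pid]
        ll[pid] = alpha * p_semisup.loglik[pid] + (1 - alpha) * p_sup.loglik[pid]
    return mgp.PosteriorSeries(pi=pi, F=F, loglik=ll)


def tune_alpha(
    labeled_series: EmbeddingSeries,
    labels: LabelSeries,
    full_series: EmbeddingSeries,
    r: float,
    alpha_grid=None,
    n_folds: int = 5,
    seed: int = 0,
    soft: bool = True,
) -> EnsembleModel:
    """Choose the blending weight by honest patient-level CV.

    Within each fold both members are refit from scratch on the training
    patients (the semi-supervised member additionally re-runs its one EM
    step against the unlabeled pool in ``full_series``), then blended
    predictions are scored on the held-out patients.  Ties in pooled AUROC
    break toward alpha = 0.5; identical members return 0.5 with a note.
    The dampener ``r`` is taken as given (tuned upstream).
    """
    from sklearn.metrics import roc_auc_score

    grid = DEFAULT_ALPHA_GRID if alpha_grid is None else np.asarray(alpha_grid, float)
    if len(grid) == 1:
        return EnsembleModel(alpha=float(grid[0]), cv_grid=grid,
                             cv_auroc=np.full(1, np.nan), note="single-value grid")

    folds = _patient_folds(labels, n_folds, seed)
    y_all, sup_all, semi_all = [], [], []
    for train_ids, test_ids in folds:
        y_true = np.concatenate([np.asarray(labels.y[pid]) for pid in test_ids])
        train_labels = LabelSeries(y={pid: labels.y[pid] for pid in train_ids})
        try:
            sup = mgp.fit_supervised(
                labeled_series.subset(train_ids), train_labels, r=r
            )
            semi = mgp.em_one_step(sup, full_series, train_labels, soft=soft)
        except ValueError as exc:
            logger.warning("alpha-CV fold failed (%s); skipped", exc)
            continue
        held = labeled_series.subset(test_ids)
        y_all.append(y_true)
        sup_all.append(mgp.predict(sup, held).pooled(test_ids))
        semi_all.append(mgp.predict(semi, held).pooled(test_ids))

    if not y_all:
        logger.warning("all alpha-CV folds failed; defaulting to alpha = 0.5")
        return EnsembleModel(alpha=0.5, note="cv-failed")
    return select_alpha(
        np.concatenate(y_all), np.concatenate(sup_all),
        np.concatenate(semi_all), grid,
    )


def select_alpha(y, p_sup, p_semi, grid) -> EnsembleModel:
    """Pick the grid alpha maximizing pooled AUROC; ties go toward 0.5."""
    from sklearn.metrics import roc_auc_score

    grid = np.asarray(grid, float)
    if np.allclose(p_sup, p_semi, atol=1e-12):
        return EnsembleModel(
            alpha=0.5, cv_grid=grid,
            cv_auroc=np.full(len(grid), roc_auc_score(y, p_sup)),
            note="identical members",
        )
    auroc = np.array([roc_auc_score(y, a * p_semi + (1 - a) * p_sup)
                      for a in grid])
    best = np.flatnonzero(auroc >= auroc.max() - 1e-12)
    alpha = float(grid[best[np.argmin(np.abs(grid[best] - 0.5))]])
    return EnsembleModel(alpha=alpha, cv_grid=grid, cv_auroc=auroc)
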