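"""End-to-end orchestration: weights -> supervised MGP -> one-step EM -> blend.

This is the library-level entry point the command-line interface wraps.
Given a feature panel (labeled + unlabeled patients), a label series for
the labeled subset, a pre-trained embedding matrix and an anchor feature,
``fit`` learns every stage and returns a bundle that can score any panel
sharing the same feature set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import ensemble as ens
from . import mgp, weights
from .io_data import FeaturePanel, LabelSeries

logger = logging.getLogger(__name__)


@dataclass
class SAMGEPFit:
    embedding: weights.EmbeddingModel
    supervised: mgp.MGPModel
    semisupervised: mgp.MGPModel
    blend: ens.EnsembleModel
    anchor_feature: object
    seed: int

    def predict(self, panel: FeaturePanel) -> mgp.PosteriorSeries:
        """Score a panel: embeddings, both members, blended posteriors."""
        if list(panel.feature_ids) != list(self._feature_ids):
            raise ValueError("panel feature set does not match the fitted model")
        series = weights.compute_patient_embeddings(
            panel, self.embedding.W, self.embedding.V
        )
        p_sup = mgp.predict(self.supervised, series)
        p_semi = mgp.predict(self.semisupervised, series)
        return ens.combine(p_sup, p_semi, self.blend.alpha)

    _feature_ids: list = None  # set by fit()


def fit(
    panel: FeaturePanel,
    labels: LabelSeries,
    V: np.ndarray,
    anchor_feature,
    lambda_grid=None,
    r: float | None = None,
    r_grid=None,
    alpha_grid=None,
    soft_em: bool = True,
    em_iterations: int = 1,
    seed: int = 0,
) -> SAMGEPFit:
    """Fit the full pipeline on a panel whose labeled subset is ``labels``."""
    labeled_ids = [pid for pid in labels.patient_ids if pid in panel.raw]
    if len(labeled_ids) != len(labels.patient_ids):
        missing = set(labels.patient_ids) - set(panel.raw)
        raise ValueError(f"labels reference patients missing from panel: {sorted(missing)}")
    labeled_panel = panel.subset(labeled_ids)

    logger.info("stage 1/4: discriminant feature weights (p=%d, m=%d)",
                panel.p, V.shape[0])
    emb = weights.fit_weights(
        labeled_panel, labels, V, anchor_feature,
        lambda_grid=lambda_grid, seed=seed,
    )
    series_all = weights.compute_patient_embeddings(panel, emb.W, emb.V)
    series_lab = series_all.subset(labeled_ids)

    logger.info("stage 2/4: supervised MGP (r tuning: %s)",
                "fixed" if r is not None else "5-fold CV")
    sup = mgp.fit_supervised(series_lab, labels, r=r, r_grid=r_grid, seed=seed)
    logger.info("selected r = %.2f", sup.gp.r)

    logger.info("stage 3/4: one-step EM over %d unlabeled patients",
                len(series_all.patient_ids) - len(labeled_ids))
    semi = mgp.em_one_step(sup, series_all, labels, soft=soft_em,
                           n_iter=em_iterations)

    logger.info("stage 4/4: adaptive blending weight")
    blend = ens.tune_alpha(series_lab, labels, series_all, r=sup.gp.r,
                           alpha_grid=alpha_grid, seed=seed, soft=soft_em)
    logger.info("selected alpha = %.2f", blend.alpha)

    out = SAMGEPFit(
        embedding=emb, supervised=sup, semisupervised=semi, blend=blend,
        anchor_feature=anchor_feature, seed=seed,
    )
    out._feature_ids = list(panel.feature_ids)
    return out
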