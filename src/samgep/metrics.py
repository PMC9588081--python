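"""Evaluation of longitudinal phenotype-state predictions.

Bin-level discrimination is summarized by the rank-based AUROC and by the
F1 score at a threshold chosen to achieve a fixed specificity (default
95%).  Trajectory-level accuracy is summarized by areas between observed
and predicted curves on the integer bin grid:

* ABC_count — area between the observed all-event counting process
  N_i(t) = sum_{k<=t} Y_k (1 - Y_{k-1}) and the predicted counting process
  N_hat_i(t) = sum_{k<=t} I(pi_hat_{i,k} >= c), where the cutoff c matches
  the flagged fraction of labeled bins to the labeled prevalence;
* ABC_cdf — area between the observed first-event indicator
  F_i(t) = 1 - prod_{k<=t}(1 - Y_k) and the predicted CDF
  F_hat_i(t) = 1 - prod_{k<=t}(1 - lambda_hat_{i,k}).  Without censoring
  this equals the mean absolute event-time error.

Raw areas are reported as their percent decrease below a prevalence-only
null model (the "gain"); the null's gain against itself is zero by
construction.  Curves are unit-width step functions, areas are averaged
over patients, and bootstrap intervals resample patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io_data import FeaturePanel, LabelSeries, counting_process, first_event_cdf


@dataclass
class EvalReport:
    auc: float
    f1: float
    threshold: float
    specificity_target: float
    abc_cdf: float
    abc_count: float
    abc_cdf_null: float
    abc_count_null: float
    abc_cdf_gain: float
    abc_count_gain: float
    counting_cutoff: float
    feature_cloud: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "auc", "f1", "threshold", "specificity_target", "abc_cdf",
            "abc_count", "abc_cdf_null", "abc_count_null", "abc_cdf_gain",
            "abc_count_gain", "counting_cutoff",
        )}
        d["feature_cloud"] = dict(self.feature_cloud)
        return d


def auc(labels, scores) -> float:
    """Rank-based AUROC with midranks for ties."""
    y = np.asarray(labels, float)
    s = np.asarray(scores, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def f1_at_specificity(labels, scores, specificity: float = 0.95):
    """F1 at the smallest threshold achieving the target specificity.

    A bin is called positive when its score is >= the threshold;
    specificity is evaluated on the supplied data.  Returns (f1, threshold).
    """
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    neg = s[y == 0]
    if len(neg) == 0:
        raise ValueError("specificity undefined without negatives")
    candidates = np.unique(s)
    threshold = None
    for c in candidates:
        if (neg < c).mean() >= specificity:
            threshold = float(c)
            break
    if threshold is None:
        warnings.warn("target specificity unattainable; F1 set to 0")
        return 0.0, float(np.nextafter(s.max(), np.inf))
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    f1 = 2 * tp / (2 * tp + fp + fn) if tp > 0 else 0.0
    return float(f1), threshold


def counting_cutoff(labels, scores) -> float:
    """Cutoff c matching the flagged fraction to the labeled prevalence.

    Implemented as the (1 - prevalence)-quantile of the labeled scores with
    a left-continuous convention: exactly round(prevalence * #bins) bins are
    flagged up to ties.  Zero prevalence returns a cutoff above all scores.
    """
    y = np.asarray(labels, int)
    s = np.asarray(scores, float)
    if len(s) == 0:
        raise ValueError("labeled predictions are empty")
    k = int(round(y.mean() * len(y)))
    if k == 0:
        return float(np.nextafter(s.max(), np.inf))
    return float(np.sort(s)[::-1][k - 1])


def predicted_counting_process(pi: np.ndarray, c: float) -> np.ndarray:
    """N_hat(t) = cumulative count of bins whose posterior meets the cutoff."""
    return np.cumsum(np.asarray(pi, float) >= c)


def cdf_from_hazards(lam: np.ndarray) -> np.ndarray:
    """F_hat(t) = 1 - prod_{k<=t}(1 - lambda_hat_k)."""
    return 1.0 - np.cumprod(1.0 - np.asarray(lam, float))


def _area(obs, pred) -> float:
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValueError("curve length mismatch")
    return float(np.abs(obs - pred).sum())


def abc_count(N_obs, N_pred) -> float:
    """Mean (over patients) area between counting-process curves.

    Accepts aligned dicts keyed by patient, or a single pair of curves.
    """
    if isinstance(N_obs, dict):
        return float(np.mean([_area(N_obs[pid], N_pred[pid]) for pid in N_obs]))
    return _area(N_obs, N_pred)


def abc_cdf(F_obs, F_pred) -> float:
    """Mean (over patients) area between first-event CDF curves."""
    if isinstance(F_obs, dict):
        return float(np.mean([_area(F_obs[pid], F_pred[pid]) for pid in F_obs]))
    return _area(F_obs, F_pred)


def abc_gains(method_abc: float, null_abc: float) -> float:
    """Percent decrease of a method's ABC below the null model's."""
    if null_abc <= 0:
        raise ValueError("null ABC must be positive for a gain to be defined")
    return float((null_abc - method_abc) / null_abc)


def null_model(labels: LabelSeries, T: dict) -> dict:
    """Prevalence-at-each-bin predictions for a target cohort.

    pi_hat_{i,k} is the labeled prevalence of Y = 1 among labeled patients
    with T_i >= k; hazards equal pi_hat.  Bin indices beyond the labeled
    support carry the last prevalence forward.
    """
    max_T = max(len(labels.y[pid]) for pid in labels.patient_ids)
    prev = np.empty(max_T)
    for k in range(max_T):
        vals = [labels.y[pid][k] for pid in labels.patient_ids
                if len(labels.y[pid]) > k]
        prev[k] = float(np.mean(vals))
    out = {}
    for pid, Ti in T.items():
        if Ti > max_T:
            warnings.warn("bin index beyond labeled support; carrying prevalence forward")
            pi = np.concatenate([prev, np.full(Ti - max_T, prev[-1])])
        else:
            pi = prev[:Ti].copy()
        out[pid] = {"pi": pi, "F": cdf_from_hazards(pi)}
    return out


def population_curves(predictions: dict, n_boot: int = 100, seed: int = 0):
    """Pointwise mean F_hat(t) and N_hat(t) with percentile bootstrap CIs.

    At each bin the mean runs over patients still under observation
    (T_i >= t); the bootstrap resamples patients to respect within-patient
    dependence.  Returns a dict with keys F, N, F_ci, N_ci.
    """
    pids = list(predictions.keys())
    if not pids:
        raise ValueError("empty cohort")
    max_T = max(len(predictions[pid]["F"]) for pid in pids)

    def _mean_curves(sample):
        F = np.full(max_T, np.nan)
        N = np.full(max_T, np.nan)
        for t in range(max_T):
            fs = [predictions[pid]["F"][t] for pid in sample
                  if len(predictions[pid]["F"]) > t]
            ns = [predictions[pid]["N"][t] for pid in sample
                  if len(predictions[pid]["N"]) > t]
            if fs:
                F[t] = np.mean(fs)
                N[t] = np.mean(ns)
        return F, N

    F, N = _mean_curves(pids)
    rng = np.random.default_rng(seed)
    boots_F = np.empty((n_boot, max_T))
    boots_N = np.empty((n_boot, max_T))
    for b in range(n_boot):
        sample = rng.choice(pids, size=len(pids), replace=True)
        boots_F[b], boots_N[b] = _mean_curves(sample)
    return {
        "F": F,
        "N": N,
        "F_ci": np.nanpercentile(boots_F, [2.5, 97.5], axis=0),
        "N_ci": np.nanpercentile(boots_N, [2.5, 97.5], axis=0),
    }


def feature_cloud_weights(W: np.ndarray, panel: FeaturePanel) -> dict:
    """w_j = W_j times the empirical SD of feature j's log1p counts."""
    C = np.vstack([panel.C[pid] for pid in panel.patient_ids])
    sd = C.std(axis=0)
    return {f: float(wj * s) for f, wj, s in zip(panel.feature_ids, W, sd)}


def build_prediction_series(
    pi: dict, c: float, F: dict | None = None
) -> dict:
    """Assemble per-patient prediction curves from marginal posteriors.

    ``F`` may come from a joint model's all-zero-path probabilities; when
    absent, hazards are taken equal to the marginals (independence across
    bins), as appropriate for methods that only predict marginals.
    """
    out = {}
    for pid, p in pi.items():
        p = np.asarray(p, float)
        Fp = np.asarray(F[pid], float) if F is not None else cdf_from_hazards(p)
        out[pid] = {"pi": p, "F": Fp, "N": predicted_counting_process(p, c)}
    return out


def evaluate(
    labels: LabelSeries,
    pi: dict,
    F: dict | None = None,
    cutoff_labels: LabelSeries | None = None,
    cutoff_pi: dict | None = None,
    specificity: float = 0.95,
    feature_cloud: dict | None = None,
) -> EvalReport:
    """Full evaluation of predictions against observed label series.

    The counting cutoff and the null model are derived from
    ``cutoff_labels``/``cutoff_pi`` (the labeled set used for training) when
    given, else from the evaluation labels themselves.
    """
    pids = labels.patient_ids
    y_pool = np.concatenate([np.asarray(labels.y[pid]) for pid in pids])
    s_pool = np.concatenate([np.asarray(pi[pid]) for pid in pids])

    cl = cutoff_labels if cutoff_labels is not None else labels
    cp = cutoff_pi if cutoff_pi is not None else pi
    yc = np.concatenate([np.asarray(cl.y[pid]) for pid in cl.patient_ids])
    sc = np.concatenate([np.asarray(cp[pid]) for pid in cl.patient_ids])
    c = counting_cutoff(yc, sc)

    preds = build_prediction_series(pi, c, F=F)
    T = {pid: len(labels.y[pid]) for pid in pids}
    null = null_model(cl, T)
    null_preds = build_prediction_series(
        {pid: null[pid]["pi"] for pid in pids}, counting_cutoff(yc, np.concatenate(
            [null_model(cl, {pid: len(cl.y[pid]) for pid in cl.patient_ids})[pid]["pi"]
             for pid in cl.patient_ids])),
        F={pid: null[pid]["F"] for pid in pids},
    )

    N_obs = {pid: counting_process(labels.y[pid]) for pid in pids}
    F_obs = {pid: first_event_cdf(labels.y[pid]) for pid in pids}

    a_cdf = abc_cdf(F_obs, {pid: preds[pid]["F"] for pid in pids})
    a_cnt = abc_count(N_obs, {pid: preds[pid]["N"] for pid in pids})
    n_cdf = abc_cdf(F_obs, {pid: null_preds[pid]["F"] for pid in pids})
    n_cnt = abc_count(N_obs, {pid: null_preds[pid]["N"] for pid in pids})

    f1, thr = f1_at_specificity(y_pool, s_pool, specificity)
    return EvalReport(
        auc=auc(y_pool, s_pool),
        f1=f1,
        threshold=thr,
        specificity_target=specificity,
        abc_cdf=a_cdf,
        abc_count=a_cnt,
        abc_cdf_null=n_cdf,
        abc_count_null=n_cnt,
        abc_cdf_gain=abc_gains(a_cdf, n_cdf) if n_cdf > 0 else 0.0,
        abc_count_gain=abc_gains(a_cnt, n_cnt) if n_cnt > 0 else 0.0,
        counting_cutoff=c,
        feature_cloud=feature_cloud or {},
    )
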