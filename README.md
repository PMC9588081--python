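# samgep

Semi-supervised prediction of **binary phenotype states over time** from
longitudinal coded health-record data — when gold-standard event-time labels
exist for only a small subset of patients.

## The problem

Coded records (diagnosis, procedure, prescription codes, NLP-extracted
concepts) are noisy surrogates for clinical events such as multiple-sclerosis
relapses or heart-failure onset. Chart-reviewed event timelines are accurate
but expensive, so typically only ~50–100 patients have per-month labels
`Y_{i,t} ∈ {0,1}` while thousands have unlabeled feature histories. This
package implements SAMGEP (semi-supervised adaptive Markov Gaussian
embedding process), which turns sparse high-dimensional count features into
per-bin phenotype-state probabilities, first-event cumulative-incidence
curves, and event counting processes.

## The model

For patient *i* with `T_i` monthly bins, `C_{i,t}` the log1p-transformed
count vector of *p* coded features, and `H_i = log(mean monthly encounter
count + 1)` a utilization covariate:

1. **Weighted patient-timepoint embeddings.** Given a pre-trained feature
   embedding matrix `V (m × p)`, each bin is compressed to
   `X_{i,t} = C_{i,t} diag(W) Vᵀ`. The sparse diagonal weights `W` maximize
   the L1-penalized discriminant objective
   `D(W) = (μ₁ − μ₀)ᵀ Σ_X⁻¹ (μ₁ − μ₀) − λ‖W‖₁`
   over labeled bins (proximal gradient ascent; the anchor feature's weight
   is pinned at 1; λ chosen by patient-level 5-fold CV).
2. **Markov Gaussian Process (MGP).** `Y_i` follows a two-state Markov chain
   with logistic initial/transition probabilities in `H_i`, `t`, and
   `log t`; given `Y_i`, the embedding series `X_i` is a Gaussian process
   whose mean is linear in state, utilization, and time, whose within-bin
   covariance scales with utilization, and whose residuals carry AR(1)
   memory `E[ε_t | ε_{t−1}] = r τ_k ε_{t−1,k}` with a dampener `r ∈ [0,1]`
   tuned by CV. Exact per-bin posteriors `π̂_{i,t} = P(Y_{i,t}=1 | X_i)` and
   joint no-event probabilities (hence `F̂_{i,t}`) come from a log-space
   forward–backward recursion.
3. **One-step EM.** The supervised fit imputes soft labels for the unlabeled
   pool; one M-step refit gives the semi-supervised estimator.
4. **Adaptive blend.** `p̂ = α p̂_semisup + (1 − α) p̂_sup` with α chosen by
   5-fold CV maximizing AUROC, guarding against misspecification.

A synthetic cohort generator (`samgep.simulate`) reproduces the reference
study design — 150 count features, mean 25 bins/patient, Markovian states
with configurable time dependence, lognormal or log-t(5) count marginals,
5–100 informative features — so the full pipeline is testable without
protected data.

## Worked example

```python
from samgep import pipeline, metrics
from samgep.io_data import LabelSeries
from samgep.simulate import SimConfig, simulate_cohort

cfg = SimConfig(N_unlabeled=400, n_labeled=100, seed=7)
panel, labels, V, truth = simulate_cohort(cfg)
labeled = LabelSeries(y={p: labels.y[p] for p in truth["labeled_ids"]})

fit = pipeline.fit(panel, labeled, V,
                   anchor_feature=truth["informative_ids"][0], seed=7)
print(f"selected r = {fit.supervised.gp.r:.1f}, alpha = {fit.blend.alpha:.2f}")
print(f"nonzero feature weights: {(fit.embedding.W != 0).sum()} of {panel.p}")

held_out = [p for p in panel.patient_ids if p not in truth["labeled_ids"]]
post = fit.predict(panel.subset(held_out))
post_lab = fit.predict(panel.subset(labeled.patient_ids))
report = metrics.evaluate(
    LabelSeries(y={p: labels.y[p] for p in held_out}), post.pi, F=post.F,
    cutoff_labels=labeled, cutoff_pi=post_lab.pi,
)
print(f"held-out AUC = {report.auc:.3f}, "
      f"F1 at 95% specificity = {report.f1:.3f}")
print(f"ABC_cdf gain vs prevalence null = {report.abc_cdf_gain:.3f}")
```

Output:

```
selected r = 0.9, alpha = 0.35
nonzero feature weights: 143 of 150
held-out AUC = 0.868, F1 at 95% specificity = 0.603
ABC_cdf gain vs prevalence null = 0.168
```

`r = 0.9` means the fitted emission keeps most of the estimated residual
autocorrelation; `alpha = 0.35` blends roughly one-third semi-supervised,
two-thirds supervised. The AUC is the bin-level discrimination of phenotype
states on 400 held-out patients; the ABC gain is the percent reduction in
area between observed and predicted first-event CDF curves relative to a
prevalence-only null model.

A command-line interface mirrors the library:

```bash
samgep simulate --seed 3 --out data/
samgep fit --panel data/panel.csv --labels data/labels.csv \
           --embedding data/embedding.csv --anchor F001 --out model/
samgep predict --panel data/panel.csv --embedding data/embedding.csv \
               --model-dir model/ --out pred.csv
samgep evaluate --predictions pred.csv --labels data/labels_all.csv \
                --out report.json
```

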