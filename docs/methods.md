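# Methods

## Data model

Events are tallied into consecutive, non-overlapping fixed-width bins
(default 30 days — a deterministic "month") anchored at each patient's
origin date, usually the first occurrence of the phenotype's sentinel code.
Bins are half-open `[start, end)` and 1-based, so `log t` is defined at the
first bin. Trailing bins after the last observed event are not fabricated;
a patient's panel ends at their last event bin unless an explicit follow-up
end date is supplied (how censoring should be encoded when observation
continues past the last event is otherwise ambiguous, so we require the
caller to say). The log1p transform is applied once at ingestion; every
downstream module consumes `C = log(1 + counts)`, never raw counts. The
utilization covariate is `H_i = log(mean monthly encounter count + 1)`.

## Feature weighting

`X_{i,t} = C_{i,t} diag(W) Vᵀ` with `V` an m × p pre-trained feature
embedding matrix. `W` maximizes
`D(W) = (μ₁−μ₀)ᵀ Σ_X⁻¹ (μ₁−μ₀) − λ‖W‖₁`, where μ_y and Σ_X are the
label-stratified means and pooled within-class covariance over labeled
patient-bins. Because X is linear in W, both moments reduce to count-space
moments (`Σ_X = Mᵀ S_C M` with `M = diag(W)Vᵀ`), so the objective and its
gradient cost O(p²) once `S_C` is cached.

Implementation notes:

* The nonsmooth L1 term is handled by proximal gradient ascent
  (soft-thresholding of non-anchor coordinates). The anchor feature's
  weight is reset to 1 after every iterate; other weights are free in sign.
* Step sizes are Barzilai–Borwein spectral steps safeguarded by a strict
  backtracking line search; convergence is declared after five consecutive
  relative improvements below 1e-6 (BB progress is uneven, so a single slow
  iteration is not evidence of stationarity), or when no ascent step exists.
  Cap: 500 iterations. The unpenalized objective can plateau along an
  infinite ray (it is scale-limited, not coercive), which is why the
  penalized problem is the one we solve along the λ path.
* Σ_X gets a ridge of 1e-6 × trace/m when its condition number exceeds
  1e10 (tiny labeled sets make near-singularity routine); the first such
  event is logged at WARNING, later ones at DEBUG.
* λ is chosen by 5-fold patient-level CV (folds stratified by the
  any-event indicator, seeded) maximizing the held-out objective with
  moments recomputed on the held-out fold; the default grid is 20
  log-spaced values over [1e-4, 10] × the unpenalized objective at W = 1.
  Ties break toward the larger (sparser) λ. The path is warm-started from
  the sparse end.
* Cosine screening retains features whose embedding-column cosine with a
  target feature is ≥ 0.1 (the screening rule's conventional threshold);
  zero-norm columns count as similarity 0.

## The latent-state model

Initial and transition probabilities:

    P(Y_1 = 1 | H)          = expit(λ_init + λ_H0 H)
    P(Y_t = 1 | y_{t-1}, H) = expit(λ_0 (1−y_{t-1}) + λ_1 y_{t-1}
                                    + λ_2 t + λ_3 log t + λ_H H),  t ≥ 2

`t` is the integer bin index — bins are the model's clock, not calendar
time. Emissions: mean linear in `{1−Y, Y, H, H·Y, t, log t, Y·t, Y·log t}`;
within-bin covariance `Σ(H) = D ρ D`, `D = diag(σ_k exp(α_k H))`; residual
memory `E[ε_t|ε_{t−1}] = r τ_k ε_{t−1,k}`.

The cross-component conditional law is under-determined by the univariate
AR(1) statement, so we adopt the unique stationary-compatible choice:
conditional mean shift `A ε_{t−1}` with `A = diag(r τ_k)` and conditional
covariance `Σ − A Σ A`. For heterogeneous τ and general ρ this matrix need
not be positive semidefinite, so it is projected by flooring eigenvalues at
1e-8; the model-based simulator applies the identical projection to its
innovation covariance so generation and inference share one law.

Posteriors are computed by an exact log-space forward–backward over the
pairwise chain (emissions at t depend on both `y_{t−1}` and `y_t` through
the residual carry-over). The per-patient Choleskys of `Σ(H)` and the
conditional covariance are computed once (they depend only on H), making a
patient's pass O(T · m²). The first-event CDF is
`F̂_{i,t} = 1 − P(Y_1 = … = Y_t = 0 | X_{i,1:T_i})`, conditioning on the
full observed series. The inner log-sum-exp is hand-rolled for the 2×2
blocks; generic library versions dominated runtime at this size.

## Estimation

**Chain (λ).** Initial states: logistic regression of `Y_1` on `{1, H}`.
Transitions: logistic regression of `Y_t` (t ≥ 2) on
`{1−y_{t−1}, y_{t−1}, t, log t, H}` with no separate intercept. Fits are
unpenalized; on non-convergence or diverging coefficients (complete
separation) a small L2 ridge is added with a logged warning. Standard
errors come from the inverse Fisher information, valid because transitions
are conditionally independent given the previous state.

**Emission (θ_GP).** Per-component weighted least squares of X on the
8-term design gives the μ's. Reported SEs are patient-clustered sandwich
estimates — residuals are AR(1)-correlated within patient, so naive WLS
errors understate uncertainty. From the residuals:

* α_k is the slope of `log ε²` on `2H`. The intercept of that regression is
  *not* used for σ: it absorbs `E[log χ²₁] ≈ −1.27`, which would bias σ by
  ~47%. Instead σ_k² is the second moment of `ε exp(−α_k H)`
  (moment-matched, consistent). When H is constant across patients α is set
  to 0 exactly (the slope is unidentifiable) and σ falls back to the raw
  residual SD.
* ρ is the correlation matrix of H-standardized residuals, projected to the
  nearest correlation matrix by eigenvalue clipping and diagonal
  renormalization.
* τ_k is the pooled within-patient lag-1 autoregression coefficient of
  standardized residuals, clipped to (−0.99, 0.99). Single-bin patients
  contribute to moments but not τ.

Exactly-zero residual variance (X equal to the design prediction) is
rejected as a degenerate emission.

**Dampener r.** Grid {0, 0.1, …, 1.0}, chosen by 5-fold patient-level CV
maximizing pooled held-out AUROC. Chain and emission estimates do not
depend on r, so each training fold is fit once and scored at every grid
value; ties break toward smaller r.

**One-step EM.** The supervised model computes marginal posteriors on all
unlabeled patient-bins; the M-step refits chain and emission on hard labels
(weight 1) plus soft labels. Each unlabeled initial state contributes its
two configurations weighted by the marginal posterior; each transition
contributes the four `(y_{t−1}, y_t)` configurations weighted by the
product of adjacent marginals (the marginal-posterior approximation to the
E-step; a flag switches to hard 0.5-thresholded imputation). One iteration
by default: initialized at the consistent supervised estimator, one step
preserves consistency while limiting the unlabeled pool's influence.

**Blend.** `p̂ = α p̂_semisup + (1−α) p̂_sup`, α on {0, 0.05, …, 1} by
5-fold patient-level CV maximizing pooled AUROC; both members are refit per
fold (honest CV) with r fixed from the full supervised fit — re-tuning r
inside each α fold would be nested CV at substantial cost for no expected
ordering change. Ties break toward 0.5; exactly identical members return
0.5 with a note. Ensemble CDFs blend each member's own joint
all-zero-path F̂ with the same α, preserving joint structure rather than
multiplying blended marginals.

## Evaluation

AUROC is rank-based with midranks for ties. F1 is computed at the smallest
threshold achieving the target specificity (default 95%) on the evaluation
data. The counting cutoff c is the (1−prevalence)-quantile of labeled
posteriors (left-continuous), matching the flagged fraction of labeled bins
to the labeled prevalence. Curves are unit-width step functions on the
integer bin grid; ABC areas are summed per patient and averaged across
patients (the alternative — pooling bin-level sums — would weight long
histories more; per-patient averaging is documented as our convention).
For methods that only produce marginals, hazards are taken equal to the
marginals (independence across bins) when forming F̂. Gains are
`(null − method)/null` against the prevalence-at-each-bin null model, whose
gain against itself is identically zero. Population curves average
per-patient F̂ and N̂ over patients still under observation at each bin;
bootstrap CIs (default 100 replicates, seeded) resample patients, not bins,
to respect within-patient dependence.

Note that the predicted counting process `N̂_i(t) = Σ_{k≤t} I(π̂ ≥ c)`
accumulates *flagged bins* while the observed process counts 0→1
*transitions*; for persistent phenotypes the predicted curve therefore
rises faster than the observed one by construction. The null model shares
this property, so the gain comparison remains meaningful, but raw
ABC_count values should not be read as event-count errors.

## Synthetic cohorts

The generator emulates the reference design: p = 150 count features,
`T_i ~ 1 + Poisson(mean_T − 1)` with mean 25, truncated-normal utilization,
and three state-generation modes — `independent` (time-free chain started
at its stationary law, so prevalence is exactly flat in t), `correct`
(the model's own chain including linear and log time), and `complex`
(over-parametrized: quadratic and annual-period sinusoidal time terms added
to the logit, a documented choice since the original over-parametrization
is not specified). Informative features follow
`log(1+count) = a_j + b_j Y + c_j H + e` with within-patient AR(1) noise
that is marginally Gaussian (lognormal counts) or scaled Student-t(5)
(log-t counts, variance-matched); counts are recovered by
`max(0, round(exp(·) − 1))`, so the ingestion transform approximately
inverts the generative scale (tests compare on the log scale).
Non-informative features have `b_j = 0` and heavy zero-inflation
(P(structural zero) = 0.85), mirroring coded-data sparsity.

Free generative constants are not dictated by the design and live in
`SimConfig` in one place. Defaults were chosen to produce realistic
difficulty: event prevalence ≈ 0.2–0.3, moderate persistence, and bin-level
AUC in the high 0.8s for a plain LDA-on-unweighted-embeddings baseline —
comparable to real-cohort discrimination levels — rather than a ceiling
regime where all methods saturate at AUC 1 and comparisons are vacuous.

The stand-in embedding matrix gives informative features a shared low-rank
signal direction plus idiosyncratic noise (columns unit-normalized), so
cosine screening and discriminant weighting have structure to find. It is
*not* the SVD-of-co-occurrence pre-training used with real data; cohorts
here carry no code co-occurrence structure to factorize.

What passing tests on these cohorts do not show: robustness to covariate
shift between labeled and unlabeled patients (not modeled; labels are
revealed uniformly at random), calendar-time irregularity within bins,
code-correlation structure beyond the shared signal direction, or informative
censoring — panels end at a drawn T_i independent of the state path.

## Problem sizes and other choices

Integration tests run the full pipeline at the design scale (100 labeled /
1000 unlabeled patients, p = 150, m = 10) across 10 seeded replicates;
parameter-recovery checks use 2000 fully labeled patients; posterior
exactness is verified against brute-force enumeration for T ≤ 8 and the
classic-HMM reduction at r = 0 to 1e-10. Fold counts are fixed at 5
throughout (sensitivity to the fold count is known to be negligible for
this procedure). All randomness descends from explicit integer seeds;
rerunning any stage with the same configuration and seed is byte-identical.

## Known limitations

* The α_k/ρ/τ_k estimators are moment-based, not joint maximum likelihood;
  they are consistent under the stated model but not efficient, and they are
  not guaranteed to match other implementations numerically.
* Soft-label transition weights use products of adjacent marginal
  posteriors rather than true pairwise posteriors — the same approximation
  the one-step EM makes for its expected log-likelihood.
* The discriminant objective is nonconvex in W; the optimizer returns a
  stationary point, and different warm starts can reach different optima of
  equal quality (the tests check attained objective values, not weight
  uniqueness, under duplicated features).
* Two-state phenotypes only; no continuous-time modeling; no correction for
  labeled/unlabeled covariate shift.
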