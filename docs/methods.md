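# Methods

## The location/scale batch model

Log2 expression of probe *g* in sample *j* of batch *i* is modelled as

    Y_ijg = α_g + X_j β_g + σ_g (γ_ig + δ_ig ε_ijg),    ε_ijg ~ N(0, 1)

with a gene baseline (α_g, σ_g), optional non-batch covariates X, an
additive batch effect γ_ig and a multiplicative batch scale δ_ig. The
batch effects carry priors shared across genes within a batch,

    γ_ig ~ N(γ̄_i, τ̄²_i),        δ²_ig ~ Inverse-Gamma(λ_i, θ_i),

which is what lets a gene with only a handful of samples per batch borrow
strength from the ensemble: the posterior location is a precision-weighted
blend of the gene's own naive estimate and the batch-level prior mean, and
the posterior scale blends the gene's residual sum of squares with the
prior's pseudo-observations.

## Estimation pipeline

1. **Gene-wise OLS.** One joint least-squares fit per gene of batch
   indicators plus covariates. The pooled anchors are
   α̂_g = Σ_i (n_i/N) · (batch intercept)_ig (batch-size-weighted grand
   mean) and σ̂²_g = mean over all N samples of the squared residuals.
   Batch-wise anchors are α̂_ig = batch mean of (Y − Xβ̂) and σ̂²_ig =
   batch mean of squared deviations. β̂_g always comes from the pooled
   joint fit and is shared by both modes. A covariate collinear with the
   batch indicators is rejected by name: with confounding, batch effect
   and covariate effect are not separable and silently dropping either
   would misattribute variance.
2. **Standardization** to Z using the chosen anchors.
3. **Naive moments.** γ̂_ig is the batch mean of Z; δ̂²_ig the batch mean
   of squared deviations from it.
4. **Method-of-moments priors.** γ̄_i, τ̄²_i are the cross-gene mean and
   variance (denominator G−1) of γ̂_ig. Matching the Inverse-Gamma mean
   θ/(λ−1) and variance θ²/((λ−1)²(λ−2)) to the cross-gene moments
   (m_i, s²_i) of δ̂²_ig gives λ̄_i = m²/s² + 2 and θ̄_i = m(m²/s² + 1).
5. **Posterior fixed point.** Alternate

       γ̂*  ← (n τ̄² γ̂ + δ̂*² γ̄) / (n τ̄² + δ̂*²)
       δ̂*² ← (θ̄ + ½ Σ_j (Z_j − γ̂*)²) / (n/2 + λ̄ − 1)

   from the naive estimates until the largest relative change of both sets
   drops below `tol`.
6. **Back-transform** to the grand anchors (α̂_g, σ̂_g) or to the
   reference batch's anchors (α̂_rg, σ̂_rg).

## Denominator conventions

These matter at O(1/n) and are chosen for internal consistency rather than
mixed per-statistic:

- σ̂²_g (pooled): denominator N over residuals of the full fit.
- σ̂²_ig and δ̂²_ig: denominator n_i (not n_i − 1).
- Cross-gene hyperparameter moments: denominator G − 1.

With denominator n_i throughout, batch-wise standardization gives
γ̂_ig = 0 and δ̂²_ig = 1 *identically*, which is what makes the
reference-anchored adjustment an exact map (below). A single-batch dataset
likewise passes through the grand pipeline as an exact identity.

## Degeneracy guards

Batch-wise standardization (and any other input with no cross-gene spread
in the naive estimates) collapses the prior moments: τ̄²_i = 0 and
s²_i = 0. The method-of-moments forms divide by s², so shrinkage is
bypassed instead, per batch and per side:

- τ̄²_i < 1e−12 → γ̂*_ig = γ̄_i exactly (the infinite-shrinkage limit of
  the location update);
- s²_i < 1e−12 → δ̂*²_ig = δ̂²_ig exactly (no prior information about the
  scale).

When only one side is degenerate the other has a closed form and is
computed in a single pass. Under both guards the reference-anchored
transform reduces to Y* = (σ̂_rg/σ̂_ig)(Y − α̂_ig) + α̂_rg: an exact
gene-wise location/scale map. The reference batch is its own fixed point
(max |Δ| at machine precision), every adjusted batch mean equals the
reference gene mean exactly, and a fixed signature score — linear in probe
means — is re-centered exactly onto the reference batch's score scale.

A consequence worth knowing: with no covariates the reference-anchored
mode performs no empirical-Bayes pooling at all (its naive moments are
degenerate by construction). The EB machinery is exercised by the
grand-anchored mode, whose pooled standardization leaves real cross-gene
spread in γ̂.

Grand-mean anchoring, by contrast, re-centers only *approximately*: the
adjusted per-gene overall mean differs from α̂_g by
(σ̂_g/N) Σ_i n_i (γ̂_ig − γ̂*_ig)/δ̂*_ig, and the shrinkage residuals do
not cancel across batches. On the strong-effect simulation below the
deviation is ~0.05–0.08 log2 units. This is a property of the method, not
an implementation artifact.

## Solver numerics

- `tol = 1e-4`, `max_iter = 5000` by default; both exposed everywhere.
  Relative change is measured as |new − old| / (|old| + tol) so estimates
  crossing zero cannot stall the criterion.
- The fixed-point map is a contraction in practice; typical convergence is
  under ten iterations. Non-convergence raises an error naming the worst
  probe and batch rather than returning a partial result.
- The residual sum of squares in the δ̂*² update is computed from
  precomputed Σz, Σz² and clipped at zero against cancellation error.
- λ̄ ≤ 1 would make the posterior-scale denominator meaningless and is
  rejected by batch name (the moment-matched λ̄ = m²/s² + 2 > 2 cannot
  trigger this; the check guards hand-supplied hyperparameters).

## Zero-variance probes

A probe with zero residual variance (pooled scope) or zero variance inside
some batch (batch-wise scope) cannot be standardized. Default policy
`passthrough`: such probes are excluded from estimation, copied to the
output unchanged, flagged in the run report, and logged. Policy `error`
aborts instead. Dropping rows silently is never done — output shape and
probe order always match the input.

## Diagnostics

- **Probe-wise ANOVA**: vectorized one-way fixed-effects F on batch label.
  Degenerate probes are flagged: zero within-batch variance with real
  between-batch spread gives p = 0, fully constant probes p = 1, and both
  count in the tested denominator.
- **q-values**: q_i = π̂0 · min_{p_j ≥ p_i} (m p_j / rank_j). π̂0 comes
  from the smoother method: π̂0(λ) = #{p > λ}/(m(1 − λ)) on
  λ ∈ {0, 0.05, …, 0.90}, smoothed by a natural cubic smoothing spline
  (GCV-chosen penalty) and evaluated at λ = 0.90, clipped to (0, 1]. With
  fewer than 100 p-values the smoother is unstable and π̂0 is fixed to 1
  (reducing q-values to Benjamini-Hochberg). The step-up is evaluated in
  the same expression order as the standard BH implementation, so π̂0 = 1
  reproduces it bitwise.
- **PCA** on the k most variable probes (cross-sample variance, ddof 1;
  ties broken by input probe order — documented because it affects
  reproducibility). Probes are centered, never scaled (standard for
  expression PCA); components come from the SVD of the centered
  samples × probes submatrix.
- **Signature scores**: mean over up-probes minus mean over down-probes
  per sample, log2 units; high risk is a score strictly above the fixed
  cutoff. The score is linear in probe means, hence exactly re-anchored by
  the reference-anchored adjustment.

## Synthetic data generator

The generator draws directly from the generative model above: baselines
α_g ~ U(4, 12), σ_g ~ U(0.2, 1.5) (log2-scale ranges typical of
MAS5-summarized arrays), then per batch γ_ig, δ²_ig from the priors and
Gaussian noise, in a fixed documented order from one seed. Defaults —
three batches of 30 samples, prior means cycling (0, +1.5, −1.0)
standardized units, τ̄² = 0.1, λ = 4, θ = 3 (prior mean scale 1) — encode
a strong kit/scanner-change scenario in which essentially every probe is
significantly batch-affected before adjustment. Setting
`tau2=0, gamma_bar=0, lam=None, theta=None` yields exchangeable
batch-free data for null calibration.

What the generator does *not* emulate: probe-level array artifacts
(PM/MM, spatial effects), heavy-tailed or skewed intensity noise,
correlated probe blocks (co-expression), outlier samples, and
missingness. Passing tests therefore demonstrate correctness of the
method under its own model assumptions, not robustness to the full mess
of real arrays.

### Identifiability of batch effects

The pooled fit absorbs the batch-size-weighted mean of γ_ig into α̂_g, so
only contrasts of batch effects against that weighted mean are estimable
(for two equal batches, γ̂_1g ≈ (γ_1g − γ_2g)/2σ̃_g). Recovery reports
(`truth_recovery_report`) therefore show per-batch correlations that are
attenuated by construction, alongside an `overall` row pooled across
batch × gene cells that also reflects between-batch separation; the
overall correlation is the headline recovery number (≈ 0.94 under the
default two-batch conditions at n = 50 per batch, with the shrinkage MSE
ratio ≈ 0.98 against the naive estimates).

## Problem sizes

The shipped checks run the method at desk scale chosen to keep the full
suite and the reproduction script in the low tens of seconds: 2,000
probes × 3 × 30 samples for the elimination study, 5,000 probes × 2 × 50
for recovery, 100 random 10-probe instances against a 10,000-iteration
brute-force oracle for the solver, and 10,000 p-values for q-value
calibration. All quantities are recomputed from scratch at run time.

## Known limitations

- Non-parametric EB priors are not implemented (parametric model only).
- Mean-only adjustment and covariate-free surrogate methods (SVA/RUV
  style) are out of scope, as are survival endpoints.
- Missing values are rejected at validation; impute upstream if needed.
- With covariates, the reference-anchored mode standardizes per batch
  after removing Xβ̂; covariate effects are added back unshifted, so the
  "reference batch unchanged" guarantee holds exactly only in the
  covariate-free case.
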