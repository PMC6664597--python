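# Methods

This note records the models implemented in `twaskit`, the assumptions they
make, the defaults and why, and the places where a genuine design choice had
to be made.

## Summary-statistic model

Everything operates on summary-level data.  Within an LD block with SNP
correlation matrix R, marginal GWAS Z scores are modelled as

    z = √N · R β + ε,   ε ~ MVN(0, R),

where β are per-standardized-genotype causal effects.  This is the standard
asymptotic model for marginal association statistics and is also how the
synthetic-data generator draws GWAS studies — no genotypes or phenotypes are
ever simulated, because no stage of the pipeline consumes them.

A feature (gene × expression panel) carries a cis weight vector w; its
predicted-expression variance is wᵀRw, and a feature's phenotypic effect α
is expressed per SD of predicted expression, so that mediated SNP effects
are α·w/√(wᵀRw) and the expected TWAS Z is √N·α.

## Synthetic studies

The generator (`synthdata`) is the package's ground-truth instrument.  Its
structure, and what it does and does not emulate:

- **LD**: AR(1) within blocks — R[i,j] = ρ^|i−j| — with ρ either constant
  or varying per block, and exactly zero across blocks.  AR(1) is chosen
  because every derived quantity (LD scores, single-SNP feature
  correlations, eigenvalues) has a closed form, making test oracles exact.
  Real LD has long-range irregular structure that this does not reproduce;
  heterogeneous per-block ρ (default range 0–0.9 in the heritability
  simulations) restores the one property that matters for LD score
  regression, a spread-out LD-score distribution.
- **Weights**: a sparse random subset of a block's SNPs receives Gaussian
  weights rescaled so wᵀRw equals the target cis-h² exactly.  Real FUSION
  weights come from penalized regression and have systematic sign/LD
  structure the generator ignores; all downstream algebra is invariant to
  that structure.
- **Effects**: per-gene α ~ N(0, σ²_α), with an additive inflation of σ²_α
  for members of designated enriched sets; direct (non-mediated) SNP
  effects are iid N(0, σ²_d).  Property scores are Gaussian with a
  controlled correlation to α².
- **Scale defaults** (`SimConfig`): 50 blocks × 100 SNPs, 500 features with
  5 weight SNPs each, cis-h² = 0.1, N = 46,350 (the effective size of the
  motivating case-control GWAS).  These are desk-scale stand-ins — roughly
  1/100th of a real genome — so passing tests demonstrate correctness of
  the estimators under the stated model, not power at genome scale.

Every output is a pure function of `SimConfig` (stage seeds are spawned
from the one seed), which the suite asserts by re-generation.

## Association and the significance threshold

Z_TWAS = wᵀz/√(wᵀRw) after harmonizing weights, summary statistics and LD
to a common allele coding (sign flips for swapped or strand-complement
codings; strand-ambiguous A/T and C/G SNPs are dropped rather than
frequency-matched, because the input formats carry no allele frequencies).
Features with wᵀRw ≤ 1e−10 are rejected as degenerate.  A feature whose
surviving SNPs span two LD blocks is an input error: cross-block
correlations are exactly zero by construction, and the generator never
produces such a feature.

The transcriptome-wide threshold is the α-quantile (family-wise α = 0.05)
of the minimum two-sided p across features over 50,000 draws from
MVN(0, C), with C the block-diagonal feature correlation matrix.  Drawing
from the null distribution of the feature statistics is equivalent in
distribution to permuting a null GWAS and rerunning the scan, and orders of
magnitude cheaper.  The Monte-Carlo SE reported with the threshold is the
order-statistic spread estimate (distance between the order statistics
±√(nα(1−α)) around the quantile, halved).

## Regions

Features cluster into regions by single linkage on ±0.5 Mb padded bounds
(1 Mb dependence window for reporting).  The joint model is greedy forward
selection: repeatedly add the feature with the smallest conditional p
(conditional Z residualized on the selected set through C) while that p
clears the transcriptome-wide threshold.  Near-singular C gets a 1e−6
ridge.  Variance explained for a conditioned GWAS SNP is reported as the
chi-square drop 1 − z²_cond/z²_uncond; it is negative when conditioning
*increases* the statistic, which is mathematically possible and is reported
as-is rather than clamped.  The SNP-wise mean gene test uses the
Satterthwaite scaled chi-square matched to the first two moments of
Σλᵢχ²₁ (λᵢ the window's LD eigenvalues); exact inversion of the quadratic
form is unnecessary at these degrees of freedom, and the approximation is
verified by simulation in the suite.

## Colocalization

Wakefield log-ABFs with sampling variance v = 1/N (standardized traits,
only Z and N available) and prior effect SD 0.15; hypothesis sums in log
space with a log1p(−exp·) correction for the distinct-pair sum, so a
single-SNP region yields PP3 = 0 identically.  Priors default to
p1 = p2 = 1e−4, p12 = 1e−5 (the conventional single-causal coloc defaults;
configurable).  The expression-side marginal statistics are not observed:
they are reconstructed from the weights as z₂ⱼ = √N_eqtl·(Rw)ⱼ/√(wᵀRw),
the expected marginal statistic when predicted expression is the trait.
This reconstruction is this package's own construction; it is exact in
expectation under the summary-statistic model but carries no eQTL sampling
noise.

## Enrichment

The response is the positive-oriented association Z, Φ⁻¹(1−p) of the
two-sided TWAS p — a magnitude scale on which opposite-direction effects
cannot cancel (p = 0 is clamped to the smallest positive float, p = 1 to
1−ε, keeping the transform finite).  The mixed model

    z_assoc = β₀ + β_s·s + g + e,  g ~ N(0, σ²_g K),  e ~ N(0, σ²_e I)

uses K assembled block-wise from *squared* feature correlations — squared
because the sign of a predicted-expression correlation is irrelevant to the
covariance of association magnitude (transcript and splicing features of
one gene are often anti-correlated).  Negative eigenvalues introduced by
entrywise squaring are clipped and the diagonal renormalized to 1.  K is
eigendecomposed once per analysis; REML profiles the single ratio
σ²_g/σ²_e by bounded search on its log over [−12, 12], and the Wald test
uses a t reference with residual degrees of freedom — with K = I the fit
and test then reduce *exactly* to OLS, which is the suite's oracle.  Set
tests are one-sided (enrichment only); continuous gene-property tests are
two-sided with Bonferroni at 0.05/(number of stages), since property
gradients can run in either direction.  Gene-set membership propagates from
genes to all their features; K absorbs the same-gene redundancy.  No
fixed-effect covariates are included by default; weight-SNP count and
cis-h² can be passed as optional covariates.

## Heritability

LD scores ℓⱼ = Σₖ r²ⱼₖ (self term included) and expression-weighted scores
ℓᴱⱼ = Σ_f ρ²(j, f), ρ(j, f) = (Rw_f)ⱼ/√(w_fᵀRw_f).  Under the generative
model E[χ²ⱼ] = 1 + N(σ²_d·ℓⱼ + σ²_α·ℓᴱⱼ), so in the stratified regression
the total-category multiplier is the SNP count M while the
expression-category multiplier is the *number of features* — each feature
contributes unit predicted-expression variance, so h²_med = (#features)·τ_E.

Two design points were settled empirically during development and are the
package's own choices:

1. **Regression weights are two-pass.**  A single pass with weights
   1/max(ℓ, 1) ignores the fact that Var(χ²ⱼ) grows with the square of
   E[χ²ⱼ]; in architectures where signal concentrates on few SNPs this
   leaves the fit dominated by the noisiest observations (the mediated
   proportion then has a sampling SD of ~20 percentage points at desk
   scale).  The default therefore refits with the standard heteroskedasticity
   factor 1/(2·fitted²) from a first-pass fit, which brings the proportion's
   SD under 4 points.  Supplying explicit `weights=` bypasses the second
   pass (the exact scale-equivariance property holds only at fixed weights).
2. **The total and the mediated h² come from the same stratified fit.**
   The reported total is M·τ + (#features)·τ_E, so numerator and
   denominator of the mediated proportion are a single coherent
   decomposition; a separate univariate total is misspecified when effects
   are concentrated in expression-weighted SNPs (measured bias of ~50% in a
   fully mediated simulation) and remains available through `ldsc_fit`
   directly.

Standard errors are delete-one block jackknife over contiguous SNP blocks
(200 by default, standard LDSC practice), propagated through the linear
combinations above.  The jackknife is honest to within ~7% at desk scale
(measured 2-SE coverage ≈ 93% against a nominal 95%).  Liability-scale
conversion uses the classical threshold-model factor
K²(1−K)²/(P(1−P)φ(t)²) with t = Φ⁻¹(1−K); the sample prevalence P must be
supplied by the caller (the motivating study's is 18,381/46,350 ≈ 0.3965).

## Numerical conventions

Coordinates are 1-based inclusive base pairs.  Two-sided p-values
throughout the association chain.  Semidefinite correlation blocks are
factored by eigenvalue-clipped Cholesky substitutes; near-singular feature
correlation matrices receive a 1e−6 ridge (logged).  Omnibus components
with eigenvalue below 1e−4 of the largest are discarded (rank detection
for duplicated panels).  Writers emit a fixed `%.10g` float format so
seeded runs are byte-identical.  Dropped SNPs and skipped features are
counted and logged once per stage, never per record.

## Known limitations

- Single-causal-variant colocalization only; no multi-signal (SuSiE-style)
  extension.
- No weight training: SNP-weight sets are consumed, never fitted.
- The SNP-wise mean gene test does not ingest gene covariate files and has
  no top-SNP variant.
- Exactly two heritability categories (total, expression-mediated); no
  baseline annotation model.
- AR(1) block LD is a model of convenience; conclusions about power or
  calibration at genome scale require real LD panels.
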