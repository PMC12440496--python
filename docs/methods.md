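# Methods

`mrmediate` implements two-sample Mendelian randomization (MR) with a
two-step mediation layer on GWAS summary statistics, together with a
ground-truth synthetic-data generator that makes every stage testable
without access to the original cohort data. This note documents the models,
the defaults and why they hold, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## Causal model and estimators

For each variant j with exposure effect β̂_xj (SE σ_xj) and outcome effect
β̂_yj (SE σ_yj) on a shared effect-allele frame, the Wald ratio is
θ̂_j = β̂_yj / β̂_xj with first-order SE σ_yj / |β̂_xj| (exposure
uncertainty ignored, the usual two-sample convention; with the instrument
strengths enforced by the weak-instrument filter the neglected second-order
term is below a percent of the first).

**IVW.** The fixed-effect estimate is the inverse-variance-weighted mean of
the ratios, θ̂ = Σw_jθ̂_j / Σw_j with w_j = 1/se(θ̂_j)², SE = (Σw_j)^{-1/2}.
Heterogeneity is measured by Cochran's Q about θ̂ (df = k−1) and
I² = max(0, (Q−df)/Q)·100. Under `model="auto"` the estimate switches to
additive random effects when the Q p-value is below .05 **or** I² exceeds
25% — the two triggers the screening protocol uses; either alone selects
random effects because both signal more dispersion than sampling noise
explains. The between-variant variance τ² is estimated by REML using the
standard fixed-point iteration (DerSimonian–Laird start, 1e-10 absolute
tolerance, 100-iteration cap, clamped at 0); weights become
1/(se² + τ²). A single instrument yields a plain Wald fit with no
heterogeneity statistics.

**MR-Egger.** Weighted regression of β̂_yj on β̂_xj *with* intercept,
weights 1/σ_yj², after orienting all rows so β̂_xj ≥ 0 (the standard
identifiability convention). The intercept estimates directional
pleiotropy; the slope is the pleiotropy-robust causal estimate. The
coefficient covariance uses a multiplicative residual-variance inflation
floored at 1, so reported precision never beats the fixed-effect bound.
The regression is solved from the weighted normal equations; tests verify
it against `statsmodels` WLS to 1e-10.

**Weighted median.** Ratios sorted ascending; standardized cumulative
weights s_j = (Σ_{i≤j}w_i − w_j/2)/Σw; the estimate interpolates the ratio
at s = 0.5 and is consistent while valid instruments hold more than half
the weight. The SE is the standard deviation of the estimate over a seeded
parametric bootstrap (each ratio redrawn from N(θ̂_j, se_j); default 5000
replicates, seed 20250912) — bootstrap rather than analytic because the
estimator is a non-smooth functional of the weighted order statistics.

**MR-PRESSO.** The observed residual sum of squares is
RSS = Σ_j w_j (β̂_yj − θ̂_{(−j)} β̂_xj)² with θ̂_{(−j)} the fixed-effect
IVW slope excluding j. Its null distribution is simulated by redrawing
β_xj* ~ N(β̂_xj, σ_xj) and β_yj* ~ N(θ̂_{(−j)}β̂_xj, σ_yj) and recomputing
RSS on each draw (default 10,000 draws; the bundled studies use 1,000,
which keeps the smallest attainable Bonferroni-adjusted outlier p at
k/1001 ≈ .03 for k = 30 and runs in milliseconds). Monte-Carlo p-values
carry the add-one correction, so they live in [1/(n_sim+1), 1]. Per-variant
outlier p-values come from the simulated distribution of the j-th residual
term, Bonferroni-adjusted over the k variants. The distortion test compares
the fixed-effect slope shift caused by removing the flagged outliers with
the shift from removing random subsets of the same size. The corrected
estimate is IVW on the non-flagged variants; with no outliers it *is* the
raw fit. At least 4 instruments are required so each leave-one-out slope
rests on 3.

**Odds ratios.** Binary-outcome effects are log odds; OR = e^β with
CI exp(β ∓ z·SE) using the exact normal quantile (1.959963…), not 1.96.

## Instrument processing

Selection keeps variants with p strictly below 1×10⁻⁵ (the protocol's
IV threshold; strict inequality matches the "<" convention). Greedy LD
clumping takes the lowest-p unclaimed variant as index and removes
unclaimed variants within ±1000 kb (inclusive) on the same chromosome with
r² ≥ 0.001 against it; ties in p break lexicographically by
(chrom, pos, variant_id) for reproducibility. Variants missing from the LD
matrix are dropped with a warning by default.

Harmonization aligns outcome effects to the exposure's effect allele:
swapped coding flips the outcome beta sign and replaces eaf by 1−eaf;
non-palindromic pairs that match only after strand complement are
complemented first. Palindromic variants (A/T, C/G) are aligned by allele
frequency — orientations chosen so both eafs sit on the same side of 0.5 —
but only when the minor-allele frequency on *both* sides is outside
[0.40, 0.60]; inside that window (endpoints included, the conservative
reading) or with either eaf missing, strand cannot be resolved and the
variant is dropped. Indels and irreconcilable allele pairs are dropped as
incompatible. Every shared variant receives exactly one audit action, so
kept + flipped + palindrome-aligned + dropped equals the overlap.

Instrument strength uses R² = t²/(t²+n−2) from the observed t statistic —
the one formula computable from beta, SE and N alone, exact for a
continuous trait and a good approximation on the observed scale for a
binary one — and F = R²(n−2)/(1−R²). Instruments with F < 10 are removed
(threshold kept, re-estimation of weak effects deliberately not attempted:
no defensible model is specified for it).

The Steiger directionality filter converts each side's R² to a correlation
r = √R² and tests the difference of Fisher-transformed correlations with
variances 1/(N−3). A variant is excluded only when the outcome R² exceeds
the exposure R² *and* the two-sided p is below .05: a non-significant
reversal is retained, so noise in weak instruments does not silently thin
the panel.

## Mediation

With stage fits β₁ (exposure→mediator), β₂ (mediator→outcome) and β_t
(exposure→outcome, all univariable IVW):

* indirect = β₁β₂; Sobel SE = √(β₁²SE₂² + β₂²SE₁²); Z = β₁β₂/SE;
  p = 2Φ(−|Z|), with the convention Z = 0, p = 1 when β₁ = β₂ = 0;
* direct = β_t − β₁β₂ (exactly, by construction);
* proportion mediated = β₁β₂/β_t, with a delta-method SE treating the
  indirect and total estimates as independent —
  SE² = SE_ind²/β_t² + (β₁β₂)²SE_t²/β_t⁴ — an approximation justified by
  the disjoint instrument sets of the two fits and flagged as such.

Proportions are signed; negative values mean the indirect path opposes the
total effect, and |proportion| > 1 is reported untruncated with an
inconsistent-mediation flag. When β_t = 0 the proportion is undefined and
reported missing while the effect decomposition is still returned.

The recomputed worked examples reproduce the published mediated effects
exactly at 3 decimals; the published *proportions* differ in the last digit
(8.8% recomputed vs 8.6% published) because they were evidently computed
from unrounded stage estimates — only 3-dp values are printed — so the
package asserts exactness on the effects, not the proportions.

## Screening cascade

Per exposure/outcome pair: p-threshold selection → clumping (when LD is
supplied; the default synthetic panels are LD-free by construction) →
exclusion list (the stand-in for external confounder lookups) →
harmonization → Steiger filter → weak-instrument filter → estimator suite.
A pair passes when the IVW p-value is below the screening alpha, the three
estimates (IVW, weighted median, PRESSO-corrected — the corrected fit
replaces IVW whenever outliers were flagged) agree in sign, and every
leave-one-out refit keeps the full fit's sign. Leave-one-out stability is
sign-based by default; a strict mode additionally demands each refit stay
significant, but that is not required of the default gate because a single
variant's removal legitimately widens the CI. Bonferroni adjustment over
the panel (default m = panel size) is reported as a flag, not used as a
gate: the protocol's primary gate is nominal .05 with the correction
confirming top hits. Mediation runs only for pairs where the exposure
passed the forward screen, the mediator passed its screen, and the
exposure→mediator IVW p is below the screening alpha.

Determinism: every stochastic component (weighted-median bootstrap,
MR-PRESSO) takes a per-pair seed derived from the run seed and the pair's
trait ids via CRC32, so results are independent of panel ordering and two
runs with one seed produce byte-identical report bundles.

## Synthetic data

Cohorts are individual-level: genotypes Binomial(2, MAF) in Hardy–Weinberg
equilibrium (MAF ~ U(0.05, 0.5)), non-overlapping samples per trait (the
two-sample assumption; overlap is deliberately not simulated). The exposure
is X = Σγ_j g_j + ε standardized to unit variance. Per-allele effects are
drawn with magnitudes U(0.5, 1.5) and random signs, jointly scaled so the
instruments explain a chosen variance fraction.

Defaults encode the study conditions. Instrument strength: variants passing
p < 1×10⁻⁵ in a discovery GWAS of ~15k samples (the scale of the protein
panels this design mirrors) necessarily have per-variant R² ≥ χ²₁(1×10⁻⁵)/N
≈ 0.13%, and detected instruments typically sit around twice the threshold;
the default is therefore h² = 7.5% across 30 instruments (≈0.25% each,
F ≈ 125 at n = 50,000). Cohort sizes default to 50,000 per trait; binary
outcome prevalence defaults to 10%.

Binary outcomes use a *logistic* liability — liability = θ·X (+ pleiotropy
and any mediator paths) + Logistic(0,1) — thresholded at the empirical
prevalence quantile, with per-variant effects from the logistic score test
(β = U/I, SE = I^{-1/2}). This makes the conditional log-odds per unit
exposure exactly θ, so IVW recovers θ on the log-odds scale and e^β is a
meaningful OR; a Gaussian liability threshold would instead rescale the
estimand by φ(z)/(K(1−K)). Two small biases remain by construction:
non-collapsibility of the odds ratio (≈1% at θ = 0.2) and regression
dilution from exposure-side noise (≈1/F̄), which is why the recovery study
reports a small negative bias rather than zero.

The three-trait mode adds a mediator M = θ_xm·X + Σδ_j g_j + ε with its own
disjoint instrument block (same strength rationale), and outcome liability
θ_my·M + θ_direct·X, giving true indirect effect θ_xm·θ_my and true total
θ_direct + θ_xm·θ_my. Reverse-causal instruments (for directionality
studies) act on the outcome's genetic score directly, with a 0.1 loading of
that score on the exposure — "through the outcome first".

An optional AR(1) block-LD mode draws haplotypes from a Gaussian copula
(latent autocorrelation ρ within blocks, thresholded at the MAF) and emits
the *empirical* r² matrix of the simulated exposure cohort, so clumping
tests always see LD consistent with the data; latent ρ = 0.9 yields
allele-level r² around 0.2–0.5. Genotypes are held in float32 with float64
accumulators for all sufficient statistics; the rounding this admits is
orders of magnitude below sampling noise and the draws remain exactly
reproducible for a given seed.

What the generator does *not* emulate: realistic LD from reference panels,
population stratification, sample overlap between cohorts, imputation
noise, winner's-curse selection of instruments (instruments are designed,
not discovered), or assortative mating. Passing calibration on these panels
therefore shows the estimators and the cascade are correct and calibrated
under the model's own assumptions — not that the original epidemiological
estimates are right.

## Study scales

The bundled studies (tests and the acceptance script) use: 500 replicates
for IVW recovery and null calibration at 30 instruments / 50k per cohort;
100 seeded runs for PRESSO outlier sensitivity and 400 homogeneous null
panels for its global test at 1,000 simulation draws; 200 replicates at
100k per trait for mediation recovery and the Sobel null; one 500-instrument
panel at 100k for the Steiger study; and the 2×6×1 toy panel (20k per
cohort, 12 SNPs per trait block) for pipeline determinism and gate
structure. These sizes put Monte-Carlo error comfortably inside the
reported bands while the full suite runs in minutes on one CPU.

## Known limitations

* Wald-ratio SEs ignore exposure-side uncertainty (NOME); bias is ≈1/F̄ and
  controlled, not removed, by the F ≥ 10 filter.
* The proportion-mediated CI assumes independence of the indirect and total
  estimates; with overlapping instrument sets it is anticonservative.
* Multivariable MR, mode-based estimators, and correlated-instrument IVW
  are out of scope; mediation is strictly univariable two-step.
* MR-PRESSO is re-derived from its definition; it reproduces the procedure,
  not the original implementation's random-number stream.
* The harmonizer assumes forward-strand input with complement matching as a
  fallback and biallelic SNVs only; no genome-build liftover.
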