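# Methods

This note documents the statistical models, estimators, numerical choices
and known limitations of `phaseaudit`, in the order a user meets them.

## Binary logistic regression (lr)

The model is the standard binomial GLM with logit link:
logit P(event | x) = β₀ + xᵀβ.  Which outcome level counts as the "event"
must be named by the user; if it is not, the alphabetically last level is
used and a warning logged, since the choice only flips all coefficient
signs.

**Estimation.**  Maximum likelihood by iteratively reweighted least squares
(IRLS), starting from β = 0.  Convergence is declared when the relative
deviance change falls below 1e-8, capped at 100 iterations; the iteration
count is reported.  Each weighted least-squares step is solved by
`numpy.linalg.lstsq` on the √w-scaled design.  A non-convergent fit is
*returned*, with `converged=False` and a populated separation report,
because downstream auditing needs to see failed fits.  The full
per-iteration coefficient trace is kept on the fit object; it costs
O(iterations × terms) memory and powers the divergence diagnostics.

**Design matrix.**  Intercept, then predictors in the order listed (order
is meaningful: rank checks alias later-listed terms first), then optional
factor interactions in treatment coding (first level of the factor is the
reference; the factor main-effect dummies are added once, then
dummy × trait products).  Complete-case filtering drops any row with a
missing or non-finite modeled value, with the count logged and recorded on
the fit.  A rank-deficient design raises an error naming the aliased
(later-listed) terms; nothing is silently dropped.

**Standardization.**  Optional means-centering and scaling of each
predictor to sample SD 1 (n−1 denominator).  The scaling constants are
retained on the fit, so predictions on new data reuse the fit-time
constants and coefficients can be mapped back to the raw scale
(β_raw = β_std / s, with the intercept shifted accordingly).
Standardization changes coefficients by exactly the scaling factors and
leaves fitted probabilities unchanged — this is tested, not assumed.

**Variance.**  Observed-information covariance (XᵀWX)⁻¹ at the final
iterate; standard errors are its diagonal square roots.  For separated
fits these SEs are reported as-is — their absurd magnitude is itself a
diagnostic the audit surfaces.

## Separation detection

Complete separation (a hyperplane splits the classes strictly) means the
MLE does not exist; quasi-separation (weak split with ties on the
boundary) inflates coefficients and SEs.  The detector combines:

1. the fraction of fitted probabilities within ε = 1e-8 of 0 or 1;
2. monotone growth of the coefficient norm over the last ≤10 IRLS
   iterations (with the terms driving the growth named);
3. for problems with n ≤ 500 and ≤15 design columns, an exact linear
   program: strict separation iff {w : yᵢ·(wᵀxᵢ) ≥ 1 ∀i} is feasible
   (the system is scale-free, so ≥1 is equivalent to >0 on finite data);
   quasi-separation iff the weak system admits a solution with positive
   total margin.  Where the LP runs it is decisive.

Inside the bootstrap loop the LP is additionally gated on a heuristic hit
(any extreme fitted probability, or non-convergence) purely as a cost
control; a converged fit with no extreme probabilities cannot be
completely separated, so the gate cannot change a verdict.  The public
`detect_separation` always runs the LP on small problems.  The report
distinguishes `complete`, `quasi`, and `nonconvergence` (IRLS failure with
no separating hyperplane found), and its note states explicitly that 0/1
fitted probabilities under separation are estimation failure, not
accuracy.

## Collinearity and redundancy screen

All pairwise Pearson correlations among predictors; pairs at or above the
configured |r| threshold (default 0.95) are flagged.  A second check
catches a subtler redundancy: a two-valued predictor that is a
deterministic function of the *sign* of another predictor (e.g. a
final-position side indicator encoding the sign of a final coordinate).
The screen's advice string reminds the analyst to check that coefficient
signs are consistent internally and with subject knowledge; the audit
additionally flags positively correlated near-collinear pairs whose
fitted coefficients have opposite signs, the classic cancellation symptom.

## Discrimination, calibration, and the optimism bootstrap (validation)

**Somers' Dxy** = (C − D)/(C + D + T) over all event/non-event pairs
(ties count in the denominator), equal to 2·(c-index − ½).  Implemented
via midranks (Mann–Whitney U), which is exact; the test suite checks it
against brute-force pair enumeration.  It is invariant under strictly
increasing transforms of the score, so it can be evaluated on
probabilities or linear predictors interchangeably.

**Calibration line.**  A logistic recalibration of the outcomes on a
model's linear predictor: logit P(y=1) = a + b·lp.  On the training data
(a, b) = (0, 1) exactly, so the apparent values carry no information; the
corrected slope is the quantity of interest, with b well below 1 the
signature of overfitting.  A constant linear predictor raises an error
(slope undefined).

**Optimism bootstrap.**  B resamples of rows with replacement,
unstratified.  For each replicate: refit; training Dxy on the resample;
test Dxy and the recalibration (a_b, b_b) of the replicate model's linear
predictor on the *original* table.  Corrected Dxy = apparent − mean(train
− test); corrected calibration intercept/slope = means of (a_b, b_b).
Replicates are excluded and tallied when the refit is singular/rank
deficient, loses an outcome class, separates, or fails to converge; the
failure fraction is reported prominently because instability under
resampling is itself evidence about the model, and no replacement draws
are taken (effective B varies and is reported).  One integer seed governs
the whole procedure; replicate b uses the independent substream
`default_rng([seed, b])`, so results are exactly reproducible and
replicates are order-independent.  B < 50 triggers a warning; B = 200 is
the default in the audit pipeline as a speed/stability compromise, with
B = 1000 the conventional choice for reported results.

## Dispersion and scale (dispersion)

The coefficient of variation cv = s/x̄ (n−1 SD, positive mean required) is
scale- and dimension-free, which makes it the correct basis for comparing
dispersion across measurement scales.  Equality of CVs across k samples is
tested with the Feltz–Miller asymptotic statistic: with mᵢ = nᵢ − 1,
cᵢ the sample CVs and D = Σmᵢcᵢ/Σmᵢ,

    χ² = Σ mᵢ (cᵢ − D)² / (D²(0.5 + D²)),  df = k − 1.

Bartlett's K² is deliberately included alongside it: applied to the same
data before and after division by a constant it rejects mechanically
(var(X/s) = var(X)/s²), which is exactly why it must not be used to judge
whether a rescaling "homogenized" dispersion.  The package's property
tests pin this pair of facts: cv(aX) = cv(X) exactly, while Bartlett on
(X, X/2) rejects.

`normalize_by_morphometric` computes trait/size ratios but tags the result
domain="hybrid", never behavioral: a behavioral variable divided by a
phase-dependent body-size measure carries morphometric information, and
the audit refuses to certify models containing hybrid traits as
"non-morphometric".  Correlations (Pearson with t on n−2 df, or Spearman
with the S statistic reported for cross-study comparability) require an
explicit scope label — within-group or across-groups — because a
correlation across two phases largely reflects the phase difference itself
and must not be read as a within-phase association.

## Design audit and strain comparison (design)

EPV = min(n_event, n_nonevent)/k.  Verdicts: fail below 2 (clearly too low
for a reliable fit), warn below the configured floor (default 10, the low
end of the conventional 10–20 minimum), else pass.  Rule-of-thumb minimum
sample sizes follow from inverting an EPV floor of 15: ≈15·(k+1) per phase
for a single-strain model, ≈15·(2k+2) per phase (strain-balanced) for the
two-strain crossed model — validating a model in a new strain therefore
costs about as much data as building a new one.

`strain_generalization_compare` fits Model 1 (predictors crossed with the
strain factor: main effect + all interactions, k+1 extra coefficients for
two strains) and Model 2 (pooled), and reports AIC for both plus the LRT
(χ² with df = difference in coefficient counts).  The recommendation is
advisory only: "pooled-model" if AIC favors Model 2 or the LRT p exceeds
the pooling threshold (default 0.15, configurable — a convention, not a
rule), "strain-specific" otherwise, and "underpowered" overriding both
whenever Model 1's EPV audit fails, since the comparison is only
meaningful with adequate data on both strains.  Separation in either
model is an error carrying the separation report.

`audit_model` chains the stages — trait-domain census, collinearity/
redundancy screen, fit, EPV audit, separation check, coefficient-sign
report, bootstrap validation — into one report with stable warning codes
(`W_SEPARATION`, `W_EPV_FAIL`, `W_HYBRID_DOMAIN`, …) so downstream code
asserts on codes, not prose.  Two behaviors are non-negotiable: a
separated or non-convergent base fit is never bootstrap-validated
(`W_VALIDATION_SKIPPED`), and separated fits are always described as
estimation failures.  Fatal errors leave a partial report with a
completed-stages manifest.

## Synthetic data (simulate)

**Latent-axis generator.**  N individuals (default 800) with t₁, t₂
independently uniform on [−0.5, 0.5]; latent score y' = β₀ + β₁t₁ + β₂t₂ +
ε with ε standard-logistic (defaults β = (0, 2.5, 5)); environment B iff
y' > 0.  This construction makes logit P(E=B|T) exactly linear with the
generating coefficients, so fits should recover them; with noise_scale = 0
the boundary is deterministic.  Logistic noise is drawn by inverse-CDF of
uniform variates for cross-platform reproducibility at a fixed seed.

**Two-phase population generator.**  Defaults: 15 solitarious and 51
gregarious individuals and 13 candidate predictors — 8 base behavioral
(fast) traits, 3 morphometric (slow) traits, a derived trait nearly
collinear with average speed (target r = 0.9998, achieved by adding
Gaussian jitter whose variance is solved from r² = var(base)/(var(base) +
var(jitter)) using the realized base-sample variance), and a ±1 trait
encoding the sign of the final coordinate.  Trait means/SDs are synthetic
shape-alikes chosen so that phase groups overlap moderately on most
behavioral traits (≈1–2.5 SD mean gaps) except one strongly separated
behavioral trait, which makes the full 13-predictor model on 66
individuals separate essentially always — the small-sample pathology the
audit exists to catch.  The hind-femur ratio between phase means is
configurable: 0.9 by default (gregarious desert locusts have relatively
shorter hind femora), 1.6 for the anomaly scenario in which gregarious
animals are simultaneously faster and longer-legged; in that scenario the
speed means were set in the same 1.6 ratio so that dividing speed by femur
length collapses the phase difference — the normalization pitfall as a
generative property.

Crowding: fast traits of solitarious individuals crowded for h hours move
toward the gregarious parameters by the saturating response
f(h) = 1 − 2^(−h/τ) with half-time τ = 4 h (within the hours-scale window
over which behavioral gregarization is observed; the functional form is a
modeling choice — only the endpoints matter for the decoupling argument,
and tests target endpoints).  Slow traits never respond to crowding.  The
phase label remains the natal phase.

**What the generator does not emulate.**  Real assay variables'
operational definitions, measurement error structure, within-individual
repeat structure, intermediate rearing densities as a continuum, and
trans-generational dynamics are all out of scope; passing tests on this
generator demonstrate the statistical machinery, not properties of any
real dataset.

**Strain generator.**  Standard-normal predictors; phase assigned by the
latent-score rule with strain-specific coefficient vectors.  Identical
vectors give the null for the pooling comparison; a sign-flipped
coefficient in one strain gives a large, easily powered alternative.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted margins: 200 replicates for
latent-axis parameter recovery (Monte-Carlo SE ≈ 0.025 on each mean);
50 replicate datasets × B = 200 bootstrap replicates for the low-EPV
overfitting property; 500 simulated datasets for the null LRT
distribution (Kolmogorov–Smirnov against χ²(k+1)); 100 replicates for the
normalization-pitfall and separation-oracle checks.  Monte-Carlo
tolerances are 3×SE for means, ±30% bands for empirical SEs, and ±0.05
between corrected indices computed from different bootstrap seeds.

## I/O and reproducibility (io, cli)

Tables travel as CSV/TSV plus a YAML/JSON sidecar mapping each trait to
{domain, timescale}; reading uses round-trip float parsing and writing
emits shortest round-trip decimal representations, so write→read preserves
values bit-for-bit — an explicit precision policy, since ill-posed fits
can amplify last-ulp differences across platforms.  Reports serialize to
canonical JSON (stable key order; non-finite values mapped to null) or
markdown carrying the warning-catalogue text.  Every CLI run logs the
package version, a configuration hash, and the seed; exit codes are 0
(clean), 1 (fatal), 2 (completed with warnings).

## Known limitations

- No penalized fitting (ridge/LASSO/Firth) and no multinomial or ordinal
  outcomes; separation is diagnosed, not remedied.
- The Feltz–Miller test is the asymptotic variant; small-sample exact
  versions are not implemented.
- The separating-hyperplane LP is exact only where it runs (n ≤ 500,
  ≤15 design columns); larger problems rely on the heuristic signals.
- Allometric (log–log) size correction is out of scope; only ratio
  normalization is analyzed, because that is the practice under audit.
- Cross-stadium or cross-species transfer of a fitted model is
  deliberately unsupported; the strain comparison exists to test, not to
  assume, transferability.
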