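# Methods

This note documents the statistical procedures `npqflow` implements, the
choices made where the design was genuinely open, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
a user re-deriving our outputs would need.

## Data model and scales

NPQ (NULISA Protein Quantification) values arrive from the platform
log2-transformed and intensity-normalized. The package treats the scale as
an explicit tag on the matrix (`log2`, `linear`, `log10`) and converts by
exponentiation / change of log base; analyses run on the log10 scale,
matching common practice for this panel. Linear values must be strictly
positive; a log transform of a nonpositive value is a hard error naming
the offending cells rather than a silent NaN. Missing tokens accepted on
read are `""`, `NA`, `NaN`, `nan`; `NA` is written.

## Quality control

1. **Outlier masking.** Per analyte, values outside
   `[Q1 − k·IQR, Q3 + k·IQR]` (default k = 1.5) are set to missing.
   Quantiles use linear interpolation (type 7), the numpy/R default; the
   pass is single-shot (fences are not re-derived after masking). Analytes
   with fewer than four observed values keep their data and are flagged —
   fences are not meaningful there. Masking is global per analyte, not
   within diagnosis groups; for group-shifted analytes this trims the
   extreme tails of both groups symmetrically around the pooled quartiles.
2. **Two-step call-rate filter.** Call rate = fraction of non-missing
   entries per analyte (over samples) or per sample (over analytes).
   Step 1 removes analytes then samples below 65%, with sample rates
   computed on the surviving analyte set; step 2 recomputes both and
   applies 85%. Analytes are filtered before samples within each step
   (configurable). The interleaving is the point: a sample missing mostly
   on junk analytes is rescued once those analytes are gone. The
   post-condition — every retained row and column has a recomputed call
   rate ≥ 85% — is asserted in the test suite.
3. **CV / LOD.** CV = sample SD / mean on the linear scale per analyte;
   LOD is a pass-through column when provided. Neither affects filtering.

## Surrogate variables and differential abundance

Each analyte is modelled by OLS:
`log10(NPQ) ~ predictor + age_at_draw + male + SV1 + SV2`, complete-case
per analyte, two-sided t-tests, BH-FDR within each contrast (p-values that
underflow to 0 are clamped to the smallest positive double so the (0,1]
contract holds). Disease contrasts use a case indicator with cognitively
unimpaired participants as reference and only the two groups' samples;
endophenotype contrasts (amyloid-PET, tau-PET, CSF Aβ42/Aβ40, CDR) use the
phenotype as a continuous predictor on all samples with that measurement.
CDR is treated as continuous. By default one sample per participant
(latest draw) enters disease contrasts. Contrasts with fewer than 10 cases
fit with a warning; rank-deficient designs raise an error naming the
collinear column. Constant analytes yield β = 0 with missing p and a
degeneracy flag.

Surrogate variables absorb unmodelled batch/technical structure. The
estimator: impute missing cells by seeded draws from the same analyte's
observed values; residualize each analyte on the primary design; scale to
unit residual SD; take the top right singular directions (analyte
loadings) of the residual matrix; score those directions on the *original*
standardized data; center and orthogonalize (QR). Scoring on the original
data rather than the residuals matters: residual left singular vectors are
orthogonal to the design by construction, so they shrink standard errors
without removing predictor-aligned batch variation, which inflates
null-analyte test statistics badly (we measured 30–40% nominal rejections
under the null). Because the original data also contain true design
effects, scoring is iteratively reweighted: analytes with design
association p < 0.01 (recomputed each iteration, 3 iterations) are
excluded from the factor subspace and projection. This mirrors the
iteratively reweighted surrogate-variable approach used in expression
analysis. Measured on the generator: canonical correlation with the true
two-factor batch space ≈ 0.97 at n = 400/100 analytes, null rejection rate
0.03–0.05, planted effects unbiased. SVs are estimated per contrast on the
contrast's samples.

Cross-contrast comparison selects analytes significant in at least one
table (FDR < 0.05, or raw p < 0.05 under the relaxed rule), reports the
Pearson r of the two β vectors, regresses βB on βA, and flags analytes
outside the 95% *prediction* band (per-point, not the mean-confidence
band — outliers are individual proteins) plus analytes with discordant
sign.

## Biomarker positivity cutoffs

Input values are log10 NPQ, z-scored against the mean/SD of all values
entering the fit; the (mean, SD) pair is stored so every cutoff is
expressible on z, log10, and linear scales (`linear = 10^log10`).

**Mixture cutoff.** Two-component univariate Gaussian mixture, unequal
variances, fitted by EM in log space with a 1e-6 variance floor. Restarts
initialize from splits at the 0.3–0.7 quantiles with component moments
from each side; the best log-likelihood wins. Convergence: log-likelihood
improvement below `tol·max(1, |loglik|)` (tol = 1e-8); up to 5,000
iterations, because near-unimodal inputs converge along a flat ridge and
genuinely need a few thousand. Components are ordered μ1 < μ2. The cutoff
solves `w1·φ(z; μ1, σ1) = w2·φ(z; μ2, σ2)` — a quadratic in z for unequal
variances (the root inside (μ1, μ2) is taken), and for equal variances
`z = (μ1+μ2)/2 + σ²·ln(w1/w2)/(μ2−μ1)`. When no crossing exists between
the means (heavily overlapped components) the cutoff falls back to the
component-mean midpoint and the model is flagged degenerate; a fit with
`μ2 − μ1 < σ1 + σ2` is flagged low-confidence either way. The EM
implementation is cross-checked against an independent mixture fitter in
the test suite; the equal-posterior root against a bisection oracle to
1e-6.

**Youden cutoff.** Candidates are the sorted unique observed scores;
`score ≥ t` classifies positive; the t maximizing sensitivity +
specificity − 1 is returned, smallest t on ties. Equivalence with
exhaustive search is tested on 200 random instances.

**Dual cutoffs.** Lower = largest candidate with sensitivity ≥ 95%;
upper = smallest candidate with specificity ≥ 95%. Scores below lower are
`low`, above upper `high`, within the closed interval [lower, upper]
`intermediate`. Thresholds are empirical (no interpolation or smoothing),
so the sensitivity/specificity targets hold on the training sample by
construction. If lower ≥ upper (e.g. perfectly separated classes) the
intermediate zone is empty and classification degrades to the single
`≥ upper` threshold, flagged.

**Reference status.** Amyloid-PET > 20 Centiloids positive (exactly 20 is
negative); tau-PET > 1.5 SUVR positive; CSF Aβ42/Aβ40 < 0.0673 positive.
Missing reference values exclude the sample.

## Concordance

Confusion summaries report tp/fp/tn/fn, concordance % (rounded half-up to
two decimals, matching the precision clinical reports use), sensitivity,
specificity, PPV, NPV (PPV/NPV are None when undefined). In trichotomous
mode the intermediate zone can be dropped before counting, so concordance
is evaluated on confident calls only. APOE-ε4 status is derived two ways
and compared: from genotype (ε2/ε2, ε2/ε3, ε3/ε3 negative; any ε4-bearing
genotype positive) and from the ε4-proteoform assay via the mixture cutoff
above — the proteoform signal is bimodal because carriers express the ε4
isoform. The proteoform classification method is this package's
convention (the vendor's is not public) and is swappable.

## Prediction

Logistic regression (maximum likelihood) of the binary outcome on the
feature(s) plus age at draw and sex; the ROC score is the full-model
linear predictor (not a partial or covariate-stratified AUC — conventions
differ and this one is documented). AUC is the Mann–Whitney rank
statistic; the 95% CI is a stratified nonparametric bootstrap (default
2,000 replicates, seeded), resampling cases and controls separately.
Perfect separation is reported as AUC 1.0 with a flag rather than an
error. Ratio features are log10 differences (= log of the linear ratio).
Horizon prediction defines the outcome as conversion within h years;
non-converters censored before h are excluded as their status is unknown,
except when h exceeds every follow-up, where the outcome degrades to
any-time conversion.

## Progression to symptomatic AD

Time-to-event for baseline cognitively-unimpaired participants: onset age
minus draw age for converters (event), last-follow-up age minus draw age
otherwise (censored); nonpositive times and converters without onset age
are dropped with a logged count. Per-protein Cox proportional-hazards
fits (lifelines) report the HR per SD of log10 NPQ, adjusted for age at
draw and sex, Efron tie handling (annual visits make tied years common;
Breslow is available), Wald p, BH-FDR across analytes; non-convergent fits
are flagged, not dropped. Kaplan–Meier curves with a two-sided log-rank
test compare cutoff-defined groups; covariate-adjusted curves are
available by direct standardization (g-formula averaging of Cox-predicted
survival over the pooled covariate distribution), with the unadjusted KM
as the primary output. KM and log-rank are verified against hand
product-limit and hypergeometric-increment computations.

## Technical reproducibility

Per-analyte Pearson r across paired samples (pairwise-complete; analytes
with fewer than 3 pairs are flagged with missing r), with the first run's
IQR retained. Summaries: mean r, fraction above 0.7, and the correlation
of per-analyte IQR with cross-run r — under equal technical noise,
analytes with larger biological spread are less attenuated, so the link
is positive. Cross-platform tables enter as plain paired matrices with a
user-supplied analyte map.

## Synthetic cohort generator

The generator produces the statistical structure the pipeline assumes, at
the scale of a large single-center dementia cohort, from one seed:

- **Cohort**: group sizes AD 1,092 / DLB 28 / FTD 39 / PD 9 / controls
  1,579; ages truncated-normal per group (means 67–78, SDs 7–12, range
  45–100); per-group male fractions 40–89%; APOE genotype frequencies
  giving ~40% ε4 carriers.
- **Matrix**: 123 analytes; per-analyte log10 baselines uniform in
  2.5–4.5 (real per-analyte abundance distributions are not public, so
  baselines are arbitrary and documented as such); disease effects from a
  named-analyte table (e.g. the AD effect 0.26 on the biomarker analyte,
  protective NPTXR/BDNF signs) extended by a deterministic ramp so 78 of
  123 analytes carry an AD effect, shared at 0.6×/0.35×/0.1× with
  DLB/FTD/PD; small random age slopes (SD 0.002/yr) and sex offsets (SD
  0.02); k = 2 standard-normal latent batch factors with N(0, 0.3)
  loadings; residual noise SD 0.15.
- **Biomarker**: the p-tau217-like analyte is drawn from a two-component
  z-scale mixture, w = (0.52, 0.48), μ = (−0.80, 0.867), σ = (0.55,
  0.548) — weights/moments chosen so the standardized mixture has mean 0
  and variance 1 with a ~52% negative fraction — conditioned on a latent
  positivity label whose per-group probability rises from 0.25 (controls)
  to 0.85 (AD). Values map to log10 as 3.67 + 0.20·z.
- **Endophenotypes**: amyloid-PET for ~10% of samples (positives 60 +
  25·z ± 15 CL, negatives background N(5, 8)); tau-PET and CSF ratio
  similarly linked to z; CDR by group.
- **Contamination**: MCAR missingness (2%), outliers displacing random
  cells to 10 IQR beyond the fences (0.5%).
- **APOE proteoform**: carriers shifted by 5 residual-SDs — the
  separation needed for the ~99% proteoform/genotype concordance this
  assay achieves; a 2-SD shift would cap agreement near 84%.
- **Survival**: exponential conversion times with rate
  0.008·exp(ln(1.71)·z) per year and uniform 1–23 y follow-up, giving
  ~8% converters among controls.
- **Technical replicates**: the stored value acts as the shared
  biological measurement; each run adds N(0, 0.20) noise, a level derived
  analytically so the mean cross-run r is 0.75 given the chi-square
  spread of per-analyte biological variance.

Every latent quantity (true βs, batch factors/loadings, biomarker z and
labels, carrier status, outlier/missing coordinates, conversion events)
is returned in a truth record, so recovery tests never re-derive latents.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: read-count chemistry and plate effects
upstream of NPQ; informative (non-MCAR) missingness; longitudinal
within-participant trajectories (repeat draws are effectively independent);
non-Gaussian analyte distributions; calibration drift between runs; and
genotype–diagnosis dependence (APOE frequencies are identical across
groups). Results on the generator validate the statistical machinery, not
the biology.

## Numerical conventions and degenerate inputs

Seeds are explicit everywhere (numpy `default_rng`; derived streams use
`[seed, k]` spawn keys); identical configuration and seed give bitwise
identical outputs. Quantiles are type 7 throughout. The EM variance floor
is 1e-6; the equal-posterior root is accepted only inside (μ1, μ2).
Youden/dual thresholds use observed scores only. Percentages print
half-up at two decimals. Degenerate inputs (constant analytes, single
classes, < 20 values for the mixture, zero-variance covariates, empty
groups, onset before draw) either raise a named error or emit a flagged
record, as documented per function — never a silent drop.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the pipeline at the full
emulated cohort scale (2,747 participants × 123 analytes) for single
passes, and scale Monte-Carlo loops to keep the whole suite in a few
minutes: mixture recovery at n = 10,000; AUC calibration at n = 10,000;
Cox CI coverage over 200 replicates of n = 950 with ~85 events; β
recovery over 50 replicates of n = 2,500; null calibration over ~1,000
simulated analytes. These sizes were chosen to make the relevant
sampling error comfortably smaller than the tolerances being checked.

## Known limitations

- SV estimation fixes the factor count (default 2) rather than selecting
  it by permutation; with more than two strong latent factors the residual
  confounding is untested.
- The dual-cutoff thresholds are training-sample empirical quantities; no
  cross-validation of the sensitivity/specificity targets is performed.
- Bootstrap AUC CIs are percentile intervals; no BCa correction.
- Cox fits assume proportional hazards; no diagnostics are run
  per-protein.
- The adjusted survival curves use direct standardization over the pooled
  covariate distribution; other adjustment conventions will differ in
  detail.
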