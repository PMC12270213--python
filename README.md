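# npqflow

Analysis toolkit for targeted plasma proteomics in mixed-dementia cohorts,
built around NULISA Protein Quantification (NPQ) panels and the plasma
p-tau217 biomarker.

Clinical proteomics groups measuring CNS panels in large
Alzheimer/Lewy-body/FTD/Parkinson cohorts face a standard chain of
questions: which analytes survive quality control; which are differentially
abundant per disease once age, sex and latent batch structure are adjusted;
where to place a data-driven positivity cutoff for a bimodal biomarker;
how well that cutoff agrees with PET-defined amyloid status; how well the
biomarker predicts diagnosis and future conversion; and how reproducible
the measurements are across runs. `npqflow` implements that chain as a
library of scikit-learn-style estimators plus thin functions, a CLI, and a
seeded synthetic-cohort generator so every stage is testable end to end
without access to restricted participant data.

## What it computes

**Quality control.** Per analyte, values outside the Tukey fences
`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` are masked to missing; analytes and samples
are then filtered on call rate in two steps (65% then 85%, with call rates
recomputed in between so borderline analytes/samples are retained). CV and
LOD are reported but never used as filters.

**Differential abundance.** Per analyte, OLS of log10 NPQ on a case
indicator (controls as reference) or a continuous endophenotype
(amyloid-PET Centiloids, tau-PET SUVR, CSF Aβ42/Aβ40, CDR), adjusted for
age at draw, sex, and the first two surrogate variables:

    log10(NPQ_ij) = β0_j + β_j x_i + γ1_j age_i + γ2_j male_i
                    + δ1_j SV1_i + δ2_j SV2_i + ε_ij

Surrogate variables are estimated by residual SVD with iterative
reweighting (analytes showing design association are excluded from factor
scoring), and p-values are Benjamini–Hochberg adjusted. Effect profiles of
two contrasts are compared by Pearson correlation of the βs with a 95%
prediction band; proteins outside the band or with discordant sign are
flagged.

**Positivity cutoffs.** On z-scored log10 biomarker values, a
two-component Gaussian mixture `w1·N(μ1,σ1²) + w2·N(μ2,σ2²)` is fitted by
EM (multiple quantile-split restarts); the cutoff solves

    w1·φ(z; μ1, σ1) = w2·φ(z; μ2, σ2),   z ∈ (μ1, μ2),

the point where a sample is equally likely to belong to either component.
A Youden-index cutoff (maximizing sensitivity + specificity − 1 against a
binary reference) and a dual-cutoff scheme (lower threshold at 95%
sensitivity, upper at 95% specificity, defining low / intermediate / high
zones) are also provided. Reference status comes from amyloid-PET
(> 20 Centiloids), tau-PET (> 1.5 SUVR) or CSF Aβ42/Aβ40 (< 0.0673).

**Concordance, prediction, progression.** Confusion-matrix summaries
(concordance %, sensitivity, specificity, PPV, NPV) against reference
status, optionally dropping the intermediate zone; covariate-adjusted
logistic regression scored by ROC AUC with a stratified bootstrap CI;
protein-ratio features; per-protein Cox proportional-hazards fits for
conversion to symptomatic AD (HR per SD of log10 NPQ, Efron ties) with
Kaplan–Meier curves and log-rank tests for cutoff-defined groups; and an
APOE-ε4 proteoform classifier checked against genotype.

**Technical reproducibility.** Per-analyte Pearson correlations across
paired runs/platforms and the relation between an analyte's biological
spread (IQR) and its cross-run reproducibility.

## Worked example

```python
import pandas as pd
import npqflow as nf

# synthetic cohort at study scale: 2,747 participants, 123 analytes
cfg = nf.CohortSimConfig(seed=7)
matrix, meta, truth = nf.simulate_cohort(cfg)
meta = nf.simulate_survival(meta, truth, cfg)

filt, analyte_qc, sample_qc = nf.run_qc(matrix)
print(f"QC kept {filt.shape[0]} samples x {filt.shape[1]} analytes")

gmm = nf.GaussianMixtureCutoff(seed=7).fit(filt.values["pTau217"].dropna())
print(f"GMM cutoff: z = {gmm.z_cutoff_:.2f}, log10 NPQ = {gmm.cutoff_log10_:.2f}, "
      f"linear NPQ = {gmm.cutoff_linear_:.0f}")

ref = nf.pet_reference(meta, "amyloid")
scores = filt.values["pTau217"].reindex(ref.index).dropna()
ref = ref.reindex(scores.index)
pred = pd.Series(gmm.predict(scores), index=scores.index).astype(int)
cs = nf.confusion(pred, ref)
print(f"Concordance with amyloid-PET: {cs.concordance_pct}% "
      f"({cs.fp + cs.fn} of {cs.n} discordant)")

dual = nf.DualCutoffs().fit(scores, ref)
cs2 = nf.confusion(list(dual.predict(scores)), list(ref), drop_intermediate=True)
print(f"Dual-cutoff concordance (intermediate zone dropped): {cs2.concordance_pct}%")

rec = nf.fit_logistic_auc(meta, pd.DataFrame({"pTau217": scores}), ref,
                          n_bootstrap=2000, seed=7, label="amyloid")
print(f"AUC for amyloid positivity: {rec.auc:.2f} "
      f"(95% CI {rec.ci_lower:.2f}-{rec.ci_upper:.2f})")
```

Output:

```
QC kept 2703 samples x 123 analytes
GMM cutoff: z = 0.03, log10 NPQ = 3.68, linear NPQ = 4743
Concordance with amyloid-PET: 91.39% (23 of 267 discordant)
Dual-cutoff concordance (intermediate zone dropped): 94.82%
AUC for amyloid positivity: 0.97 (95% CI 0.95-0.99)
```

The mixture splits the bimodal p-tau217 distribution near the population
z-mean; single-cutoff classification agrees with amyloid-PET status for
~91% of imaged participants, and removing the uncertain intermediate zone
raises agreement to ~95%. The same stages run from the shell via the
`npqflow` executable (`simulate`, `qc`, `associate`, `compare-effects`,
`cutoff`, `predict`, `survival`, `concordance`, `technical` subcommands).

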