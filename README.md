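# ecmir

Infrared spectroscopic imaging of breast-tumor tissue can visualize the
downstream effects of the ECM3 gene-expression program — a prognostic
extracellular-matrix signature — directly on the tissue section, without
stains or dyes. `ecmir` implements that analysis as a tested Python pipeline:
from hyperspectral absorbance cubes to a patient-level ECM3/non-ECM3 call and
outcome statistics, together with a synthetic-cohort generator (with full
ground truth) that stands in for tissue scans so every stage can be exercised
and validated end to end.

It is written for spectroscopic-imaging and computational-pathology
researchers who want a reproducible reference implementation of the method
and a harness to study its statistical behavior.

## The method

1. **Histologic segmentation.** Each pixel's spectrum is reduced to spectral
   metrics (peak heights, band areas, peak locations, ratios) and classified
   into epithelium, fibroblast, myofibroblast, collagen, blood or necrosis by
   a Gaussian-Bayes classifier; low amide-I pixels are background.
2. **Collagen spectral discriminant.** Per-patient mean collagen spectra on
   872–1320 cm⁻¹ (baseline-corrected, amide-I-normalized, Savitzky-Golay
   smoothed, cleaned to absorbance ∈ [−1, 2]) are projected on the first 20
   principal components, and a two-class linear discriminant is fitted with a
   shrunk pooled covariance and coefficient thresholding:

       S_γ = (1 − γ)·S + γ·diag(S)
       w   = S_γ⁻¹(μ₊ − μ₋),  |w_j| ≤ δ ⇒ w_j = 0
       P(ECM3 | x) = σ(wᵀx + b)

   (γ, δ) are chosen by stratified 5-fold cross-validation; performance is an
   ROC on out-of-fold posteriors with a bootstrap CI.
3. **IR score.** Every collagen pixel is classified; the IR score of a tumor
   is the fraction of its collagen pixels called ECM3. A logistic regression
   of the gene-expression labels on the score yields the cutoff (−β₀/β₁) that
   dichotomizes patients.
4. **Cohort statistics.** Welch t / Mann-Whitney group comparison of scores,
   OLS association between IR score and the 58-gene mean log2 expression,
   Fisher's exact tests on clinico-pathological characteristics, and
   Kaplan-Meier / log-rank survival by ECM × grade.

## Worked example

```python
from ecmir import RunConfig, run_end_to_end

report = run_end_to_end(RunConfig(seed=1))
print(report["discriminant"]["oof_auc"])                 # 0.9999999999999999
print(report["ir_score"]["sensitivity_pct"],
      report["ir_score"]["specificity_pct"])             # 100 100
print(report["ir_score"]["cutoff"])                      # 0.4916326530612245
print(report["ir_score"]["score_vs_truth_pearson_r"])    # 0.9508616525243111
print(report["association"]["r_squared"])                # 0.8431769584840898
print(report["survival"]["logrank_p"])                   # 0.14544672838277117
```

This simulates the default 42-patient cohort (22 ECM3, 20 non-ECM3 tumors,
collagen phenotypes mixed within each tumor), runs the full analysis, and
reports: a perfect out-of-fold ROC for the patient-level discriminant, a
patient dichotomization that recovers every gene-expression label at the
logistic cutoff ≈ 0.49, an IR score that tracks the true ECM3 pixel fraction
at r ≈ 0.95 despite per-pixel spectral noise, and a four-group
(ECM × grade) log-rank test on the simulated survival times. The same run is
available from the shell:

```sh
ecmir run-all --seed 1                 # report as JSON on stdout
ecmir simulate --seed 1 --out sim/     # write ENVI cubes + tables
ecmir analyze --data sim/ --seed 1     # analyze a saved simulation
```

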