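# Methods

## Scope and data model

`ecmir` analyzes FT-IR spectroscopic images of breast-carcinoma sections: an
absorbance cube per patient (H×W pixels × B wavenumbers, stored/exchanged as
ENVI header + raw binary), a clinical table (gene-expression ECM class, grade,
size, nodal/receptor status, mean log2 expression of the 58-gene ECM3
cluster, disease-free survival), and produces a patient-level ECM3/non-ECM3
call from the collagen-pixel spectra plus cohort statistics. Real scans are
not bundled; a synthetic cohort generator with full ground truth emulates the
study design so the complete chain is testable.

## Synthetic cohort generator

Each tissue class (epithelium, fibroblast, myofibroblast, two collagen
phenotypes, blood, necrosis) has a template spectrum built from Gaussian
peaks at standard FFPE tissue band positions (amide I 1656, amide II 1546,
amide III ~1236, carbohydrate/nucleic-acid 1080 and 1032 cm⁻¹, …). The two
collagen phenotypes share every peak outside 872–1320 cm⁻¹; inside that
window the ECM3 phenotype redistributes amplitude between the amide III and
carbohydrate bands, scaled by `ecm3_contrast` (1 = default effect, 0 = null
cohort). No template has intensity near 1826 cm⁻¹, keeping the SNR reference
band signal-free.

The spatial layout is randomized multi-seed region growing: each class owns a
few seeds (collagen the most), blobs grow by random frontier expansion, and
seed pixels are pre-assigned so every class survives. The layout is
deliberately non-anatomical — contiguous blobs are sufficient to exercise
per-pixel classification, extraction and score aggregation, and nothing
downstream depends on morphology. Collagen pixels carry the ECM3 template
i.i.d. with the patient's true fraction (drawn per group from
[0.4, 0.9] / [0.0, 0.3], straddling the expected patient-level cutoff
≈ 0.35); optional majority-vote smoothing passes add spatial correlation but
are off by default since no implemented statistic uses it.

Pixel spectra are `scale·template + drift + noise` with per-pixel
multiplicative scale in [0.8, 1.2] (stands in for section thickness /
scattering so normalization is actually exercised), a random bounded
quadratic drift (≤ 0.02 a.u.) and i.i.d. Gaussian band noise (σ = 0.01 a.u.,
i.e. amide-I SNR ≈ 80, typical of a few co-added scans). The
gene-expression surrogate is `8.2 + 7.7·fraction + N(0, 0.8)` on the mean
log2 scale — the inverse of the ~0.13 slope linking expression to IR score on
the printed scale. Survival is exponential (baseline 0.006 events/month,
log-hazard +1.1 for ECM3 × grade III), administratively censored at 120
months; grades are assigned 50/50, and the remaining covariates are sampled
at the per-group frequencies of the published characteristics table.

What the generator does **not** emulate: Mie/resonant-Mie scattering,
paraffin residue, water-vapor lines, spatially structured noise, realistic
tumor morphology, or inter-batch drift. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
instrument-level robustness.

## Preprocessing

Fixed order: baseline → normalize → (optional SNR gate) → smooth → subset →
clean; every parameter is recorded in a manifest. Defaults: rubberband
baseline (lower convex hull, computed over the full measured range; exact
zeros at hull points), amide-I peak normalization (common FFPE practice;
unit-vector available), 9-point quadratic Savitzky-Golay with
truncated-window polynomial edges, training window 872–1320 cm⁻¹ inclusive
(225 bands on the default 2 cm⁻¹ axis), cleaning bounds (−1, 2) a.u. applied
after smoothing on the training window. Pixels whose baseline-corrected
amide-I intensity falls below 0.1 a.u. are background. "Nearest band" lookup
ties resolve to the lower wavenumber. SNR is the 1656/1826 intensity ratio,
computed on per-sample mean collagen spectra by convention (per-pixel
available); a zero denominator yields +inf with a logged warning.

## Histology classifier

The upstream published pixel classifier is external to this work; the
stand-in is a Gaussian-Bayes model on nine spectral metrics (heights at
1080/1236/1546/1656, areas 1000–1140 and 1500–1700, argmax location in
1200–1300, ratios 1080/1656 and 1236/1546), trained on labeled synthetic
pixels from dedicated training images (default four, collagen phenotypes
mixed 50/50 and merged into one "collagen" class). Covariances are MLE plus
a relative ridge (10⁻⁶ of the mean diagonal); priors are class frequencies.
It is validated against synthetic ground truth only (pixel accuracy ≥ 95% at
default noise; exact on noiseless cubes).

## Discriminant

Per-patient mean collagen spectra → centering-only PCA (first 20 components,
SVD, deterministic sign: largest-magnitude loading positive) → two-class
linear discriminant with shrunk pooled covariance
`S_γ = (1−γ)S + γ·diag(S)` and coefficient threshold δ applied in the
fitting space (PC space): `w = S_γ⁻¹(μ₊−μ₋)`, entries with |w| ≤ δ zeroed,
offset from class means and priors, posterior σ(wᵀx + b). Shrink-to-diagonal
is this package's reading of a generic "regularization parameter";
shrink-to-spherical is available. Grids: γ ∈ 10⁻⁴…10⁰ (9 log steps),
δ ∈ {0} ∪ 10⁻⁶…10⁻¹ (11 log steps); stratified seeded 5-fold CV minimizes
out-of-fold misclassification at the 0.5 posterior, ties resolving to the
smallest γ then δ. PCA is refit inside each training fold by default (no
leakage); `pca_before_cv=True` fits PCA once on all patients before
splitting, reproducing the simpler (leakier) ordering for comparison — on
separable synthetic cohorts both reach out-of-fold AUC 1.0. ROC: threshold sweep over unique
posteriors, trapezoid AUC (equals the concordant-pair fraction, ties half),
Youden optimal point (ties → lower FPR), 95% CI by seeded patient-level
bootstrap (2000 resamples; percentile — the CI method is a package choice).

## IR score, cutoff and statistics

IR score = ECM3-called collagen pixels / all collagen pixels (exact count
ratio). Cutoff: logistic regression of the gene-expression label on the
score, cutoff −β₀/β₁; complete separation (detected directly, plus an MLE
blow-up backstop) falls back to the midpoint of the separation gap, a
non-positive slope to the Youden point. Score = cutoff counts as positive.
The cutoff is chosen on the full cohort, matching the study design; nested
selection can be assembled from the library pieces for honest evaluation.
Sensitivity/specificity are kept as exact fractions and reported as rounded
integer percentages.

Cohort statistics: Welch t (default; Mann-Whitney with exact enumeration for
small samples is available) for score-by-group; OLS with intercept for
IR score vs mean log2 expression — the default orientation regresses the
score on expression, matching the published fit's slope scale (the text is
ambiguous; both orientations are supported and logged); two-sided Fisher's
exact (point-probability method) per 2×2 characteristic with within-column
integer percentages over non-missing rows; Kaplan-Meier (events before
censorings at ties) and k-group log-rank (χ², df = k−1) via lifelines,
applied to the four ECM × grade curves plus the 2-group grade-III contrast.
Significance is two-sided p < 0.05, no multiplicity correction.

## Reproducibility and numerics

All randomness flows from one root seed through named substreams (cohort,
histology training, CV folds, ROC bootstrap); identical config + seed gives
bit-identical cubes, tables and reports, and an analysis of a saved
simulation equals the combined run (cohort CSVs are parsed with round-trip
float precision; ENVI float64 I/O is lossless). Degenerate inputs are
explicit errors: zero normalizer (pixel flagged), zero collagen pixels
(patient excluded with warning), singular covariance at γ = 0 (error
advising γ > 0), empty band selection, single-class ROC. The default image
frame is 32×32 pixels (≈ 150–400 collagen pixels per tumor) — enough for
stable scores while keeping a 42-patient run in seconds on one CPU.

## Known limitations

- The per-pixel ECM3 call inherits noise the patient-level model averages
  out: pixel error rates are ~25–35% at default noise, so scores are
  compressed toward the middle while remaining strongly rank-correlated with
  truth (r ≈ 0.95). This mirrors the mixed-pixel behavior expected of the
  method on tissue.
- The log-rank χ² reference is anticonservative at small samples (~6%
  rejection at α = 0.05 with 4 groups × 25; the identical statistic and
  inflation occur in R's survdiff). Calibration tests therefore simulate in
  the asymptotic regime (4 × 100).
- The histology stand-in is validated only on synthetic data and makes no
  claim of equivalence to any previously published tissue classifier.
- Headline numbers from the default synthetic cohort (AUC 1.0, 100%/100%
  calls, R² ≈ 0.84) reflect the chosen effect size and noise, not the harder
  real-tissue problem; the null-contrast configuration is provided to verify
  chance-level behavior.
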