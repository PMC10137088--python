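# spectroscreen

Chemometrics for salivary ATR-FTIR disease screening: spectral
preprocessing, univariate band statistics, LDA/SVM classification under
repeated stratified cross-validation, and Shapley feature attribution —
plus a synthetic cohort generator so the whole pipeline is testable
without clinical data.

## The problem

Attenuated-total-reflection FTIR spectroscopy of dried saliva films
yields an absorbance spectrum A(ν) over 4000–400 cm⁻¹ whose bands report
on lipids (CH stretches, 2850–2962 cm⁻¹), proteins (amide I ~1641 cm⁻¹,
amide II ~1550 cm⁻¹), carbohydrates/glycosylated proteins (~1073 cm⁻¹)
and nucleic acids (~918 cm⁻¹). In type-2 diabetes these components shift
in concentration and conformation, so a saliva spectrum plus a
classifier can act as a reagent-free screening test. This package
implements the full analysis chain such a study needs, for cohorts of
the typical size (tens of subjects, a few replicate spectra each).

## Methods at a glance

* **Rubberband baseline**: the baseline is the lower boundary of the
  convex hull of {(νᵢ, Aᵢ)}, interpolated between hull vertices;
  subtraction removes smooth drift and anchors the corrected spectrum to
  zero at the hull touch points.
* **Normalization**: division by the Euclidean norm ‖A‖₂ of the full
  spectrum (vector normalization) or of the 1700–1600 cm⁻¹ amide-I
  segment (internal protein reference).
* **Savitzky–Golay first derivative**: local least-squares polynomial
  convolution (default window 9 points, order 2), derivative taken with
  respect to wavenumber; removes residual baseline and sharpens
  overlapping bands.
* **Region truncation**: analysis restricted to the lipid
  (3050–2800 cm⁻¹) and biofingerprint (1800–900 cm⁻¹) windows.
* **Band statistics**: trapezoidal band areas ∫A dν and weight centers
  ∫νA dν / ∫A dν; pooled-variance Student's t, Kolmogorov–Smirnov
  normality, and ROC analysis where AUC equals the Mann–Whitney
  probability and the operating cutoff maximizes Youden's
  J = sensitivity + specificity − 1.
* **Classification**: linear SVM (C = 1) and LDA under 10-fold
  stratified cross-validation repeated 3× (30 executions); features are
  standardized with train-fold statistics only; confusion counts are
  pooled within each repeat and metrics averaged over repeats.
* **Attribution**: Shapley values of the SVM decision margin over
  wavenumber features — exact enumeration for ≤ 12 features, a
  kernel-weighted sampling estimator above that — with ranking and
  lookup of vibrational band assignments.

Preprocessing presets mirror the variants such studies compare:
`raw` (truncation only), `rubberband_amideI` (baseline → amide-I
normalization → truncation) and `savgol_deriv` (smoothed first
derivative → amide-I normalization → truncation).

## Worked example

```python
import spectroscreen as sc

cohort   = sc.generate(sc.SyntheticConfig(seed=0))   # 204 replicate spectra
subjects = sc.aggregate_replicates(cohort)           # 68 subject means
features = sc.apply_pipeline(subjects, sc.preset("savgol_deriv"))
result   = sc.cross_validate(features, sc.CVConfig(algorithm="SVM", seed=0))
print(f"accuracy    {result.accuracy_mean:.3f} +/- {result.accuracy_sd:.3f}")
print(f"sensitivity {result.sensitivity_mean:.3f}")
print(f"specificity {result.specificity_mean:.3f}")
```

prints

```
accuracy    0.809 +/- 0.015
sensitivity 0.881
specificity 0.667
```

i.e. the derivative + SVM pipeline classifies the 68 simulated subjects
with 81% cross-validated accuracy; sensitivity runs ahead of specificity
because the diabetic class is larger (45 vs 23). Attribution of the
fitted SVM,

```python
from spectroscreen.pipeline import explain_svm
attr, table = explain_svm(features, seed=0, top_k=5)
print(table.to_string(index=False))
```

```
 wavenumber  mean_abs_shap assignment  component
     1644.0       0.015709 unassigned unassigned
     1642.0       0.015628 unassigned unassigned
     1640.0       0.015328 unassigned unassigned
     1646.0       0.015115 unassigned unassigned
     1638.0       0.014419 unassigned unassigned
```

ranks the amide I region (1638–1646 cm⁻¹) as the main discriminator —
exactly where the generator injects its protein effect. (Assignments
read "unassigned" unless a wavenumber falls within ±4 cm⁻¹ of a
tabulated literature mode.)

The same workflow is scriptable from the shell:

```sh
spectroscreen simulate --out spectra.csv --meta meta.csv --seed 1
spectroscreen classify --in spectra.csv --meta meta.csv \
    --preset savgol_deriv --algorithm SVM --seed 1
spectroscreen run --config run.yaml        # full grid + report
```

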