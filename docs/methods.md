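# Methods

This note records the models behind each pipeline stage, the parameter
choices that matter, what the synthetic cohort does and does not
emulate, and the numerical conventions a user re-implementing or
auditing the package would want spelled out.

## Data model

A `Spectrum` is one absorbance trace on a strictly monotonic, positive
wavenumber axis (cm⁻¹), stored descending (4000 → 400) to match
instrument display convention; ascending input is flipped on
construction. A `SpectrumSet` is an aligned collection on one shared
axis with an append-only provenance log — every transformation records
its name and parameters, so any output can be re-derived from the log
plus the input. Subject metadata is carried per spectrum: `subject_id`,
`replicate` (0 marks a replicate average), and `group` ∈ {ND, T2D} with
T2D the positive class throughout.

File formats are a wide CSV matrix (wavenumber column + one column per
sample, or the transposed layout with inline metadata columns) and
single-spectrum JCAMP-DX (`XYDATA=(X++(Y..Y))` in plain AFFN form, or
`XYPOINTS`, with XFACTOR/YFACTOR scaling). Compressed JCAMP encodings
(SQZ/DIF/DUP) and vendor binary formats are out of scope. Loading
enforces ≥ 8 points and finite values; short axes are still accepted
when containers are built directly in code, which the unit tests use
for closed-form cases.

## Preprocessing

**Replicate aggregation** is the pointwise arithmetic mean of a
subject's replicate spectra, applied before any other transformation.
Aggregating raw spectra first (rather than normalizing each replicate)
keeps the replicate average an unbiased estimate of the subject's
spectrum; because the mean commutes with every linear step downstream,
the order only matters for the nonlinear normalizations, where
averaging first is the lower-variance choice.

**Rubberband baseline.** The baseline is the lower boundary of the
convex hull of the point set, built by a monotone-chain scan and
evaluated by linear interpolation between hull vertices. The corrected
spectrum is non-negative, exactly zero at every hull vertex (both
endpoints included), and invariant under addition of any line — a line
is absorbed into the hull. The hull anchors at global minima, so the
method is applied to the full spectrum *before* truncation; running it
on a cut-out region would anchor to the artificial cut endpoints.
Rubberband is meaningful only for non-negative band-on-baseline data;
the presets never apply it after a derivative.

**Normalizations.** Vector normalization divides by the Euclidean norm
of the full trace; amide-I normalization divides by the Euclidean norm
of the 1700–1600 cm⁻¹ segment, using the amide I band as an internal
protein reference. Both are idempotent and invariant to positive
scaling, which is what makes them remove multiplicative
collection-geometry variation. The amide-I step is deliberately defined
as a segment *norm* (not peak height or area): on derivative spectra a
peak height is ill-defined, while the segment norm is equally valid
before or after differentiation. In the `savgol_deriv` preset it is
applied after the derivative.

**Savitzky–Golay.** Local least-squares polynomial convolution on a
uniformly spaced axis; edges use the polynomial fitted on the boundary
windows (`mode="interp"`). Defaults: window 9 points, polynomial order
2 — at 2–4 cm⁻¹ spacing a 9-point window spans ≲ 36 cm⁻¹, below the
width of the narrowest bands of interest, so band shape is preserved
while pixel noise is suppressed. The derivative is taken with respect
to *ascending* wavenumber and stored back on the descending canonical
axis, making flank signs independent of scan direction. Only
derivative orders 0 and 1 are supported.

**Truncation** keeps the closed union of the lipid (3050–2800 cm⁻¹) and
biofingerprint (1800–900 cm⁻¹) windows, retaining native grid points
(no interpolation); boundary points are kept (closed intervals). It is
the last step of every preset.

## Band statistics

Band areas are trapezoidal integrals over closed windows on the native
grid; weight centers are intensity-weighted mean wavenumbers over the
same windows. Default windows: 2962 → [2980, 2945], 1641 → [1670, 1620],
1073 → [1100, 1040] cm⁻¹ — wide enough to cover the band, narrow enough
not to swallow neighbours; all configurable. Group differences use the
pooled-variance two-sided Student's t (threshold 0.05, no
multiple-testing correction across the three bands — deliberately
mirroring common practice in this literature, and documented as such).
Normality screening uses the one-sample Kolmogorov–Smirnov statistic
against a normal with estimated mean/SD and the asymptotic p-value;
with estimated parameters this p-value is anti-conservative (the
Lilliefors correction is not applied), which is acceptable for a
descriptive screen.

ROC analysis reports the full curve, AUC (trapezoidal, equal to the
Mann–Whitney probability with ties counted ½), and the Youden-optimal
cutoff; J-ties are broken toward higher specificity, the
screening-friendly side. AUC is invariant under strictly increasing
transforms of the marker.

## Classification

Stratified k-fold assignment (default 10 folds) keeps per-fold class
counts within one sample of proportionality; `n_folds` equal to the
sample count degenerates to leave-one-out. The procedure repeats 3×
with reshuffled folds — 30 executions — with one master seed spawning
per-repeat fold seeds (recorded in the result). Within each fold,
features are standardized using train-fold statistics only and the
classifier fitted on the train fold predicts the held-out fold; test
predictions are pooled into confusion counts per repeat, and
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/n are averaged over repeats (±SD).

The SVM is linear with C = 1: with n ≈ 68 samples and hundreds of
wavenumber features, a maximum-margin hyperplane is the appropriate
capacity and an RBF kernel (available by config) has nothing to bend
around. LDA defaults to the plain pooled-covariance discriminant. In
the p ≫ n regime its empirical covariance is ill-conditioned and the
classifier degrades toward chance — which is precisely the behavior
applied spectroscopy studies report for LDA on full spectra, and the
package's default deliberately reproduces that reference behavior
rather than silently upgrading it. A Ledoit-Wolf shrinkage covariance
(`lda_shrinkage="auto"`) is available and brings LDA close to the SVM.
No class reweighting is applied by default (the 45/23 imbalance is part
of the study design); balanced weighting sits behind a flag.

## Shapley attribution

Attribution targets the SVM decision margin (not the thresholded
label): margins vary smoothly with the input, so per-wavenumber
contributions are well defined. Coalition values use interventional
semantics — features outside the coalition are replaced by background
rows and the score averaged over the background set, a class-balanced
subsample (default 30) of the training data. For ≤ 12 features the
estimator enumerates all 2^p coalitions and the efficiency, symmetry
and dummy axioms hold exactly; above that a kernel-weighted sampling
estimator draws coalitions from the Shapley kernel size distribution
with antithetic complements (default 4096 draws) and solves a
least-squares system with the efficiency constraint eliminated into the
design, so local accuracy holds by construction in both modes.

The attribution SVM is fitted on the preprocessed features in their
native units, *without* per-feature standardization: spectra share one
unit (absorbance), and standardizing inflates near-constant noise
channels to unit variance, after which the margin solution scatters
weight over empty spectral regions and the importance ranking loses its
physical meaning. Global importance is the mean |Shapley value| per
wavenumber over the explained samples (default 20, class-balanced);
ranking breaks ties toward lower wavenumber. Top wavenumbers are
annotated from a shipped table of literature vibrational assignments by
nearest-neighbour lookup within ±4 cm⁻¹ (≈ two grid points), else
"unassigned".

## Synthetic cohort

The generator emulates the study design the pipeline targets: 23
non-diabetic vs 45 type-2-diabetic subjects, 3 replicate spectra each,
4000–400 cm⁻¹ at 2 cm⁻¹ spacing. Each subject's latent spectrum is a
sum of Gaussian bands (water hump 3350/σ150, CH₃ 2962/σ12, CH₂ 2925/σ14,
CH 2870/σ12, amide I 1641/σ25, amide II 1550/σ20, carbohydrate 1073/σ30,
nucleic acid 918/σ10; amplitudes 0.08–0.50 AU, typical of dried films).

Between-subject variation has two layers: a shared concentration factor
(CV 0.12 — film thickness/dilution, the dominant nuisance in biofluid
films) multiplying the whole spectrum, and independent per-band
amplitude CVs (0.10; 0.25 for the water hump and amide II, which vary
most between subjects), plus N(0, 1.5 cm⁻¹) jitter of each band center.
Replicate measurements add a multiplicative scatter factor U(0.9, 1.1),
a smooth non-negative baseline (random quadratic, coefficient scale
0.02, plus four broad Gaussian undulations of amplitude ≤ 0.05 and
width 120–350 cm⁻¹, emulating scattering residuals), and white noise
(SD 0.002 AU).

Disease effects: T2D subjects gain an additive amplitude shift
d × (total between-subject SD) on the 2962, 1641 and 1073 bands with
d = 1.2, so each carrier's amplitude separates the groups with the
closed-form ROC AUC Φ(d/√2) ≈ 0.80. The amide I center additionally
shifts +3 cm⁻¹ in T2D (a protein-conformation signature of the kind
weight-center analysis is designed to catch). The position effect
matters structurally: because every amplitude effect is expressed as
the same fraction of its band's mean, amide-I normalization divides the
carriers' amplitude shifts away almost exactly (the reference is itself
a carrier); the surviving multivariate signal after that preset comes
from the position shift and from the concentration-free contrast the
normalization creates. This is why the defaults place the top Shapley
features on the amide I profile, and it mirrors the real phenomenon
that normalized derivative spectra discriminate through band *shape*
rather than raw intensity.

Calibration targets of the defaults (chosen once, as study conditions):
cross-validated SVM accuracy with the `savgol_deriv` preset in the
0.8–0.9 band; the injected carriers carrying the top univariate t
statistics; band-area AUC converging to Φ(d/√2). The convergence checks
integrate rubberband-corrected (but unnormalized) areas, because
per-sample normalization divides by a random norm and the closed form
assumes an additive equal-variance model; the carbohydrate band is used
because its window is free of neighbouring-band overlap (the 2962
window inherits CH₂/water leakage and its empirical AUC sits ≈ 0.07
below the closed form — a realistic, documented confound).

What the generator does **not** emulate: Mie/ATR penetration-depth
physics, instrument line-shape convolution, water-vapor and CO₂
rotational fine structure, covariation with demographics or glycemia,
and correlated component chemistry (each band's amplitude varies
independently apart from the concentration factor). Passing tests
therefore demonstrate the *pipeline's* correctness and statistical
behavior under a plausible data model, not clinical performance on
real saliva.

## Numerical conventions and degenerate inputs

* Hull construction pops collinear points (`cross ≤ 0`), so the
  baseline of a straight line is the line itself and the corrected
  spectrum is exactly zero; baseline values at hull vertices are set
  from the data, not interpolation, making the zero exact.
* Normalizations raise a degenerate-input error on zero-norm segments
  (e.g. the derivative of a constant spectrum), and the pipeline
  propagates the error with the failing step identifiable from the
  provenance log.
* The Savitzky–Golay step requires a uniformly spaced axis (relative
  tolerance 10⁻⁶) and validates window/order/derivative relations.
* ROC cutoff ties (equal Youden J) resolve to the higher-specificity
  threshold; the reported operating point always lies on the curve.
* Cross-validation requires the minority class to hold at least
  `n_folds` members (error suggests a smaller fold count), except the
  exact leave-one-out case.
* All stochastic components (fold shuffles, coalition sampling,
  background subsampling, simulation) derive from explicit seeds;
  repeat runs with one seed are bit-identical.

## Problem sizes

Default analyses run 68 subjects × 577 retained wavenumbers; the
classification grid is 3 presets × 2 algorithms × 30 fits. The
attribution step explains 20 samples with 4096 coalition draws against
a 30-spectrum background. The effect-size calibration simulates 1000
subjects per group. These sizes were chosen so the full acceptance
analysis completes in a few minutes on one CPU while leaving Monte
Carlo error well inside the stated tolerances.

## Known limitations

* The amide-I normalization formula (segment norm, applied after the
  derivative) is one defensible reading of a step the literature names
  but rarely defines; peak-height or area variants would scale spectra
  differently, though all are proportional on amplitude-dominated data.
* The KS normality p-value ignores parameter estimation (no Lilliefors
  correction).
* No confidence intervals on AUC and no multiple-testing correction
  across bands; the univariate stage is descriptive.
* The sampled Shapley estimator is unregularized least squares; for
  feature counts ≫ coalition budget the per-feature values are noisy
  even though their sum is exact, so rankings should be read from the
  mean-|value| aggregate, not a single sample's attribution.
* Plain-LDA results depend on the iterative solver's behavior on an
  ill-conditioned covariance; they are reproducible under a fixed seed
  but should be interpreted as "LDA without regularization fails in
  p ≫ n", not as a meaningful discriminant.
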