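# Methods

`ggnquant` quantifies ground-glass opacity nodules (GGNs) on thin-section
chest CT and reproduces the classical analysis chain used to separate
invasive adenocarcinoma from pre-invasive (AIS) or minimally invasive (MIA)
lesions: first-order histogram and texture features from a segmented
nodule, group comparison, interobserver agreement, multicollinearity
screening, backward-stepwise logistic modelling, ROC analysis, and a fixed
two-threshold decision rule. Because no clinical cohort ships with the
package, a synthetic phantom generator provides cohorts with the class
structure the analysis assumes.

## Feature definitions

All features are computed from the multiset of integer HU values of the
masked voxels plus voxel geometry; traversal order never matters.

- **Percentiles** (2.5th, 25th, 50th, 75th, 97.5th): linear interpolation
  between order statistics.
- **Skewness / kurtosis**: standardised third and fourth central moments;
  kurtosis is non-excess (Gaussian → 3). Undefined on a zero-variance
  sample and recorded as missing.
- **Uniformity** `Σ p_i²` and **entropy** `−Σ p_i log₂ p_i` over a
  histogram with 1-HU-wide bins spanning the nodule's own range. The 1-HU
  bin width (configurable) makes both statistics exactly invariant under a
  constant HU shift and puts entropy in the 7–9 bit range typical for
  lesions of a few hundred to a few thousand voxels with ~150–300 occupied
  grey levels. Log base 2 throughout.
- **Volume** = voxel count × voxel volume (cm³); **density** =
  (mean HU + 1000)/1000 clamped at 0, i.e. the physical-density convention
  with air at 0 and water at 1 g/mL; **mass** = density × volume, exactly.
- **Size, lung setting**: the largest per-axial-slice Feret (caliper)
  diameter of the mask, computed as the maximum pairwise distance between
  voxel centres (via the slice's convex hull) plus one in-plane pixel so a
  single voxel measures one pixel.
- **Size, mediastinal setting**: the same Feret measure applied to the
  largest 26-connected cluster of masked voxels with HU ≥ −160 (the
  conventional soft-tissue visibility bound on mediastinal windows;
  configurable), or 0 for a pure GGN. Note this measure is deliberately
  tied to an absolute HU threshold: it is the one feature that is *not*
  invariant under an HU shift unless the threshold is shifted too.

Two observers' measurements are combined by the per-feature arithmetic
mean.

## Statistical chain

1. **Cohort filter**: nodules whose solid component measures ≥ 5 mm on the
   mediastinal window are excluded (inclusive boundary), mirroring the
   definition of "GGN with little or no solid component".
2. **ANOVA**: classic one-way F-test across AIS/MIA/invasive per feature.
   The overall P is Bonferroni-corrected by the variable family (×2 for
   the two size variables, ×7 for the seven histogram variables). Post hoc
   pairwise comparisons are pooled-variance t-tests with Bonferroni ×3.
3. **Spearman** correlation of every feature with the pathologic invasion
   extent.
4. **ICC(2,1)**: two-way random-effects, absolute-agreement, single-measure
   intraclass correlation from the subject×rater mean squares, with the
   McGraw–Wong F-based 95% CI. Symmetric in the observers; requires ≥ 5
   pairs.
5. **VIF screen**: VIF_j = 1/(1−R²_j) from regressing candidate j on the
   other candidates; the largest-VIF candidate is removed iteratively
   until all VIF ≤ 10. Perfect collinearity counts as infinite VIF.
6. **Backward-stepwise logistic regression** (invasive vs AIS∪MIA):
   candidates are the features with raw ANOVA P < 0.10 that survive the
   VIF screen; starting from the full model, the variable with the largest
   likelihood-ratio removal P is dropped while that P exceeds 0.10.
   Retained variables are reported as odds ratio, Wald 95% CI and Wald P,
   with the full selection trace. Numerically the fit standardises
   predictors internally (Newton on raw HU scales is ill-conditioned) and
   back-transforms the coefficients; likelihood-ratio and Wald statistics
   are invariant to this. Perfect or quasi-separation raises a typed
   error rather than returning diverged coefficients.
7. **ROC**: AUC by tie-aware trapezoidal integration (equal to the
   Mann–Whitney concordance probability); the 95% CI is a stratified
   bootstrap (2000 resamples, seeded) because the analytical CI of the
   reference analysis is not specified. Both the fitted-probability ROC
   and the binary-rule ROC are reported separately.
8. **Two-threshold rule**: predict invasive iff 75th-percentile
   attenuation ≥ −470 HU **and** entropy ≥ 7.90 bits, inclusive at both
   boundaries; evaluated as PPV among rule-positives, sensitivity,
   specificity and binary AUC.

## The phantom generator

Each nodule is a smooth star-shaped blob — a sphere whose radius is
modulated by a low-order random field with ±12% amplitude — embedded in
uniform aerated-lung background (−880 ± 25 HU), voxelised at 0.7 × 0.7 ×
1.25 mm (in-plane pixel size chosen as typical chest CT; slice thickness
fixed by the imaging protocol being emulated). HU values are integers, so
1-HU histogram bins are exact. Generation is a pure function of
(spec, seed); per-nodule seeds derive deterministically from the cohort
master seed, so a cohort is reproducible under parallel generation.

Voxels inside the mask are drawn from a mixture that separates the classes
through *heterogeneity* rather than baseline attenuation:

- a ground-glass matrix `N(μ, σ)` where μ ≈ −670 HU is a **class-
  independent** nuisance (SD 75 HU across nodules) and σ is log-normal
  across nodules with class-ordered medians (AIS 46, MIA 66, INV 90 HU);
- a dense right tail (regional invasive foci) with class-ordered weight
  (≈6%/11.5%/19%) and per-nodule morphology (shift 140–400 HU, width
  50–160 HU);
- class-independent per-nodule histogram idiosyncrasies: a 1–2-HU-wide
  spike at a random offset (collapsed alveoli / scar peaks; weight up to
  15%), a diffuse ±300 HU haze layer (partial-volume rim voxels; up to
  12%), an air-side left tail (air bronchograms; up to 10%), and partial
  quantisation to a 2-HU grid (reconstruction granularity; up to 80% of
  voxels).

The design rationale: entropy is the most linear readout of the latent
heterogeneity (≈ log σ, normally distributed with equal variance per class
when σ is log-normal) and is immune to the baseline-attenuation nuisance
that corrupts every percentile, density and mass. The idiosyncratic
components give uniformity, skewness, kurtosis and the extreme percentiles
substantial between-nodule variation of their own — as real GGN histograms
have — so no feature is a deterministic transform of another and the
multivariable analysis is well-posed (without them, the classes are
jointly separable and the logistic model degenerates). Matrix voxels are
capped just below −160 HU, so a nodule without an explicit solid focus has
no solid component by construction; an optional solid focus (< 5 mm by
invariant, with class-ordered frequency ≈8%/13%/26%) is a contiguous
sphere of soft-tissue attenuation clipped to ≥ −159 HU.

Class geometry: mean diameters 13.2/15.2/18.3 mm (SD 5 mm) for
AIS/MIA/INV; invasion extents are 0 for AIS, uniform (0.5, 5] mm for MIA
and log-normal with median 9.8 mm clipped to [5.1, 19.7] mm for invasive
tumours.

**Observer simulation**: each observer's mask compares the signed
Euclidean distance to the true boundary against `noise` × a smoothed
unit-variance Gaussian field, locally eroding/dilating the contour by
about `noise` voxels (default 1). Zero noise returns the input mask twice;
a perturbation that empties the mask raises an error.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes:
class-ordered entropy/uniformity/high-percentile trends with realistic
overlap (model AUC ≈ 0.88–0.96 across master seeds), interobserver
variability, part-solid frequencies, and the inclusion filter. It does not
model lung anatomy, vessels, airways, scanner noise spectra, or DICOM
acquisition, and no attempt is made to match the absolute per-class
feature means of any clinical cohort — only orderings and dispersion
structure. Consequently the fixed (−470 HU, 7.90 bit) rule sits
conservatively in the synthetic feature distribution: its PPV is high
(≈0.85–1.0) but its sensitivity (≈30–55%) is below what a rule tuned to
the synthetic cohort would achieve. Passing tests therefore demonstrate
correctness and calibration of the *methods*, not clinical performance on
real CT data.

## Numerical choices and degenerate inputs

- Percentile interpolation: linear between order statistics (the most
  common convention), oracle-tested against sort-and-interpolate.
- Constant-HU nodules: entropy 0, uniformity 1, all percentiles equal;
  skewness/kurtosis undefined → NaN, never silently 0.
- Bonferroni: corrected P = min(1, raw P × family size).
- ANOVA with all group means equal and zero between-group SS returns
  F = 0, P = 1 (scipy returns NaN there); all-constant groups raise.
- ICC with perfect agreement returns 1 with CI (1, 1) instead of dividing
  by zero.
- Odds ratios of tiny-scale features (e.g. uniformity, SD ≈ 0.002) can
  exceed the float range per unit; `exp` saturates to `inf`/0 instead of
  overflowing.
- The VIF screen always retains at least one feature; ties in removal are
  broken by dict order (insertion = candidate order), which is
  deterministic.
- Problem sizes in the test suite (cohorts of 60–191 nodules, 20 master
  seeds for the selection-stability check, 1000 small phantoms for the
  invariance sweep, 200 replicates for selection calibration) were chosen
  to estimate the relevant proportions stably while keeping the default
  suite fast.

## Known limitations

- First-order texture only; no co-occurrence (second-order) features.
- The mediastinal-size definition (threshold −160 HU on the segmented
  mask) is a stand-in for window/level-based visual measurement, whose
  exact protocol is not specified in the source analysis.
- Backward elimination inherits the usual instability of stepwise
  selection under collinearity; the selection trace is emitted so every
  removal decision is auditable.
- Within-patient correlation of multiple nodules is ignored by design
  (each nodule treated as an independent lesion).
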