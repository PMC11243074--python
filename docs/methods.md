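# Methods

This note documents the models, defaults and design choices behind
`neuroraman`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the synthetic experiments do
and do not demonstrate.

## Instrument geometry

Two closed forms describe the spiral-scanning optics:

* **Deflection angle.** A scan circle of diameter *D* at optical path
  length *L* from the galvano mirror requires a mirror deflection
  θ ≈ D/(2L) (small-angle approximation; no validity check is applied
  because the approximation *is* the model).  Angles are kept in radians
  internally and converted to mrad at the API boundary.  The inverse,
  `infer_focal_length`, lets a single printed (D, θ) pair pin down *L*;
  the 10 µm ↔ 0.0082 mrad single-cell pair gives L ≈ 0.6098 m, under which
  40 and 70 µm regions give 0.0328 and 0.0574 mrad.
* **Spot size.** The focused-beam diameter is 2M²λ/(πNA).  The
  beam-quality factor enters squared: with M = 1.1, λ = 532 nm, NA = 1.3
  the value is ≈315 nm, consistent only with the squared form.

Exposure times per scan diameter (10 µm → 3 s, 40 µm → 5 s) are stored as
defaults but never enforced; they are acquisition metadata.

## Synthetic data generator

No spectra for this assay are publicly deposited, so the generator defines
the study conditions the pipeline is validated under.

**Spectra.** A cell spectrum on the instrument grid (46–3110 cm⁻¹,
2 cm⁻¹ sampling) is

```
I(ν) = b(ν) + Σ_b A_b · (1 + e·(m_b − 1)) · L(ν; c_b, w_b) + ε(ν) + spikes
```

* `L` is a unit-height Lorentzian (FWHM parametrization) — the standard
  lineshape for Raman bands.
* The band table holds the canonical biomolecular positions seen in cell
  spectra (748, 1000, 1126, 1301, 1337, 1447, 1585, 1660, 2930 cm⁻¹ with
  their usual assignments) plus the activity markers 740, 994, 1121 and
  2848 cm⁻¹.  Amplitudes are 25–100 a.u. over a ~200 a.u. background.
* The ligand effect `e ∈ [0, 1]` acts multiplicatively on band amplitudes:
  the four marker bands carry `m_b = 1.5` (a 50 % rise at full effect), the
  amide-I/C=C region (1585, 1660 cm⁻¹) a weaker `m_b = 1.2`, all other
  bands 1.0.  True effect sizes for this assay are not published in intensity
  units; 1.5× was chosen once as a realistic "clearly detectable by
  multivariate analysis, invisible by eye against the background" effect.
* The fluorescence background `b` is an order-4 polynomial in the
  normalized axis coordinate, positive and slowly varying — deliberately
  inside the span of the preprocessing baseline model so baseline-recovery
  tests have an exact oracle.
* Noise is Gaussian with sd `noise_scale·sqrt(max(signal, 0) + 1)`, a
  shot-noise proxy (variance proportional to intensity); default
  `noise_scale = 0.02`.  Per-cell band amplitudes additionally jitter by a
  5 % multiplicative Gaussian factor, representing biological variability.
* Cosmic rays are single-pixel positive spikes, Poisson-counted per
  measured spectrum (default rate 0.02, realistic for few-second CCD
  exposures), uniform amplitude in 100–600 a.u.
* Ganglion mode averages k = 10 independent cell draws per measured
  spectrum, reproducing the √k noise reduction of population scans.

**Dose-response.** Effects follow a Hill curve e(c) = Emax·cʰ/(EC50ʰ + cʰ)
with Emax = 1, EC50 = 0.5 µM, h = 1 over the dose grid 0, 0.05, 0.5, 5,
50, 500 µM — near-saturation from 5 µM upward, matching the qualitative
ordering of classification difficulty across doses.  Group size defaults
to 30 spectra per condition (20 cells for calcium runs).

**Calcium traces.** Fluorescence is sampled at 0.8 frames s⁻¹ for 200 s
with stimulation at 80 s.  Post-stimulus fluorescence rises with a 2 s
exponential onset toward fold 1 + (2.5 − 1)·e and relaxes with a 60 s
decay; multiplicative Gaussian noise has sd 2 % of baseline, and per-cell
responsiveness jitters log-normally (sd 0.15).  `calcium_present = False`
forces e = 0 at any dose: the calcium-free bath in which receptor
activation cannot raise intracellular calcium.

**What passing tests show.** The synthetic generator exercises the
pipeline's statistical logic (separability, dose ordering, null
calibration, seed reproducibility).  It does not emulate instrument drift,
focus variation, autofluorescence photobleaching kinetics, or real
biological spectral diversity beyond the listed band table — conclusions
about real spectra require real spectra.

## Preprocessing

Fixed stage order: optional despiking → Savitzky–Golay smoothing → baseline
removal → crop + vector normalization.

* **Despiking** (off by default; the acquisition protocol this package
  mirrors does not despike): points deviating from a 7-point running
  median by more than 6 robust (MAD) standard deviations are replaced by
  that median.  The robust sd is floored at 10⁻⁴ of full scale so smooth
  noiseless spectra are not self-flagged on curvature.  If over 5 % of
  points are flagged the spectrum is rejected as broken instead of being
  silently repaired.
* **Smoothing**: order-2 Savitzky–Golay, default window 11 points (~22
  cm⁻¹) — wide enough to suppress shot noise, narrow enough not to flatten
  the narrowest (~8 cm⁻¹ FWHM) bands at 2 cm⁻¹ sampling.  Edges are
  handled by evaluating the boundary-window polynomial fit at the edge
  points.  An order-2 filter reproduces any quadratic exactly.
* **Baseline**: iterative clipped refit ("ModPoly" style) of an order-4
  polynomial — fit, clip the spectrum down onto the fit wherever it lies
  above (bands), refit, iterate to a fixed point.  A plain least-squares
  fit would be biased upward by the bands.  Convergence is geometric with
  a heavy tail (typically ~220 iterations at the 10⁻⁶ relative tolerance,
  occasionally a few thousand), so the iteration cap is 5000 with per-row
  active-set iteration; the polynomial projector is precomputed once, so
  each iteration is two small matrix products and whole spectrum sets are
  processed in well under a second.  Non-convergence warns and returns the
  last iterate.  The procedure is *approximately* idempotent on its own
  output (a second pass re-fits the band envelope and changes the result
  by ~10⁻⁴ of scale on band-bearing spectra); exact idempotency is not a
  property of any clipped-refit scheme.
* **Normalization**: the spectrum is cropped to 600–2980 cm⁻¹ and divided
  by its Euclidean norm over that range; downstream analysis uses only
  this range, making the pipeline exactly invariant to uniform intensity
  rescaling.  Cropping precedes normalization (the norm is defined over
  the stated range).

## Chemometrics

* **PCA** is a mean-centered SVD with explained-variance ratios σᵢ²/Σσⱼ²
  and a deterministic sign convention (largest-magnitude loading element
  positive), so repeated fits are bit-identical.
* **Cross-validated classification** uses stratified k-fold (leave-one-out
  when k = n): per fold, PCA is fitted on the training rows only, both
  partitions are projected, the scores are standardized with
  training-partition statistics, and a linear SVM is trained and scored on
  the held-out fold.  The standardization matters: unit-norm spectra give
  PCA scores of order 10⁻², which the SVM's margin regularization would
  otherwise dominate.  Test rows never influence the projection — the
  suite asserts this fold-honesty explicitly.
* **PLS-DA** codes the two classes as a {0, 1} indicator and extracts five
  latent components by NIPALS (covariance-maximizing deflation, via
  scikit-learn's PLS regression with scaling disabled); successive score
  vectors are mutually orthogonal and the first weight vector is the
  centered covariance direction Xᵀy — both verified against closed forms.
* **Mahalanobis binomialization** turns the five test-spectrum PLS scores
  back into a binary call: class centroids are the per-class means of the
  training scores, the metric is the inverse of the pooled within-class
  covariance plus a ridge λ·I (default λ = 10⁻⁶·trace/5 — with as few as
  16 spectra per class in 5 dimensions, an unridged covariance can be
  near-singular), and each spectrum is assigned to the nearer centroid.
  The continuous decision score for ROC analysis is d(class₀) − d(class₁),
  the canonical monotone surrogate when only distances are defined.
* **Evaluation** follows the 80/20 random split protocol (resampled once
  if a partition misses a class, then an error): confusion counts and the
  three printed metrics, trapezoidal ROC/AUC over the decision score
  (tie-handling equals the Mann–Whitney statistic), and RMSE of the
  continuous PLS prediction against the indicator.  Several published
  variants of the validation protocol exist (10-fold CV, five repeats,
  80/20 split); all are reachable through configuration and none is
  hard-wired as "the" protocol.

## Dose statistics

* **ΔF/F**: the baseline F is the mean fluorescence before stimulation;
  ΔF(t)/F is reported per frame with the peak post-stimulus fold as
  summary.  A cell is a *responder* if its fold strictly exceeds 1.5.
* **t-test / ANOVA**: Student's pooled-variance t (not Welch), classical
  one-way ANOVA; degenerate zero-variance inputs yield flagged p ∈ {0, 1}
  rather than NaN.  Tukey's HSD is delegated to scipy behind the same
  report interface.
* **Williams-type trend test**: treatment means are replaced by their
  isotonic (monotone non-decreasing) estimates via pooled-adjacent-
  violators weighted by group size; dose i is tested with
  t̄ᵢ = (μ̂ᵢ − ȳ₀)/√(s²(1/nᵢ + 1/n₀)), s² the ANOVA within-group variance.
  Critical values come from a seeded Monte-Carlo simulation of the null
  (equal normal means, the same n-structure, the same isotonic procedure)
  rather than printed tables, which cover few (k, n) combinations; the
  per-dose rejection rate is thereby calibrated to α by construction, and
  the calibration is itself verified empirically (2000 null replicates).
  Significance is assigned step-down from the highest dose — a dose is
  declared significant only if every higher dose is — following the
  closed-testing logic of trend tests.  Precomputed critical values can be
  passed in when many tests share one n-structure.

## Reproducibility

Every stochastic stage derives its seed from the single global seed and
the stage name (SHA-256, reduced below 2³¹), so stages can be re-run in
isolation and full runs are bit-reproducible; the run manifest records the
configuration hash, stage seeds and timings.  Problem sizes used in the
validation suite — 30 spectra per condition (the assay's own group size),
10 seeds for recovery experiments, 2000 null replicates with a 10⁴-sample
critical-value simulation — were chosen as the smallest designs at which
the checked properties are stable.

## Known limitations

* Binary PLS-DA only; multi-dose designs are handled one-vs-control.
* The JCAMP-DX reader supports the `(X++(Y..Y))` dialect with
  XFACTOR/YFACTOR; compressed (DIF/DUP/SQZ) forms and vendor binary
  formats are out of scope.
* The baseline model is a single global polynomial; wavelet or asymmetric
  least-squares baselines are not provided.
* Calibration fits a degree-≤2 polynomial; higher-order axis distortions
  require more anchors than the three-point sulfur protocol provides.
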