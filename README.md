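# neuroraman

Label-free chemometric assessment of neuronal activity from single-cell
Raman micro-spectroscopy.

## The problem

Spiral-scanning Raman microscopes can collect an integrated spectrum from a
whole cell (a ~10 µm circle) or a whole autonomic ganglion (40–70 µm) in a
few seconds, without any label.  Whether a neuron has just been activated
by a ligand (glutamate on cortical-type neurons, nicotine on autonomic
ganglia) is not visible as a new peak: it is a small, distributed change in
band intensities — notably at 740, 994, 1121 and 2848 cm⁻¹ — that only
multivariate analysis can read out.  `neuroraman` implements that read-out
as a tested, reproducible pipeline for scientists working with such
spectra, together with a synthetic-data generator that emulates the assay
designs (no public spectra exist for this kind of experiment), and the
calcium-imaging statistics used to validate the spectral read-out.

## What it computes

- **Scan geometry** — mirror deflection angle θ ≈ D/(2L) for a scan circle
  of diameter D at optical path length L, and the diffraction-limited spot
  diameter 2M²λ/(πNA).
- **Preprocessing** — optional cosmic-ray despiking, Savitzky–Golay
  smoothing (order 2), iterative order-4 polynomial baseline removal,
  cropping to 600–2980 cm⁻¹ and L2 vector normalization.
- **Chemometrics** — mean-centered PCA (scores, loadings,
  explained-variance ratios); fold-honest k-fold PCA + linear-SVM
  classification; two-class PLS-DA onto the {0, 1} indicator; Mahalanobis
  nearest-centroid *binomialization* of the five PLS scores under a pooled
  within-class covariance; sensitivity = TP/(TP+FN), specificity =
  TN/(TN+FP), accuracy = (TP+TN)/total; ROC/AUC over the decision score
  d(class₀) − d(class₁); RMSE of the continuous prediction.
- **Dose-response statistics** — ΔF/F of calcium-indicator traces, the
  strict 1.5-fold responder rule, Student's t-test, one-way ANOVA, and a
  Williams-type step-down trend test against the 0 µM control using
  isotonic (pooled-adjacent-violators) mean estimates with seeded
  Monte-Carlo critical values.
- **Synthetic data** — Lorentzian band spectra on a polynomial fluorescence
  background with shot-like noise and Poisson cosmic-ray spikes; a
  multiplicative marker-band ligand effect following a Hill dose-response
  e(c) = Emax·cʰ/(EC50ʰ + cʰ) over the 0–500 µM nicotine grid; sulfur
  calibration standards (peaks at 50.0, 85.1, 153.8, 219.1, 473.2 cm⁻¹);
  calcium traces sampled at 0.8 s⁻¹ with stimulation at 80 s and a
  calcium-free null condition.

## Worked example

```python
import numpy as np
from neuroraman import (SyntheticDesign, generate_dataset,
                        preprocess_pipeline, fit_pca, plsda_evaluate)

design = SyntheticDesign(seed=42)                     # 30 + 30 spectra
raw = generate_dataset(design, mode="two_class", seed=42)
processed = preprocess_pipeline(raw)                  # smooth, baseline, norm

pca = fit_pca(processed, n_components=5)
print("EVR:", np.round(pca.explained_variance_ratio, 3))

result = plsda_evaluate(processed, processed.labels, rng=42)
print(result.summary())
```

prints

```
EVR: [0.789 0.08  0.045 0.02  0.017]
PLS-DA + Mahalanobis binomial classification
positive class: 'stimulated'; 48 train / 12 test spectra; 5 latent components
confusion: TP=6 FP=0 TN=6 FN=0
sensitivity = 1.000   specificity = 1.000   accuracy = 1.000
AUC = 1.000   RMSE = 0.166
```

The explained-variance ratios say that one spectral direction carries most
of the between-spectrum variance (dominated by the ligand effect on the
marker bands), and the held-out evaluation shows the stimulated and control
populations are perfectly separable under these synthetic conditions: AUC
of 1.0 with no false calls among the 12 test spectra.  A zero-effect
("calcium-free") twin of the same design yields chance-level AUC.

The same chain is scriptable from the shell:

```sh
neuroraman geometry                       # (D, θ mrad, spot nm) table
neuroraman run --seed 3 --outdir out/     # simulate→preprocess→classify→dose
```

## Layout

```
src/neuroraman/
  geometry.py       scan-geometry closed forms
  synth.py          synthetic spectra, sulfur standard, calcium traces
  spectra.py        Spectrum/SpectrumSet, file I/O, calibration, regridding
  preprocess.py     smoothing, baseline, crop + vector normalization
  chemometrics.py   PCA, PLS-DA, Mahalanobis binomialization, ROC/AUC
  dosestats.py      ΔF/F, responders, t/ANOVA, Williams-type trend test
  config.py         RunConfig with YAML round-trip and seed fan-out
  pipeline.py       end-to-end orchestration with manifest
  cli.py            `neuroraman` command-line interface
docs/methods.md     model and design notes
```
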