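"""Seedable synthetic data with the statistical structure of the real assays.

No spectra from the original experiments are publicly deposited, so this
module generates datasets that emulate their design:

* single-cell and ganglion Raman spectra built from Lorentzian bands at the
  canonical biomolecular positions (nucleic acids 748/1337, proteins
  1000/1126/1447/1585/1660, lipids 1301/2930 cm⁻¹, ...) riding on a broad
  order-4 polynomial fluorescence background, with shot-like
  intensity-dependent Gaussian noise and sparse single-pixel cosmic-ray
  spikes;
* a ligand-response effect that multiplicatively raises the activity-marker
  bands (740, 994, 1121 and 2848 cm⁻¹, plus a weaker change in the
  1592-1668 cm⁻¹ amide-I/C=C region);
* a saturating Hill dose-response over the nicotine dose grid
  0, 0.05, 0.5, 5, 50, 500 µM;
* a sulfur wavenumber-calibration standard with its five characteristic
  peaks (50.0, 85.1, 153.8, 219.1, 473.2 cm⁻¹) seen through a configurable
  pixel-axis distortion;
* Fluo-8-style calcium fluorescence traces sampled at 0.8 s⁻¹ with ligand
  stimulation at 80 s, including a calcium-free null condition.

Every generator is a pure function of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from neuroraman.dosestats import CalciumTrace
from neuroraman.exceptions import InvalidParameterError
from neuroraman.spectra import Spectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "SyntheticDesign",
    "CalciumDesign",
    "SulfurReference",
    "SULFUR_PEAKS_CM1",
    "SULFUR_CALIBRATION_ANCHORS_CM1",
    "default_band_table",
    "effect_fraction",
    "generate_spectrum",
    "generate_dataset",
    "generate_sulfur_reference",
    "generate_calcium_traces",
]

_INSTRUMENT_RANGE_CM1 = (46.0, 3110.0)

#: The five characteristic sulfur peaks used for spectrometer calibration.
SULFUR_PEAKS_CM1 = (50.0, 85.1, 153.8, 219.1, 473.2)
#: The three of them used as calibration anchors.
SULFUR_CALIBRATION_ANCHORS_CM1 = (153.8, 219.1, 473.2)


@dataclass(frozen=True)
class BandSpec:
    """One Raman band of the synthetic cell spectrum.

    ``effect_multiplier`` is the fold-change of the band amplitude at full
    ligand effect; 1.0 marks an unresponsive band.
    """

    center_cm1: float
    width_cm1: float
    amplitude: float
    effect_multiplier: float = 1.0
    assignment: str = ""

    def __post_init__(self) -> None:
        lo, hi = _INSTRUMENT_RANGE_CM1
        if not lo <= self.center_cm1 <= hi:
            raise InvalidParameterError(
                f"band center {self.center_cm1} outside instrument range {lo}-{hi} cm-1")
        if self.width_cm1 <= 0:
            raise InvalidParameterError("band width must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("band amplitude must be non-negative")
        if self.effect_multiplier <= 0:
            raise InvalidParameterError("effect multiplier must be positive")


def default_band_table() -> tuple[BandSpec, ...]:
    """Band table of the synthetic neuron spectrum.

    Positions follow the standard biomolecular assignments observed in the
    cell spectra; the activity markers (740, 994, 1121, 2848 cm⁻¹) carry a
    1.5-fold amplitude response at full ligand effect and the amide-I/C=C
    region (1585, 1660 cm⁻¹) a weaker 1.2-fold response.  Amplitudes are
    arbitrary units on top of a ~200 a.u. fluorescence background.
    """
    return (
        BandSpec(740.0, 12.0, 30.0, 1.5, "purine ring breathing (nucleic acids)"),
        BandSpec(748.0, 12.0, 40.0, 1.0, "DNA"),
        BandSpec(994.0, 10.0, 25.0, 1.5, "O-P-O symmetric stretch"),
        BandSpec(1001.0, 8.0, 60.0, 1.0, "phenylalanine ring breathing"),
        BandSpec(1121.0, 12.0, 30.0, 1.5, "C-O stretch in ribose"),
        BandSpec(1126.0, 12.0, 45.0, 1.0, "C-C lipid / C-N protein stretch"),
        BandSpec(1301.0, 16.0, 50.0, 1.0, "CH2 twist in lipids"),
        BandSpec(1337.0, 16.0, 55.0, 1.0, "amide III / adenine-guanine"),
        BandSpec(1447.0, 18.0, 70.0, 1.0, "CH2 bending in proteins and lipids"),
        BandSpec(1585.0, 14.0, 40.0, 1.2, "C=C stretch / cytochrome c"),
        BandSpec(1660.0, 20.0, 65.0, 1.2, "amide I / C=C cis lipids"),
        BandSpec(2848.0, 30.0, 80.0, 1.5, "CH2 symmetric stretch in lipids"),
        BandSpec(2930.0, 35.0, 100.0, 1.0, "CH2 asymmetric stretch"),
    )


def _default_grid() -> np.ndarray:
    lo, hi = _INSTRUMENT_RANGE_CM1
    return np.arange(lo, hi + 1e-9, 2.0)


def _default_baseline_coeffs() -> tuple[float, ...]:
    # order-4 polynomial in the normalized axis coordinate t in [0, 1];
    # positive and slowly varying (~175-200 a.u.), exactly representable by
    # the preprocessing baseline model.
    return (200.0, -150.0, 300.0, -250.0, 100.0)


@dataclass(frozen=True)
class SyntheticDesign:
    """Full generative specification of a synthetic Raman experiment.

    Defaults mirror the real assay designs: 30 spectra per condition, the
    0-500 µM nicotine dose grid, near-saturation at ≥5 µM (Hill EC50 0.5 µM,
    h = 1, Emax = 1), shot-like noise with scale 0.02 and sparse cosmic-ray
    spikes.
    """

    bands: tuple[BandSpec, ...] = field(default_factory=default_band_table)
    baseline_coeffs: tuple[float, ...] = field(default_factory=_default_baseline_coeffs)
    noise_scale: float = 0.02
    spike_rate: float = 0.02
    spike_amplitude_range: tuple[float, float] = (100.0, 600.0)
    amplitude_jitter: float = 0.05
    dose_grid_um: tuple[float, ...] = (0.0, 0.05, 0.5, 5.0, 50.0, 500.0)
    emax: float = 1.0
    ec50_um: float = 0.5
    hill_h: float = 1.0
    n_per_group: int = 30
    grid_cm1: np.ndarray = field(default_factory=_default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid_cm1, dtype=float)
        object.__setattr__(self, "grid_cm1", grid)
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        object.__setattr__(self, "dose_grid_um", tuple(self.dose_grid_um))
        doses = np.asarray(self.dose_grid_um, float)
        if np.any(doses < 0) or np.any(np.diff(doses) <= 0):
            raise InvalidParameterError("dose grid must be non-negative and sorted")
        if self.ec50_um <= 0 or self.hill_h <= 0 or self.emax < 0:
            raise InvalidParameterError("ec50 > 0, hill_h > 0 and emax >= 0 required")
        if self.n_per_group < 2:
            raise InvalidParameterError("n_per_group must be >= 2")
        if np.any(np.diff(grid) <= 0):
            raise InvalidParameterError("wavenumber grid must be strictly increasing")
        if self.noise_scale < 0 or self.spike_rate < 0 or self.amplitude_jitter < 0:
            raise InvalidParameterError("noise parameters must be non-negative")

    def with_(self, **changes) -> "SyntheticDesign":
        """Functional update (`dataclasses.replace` shorthand)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class CalciumDesign:
    """Design of a synthetic calcium-imaging run.

    Sampling at 0.8 frames s⁻¹, ligand stimulation at 80 s, 20 cells per
    condition.  ``calcium_present = False`` models the calcium-free bath in
    which receptor activation cannot raise intracellular calcium: the
    evoked effect is forced to zero.
    """

    frame_rate_hz: float = 0.8
    stim_time_s: float = 80.0
    duration_s: float = 200.0
    n_cells: int = 20
    baseline_f: float = 100.0
    peak_fold_at_emax: float = 2.5
    noise_sd_frac: float = 0.02
    rise_tau_s: float = 2.0
    decay_tau_s: float = 60.0
    cell_effect_jitter: float = 0.15
    calcium_present: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame rate must be positive")
        if not 0 < self.stim_time_s < self.duration_s:
            raise InvalidParameterError("stimulation time must fall inside the trace")
        if self.n_cells < 1:
            raise InvalidParameterError("need at least one cell")
        if self.baseline_f <= 0 or self.peak_fold_at_emax < 1:
            raise InvalidParameterError(
                "baseline fluorescence must be positive and peak fold >= 1")


# ---------------------------------------------------------------------------
# dose-response


def effect_fraction(dose_um: float, design: SyntheticDesign) -> float:
    """Hill-model effect fraction Emax·cʰ/(EC50ʰ + cʰ) at dose c (µM).

    Zero at dose 0 and monotone non-decreasing in dose, saturating at
    ``design.emax``.
    """
    dose = float(dose_um)
    if dose < 0:
        raise InvalidParameterError("dose must be non-negative")
    if dose == 0.0:
        return 0.0
    ch = dose ** design.hill_h
    return design.emax * ch / (design.ec50_um ** design.hill_h + ch)


# ---------------------------------------------------------------------------
# spectra


def _lorentzian(nu: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return 1.0 / (1.0 + (2.0 * (nu - center) / fwhm) ** 2)


def _baseline(design: SyntheticDesign) -> np.ndarray:
    grid = design.grid_cm1
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    return np.polynomial.polynomial.polyval(t, np.asarray(design.baseline_coeffs))


def _noiseless_signal(design: SyntheticDesign, effect: float,
                      band_scale: np.ndarray | None = None) -> np.ndarray:
    """Baseline plus effect-scaled bands; `band_scale` holds per-band jitter."""
    grid = design.grid_cm1
    signal = _baseline(design).copy()
    for i, band in enumerate(design.bands):
        amp = band.amplitude * (1.0 + effect * (band.effect_multiplier - 1.0))
        if band_scale is not None:
            amp *= band_scale[i]
        signal += amp * _lorentzian(grid, band.center_cm1, band.width_cm1)
    return signal


def generate_spectrum(design: SyntheticDesign, label: str = "control",
                      dose_um: float | None = None, effect: float | None = None,
                      rng: np.random.Generator | None = None,
                      n_cells_averaged: int = 1) -> Spectrum:
    """Draw one synthetic cell (or ganglion-averaged) spectrum.

    The deterministic part is ``baseline(ν) + Σ_b A_b·(1 + effect·(mult_b −
    1))·Lorentz(ν; c_b, w_b)``.  Per-cell band amplitudes are jittered by a
    multiplicative Gaussian factor, shot-like noise with standard deviation
    ``noise_scale·sqrt(max(signal, 0) + 1)`` is added, and a
    Poisson(``spike_rate``) number of single-pixel positive cosmic-ray
    spikes is injected.  ``n_cells_averaged > 1`` averages that many
    independent cell draws (ganglion mode); spikes are per measured
    spectrum, not per cell.

    If ``effect`` is None it is derived from ``dose_um`` through the Hill
    model (dose None ⇒ effect 0).
    """
    if not design.bands:
        raise InvalidParameterError("band list must not be empty")
    if effect is None:
        effect = effect_fraction(dose_um, design) if dose_um is not None else 0.0
    rng = rng if rng is not None else np.random.default_rng(design.seed)

    grid = design.grid_cm1
    acc = np.zeros_like(grid)
    for _ in range(n_cells_averaged):
        if design.amplitude_jitter > 0:
            scale = 1.0 + design.amplitude_jitter * rng.standard_normal(len(design.bands))
            scale = np.clip(scale, 0.0, None)
        else:
            scale = None
        signal = _noiseless_signal(design, effect, scale)
        if design.noise_scale > 0:
            sd = design.noise_scale * np.sqrt(np.maximum(signal, 0.0) + 1.0)
            signal = signal + sd * rng.standard_normal(len(grid))
        acc += signal
    intensities = acc / n_cells_averaged

    if design.spike_rate > 0:
        n_spikes = rng.poisson(design.spike_rate)
        if n_spikes:
            idx = rng.integers(0, len(grid), size=n_spikes)
            lo, hi = design.spike_amplitude_range
            intensities[idx] += rng.uniform(lo, hi, size=n_spikes)

    meta = {"label": label, "effect": float(effect)}
    if dose_um is not None:
        meta["dose_um"] = float(dose_um)
    return Spectrum(grid.copy(), intensities, meta)


def generate_dataset(design: SyntheticDesign, mode: str = "two_class",
                     cells_per_spectrum: int = 1, null_effect: bool = False,
                     stim_dose_um: float | None = None,
                     seed: int | None = None) -> SpectrumSet:
    """Generate a labelled synthetic :class:`SpectrumSet`.

    Parameters
    ----------
    mode : {"two_class", "dose_series"}
        ``two_class`` draws ``n_per_group`` control spectra (effect 0) and
        ``n_per_group`` stimulated spectra at full effect (or at
        ``stim_dose_um`` through the Hill model).  ``dose_series`` draws
        ``n_per_group`` spectra at every dose of ``design.dose_grid_um``,
        with per-row dose labels.
    cells_per_spectrum : int
        1 reproduces single-cell scans; ~10 emulates ganglion scans, where
        each measured spectrum is the average over the cells in the region.
    null_effect : bool
        Force the ligand effect to zero in every condition — the
        calcium-free control in which stimulation cannot act.  Labels and
        doses are still attached, so downstream classification faces pure
        noise.
    """
    if mode not in ("two_class", "dose_series"):
        raise InvalidParameterError(f"unknown dataset mode {mode!r}")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows, labels, doses = [], [], []

    if mode == "two_class":
        stim_effect = (effect_fraction(stim_dose_um, design)
                       if stim_dose_um is not None else design.emax)
        conditions = [("control", 0.0, 0.0), ("stimulated", stim_effect,
                                              stim_dose_um or np.nan)]
        for label, eff, dose in conditions:
            if null_effect:
                eff = 0.0
            for _ in range(design.n_per_group):
                spec = generate_spectrum(design, label=label, effect=eff, rng=rng,
                                         n_cells_averaged=cells_per_spectrum)
                rows.append(spec.intensities_au)
                labels.append(label)
                doses.append(dose)
        dose_arr = np.asarray(doses)
        return SpectrumSet(design.grid_cm1.copy(), np.vstack(rows),
                           np.asarray(labels),
                           None if np.all(np.isnan(dose_arr)) else dose_arr)

    for dose in design.dose_grid_um:
        eff = 0.0 if null_effect else effect_fraction(dose, design)
        label = "control" if dose == 0 else f"{dose:g}uM"
        for _ in range(design.n_per_group):
            spec = generate_spectrum(design, label=label, effect=eff, rng=rng,
                                     n_cells_averaged=cells_per_spectrum)
            rows.append(spec.intensities_au)
            labels.append(label)
            doses.append(dose)
    return SpectrumSet(design.grid_cm1.copy(), np.vstack(rows),
                       np.asarray(labels), np.asarray(doses))


# ---------------------------------------------------------------------------
# sulfur calibration standard


@dataclass
class SulfurReference:
    """A synthetic sulfur standard plus its calibration ground truth."""

    spectrum: Spectrum          # intensities on the distorted (pixel) axis
    true_peaks_cm1: np.ndarray  # the five certified positions
    observed_peaks: np.ndarray  # where they fall on the distorted axis
    true_axis_cm1: np.ndarray   # undistorted axis, for round-trip tests


def generate_sulfur_reference(noise_scale: float = 0.0,
                              pixel_distortion=None,
                              rng: np.random.Generator | None = None,
                              n_points: int = 1024) -> SulfurReference:
    """Synthesize the sulfur calibration standard.

    Lorentzian bands are placed at exactly the five certified positions
    (50.0, 85.1, 153.8, 219.1, 473.2 cm⁻¹) on a dense axis covering
    30-520 cm⁻¹; ``pixel_distortion`` (a monotone map true-cm⁻¹ →
    observed-axis units, default identity) then warps the axis, emulating an
    uncalibrated spectrometer.  The returned ground truth lets calibration
    be tested as a round trip.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    true_axis = np.linspace(30.0, 520.0, n_points)
    amplitudes = (35.0, 25.0, 60.0, 100.0, 80.0)
    widths = (4.0, 4.0, 4.5, 5.0, 6.0)
    intensities = np.zeros_like(true_axis)
    for pos, amp, w in zip(SULFUR_PEAKS_CM1, amplitudes, widths):
        intensities += amp * _lorentzian(true_axis, pos, w)
    if noise_scale > 0:
        intensities = intensities + noise_scale * rng.standard_normal(n_points)

    if pixel_distortion is None:
        observed_axis = true_axis.copy()
        observed_peaks = np.asarray(SULFUR_PEAKS_CM1, float)
    else:
        observed_axis = np.asarray(pixel_distortion(true_axis), dtype=float)
        if np.any(np.diff(observed_axis) <= 0):
            raise InvalidParameterError("pixel distortion must be strictly monotone")
        observed_peaks = np.asarray(
            [float(pixel_distortion(np.asarray([p]))[0]) for p in SULFUR_PEAKS_CM1])

    spectrum = Spectrum(observed_axis, intensities, {"label": "sulfur"})
    return SulfurReference(spectrum, np.asarray(SULFUR_PEAKS_CM1, float),
                           observed_peaks, true_axis)


# ---------------------------------------------------------------------------
# calcium traces


def generate_calcium_traces(cal: CalciumDesign, dose_um: float,
                            design: SyntheticDesign | None = None,
                            seed: int | None = None) -> list[CalciumTrace]:
    """Draw synthetic Fluo-8 fluorescence traces for one dose condition.

    Each cell's fluorescence sits at ``baseline_f`` with multiplicative
    Gaussian noise; after the stimulation time it rises with a fast
    exponential onset toward ``1 + (peak_fold_at_emax − 1)·effect`` fold and
    relaxes back with a slow exponential decay.  Per-cell responsiveness is
    jittered log-normally.  With ``calcium_present = False`` the effect is
    forced to zero regardless of dose.
    """
    design = design if design is not None else SyntheticDesign()
    rng = np.random.default_rng(cal.seed if seed is None else seed)
    eff = effect_fraction(dose_um, design) if cal.calcium_present else 0.0

    n_frames = int(round(cal.duration_s * cal.frame_rate_hz))
    t = np.arange(n_frames) / cal.frame_rate_hz
    post = t >= cal.stim_time_s
    dt = t[post] - cal.stim_time_s
    kinetics = (1.0 - np.exp(-dt / cal.rise_tau_s)) * np.exp(-dt / cal.decay_tau_s)

    traces = []
    for _ in range(cal.n_cells):
        cell_eff = eff * np.exp(cal.cell_effect_jitter * rng.standard_normal())
        f = np.full(n_frames, cal.baseline_f)
        f[post] *= 1.0 + (cal.peak_fold_at_emax - 1.0) * cell_eff * kinetics
        f = f * (1.0 + cal.noise_sd_frac * rng.standard_normal(n_frames))
        traces.append(CalciumTrace(time_s=t.copy(), fluorescence_au=f,
                                   stim_time_s=cal.stim_time_s))
    return traces
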