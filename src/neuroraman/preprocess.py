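"""The spectral preprocessing chain.

Order of operations (fixed): optional despiking → Savitzky-Golay smoothing
(second polynomial order) → iterative order-4 polynomial baseline removal →
crop to 600-2980 cm⁻¹ + Euclidean vector normalization.  Downstream
analysis uses only the cropped, unit-norm range, so the pipeline output is
invariant to uniform intensity rescaling of the input.

Baseline estimation is a ModPoly-style clipped refit: fit an order-4
polynomial, clip the spectrum down onto the fit wherever it lies above
(peaks), refit, and iterate to a fixed point.  A plain least-squares fit
would be biased upward by the Raman bands; the clipped iteration converges
to the smooth fluorescence background instead.

Despiking is OFF by default (the measured spectra are assumed clean); it
exists because the synthetic generator can inject cosmic-ray spikes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from neuroraman.exceptions import (
    DataQualityError,
    InvalidParameterError,
    NormalizationError,
)
from neuroraman.spectra import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "despike",
    "sg_smooth",
    "baseline_correct",
    "crop_and_vector_normalize",
    "preprocess_spectrum",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The smoothing window is not dictated by the protocol; 11 points is the
    default — wide enough to suppress shot noise, narrow enough not to
    flatten the narrowest (~8 cm⁻¹ FWHM) bands at ~2 cm⁻¹ sampling.
    """

    sg_window: int = 11
    sg_polyorder: int = 2
    baseline_order: int = 4
    baseline_max_iter: int = 5000
    baseline_tol: float = 1e-6
    norm_range_cm1: tuple[float, float] = (600.0, 2980.0)
    despike_enabled: bool = False
    despike_window: int = 7
    despike_z: float = 6.0
    despike_max_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise InvalidParameterError(
                "sg_window must be odd and larger than sg_polyorder")
        if self.baseline_order < 1:
            raise InvalidParameterError("baseline order must be >= 1")
        if self.norm_range_cm1[0] >= self.norm_range_cm1[1]:
            raise InvalidParameterError("norm range must be (low, high)")
        if self.despike_window < 5:
            raise InvalidParameterError("despike window must be >= 5 points")

    def with_(self, **changes) -> "PreprocessConfig":
        return replace(self, **changes)


def despike(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Remove single-pixel cosmic-ray spikes by running-median comparison.

    Points deviating from the running median by more than ``despike_z``
    robust (MAD-based) standard deviations are replaced by that median.  If
    more than ``despike_max_fraction`` of points are flagged the spectrum is
    considered broken and a :class:`DataQualityError` is raised instead of
    silently repairing it.
    """
    config = config or PreprocessConfig()
    y = spectrum.intensities_au
    med = median_filter(y, size=config.despike_window, mode="nearest")
    resid = y - med
    sd = 1.4826 * np.median(np.abs(resid))
    # floor at 1e-4 of full scale: on a smooth noiseless spectrum both the
    # residuals and their MAD are curvature-sized, and without a floor the
    # ratio would flag ordinary curvature as spikes
    sd = max(sd, 1e-4 * max(1.0, float(np.max(np.abs(y), initial=0.0))))
    flagged = np.abs(resid) > config.despike_z * sd
    if flagged.mean() > config.despike_max_fraction:
        raise DataQualityError(
            f"{flagged.sum()} of {len(y)} points ({100 * flagged.mean():.1f}%) "
            "flagged as spikes; spectrum looks broken")
    if not flagged.any():
        return spectrum.copy_with(y.copy())
    out = y.copy()
    out[flagged] = med[flagged]
    return spectrum.copy_with(out, despiked_points=int(flagged.sum()))


def sg_smooth(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Endpoints are handled by fitting the boundary window and evaluating the
    fitted polynomial at the edge points.  An order-2 filter reproduces any
    quadratic sequence exactly.
    """
    config = config or PreprocessConfig()
    if config.sg_window > len(spectrum):
        raise InvalidParameterError(
            f"SG window {config.sg_window} exceeds spectrum length {len(spectrum)}")
    smoothed = savgol_filter(spectrum.intensities_au, config.sg_window,
                             config.sg_polyorder, mode="interp")
    return spectrum.copy_with(smoothed)


def _fit_baselines(x: np.ndarray, Y: np.ndarray,
                   config: PreprocessConfig) -> tuple[np.ndarray, bool]:
    """Clipped-refit polynomial baselines for every row of ``Y``.

    The order-``baseline_order`` least-squares fit is a fixed linear map,
    so it is precomputed once (Vandermonde on the [-1, 1]-scaled axis and
    its pseudo-inverse) and each iteration costs two small matrix products.
    Returns the baseline matrix and a convergence flag.
    """
    t = 2.0 * (x - x[0]) / (x[-1] - x[0]) - 1.0
    V = np.polynomial.polynomial.polyvander(t, config.baseline_order)
    P = np.linalg.pinv(V)                       # coefficients = P @ y
    Yw = Y.astype(float).copy()
    scale = np.maximum(np.max(np.abs(Yw), axis=1, keepdims=True), 1e-300)
    baselines = np.empty_like(Yw)
    # per-row active set: most rows converge in a few hundred iterations,
    # a few stragglers dominate the cap, so finished rows drop out
    active = np.arange(Yw.shape[0])
    for _ in range(config.baseline_max_iter):
        B = (Yw[active] @ P.T) @ V.T
        baselines[active] = B
        clipped = np.minimum(Yw[active], B)
        change = np.max(np.abs(clipped - Yw[active]) / scale[active], axis=1)
        Yw[active] = clipped
        active = active[change >= config.baseline_tol]
        if active.size == 0:
            return baselines, True
    return baselines, False


def baseline_correct(spectrum: Spectrum,
                     config: PreprocessConfig | None = None
                     ) -> tuple[Spectrum, Spectrum]:
    """Iterative clipped polynomial baseline estimation and removal.

    Fit an order-4 polynomial, clip the spectrum down onto the fit, refit;
    iterate until the clipping step changes nothing (relative tolerance
    ``baseline_tol``).  Returns ``(corrected, baseline)``.  Non-convergence
    within ``baseline_max_iter`` iterations logs a warning and returns the
    last iterate rather than raising.
    """
    config = config or PreprocessConfig()
    if len(spectrum) < config.baseline_order + 2:
        raise InvalidParameterError("too few points for the baseline order")
    baselines, converged = _fit_baselines(
        spectrum.wavenumbers_cm1, spectrum.intensities_au[None, :], config)
    if not converged:
        warnings.warn("baseline fit did not converge; returning last iterate",
                      stacklevel=2)
        logger.warning("baseline fit did not converge after %d iterations",
                       config.baseline_max_iter)
    baseline = baselines[0]
    corrected = spectrum.copy_with(spectrum.intensities_au - baseline)
    return corrected, spectrum.copy_with(baseline, label="baseline")


def crop_and_vector_normalize(spectrum: Spectrum,
                              config: PreprocessConfig | None = None) -> Spectrum:
    """Crop to the normalization range and divide by the Euclidean norm.

    The output spectrum covers only ``norm_range_cm1`` (600-2980 cm⁻¹ by
    default) and has unit L2 norm there; uniform input rescaling therefore
    cancels exactly.
    """
    config = config or PreprocessConfig()
    lo, hi = config.norm_range_cm1
    mask = (spectrum.wavenumbers_cm1 >= lo) & (spectrum.wavenumbers_cm1 <= hi)
    if mask.sum() < 2:
        raise InvalidParameterError(
            f"normalization range [{lo}, {hi}] does not overlap the grid")
    values = spectrum.intensities_au[mask]
    norm = float(np.linalg.norm(values))
    if norm == 0.0:
        raise NormalizationError(
            f"spectrum is identically zero on the normalization range [{lo}, {hi}]")
    return Spectrum(spectrum.wavenumbers_cm1[mask], values / norm,
                    dict(spectrum.meta))


def preprocess_spectrum(spectrum: Spectrum,
                        config: PreprocessConfig | None = None) -> Spectrum:
    """Run the full chain on one spectrum (despike? → smooth → baseline →
    crop + normalize)."""
    config = config or PreprocessConfig()
    if config.despike_enabled:
        spectrum = despike(spectrum, config)
    spectrum = sg_smooth(spectrum, config)
    spectrum, _ = baseline_correct(spectrum, config)
    return crop_and_vector_normalize(spectrum, config)


def preprocess_pipeline(sset: SpectrumSet,
                        config: PreprocessConfig | None = None) -> SpectrumSet:
    """Apply the chain to every row of a :class:`SpectrumSet`.

    Equivalent to :func:`preprocess_spectrum` per row (same stage order and
    parameters) but with the smoothing and baseline stages vectorized over
    the whole matrix.  Labels and doses are preserved row-for-row; stage
    errors are re-raised annotated with the row index.
    """
    config = config or PreprocessConfig()
    x = sset.grid
    Y = sset.matrix.astype(float).copy()

    if config.despike_enabled:
        for i in range(Y.shape[0]):
            try:
                Y[i] = despike(Spectrum(x, Y[i]), config).intensities_au
            except Exception as exc:
                raise type(exc)(f"row {i}: {exc}") from exc

    if config.sg_window > Y.shape[1]:
        raise InvalidParameterError("SG window exceeds spectrum length")
    Y = savgol_filter(Y, config.sg_window, config.sg_polyorder,
                      axis=1, mode="interp")

    baselines, converged = _fit_baselines(x, Y, config)
    if not converged:
        warnings.warn("baseline fit did not converge on some rows; "
                      "returning last iterate", stacklevel=2)
    Y = Y - baselines

    lo, hi = config.norm_range_cm1
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        raise InvalidParameterError(
            f"normalization range [{lo}, {hi}] does not overlap the grid")
    Y = Y[:, mask]
    norms = np.linalg.norm(Y, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise NormalizationError(
            f"row {zero[0]}: spectrum is identically zero on the "
            f"normalization range [{lo}, {hi}]")
    Y = Y / norms[:, None]
    return SpectrumSet(x[mask], Y, sset.labels.copy(),
                       None if sset.doses_um is None else sset.doses_um.copy())
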