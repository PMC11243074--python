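"""Closed-form scan geometry of the spiral-scanning Raman instrument.

The instrument steers a focused 532 nm laser over a user-selected circular
region (0.5-100 µm diameter) with a pair of galvano mirrors.  Two small
closed forms fully describe the optical geometry used in the analysis:

* the mirror deflection angle ``θ = D / (2 L)`` for a scan circle of
  diameter ``D`` and an effective optical path length ``L`` from mirror to
  specimen, reported in milliradians, and
* the diffraction-limited laser spot diameter
  ``2 M² λ / (π NA)`` for beam-quality factor ``M``, excitation wavelength
  ``λ`` and objective numerical aperture ``NA``.

Angles are computed in radians internally and converted to mrad at the
boundary; the small-angle relation is itself the model, so no validity
check is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from neuroraman.exceptions import InvalidParameterError

__all__ = [
    "ScanGeometry",
    "BeamSpec",
    "DEFAULT_EXPOSURE_S",
    "deflection_angle",
    "spot_size",
    "infer_focal_length",
    "geometry_table",
]

#: Default exposure time per scan-region diameter (µm -> s).  Metadata only:
#: single cells are scanned at 10 µm / 3 s, ganglia at 40 µm / 5 s.
DEFAULT_EXPOSURE_S = {10.0: 3.0, 40.0: 5.0}


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of one spiral scan.

    Parameters
    ----------
    diameter_um : float
        Diameter D of the circular scan region, µm.  The instrument accepts
        0.5-100 µm.
    focal_length_m : float
        Effective optical path length L from the galvano mirror to the
        specimen, m.
    exposure_s : float
        Exposure time, s.
    marking_speed_mm_per_ms : float
        Laser marking speed, mm ms⁻¹ (instrument range 0.002-2).
    """

    diameter_um: float
    focal_length_m: float
    exposure_s: float = 3.0
    marking_speed_mm_per_ms: float = 2.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.diameter_um <= 100.0:
            # D = 0 is allowed only through deflection_angle's explicit zero
            # numerator case; the dataclass models the instrument's dial.
            raise InvalidParameterError(
                f"scan diameter must be in [0.5, 100] µm, got {self.diameter_um}"
            )
        if self.focal_length_m <= 0:
            raise InvalidParameterError("focal length must be positive")
        if self.exposure_s <= 0:
            raise InvalidParameterError("exposure time must be positive")
        if not 0.002 <= self.marking_speed_mm_per_ms <= 2.0:
            raise InvalidParameterError(
                "marking speed must be in [0.002, 2] mm/ms"
            )


@dataclass(frozen=True)
class BeamSpec:
    """Excitation beam and objective parameters for the spot-size formula."""

    beam_quality_m: float = 1.1
    wavelength_nm: float = 532.0
    numerical_aperture: float = 1.3

    def __post_init__(self) -> None:
        if self.beam_quality_m <= 0 or self.wavelength_nm <= 0:
            raise InvalidParameterError("beam quality and wavelength must be positive")
        if not 0 < self.numerical_aperture <= 1.7:
            raise InvalidParameterError("numerical aperture must be in (0, 1.7]")


def deflection_angle(geometry: ScanGeometry | None = None, *,
                     diameter_um: float | None = None,
                     focal_length_m: float | None = None) -> float:
    """Galvano-mirror deflection angle, in mrad.

    θ = D / (2 L) under the small-angle approximation, with D the scan-circle
    diameter and L the optical path length.  Accepts either a
    :class:`ScanGeometry` or the two raw values.

    Returns
    -------
    float
        Deflection angle in milliradians.
    """
    if geometry is not None:
        diameter_um = geometry.diameter_um
        focal_length_m = geometry.focal_length_m
    if diameter_um is None or focal_length_m is None:
        raise InvalidParameterError("provide a ScanGeometry or diameter and focal length")
    if diameter_um < 0 or focal_length_m <= 0:
        raise InvalidParameterError("diameter must be >= 0 and focal length > 0")
    theta_rad = (diameter_um * 1e-6) / (2.0 * focal_length_m)
    return theta_rad * 1e3


def spot_size(beam: BeamSpec | None = None, *,
              beam_quality_m: float | None = None,
              wavelength_nm: float | None = None,
              numerical_aperture: float | None = None) -> float:
    """Diffraction-limited laser spot diameter, in nm.

    spot = 2 M² λ / (π NA).  The beam-quality factor enters squared (M²);
    with the instrument values M = 1.1, λ = 532 nm, NA = 1.3 the formula
    gives ≈315 nm.
    """
    if beam is not None:
        beam_quality_m = beam.beam_quality_m
        wavelength_nm = beam.wavelength_nm
        numerical_aperture = beam.numerical_aperture
    if beam_quality_m is None or wavelength_nm is None or numerical_aperture is None:
        raise InvalidParameterError("provide a BeamSpec or all three beam parameters")
    if beam_quality_m <= 0 or wavelength_nm <= 0 or numerical_aperture <= 0:
        raise InvalidParameterError("all beam parameters must be positive")
    return 2.0 * beam_quality_m**2 * wavelength_nm / (math.pi * numerical_aperture)


def infer_focal_length(diameter_um: float, angle_mrad: float) -> float:
    """Invert the deflection relation: L = D / (2 θ), in m.

    Round-trips with :func:`deflection_angle` to machine precision, so a
    single printed (D, θ) pair pins down the instrument's path length.
    """
    if diameter_um <= 0 or angle_mrad <= 0:
        raise InvalidParameterError("diameter and angle must be positive")
    return (diameter_um * 1e-6) / (2.0 * angle_mrad * 1e-3)


def geometry_table(diameters_um, focal_length_m: float,
                   beam: BeamSpec | None = None) -> list[dict]:
    """Tabulate (D, θ mrad, spot nm) rows for the CLI `geometry` subcommand."""
    beam = beam or BeamSpec()
    spot = spot_size(beam)
    rows = []
    for d in diameters_um:
        rows.append({
            "diameter_um": float(d),
            "deflection_mrad": deflection_angle(
                diameter_um=float(d), focal_length_m=focal_length_m),
            "spot_nm": spot,
            "exposure_s": DEFAULT_EXPOSURE_S.get(float(d)),
        })
    return rows
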