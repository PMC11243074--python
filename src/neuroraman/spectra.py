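"""Spectrum containers, file I/O, wavenumber calibration and regridding.

Conventions
-----------
* Wavenumber axes are strictly increasing ``cm⁻¹`` everywhere inside the
  package; files with descending axes are reversed on read.
* A single trace is a :class:`Spectrum`; an aligned labelled matrix of
  traces (the unit of analysis) is a :class:`SpectrumSet`.
* Supported on-disk formats: two-column text (whitespace or comma
  separated), a CSV matrix with a header row of wavenumbers plus ``label``
  and optional ``dose_um`` columns, and the JCAMP-DX
  ``##XYDATA=(X++(Y..Y))`` dialect with XFACTOR/YFACTOR honored.
  Vendor binary formats are out of scope.

Wavenumber calibration follows the sulfur-standard protocol: observed peak
positions of a reference material are matched to their certified values and
a degree-≤2 polynomial map is fitted (three anchors determine a quadratic
exactly; more anchors are fitted by least squares).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuroraman.exceptions import (
    CalibrationError,
    InvalidParameterError,
    RangeError,
    SpectrumFormatError,
)

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "CalibrationModel",
    "read_spectrum",
    "write_spectrum",
    "read_spectrum_set",
    "write_spectrum_set",
    "calibrate_wavenumbers",
    "find_peak_positions",
    "resample_to_grid",
]

_MIN_POINTS = 16


@dataclass
class Spectrum:
    """One calibrated Raman trace.

    Attributes
    ----------
    wavenumbers_cm1 : ndarray
        Strictly increasing wavenumber grid, cm⁻¹.
    intensities_au : ndarray
        Intensities, arbitrary units; same length as the grid.
    meta : dict
        Free-form acquisition metadata (label, dose_um, diameter_um,
        exposure_s, ...).
    """

    wavenumbers_cm1: np.ndarray
    intensities_au: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers_cm1 = np.asarray(self.wavenumbers_cm1, dtype=float)
        self.intensities_au = np.asarray(self.intensities_au, dtype=float)
        if self.wavenumbers_cm1.ndim != 1 or self.intensities_au.ndim != 1:
            raise InvalidParameterError("spectrum axes must be 1-D")
        if len(self.wavenumbers_cm1) != len(self.intensities_au):
            raise InvalidParameterError("grid and intensities differ in length")
        if len(self.wavenumbers_cm1) < _MIN_POINTS:
            raise InvalidParameterError(
                f"spectrum needs >= {_MIN_POINTS} points, got {len(self.wavenumbers_cm1)}"
            )
        if not np.all(np.diff(self.wavenumbers_cm1) > 0):
            raise InvalidParameterError("wavenumber grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities_au)):
            raise InvalidParameterError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.wavenumbers_cm1)

    def copy_with(self, intensities: np.ndarray, **meta) -> "Spectrum":
        """New spectrum on the same grid with replaced intensities."""
        return Spectrum(self.wavenumbers_cm1.copy(), np.asarray(intensities, float),
                        {**self.meta, **meta})


@dataclass
class SpectrumSet:
    """Aligned spectrum matrix with per-row class and dose labels."""

    grid: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    doses_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.matrix.shape[1] != len(self.grid):
            raise InvalidParameterError("matrix columns must match the grid length")
        if len(self.labels) != self.matrix.shape[0]:
            raise InvalidParameterError("one label per spectrum row required")
        if not np.all(np.diff(self.grid) > 0):
            raise InvalidParameterError("shared grid must be strictly increasing")
        if self.doses_um is not None:
            self.doses_um = np.asarray(self.doses_um, dtype=float)
            if len(self.doses_um) != self.matrix.shape[0]:
                raise InvalidParameterError("one dose per spectrum row required")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.n_spectra

    def spectrum(self, i: int) -> Spectrum:
        meta = {"label": self.labels[i]}
        if self.doses_um is not None:
            meta["dose_um"] = float(self.doses_um[i])
        return Spectrum(self.grid.copy(), self.matrix[i].copy(), meta)

    def subset(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask)
        return SpectrumSet(
            self.grid.copy(), self.matrix[mask], self.labels[mask],
            None if self.doses_um is None else self.doses_um[mask])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{w:.10g}" for w in self.grid])
        df.insert(0, "label", self.labels)
        if self.doses_um is not None:
            df.insert(1, "dose_um", self.doses_um)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpectrumSet":
        labels = df["label"].to_numpy()
        doses = df["dose_um"].to_numpy(float) if "dose_um" in df.columns else None
        wn_cols = [c for c in df.columns if c not in ("label", "dose_um")]
        grid = np.array([float(c) for c in wn_cols])
        order = np.argsort(grid)
        return cls(grid[order], df[wn_cols].to_numpy(float)[:, order], labels, doses)


# ---------------------------------------------------------------------------
# single-spectrum file formats


def _parse_two_column(lines, path: str) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}:{lineno}: non-numeric entry ({line!r})") from exc
    if len(xs) < _MIN_POINTS:
        raise SpectrumFormatError(
            f"{path}: only {len(xs)} data points, need >= {_MIN_POINTS}")
    return np.array(xs), np.array(ys)


def _parse_jcamp(lines, path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader for the ##XYDATA=(X++(Y..Y)) dialect."""
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value.strip()
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: non-numeric JCAMP data ({line!r})") from exc
            # first token is the line-start X (checked loosely, not used)
            ys.extend(values[1:])
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        npoints = int(float(header["NPOINTS"]))
    except KeyError as exc:
        raise SpectrumFormatError(f"{path}: missing JCAMP header {exc}") from exc
    xfactor = float(header.get("XFACTOR", "1"))
    yfactor = float(header.get("YFACTOR", "1"))
    if len(ys) != npoints:
        raise SpectrumFormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found")
    x = np.linspace(firstx, lastx, npoints) * xfactor
    y = np.array(ys) * yfactor
    return x, y


def read_spectrum(path, fmt: str | None = None, meta: dict | None = None) -> Spectrum:
    """Read a single spectrum from disk.

    Parameters
    ----------
    path : str or Path
        File to read.
    fmt : {"txt", "jcamp", None}
        Force a format; by default ``.jdx``/``.dx`` files are parsed as
        JCAMP-DX and everything else as two-column text (whitespace or
        comma separated).

    Descending axes are reversed (with their intensities) so the returned
    spectrum always has a strictly increasing grid.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = "jcamp" if path.lower().endswith((".jdx", ".dx")) else "txt"
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    if fmt == "jcamp":
        x, y = _parse_jcamp(lines, path)
    elif fmt == "txt":
        x, y = _parse_two_column(lines, path)
    else:
        raise InvalidParameterError(f"unknown spectrum format {fmt!r}")
    if len(x) > 1 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    return Spectrum(x, y, dict(meta or {}))


def write_spectrum(spectrum: Spectrum, path, fmt: str = "txt") -> None:
    """Write a spectrum as two-column text (exact decimal repr, lossless) or
    JCAMP-DX (requires an equispaced grid)."""
    path = os.fspath(path)
    if fmt == "txt":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# wavenumber_cm1 intensity_au\n")
            for x, y in zip(spectrum.wavenumbers_cm1, spectrum.intensities_au):
                fh.write(f"{float(x)!r} {float(y)!r}\n")
        return
    if fmt != "jcamp":
        raise InvalidParameterError(f"unknown spectrum format {fmt!r}")
    x = spectrum.wavenumbers_cm1
    y = spectrum.intensities_au
    dx = np.diff(x)
    if not np.allclose(dx, dx[0], rtol=1e-9, atol=0):
        raise InvalidParameterError("JCAMP-DX export requires an equispaced grid")
    yfactor = (np.max(np.abs(y)) or 1.0) / 32767.0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##TITLE=neuroraman export\n##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=RAMAN SPECTRUM\n##XUNITS=1/CM\n##YUNITS=ARBITRARY UNITS\n")
        fh.write(f"##XFACTOR=1.0\n##YFACTOR={float(yfactor)!r}\n")
        fh.write(f"##FIRSTX={float(x[0])!r}\n##LASTX={float(x[-1])!r}\n"
                 f"##NPOINTS={len(x)}\n")
        fh.write("##XYDATA=(X++(Y..Y))\n")
        scaled = y / yfactor
        per_line = 6
        for i in range(0, len(x), per_line):
            chunk = scaled[i:i + per_line]
            fh.write(f"{float(x[i])!r} " + " ".join(f"{float(v)!r}" for v in chunk) + "\n")
        fh.write("##END=\n")


def read_spectrum_set(path) -> SpectrumSet:
    """Read a labelled spectrum matrix from its CSV form."""
    return SpectrumSet.from_dataframe(pd.read_csv(path))


def write_spectrum_set(sset: SpectrumSet, path) -> None:
    sset.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# calibration and regridding


@dataclass
class CalibrationModel:
    """Polynomial map from observed peak position to true wavenumber.

    ``coefficients`` are in ascending-power order (numpy polynomial
    convention); ``residuals`` are true − mapped at the anchor points.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    observed_anchors: np.ndarray
    reference_anchors: np.ndarray

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    @property
    def residual_rms(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))

    def __call__(self, observed) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(observed, float),
                                                self.coefficients)

    def apply(self, spectrum: Spectrum) -> Spectrum:
        """Map a spectrum's axis into calibrated wavenumbers."""
        new_axis = self(spectrum.wavenumbers_cm1)
        if not np.all(np.diff(new_axis) > 0):
            raise CalibrationError("calibrated axis is not strictly increasing")
        return Spectrum(new_axis, spectrum.intensities_au.copy(), dict(spectrum.meta))


def calibrate_wavenumbers(observed_peaks, reference_peaks,
                          domain: tuple[float, float] | None = None) -> CalibrationModel:
    """Fit the observed → true wavenumber map from matched peak pairs.

    A degree ``min(2, n_pairs − 1)`` polynomial is fitted by least squares;
    with exactly three anchors (the sulfur protocol: 153.8, 219.1 and
    473.2 cm⁻¹) the quadratic interpolates and residuals are zero.

    Parameters
    ----------
    observed_peaks, reference_peaks : array-like
        Matched positions; references must be strictly increasing.
    domain : (low, high), optional
        Interval on which the fitted map must be monotone increasing;
        defaults to the span of the observed anchors.

    Raises
    ------
    CalibrationError
        Fewer than two pairs, or the fitted map is non-monotone on the
        domain.
    """
    obs = np.asarray(observed_peaks, dtype=float)
    ref = np.asarray(reference_peaks, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 1:
        raise CalibrationError("observed and reference peak lists must match")
    if len(obs) < 2:
        raise CalibrationError("calibration needs at least 2 matched peak pairs")
    if not np.all(np.diff(ref) > 0):
        raise CalibrationError("reference peaks must be strictly increasing")
    degree = min(2, len(obs) - 1)
    coeffs = np.polynomial.polynomial.polyfit(obs, ref, degree)
    mapped = np.polynomial.polynomial.polyval(obs, coeffs)
    model = CalibrationModel(coeffs, ref - mapped, obs, ref)
    low, high = domain if domain is not None else (obs.min(), obs.max())
    check = np.linspace(low, high, 512)
    if np.any(np.diff(model(check)) <= 0):
        raise CalibrationError(
            f"fitted calibration map is non-monotone on [{low:g}, {high:g}]")
    return model


def find_peak_positions(spectrum: Spectrum, prominence_fraction: float = 0.1,
                        refine: bool = True) -> np.ndarray:
    """Positions (axis units) of local maxima with prominence above the
    given fraction of the global intensity maximum.

    With ``refine`` (default) each apex is interpolated sub-grid by a
    parabola through the maximum and its two neighbours — calibration
    anchors would otherwise be quantized to half a grid step, which a
    polynomial calibration fit then amplifies.  Used to locate
    calibration-standard peaks.
    """
    from scipy.signal import find_peaks

    x = spectrum.wavenumbers_cm1
    y = spectrum.intensities_au
    prominence = prominence_fraction * float(np.max(y))
    idx, _ = find_peaks(y, prominence=prominence)
    if not refine:
        return x[idx]
    positions = []
    for i in idx:
        if 0 < i < len(y) - 1:
            y0, y1, y2 = y[i - 1], y[i], y[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            # local grid step; assumes near-uniform spacing around the apex
            step = 0.5 * (x[i + 1] - x[i - 1])
            positions.append(x[i] + delta * step)
        else:
            positions.append(x[i])
    return np.asarray(positions)


def resample_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation).

    Values at knots shared with the source grid are unchanged; linear
    inputs are reproduced exactly anywhere inside the source range.
    """
    grid = np.asarray(grid, dtype=float)
    src = spectrum.wavenumbers_cm1
    if grid.min() < src[0] or grid.max() > src[-1]:
        raise RangeError(
            f"target grid [{grid.min():g}, {grid.max():g}] extends beyond the "
            f"source range [{src[0]:g}, {src[-1]:g}]")
    values = np.interp(grid, src, spectrum.intensities_au)
    return Spectrum(grid, values, dict(spectrum.meta))
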