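"""Wavelength grids, LED spectra, filter transmittances and spectral CSV I/O.

Every spectral object in the package lives on a shared uniform wavelength
grid; all downstream arithmetic (filtering, mixing, cone inner products)
requires identical grids and raises :class:`GridMismatchError` otherwise.
Values are in arbitrary energy units (energy per unit wavelength).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, SpectralIOError

logger = logging.getLogger(__name__)

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "Transmittance",
    "DEFAULT_GRID",
    "make_grid",
    "synthesize_led_spd",
    "synthesize_cuton_filter",
    "wratten15_filter",
    "orange_filter",
    "apply_filter",
    "resample_spectrum",
    "read_spectrum_csv",
    "read_transmittance_csv",
    "write_spectrum_csv",
    "measure_fwhm",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling: ``start_nm .. stop_nm`` in steps of ``step_nm``.

    The step must divide the span exactly; the number of samples is
    ``(stop - start) / step + 1``.
    """

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self):
        if not (self.start_nm < self.stop_nm):
            raise ValueError(
                f"reversed or degenerate bounds: start={self.start_nm}, stop={self.stop_nm}"
            )
        if not (self.step_nm > 0):
            raise ValueError(f"step must be positive, got {self.step_nm}")
        n = (self.stop_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"step {self.step_nm} does not divide span "
                f"[{self.start_nm}, {self.stop_nm}]"
            )

    def __len__(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.stop_nm, len(self))

    def contains(self, wavelength_nm: float) -> bool:
        return self.start_nm <= wavelength_nm <= self.stop_nm


DEFAULT_GRID = WavelengthGrid(390.0, 780.0, 1.0)


def _validate_values(grid: WavelengthGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (len(grid),):
        raise ValueError(
            f"{name}: expected {len(grid)} samples, got shape {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name}: non-finite values")
    if np.any(values < 0):
        raise ValueError(f"{name}: negative values")
    return values


@dataclass(frozen=True)
class Spectrum:
    """A non-negative wavelength-sampled power distribution (energy units)."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "values", _validate_values(self.grid, self.values, "Spectrum"))

    def __mul__(self, k: float) -> "Spectrum":
        return Spectrum(self.grid, self.values * float(k))

    __rmul__ = __mul__

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.grid.wavelengths[int(np.argmax(self.values))])

    def integral(self) -> float:
        """Total energy: sum of samples times the grid step."""
        return float(self.values.sum() * self.grid.step_nm)


@dataclass(frozen=True)
class Transmittance:
    """A dimensionless per-wavelength transmission fraction in [0, 1]."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = _validate_values(self.grid, self.values, "Transmittance")
        if np.any(values > 1.0):
            raise ValueError("Transmittance: values above 1")
        object.__setattr__(self, "values", values)


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform wavelength grid; rejects reversed bounds or a non-dividing step."""
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm))


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def synthesize_led_spd(
    peak_nm: float,
    fwhm_nm: float,
    grid: WavelengthGrid = DEFAULT_GRID,
    *,
    shoulder_peak_nm: float | None = None,
    shoulder_fwhm_nm: float | None = None,
    shoulder_amplitude: float = 0.0,
) -> Spectrum:
    """Model an LED emission as a Gaussian in wavelength, peak value 1.

    ``peak_nm``/``fwhm_nm`` set the main band.  An optional secondary Gaussian
    (``shoulder_*``, amplitude relative to the main peak and < 1) models the
    long-wavelength shoulder some tricolor-LED green channels exhibit; it is
    off by default.
    """
    if not grid.contains(peak_nm):
        raise ValueError(f"peak {peak_nm} nm outside grid [{grid.start_nm}, {grid.stop_nm}]")
    if not fwhm_nm > 0:
        raise ValueError("fwhm must be positive")
    w = grid.wavelengths
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    v = np.exp(-0.5 * ((w - peak_nm) / sigma) ** 2)
    if shoulder_amplitude:
        if not (0 <= shoulder_amplitude < 1):
            raise ValueError("shoulder amplitude must be in [0, 1)")
        if shoulder_peak_nm is None or shoulder_fwhm_nm is None:
            raise ValueError("shoulder amplitude given without shoulder peak/fwhm")
        s_sigma = shoulder_fwhm_nm * _FWHM_TO_SIGMA
        v = v + shoulder_amplitude * np.exp(-0.5 * ((w - shoulder_peak_nm) / s_sigma) ** 2)
    return Spectrum(grid, v / v.max())


def synthesize_cuton_filter(
    cuton_nm: float,
    slope_per_nm: float,
    t_max: float,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Transmittance:
    """Logistic cut-on (long-pass) filter: T(w) = t_max / (1 + exp(-slope (w - cuton)))."""
    if not (0 < t_max <= 1):
        raise ValueError("t_max must be in (0, 1]")
    if not slope_per_nm > 0:
        raise ValueError("slope must be positive")
    w = grid.wavelengths
    with np.errstate(over="ignore"):  # exp overflow saturates T to 0 correctly
        t = t_max / (1.0 + np.exp(-slope_per_nm * (w - cuton_nm)))
    return Transmittance(grid, t)


def wratten15_filter(grid: WavelengthGrid = DEFAULT_GRID) -> Transmittance:
    """Deep-yellow gelatin cut-on model, calibrated so that T(590 nm) = 0.90."""
    t_max = 0.92
    slope = 0.25
    # solve t_max / (1 + exp(-slope (590 - cuton))) = 0.90 for the cut-on
    cuton = 590.0 + math.log(t_max / 0.90 - 1.0) / slope
    return synthesize_cuton_filter(cuton, slope, t_max, grid)


def orange_filter(grid: WavelengthGrid = DEFAULT_GRID) -> Transmittance:
    """Orange theatrical-gel model screening the red/green channel: gentle cut-on near 540 nm."""
    return synthesize_cuton_filter(540.0, 0.05, 0.95, grid)


def apply_filter(spd: Spectrum, t: Transmittance) -> Spectrum:
    """Pointwise product of a spectrum with a filter transmittance (shared grid)."""
    if spd.grid != t.grid:
        raise GridMismatchError("spectrum and transmittance grids differ")
    return Spectrum(spd.grid, spd.values * t.values)


def resample_spectrum(spectrum: Spectrum, new_grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid.

    Samples outside the original support extend as zero (the package's spectra
    have compact support); full non-overlap is rejected.
    """
    old = spectrum.grid
    if new_grid.stop_nm < old.start_nm or new_grid.start_nm > old.stop_nm:
        raise ValueError("no overlap between old and new grids")
    if new_grid.start_nm < old.start_nm or new_grid.stop_nm > old.stop_nm:
        logger.info(
            "resampling beyond original support [%s, %s] -> [%s, %s]; padding with zeros",
            old.start_nm, old.stop_nm, new_grid.start_nm, new_grid.stop_nm,
        )
    vals = np.interp(new_grid.wavelengths, old.wavelengths, spectrum.values,
                     left=0.0, right=0.0)
    return Spectrum(new_grid, vals)


def measure_fwhm(spectrum: Spectrum) -> float:
    """Full width at half maximum, measured by linear interpolation of the
    half-height crossings on the grid."""
    w = spectrum.grid.wavelengths
    v = spectrum.values
    half = v.max() / 2.0
    above = v >= half
    idx = np.nonzero(above)[0]
    i0, i1 = idx[0], idx[-1]
    # interpolate the two crossings
    if i0 > 0:
        lo = np.interp(half, [v[i0 - 1], v[i0]], [w[i0 - 1], w[i0]])
    else:
        lo = w[0]
    if i1 < len(w) - 1:
        hi = np.interp(half, [v[i1 + 1], v[i1]], [w[i1 + 1], w[i1]])
    else:
        hi = w[-1]
    return float(hi - lo)


_CSV_HEADER = ["wavelength_nm", "value"]


def write_spectrum_csv(spectrum: Spectrum | Transmittance, path) -> None:
    """Write a two-column spectral CSV (``wavelength_nm,value``)."""
    df = pd.DataFrame({
        "wavelength_nm": spectrum.grid.wavelengths,
        "value": spectrum.values,
    })
    df.to_csv(path, index=False)


def _read_two_column_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if list(df.columns) != _CSV_HEADER:
        raise SpectralIOError(
            f"expected header {','.join(_CSV_HEADER)!r}, got {','.join(map(str, df.columns))!r}"
        )
    for col in _CSV_HEADER:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(coerced.isna().to_numpy())[0]
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise SpectralIOError(f"malformed value in column {col!r} at row {bad[0] + 2}")
        df[col] = coerced
    w = df["wavelength_nm"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    neg = np.nonzero(v < 0)[0]
    if neg.size:
        raise SpectralIOError(f"negative value at row {neg[0] + 2}")
    if w.size < 2:
        raise SpectralIOError("need at least two samples")
    dec = np.nonzero(np.diff(w) <= 0)[0]
    if dec.size:
        raise SpectralIOError(f"wavelengths not strictly increasing at row {dec[0] + 3}")
    return w, v


def read_spectrum_csv(path, grid: WavelengthGrid | None = None) -> Spectrum:
    """Read a spectral CSV.

    A uniformly sampled file is loaded as-is (or resampled onto ``grid`` when
    given).  A non-uniform wavelength column is resampled onto a uniform grid
    spanning the same range, with a logged notice.
    """
    w, v = _read_two_column_csv(path)
    steps = np.diff(w)
    uniform = np.allclose(steps, steps[0], rtol=0, atol=1e-9)
    if uniform and grid is None:
        file_grid = make_grid(w[0], w[-1], steps[0])
        return Spectrum(file_grid, v)
    if grid is None:
        grid = make_grid(w[0], w[-1], (w[-1] - w[0]) / (w.size - 1))
        logger.info("non-uniform wavelength column in %s: resampling onto %s", path, grid)
    vals = np.interp(grid.wavelengths, w, v, left=0.0, right=0.0)
    return Spectrum(grid, vals)


def read_transmittance_csv(path, grid: WavelengthGrid | None = None) -> Transmittance:
    """Read a transmittance CSV; values are validated into [0, 1]."""
    s = read_spectrum_csv(path, grid)
    return Transmittance(s.grid, s.values)
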