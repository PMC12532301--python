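"""Cone fundamentals and the construction of anomalous observers.

A normal trichromat carries long- (L), middle- (M) and short-wave (S) cone
sensitivities.  An anomalous trichromat replaces one member of the L/M pair
with a spectrally shifted variant of the *other kind's* normal pigment:

* protanomalous — L is replaced by M', a frequency-shifted copy of M,
  leaving the pair (M', M);
* deuteranomalous — M is replaced by L', a frequency-shifted copy of L,
  leaving the pair (L, L').

The variant is constructed the classical way: strip the lens and macular
optical densities off the corneal sensitivity (recovering the bare
photopigment template), translate the template along a wavenumber (cm^-1)
abscissa, and restore the pre-receptoral densities.  Positive shifts move
the peak toward *shorter* wavelengths (higher frequency).

The S cone is built but never enters Rayleigh-range computations: it is
essentially insensitive to the red/green/amber primaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridMismatchError, ShiftOutOfRangeError, UnreachableTargetError
from .spectra import DEFAULT_GRID, WavelengthGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ConeSensitivity",
    "PrereceptoralFilter",
    "Observer",
    "LAMBDA_MAX_DEFAULTS",
    "pigment_template_a1",
    "default_prereceptoral",
    "build_normal_fundamentals",
    "write_fundamentals_csv",
    "strip_prereceptoral",
    "restore_prereceptoral",
    "shift_pigment_frequency",
    "make_anomalous_observer",
    "make_normal_observer",
    "fit_shift_to_match",
]

#: Default peak wavelengths (nm) for the normal pigments.
LAMBDA_MAX_DEFAULTS = {"L": 559.0, "M": 530.0, "S": 421.0}

NM_PER_CM = 1.0e7  # wavenumber (cm^-1) = 1e7 / wavelength (nm)


@dataclass(frozen=True)
class ConeSensitivity:
    """A relative spectral sensitivity (energy units), peak-normalized to 1."""

    grid: WavelengthGrid
    values: np.ndarray = field(repr=False)
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("sensitivity length does not match grid")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("sensitivity values must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def peak_wavelength_nm(self) -> float:
        return float(self.grid.wavelengths[int(np.argmax(self.values))])


@dataclass(frozen=True)
class PrereceptoralFilter:
    """Lens and macular pigment optical densities (log10 units) on a grid."""

    grid: WavelengthGrid
    lens_density: np.ndarray = field(repr=False)
    macular_density: np.ndarray = field(repr=False)

    def __post_init__(self):
        for name in ("lens_density", "macular_density"):
            d = np.asarray(getattr(self, name), dtype=float)
            if d.shape != (len(self.grid),):
                raise ValueError(f"{name} length does not match grid")
            if np.any(d < 0) or not np.all(np.isfinite(d)):
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, d)

    @property
    def total_density(self) -> np.ndarray:
        return self.lens_density + self.macular_density


@dataclass(frozen=True)
class Observer:
    """A labeled pair of Rayleigh-range cone sensitivities.

    ``cone_a`` is the ratio numerator, ``cone_b`` the denominator:
    normal (L, M); protanomalous (M', M); deuteranomalous (L, L').
    ``shift_cm1`` records the frequency shift that generated the variant
    member (0 for an unjittered normal).
    """

    label: str
    cone_a: ConeSensitivity
    cone_b: ConeSensitivity
    shift_cm1: float = 0.0

    def __post_init__(self):
        if self.label not in ("normal", "protanomalous", "deuteranomalous"):
            raise ValueError(f"unknown observer label {self.label!r}")
        if self.cone_a.grid != self.cone_b.grid:
            raise GridMismatchError("observer cones live on different grids")

    @property
    def grid(self) -> WavelengthGrid:
        return self.cone_a.grid


def pigment_template_a1(lambda_max_nm: float, grid: WavelengthGrid = DEFAULT_GRID,
                        label: str = "") -> ConeSensitivity:
    """A1 visual-pigment absorbance template (alpha + beta band), peak 1.

    The standard vitamin-A1 rhodopsin-family nomogram: a universal band shape
    parameterized only by the peak wavelength, expressed in the normalized
    variable x = lambda_max / lambda, plus a small short-wave beta band.
    """
    w = grid.wavelengths
    x = lambda_max_nm / w
    A, B, C, D = 69.7, 28.0, -14.44, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    with np.errstate(over="ignore"):
        alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    lam_beta = 189.0 + 0.315 * lambda_max_nm
    b_beta = -40.5 + 0.195 * lambda_max_nm
    beta = 0.26 * np.exp(-(((w - lam_beta) / b_beta) ** 2))
    v = alpha + beta
    return ConeSensitivity(grid, v / v.max(), label)


def default_prereceptoral(grid: WavelengthGrid = DEFAULT_GRID) -> PrereceptoralFilter:
    """Synthetic smooth lens and macular density curves for a 2-degree observer.

    These are analytic stand-ins for the standard tabulated templates (which
    are not redistributed here): the lens density decays exponentially with
    wavelength from 1.0 at 400 nm (scale 60 nm), and the macular pigment is a
    Gaussian band peaking at 0.35 density at 458 nm (sigma 28 nm), which makes
    it negligible (< 0.01) above 550 nm as required in the Rayleigh range.
    A CSV loader (:func:`read_prereceptoral_csv`) accepts measured tables.
    """
    w = grid.wavelengths
    lens = np.exp(-(w - 400.0) / 60.0)
    macular = 0.35 * np.exp(-0.5 * ((w - 458.0) / 28.0) ** 2)
    return PrereceptoralFilter(grid, lens, macular)


def read_prereceptoral_csv(path, grid: WavelengthGrid = DEFAULT_GRID) -> PrereceptoralFilter:
    """Read ``wavelength_nm,lens_density,macular_density`` and resample onto ``grid``."""
    df = pd.read_csv(path)
    required = ["wavelength_nm", "lens_density", "macular_density"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"pre-receptoral CSV missing column {col!r}")
    w = df["wavelength_nm"].to_numpy(dtype=float)
    lens = np.interp(grid.wavelengths, w, df["lens_density"].to_numpy(dtype=float),
                     left=0.0, right=0.0)
    mac = np.interp(grid.wavelengths, w, df["macular_density"].to_numpy(dtype=float),
                    left=0.0, right=0.0)
    return PrereceptoralFilter(grid, lens, mac)


def build_normal_fundamentals(
    grid: WavelengthGrid = DEFAULT_GRID,
    source: str = "nomogram",
    lambda_max: dict[str, float] | None = None,
    pre: PrereceptoralFilter | None = None,
) -> dict[str, ConeSensitivity]:
    """Build the normal L, M, S corneal sensitivities.

    ``source`` is either ``"nomogram"`` (pigment template times pre-receptoral
    attenuation, renormalized) or ``"csv:<path>"`` pointing at a table with
    columns ``wavelength_nm,L,M,S``.
    """
    if source.startswith("csv:"):
        path = source[4:]
        df = pd.read_csv(path)
        out = {}
        for label in ("L", "M", "S"):
            if label not in df.columns:
                raise ValueError(f"fundamentals CSV missing cone column {label!r}")
            w = df["wavelength_nm"].to_numpy(dtype=float)
            v = np.interp(grid.wavelengths, w, df[label].to_numpy(dtype=float),
                          left=0.0, right=0.0)
            out[label] = ConeSensitivity(grid, v / v.max(), label)
        return out
    if source != "nomogram":
        raise ValueError(f"source must be 'nomogram' or 'csv:<path>', got {source!r}")
    lambda_max = dict(LAMBDA_MAX_DEFAULTS, **(lambda_max or {}))
    pre = pre if pre is not None else default_prereceptoral(grid)
    atten = 10.0 ** (-pre.total_density)
    out = {}
    for label in ("L", "M", "S"):
        template = pigment_template_a1(lambda_max[label], grid, label)
        v = template.values * atten
        out[label] = ConeSensitivity(grid, v / v.max(), label)
    return out


def write_fundamentals_csv(fundamentals: dict[str, ConeSensitivity], path) -> None:
    """Write a fundamentals table ``wavelength_nm,L,M,S`` (plus any extra labels)."""
    grids = {c.grid for c in fundamentals.values()}
    if len(grids) != 1:
        raise GridMismatchError("fundamentals on mixed grids")
    grid = grids.pop()
    data = {"wavelength_nm": grid.wavelengths}
    for label, cone in fundamentals.items():
        data[label] = cone.values
    pd.DataFrame(data).to_csv(path, index=False)


def strip_prereceptoral(cone: ConeSensitivity, pre: PrereceptoralFilter) -> ConeSensitivity:
    """Remove lens + macular screening: multiply by 10^(+density), renormalize."""
    if cone.grid != pre.grid:
        raise GridMismatchError("cone and pre-receptoral grids differ")
    v = cone.values * 10.0 ** (+pre.total_density)
    return ConeSensitivity(cone.grid, v / v.max(), cone.label)


def restore_prereceptoral(cone: ConeSensitivity, pre: PrereceptoralFilter) -> ConeSensitivity:
    """Re-apply lens + macular screening: multiply by 10^(-density), renormalize."""
    if cone.grid != pre.grid:
        raise GridMismatchError("cone and pre-receptoral grids differ")
    v = cone.values * 10.0 ** (-pre.total_density)
    return ConeSensitivity(cone.grid, v / v.max(), cone.label)


def shift_pigment_frequency(
    pigment: ConeSensitivity,
    shift_cm1: float,
    max_shift_cm1: float = 3000.0,
) -> ConeSensitivity:
    """Translate a pigment template along the wavenumber axis.

    With q(nu) the template as a function of wavenumber nu = 1e7 / lambda_nm,
    the output is q(nu - shift): a positive ``shift_cm1`` moves the peak to
    higher frequency, i.e. toward *shorter* wavelengths, landing at
    ``1e7 / (nu_peak + shift)`` nm.  Implemented by evaluating the template
    at the frequency-translated sample points with a shape-preserving
    (PCHIP) interpolant in wavenumber, which keeps the band unimodal and
    non-negative; values translated beyond the grid support become zero.
    The result is renormalized to peak 1.
    """
    if abs(shift_cm1) > max_shift_cm1:
        raise ValueError(f"|shift| = {abs(shift_cm1)} exceeds bound {max_shift_cm1} cm^-1")
    w = pigment.grid.wavelengths
    nu = NM_PER_CM / w                       # decreasing with wavelength
    nu_asc = nu[::-1]
    q_asc = pigment.values[::-1]
    new_peak_nu = NM_PER_CM / pigment.peak_wavelength_nm + shift_cm1
    if not (nu_asc[0] <= new_peak_nu <= nu_asc[-1]):
        raise ShiftOutOfRangeError(
            f"shift {shift_cm1} cm^-1 moves the peak to "
            f"{NM_PER_CM / new_peak_nu:.1f} nm, outside the grid"
        )
    from scipy.interpolate import PchipInterpolator

    interp = PchipInterpolator(nu_asc, q_asc, extrapolate=False)
    out = interp(nu - shift_cm1)
    out = np.clip(np.nan_to_num(out, nan=0.0), 0.0, None)
    return ConeSensitivity(pigment.grid, out / out.max(), pigment.label)


def _make_variant(base: ConeSensitivity, shift_cm1: float,
                  pre: PrereceptoralFilter, label: str) -> ConeSensitivity:
    """strip -> shift on a frequency abscissa -> restore, relabeled."""
    bare = strip_prereceptoral(base, pre)
    shifted = shift_pigment_frequency(bare, shift_cm1)
    restored = restore_prereceptoral(shifted, pre)
    return ConeSensitivity(restored.grid, restored.values, label)


def make_anomalous_observer(
    normal_set: dict[str, ConeSensitivity],
    kind: str,
    shift_cm1: float,
    pre: PrereceptoralFilter,
) -> Observer:
    """Construct a protanomalous (M', M) or deuteranomalous (L, L') observer.

    The variant pigment is a frequency-shifted copy of the normal pigment of
    the *same* spectral class (protan: M -> M'; deutan: L -> L'); the other
    member is taken unmodified from the normal set.  A zero shift therefore
    produces a degenerate observer whose two cones are identical — effectively
    a dichromat that accepts the whole instrument scale.
    """
    if kind == "protanomalous":
        variant = _make_variant(normal_set["M"], shift_cm1, pre, "M'")
        return Observer(kind, cone_a=variant, cone_b=normal_set["M"], shift_cm1=shift_cm1)
    if kind == "deuteranomalous":
        variant = _make_variant(normal_set["L"], shift_cm1, pre, "L'")
        return Observer(kind, cone_a=normal_set["L"], cone_b=variant, shift_cm1=shift_cm1)
    raise ValueError(f"kind must be 'protanomalous' or 'deuteranomalous', got {kind!r}")


def make_normal_observer(
    normal_set: dict[str, ConeSensitivity],
    jitter_cm1: float = 0.0,
    pre: PrereceptoralFilter | None = None,
) -> Observer:
    """A normal (L, M) observer, optionally with a small frequency jitter on L.

    The jitter models normal individual differences in the long-wave pigment
    (polymorphism-scale spectral variation); it uses the same
    strip/shift/restore construction as the anomalous variants.
    """
    L = normal_set["L"]
    if jitter_cm1 != 0.0:
        if pre is None:
            raise ValueError("pre-receptoral filter required to jitter a pigment")
        L = _make_variant(L, jitter_cm1, pre, "L")
    return Observer("normal", cone_a=L, cone_b=normal_set["M"], shift_cm1=jitter_cm1)


def _observer_for_shift(kind, shift, normal_set, pre):
    if kind == "normal":
        return make_normal_observer(normal_set, shift, pre)
    return make_anomalous_observer(normal_set, kind, shift, pre)


def fit_shift_to_match(
    kind: str,
    target_lambda: float,
    instrument,
    normal_set: dict[str, ConeSensitivity],
    pre: PrereceptoralFilter,
    step_cm1: float = 10.0,
    bounds: tuple[float, float] = (-2000.0, 2000.0),
) -> float:
    """Find the pigment shift whose predicted match is closest to a target setting.

    Scans the shift axis on a uniform grid (default 10 cm^-1 steps within
    +/- 2000 cm^-1), predicting the Rayleigh match for each candidate observer,
    and returns the shift minimizing |predicted - target|; ties break toward
    the smaller |shift|.  Shifts whose match falls off the instrument scale
    (or is indeterminate) are skipped.  If the target lies outside the control
    range, or no candidate shift yields an on-scale match, the target is
    flagged unreachable.
    """
    from .errors import MatchIndeterminateError, NoMatchInRangeError
    from .matching import predict_match

    if step_cm1 <= 0:
        raise ValueError("step must be positive")
    lo, hi = instrument.control_range
    if not (lo <= target_lambda <= hi):
        raise UnreachableTargetError(
            f"unreachable target: {target_lambda} outside control range [{lo}, {hi}]"
        )
    b_lo, b_hi = bounds
    shifts = np.arange(b_lo, b_hi + step_cm1 / 2, step_cm1)
    best: tuple[float, float, float] | None = None  # (dist, |shift|, shift)
    for s in shifts:
        try:
            obs = _observer_for_shift(kind, float(s), normal_set, pre)
            lam = predict_match(instrument, obs).lambda_star
        except (NoMatchInRangeError, MatchIndeterminateError, ShiftOutOfRangeError):
            continue
        key = (abs(lam - target_lambda), abs(s), float(s))
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        raise UnreachableTargetError(
            "unreachable target: no shift in bounds yields an on-scale match"
        )
    return best[2]
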