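"""Rayleigh-match prediction by cone-excitation ratio intersection.

For a given observer and instrument, the excitation of each of the
observer's two Rayleigh-range cones is the inner product of the field SPD
with the cone sensitivity (summed over the grid, times the step — energy
units throughout).  Because the mixture SPD is linear in the two channel
outputs, each excitation reduces to ``r(lam) * E_red + g(lam) * E_green``
with precomputed per-channel excitations, which makes ratio-curve
evaluation a scalar operation.

The amber reference field produces a *fixed* excitation ratio, independent
of its intensity (the intensity cancels).  The predicted match ``lambda*``
is the mixture setting at which the mixture's ratio equals the amber's:
found by a 64-point bracketing scan of f(lam) = log ratio_mix(lam) - log
ratio_amber followed by bisection.  A brute-force grid argmin of |f| is
provided as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GridMismatchError,
    MatchIndeterminateError,
    NoMatchInRangeError,
)
from .instrument import Instrument
from .observers import ConeSensitivity, Observer
from .spectra import Spectrum

__all__ = [
    "ExcitationCurve",
    "MatchPrediction",
    "MatchingRange",
    "cone_excitation",
    "excitation_ratio_curve",
    "reference_ratio",
    "predict_match",
    "brute_force_match",
    "matching_range",
    "brightness_match_intensity",
]

#: Bisection stops once |log ratio_mix - log ratio_amber| <= LOG_TOL ...
LOG_TOL = 1e-8
#: ... and the bracket width has shrunk below WIDTH_TOL times the scale span,
#: so the returned setting is pinned independently of tiny perturbations of
#: the amber spectrum.
WIDTH_TOL = 1e-12
#: Below this |f| everywhere on the scan the two ratios coincide identically
#: (degenerate identical-cone observer) and no unique match exists.
DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ExcitationCurve:
    """Cone excitations and their ratio across the mixture scale.

    ``flagged`` marks settings where a ratio could not be formed (zero
    excitation in numerator or denominator); the ratio is NaN there.
    """

    lambdas: np.ndarray = field(repr=False)
    excitation_a: np.ndarray = field(repr=False)
    excitation_b: np.ndarray = field(repr=False)
    ratio: np.ndarray = field(repr=False)
    flagged: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class MatchPrediction:
    lambda_star: float
    amber_ratio: float
    mixture_ratio_at_match: float
    bracket: tuple[float, float]
    solver_iterations: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class MatchingRange:
    """The connected interval of settings within a log-ratio tolerance of the match."""

    lambda_lo: float
    lambda_hi: float
    delta: float
    touches_end: bool

    @property
    def width(self) -> float:
        return self.lambda_hi - self.lambda_lo


def cone_excitation(spd: Spectrum, cone: ConeSensitivity) -> float:
    """Total excitation: sum over wavelengths of SPD x sensitivity x step."""
    if spd.grid != cone.grid:
        raise GridMismatchError("SPD and cone sensitivity grids differ")
    return float(np.dot(spd.values, cone.values) * spd.grid.step_nm)


def _channel_excitations(instrument: Instrument, observer: Observer):
    """Per-channel excitations (A = cone_a, B = cone_b) x (red, green, amber)."""
    if instrument.grid != observer.grid:
        raise GridMismatchError("instrument and observer grids differ")
    step = instrument.grid.step_nm
    a, b = observer.cone_a.values, observer.cone_b.values
    Ar = float(np.dot(instrument.red.spd.values, a)) * step
    Ag = float(np.dot(instrument.green.spd.values, a)) * step
    Aa = float(np.dot(instrument.amber.spd.values, a)) * step
    Br = float(np.dot(instrument.red.spd.values, b)) * step
    Bg = float(np.dot(instrument.green.spd.values, b)) * step
    Ba = float(np.dot(instrument.amber.spd.values, b)) * step
    return (Ar, Ag, Aa), (Br, Bg, Ba)


def excitation_ratio_curve(
    instrument: Instrument, observer: Observer, n_points: int = 101
) -> ExcitationCurve:
    """Evaluate the two cone excitations and their ratio on a uniform setting grid."""
    if n_points < 2:
        raise ValueError("need at least 2 points")
    (Ar, Ag, _), (Br, Bg, _) = _channel_excitations(instrument, observer)
    lo, hi = instrument.control_range
    lam = np.linspace(lo, hi, n_points)
    r = np.asarray(instrument.red.output_curve(lam), dtype=float)
    g = np.asarray(instrument.green.output_curve(lam), dtype=float)
    Ea = r * Ar + g * Ag
    Eb = r * Br + g * Bg
    flagged = (Ea <= 0) | (Eb <= 0)
    ratio = np.where(flagged, np.nan, Ea / np.where(Eb > 0, Eb, 1.0))
    return ExcitationCurve(lam, Ea, Eb, ratio, flagged)


def reference_ratio(
    instrument: Instrument, observer: Observer, amber_intensity: float = 1.0
) -> float:
    """The amber field's cone-excitation ratio; invariant to the (positive) intensity."""
    if not amber_intensity > 0:
        raise ValueError("amber intensity must be positive")
    (_, _, Aa), (_, _, Ba) = _channel_excitations(instrument, observer)
    if Aa <= 0 or Ba <= 0:
        raise ValueError("amber field excites a cone not at all; ratio undefined")
    return (amber_intensity * Aa) / (amber_intensity * Ba)


def _log_ratio_mismatch(instrument: Instrument, observer: Observer):
    """Return f(lam) = log ratio_mix(lam) - log ratio_amber as a scalar/vector closure."""
    (Ar, Ag, Aa), (Br, Bg, Ba) = _channel_excitations(instrument, observer)
    if Aa <= 0 or Ba <= 0:
        raise ValueError("amber field excites a cone not at all")
    log_amber = math.log(Aa / Ba)
    red_curve = instrument.red.output_curve
    green_curve = instrument.green.output_curve

    def f(lam):
        r = red_curve(lam)
        g = green_curve(lam)
        Ea = r * Ar + g * Ag
        Eb = r * Br + g * Bg
        return np.log(Ea / Eb) - log_amber

    return f, log_amber, (Aa / Ba)


def predict_match(
    instrument: Instrument,
    observer: Observer,
    scan_points: int = 64,
    max_iter: int = 200,
) -> MatchPrediction:
    """Predict the Rayleigh match: the setting where the mixture ratio equals the amber ratio.

    Raises :class:`NoMatchInRangeError` (carrying the end-point mismatch
    signs) when the ratio curve never crosses the amber level on the scale —
    the mechanism behind the extreme-anomalous exclusion — and
    :class:`MatchIndeterminateError` when the two ratios coincide identically
    (identical-cone degenerate observer, who accepts the whole scale).
    """
    f, _, amber_ratio = _log_ratio_mismatch(instrument, observer)
    lo, hi = instrument.control_range
    span = hi - lo
    lam_scan = np.linspace(lo, hi, scan_points)
    f_scan = np.asarray(f(lam_scan), dtype=float)
    if not np.all(np.isfinite(f_scan)):
        raise ValueError("ratio curve undefined somewhere on the scale")
    if np.max(np.abs(f_scan)) < DEGENERATE_TOL:
        raise MatchIndeterminateError(
            "mixture and amber ratios coincide at every setting; "
            "the observer accepts the entire scale"
        )
    crossings = np.nonzero(np.sign(f_scan[:-1]) * np.sign(f_scan[1:]) <= 0)[0]
    crossings = [i for i in crossings if f_scan[i] != 0 or f_scan[i + 1] != 0]
    if np.any(f_scan == 0.0):
        exact = int(np.nonzero(f_scan == 0.0)[0][0])
        lam0 = float(lam_scan[exact])
        return MatchPrediction(lam0, amber_ratio, amber_ratio,
                               (lam0, lam0), 0)
    if len(crossings) == 0:
        side = "green" if f_scan[0] > 0 else "red"
        raise NoMatchInRangeError(
            f"no match in range: ratio curve stays on one side of the amber "
            f"ratio (match lies beyond the {side} end)",
            f_low=float(f_scan[0]),
            f_high=float(f_scan[-1]),
        )
    warnings: list[str] = []
    if len(crossings) > 1:
        warnings.append("multiple_crossings")
        mid = 0.5 * (lo + hi)
        crossings.sort(key=lambda i: abs(0.5 * (lam_scan[i] + lam_scan[i + 1]) - mid))
    i = crossings[0]
    a, b = float(lam_scan[i]), float(lam_scan[i + 1])
    bracket = (a, b)
    # verify monotonicity of f across the chosen bracket on a 64-point scan
    fb = np.asarray(f(np.linspace(a, b, 64)), dtype=float)
    d = np.diff(fb)
    if not (np.all(d >= 0) or np.all(d <= 0)):
        warnings.append("non_monotone_bracket")
    fa = float(f(a))
    iterations = 0
    m, fm = a, fa
    for iterations in range(1, max_iter + 1):
        m = 0.5 * (a + b)
        fm = float(f(m))
        if abs(fm) <= LOG_TOL and (b - a) <= WIDTH_TOL * span:
            break
        if fm == 0.0:
            break
        if (fm > 0) == (fa > 0):
            a, fa = m, fm
        else:
            b = m
    return MatchPrediction(
        lambda_star=float(m),
        amber_ratio=float(amber_ratio),
        mixture_ratio_at_match=float(amber_ratio * math.exp(fm)),
        bracket=bracket,
        solver_iterations=iterations,
        warnings=tuple(warnings),
    )


def brute_force_match(
    instrument: Instrument, observer: Observer, grid_resolution: float = 1e-4
) -> float:
    """Oracle: exhaustive argmin of |log ratio mismatch| on a uniform setting grid.

    Ties break toward the smallest setting.
    """
    if not grid_resolution > 0:
        raise ValueError("resolution must be positive")
    f, _, _ = _log_ratio_mismatch(instrument, observer)
    lo, hi = instrument.control_range
    n = int(math.floor((hi - lo) / grid_resolution)) + 1
    lam = lo + np.arange(n) * grid_resolution
    if lam[-1] < hi:
        lam = np.append(lam, hi)
    vals = np.abs(np.asarray(f(lam), dtype=float))
    return float(lam[int(np.argmin(vals))])


def matching_range(
    instrument: Instrument, observer: Observer, delta: float = 0.01,
    n_scan: int = 4001,
) -> MatchingRange:
    """The connected interval around the match where |log ratio mismatch| <= delta.

    ``touches_end`` reports whether the interval reaches an end of the
    instrument scale — the criterion used to flag extreme anomalous behaviour.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    pred = predict_match(instrument, observer)
    lam_star = pred.lambda_star
    if delta == 0:
        lo, hi = instrument.control_range
        return MatchingRange(lam_star, lam_star, 0.0,
                             touches_end=(lam_star in (lo, hi)))
    f, _, _ = _log_ratio_mismatch(instrument, observer)
    lo, hi = instrument.control_range
    lam = np.linspace(lo, hi, n_scan)
    ok = np.abs(np.asarray(f(lam), dtype=float)) <= delta
    i_star = int(np.argmin(np.abs(lam - lam_star)))
    if not ok[i_star]:
        ok[i_star] = True  # numerical guard: the match itself always qualifies
    i0 = i_star
    while i0 > 0 and ok[i0 - 1]:
        i0 -= 1
    i1 = i_star
    while i1 < n_scan - 1 and ok[i1 + 1]:
        i1 += 1

    def _edge(inside_idx, outside_idx):
        a, b = lam[inside_idx], lam[outside_idx]
        g = lambda x: abs(float(f(x))) - delta  # noqa: E731
        for _ in range(80):
            m = 0.5 * (a + b)
            if g(m) <= 0:
                a = m
            else:
                b = m
        return float(a)

    lam_lo = lam[0] if i0 == 0 else _edge(i0, i0 - 1)
    lam_hi = lam[-1] if i1 == n_scan - 1 else _edge(i1, i1 + 1)
    return MatchingRange(float(lam_lo), float(lam_hi), float(delta),
                         touches_end=(i0 == 0 or i1 == n_scan - 1))


def brightness_match_intensity(
    instrument: Instrument, observer: Observer, lambda_setting: float
) -> float:
    """Amber intensity equating the summed two-cone excitation of the two fields.

    The amber excitation is linear in its intensity, so the equation is always
    solvable; results falling outside the instrument's amber control range are
    clamped (the simulated device cannot exceed its dial).
    """
    lo, hi = instrument.control_range
    if not (lo <= lambda_setting <= hi):
        raise ValueError(f"mixture setting {lambda_setting} outside [{lo}, {hi}]")
    (Ar, Ag, Aa), (Br, Bg, Ba) = _channel_excitations(instrument, observer)
    r = instrument.red.output_curve(lambda_setting)
    g = instrument.green.output_curve(lambda_setting)
    target = r * (Ar + Br) + g * (Ag + Bg)
    per_unit = Aa + Ba
    intensity = float(target / per_unit)
    lo, hi = instrument.amber_range
    if not (lo <= intensity <= hi):
        import logging
        logging.getLogger(__name__).warning(
            "brightness-matching intensity %.4g clamped into [%g, %g]",
            intensity, lo, hi,
        )
        intensity = min(max(intensity, lo), hi)
    return intensity
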