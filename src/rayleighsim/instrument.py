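"""Anomaloscope models: mixture and reference channels with control curves.

An instrument is three LED primaries — red and green forming the mixture
field, amber forming the reference field — each with a control-to-intensity
output curve.  The mixture control ("lambda" on the Penn device, a 0-73
scale on the Oculus/Nagel convention) trades red against green; the amber
control scales the reference intensity.

Presets:

``penn``
    red 623 nm / green 523 nm tricolor LED behind an orange gel, amber
    592 nm behind a deep-yellow (Wratten-15-like) cut-on filter; control
    range [0, 1], red output rising linearly with the setting, green output
    constant up to a knee at 0.3 and then falling linearly to zero — so the
    total output of the mixture is *not* constant across the scale.
``oculus``
    545/670 nm mixture primaries, 589 nm amber, scale [0, 73] with
    complementary linear outputs (0 = pure green, 73 = pure red).
``nagel``
    537/666 nm mixture primaries, 589 nm amber, scale [0, 73].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import GridMismatchError
from .spectra import (
    DEFAULT_GRID,
    Spectrum,
    WavelengthGrid,
    apply_filter,
    synthesize_cuton_filter,
    synthesize_led_spd,
)

__all__ = [
    "OutputCurve",
    "PrimaryChannel",
    "Instrument",
    "InstrumentConfig",
    "make_instrument",
    "mixture_spd",
    "reference_spd",
    "with_amber_spd",
    "PRESETS",
]


@dataclass(frozen=True)
class OutputCurve:
    """Mapping from a control setting to a non-negative intensity multiplier.

    Kinds (over the control interval [lo, hi]):

    - ``linear_up``:   0 at lo rising linearly to 1 at hi
    - ``linear_down``: 1 at lo falling linearly to 0 at hi
    - ``knee_down``:   1 up to ``knee``, then linear to 0 at hi
    - ``identity``:    the setting itself (used for the amber intensity dial)
    """

    kind: str
    lo: float
    hi: float
    knee: float | None = None

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        span = self.hi - self.lo
        if self.kind == "linear_up":
            y = (x - self.lo) / span
        elif self.kind == "linear_down":
            y = 1.0 - (x - self.lo) / span
        elif self.kind == "knee_down":
            y = np.where(x <= self.knee, 1.0, (self.hi - x) / (self.hi - self.knee))
        elif self.kind == "identity":
            y = x
        else:  # pragma: no cover - guarded by config validation
            raise ValueError(f"unknown curve kind {self.kind!r}")
        return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class PrimaryChannel:
    """A peak-normalized primary SPD plus its control-to-output curve."""

    spd: Spectrum
    output_curve: OutputCurve


@dataclass(frozen=True)
class Instrument:
    name: str
    red: PrimaryChannel
    green: PrimaryChannel
    amber: PrimaryChannel
    control_range: tuple[float, float]
    amber_range: tuple[float, float] = (0.0, 2.0)

    def __post_init__(self):
        lo, hi = self.control_range
        if not lo < hi:
            raise ValueError("degenerate control range")
        grids = {self.red.spd.grid, self.green.spd.grid, self.amber.spd.grid}
        if len(grids) != 1:
            raise GridMismatchError("primary SPDs live on different grids")

    @property
    def grid(self) -> WavelengthGrid:
        return self.red.spd.grid


class FilterConfig(BaseModel):
    cuton_nm: float
    slope_per_nm: float = Field(gt=0)
    t_max: float = Field(gt=0, le=1)


class PrimaryConfig(BaseModel):
    peak_nm: float
    fwhm_nm: float = Field(gt=0)
    shoulder_peak_nm: float | None = None
    shoulder_fwhm_nm: float | None = None
    shoulder_amplitude: float = Field(default=0.0, ge=0, lt=1)
    filters: list[FilterConfig] = []


class CurveConfig(BaseModel):
    kind: Literal["linear_up", "linear_down", "knee_down", "identity"]
    knee: float | None = None

    @model_validator(mode="after")
    def _knee_required(self):
        if self.kind == "knee_down" and self.knee is None:
            raise ValueError("knee_down curve requires a knee position")
        return self


class InstrumentConfig(BaseModel):
    """Validated JSON-facing instrument description."""

    name: str
    red: PrimaryConfig
    green: PrimaryConfig
    amber: PrimaryConfig
    red_curve: CurveConfig
    green_curve: CurveConfig
    control_range: tuple[float, float]
    amber_range: tuple[float, float] = (0.0, 2.0)


def _penn_config() -> InstrumentConfig:
    orange = FilterConfig(cuton_nm=540.0, slope_per_nm=0.05, t_max=0.95)
    return InstrumentConfig(
        name="penn",
        red=PrimaryConfig(peak_nm=623.0, fwhm_nm=20.0, filters=[orange]),
        green=PrimaryConfig(peak_nm=523.0, fwhm_nm=30.0, filters=[orange],
                            shoulder_peak_nm=590.0, shoulder_fwhm_nm=60.0,
                            shoulder_amplitude=0.0),
        amber=PrimaryConfig(peak_nm=592.0, fwhm_nm=16.0, filters=[_wratten15_config()]),
        red_curve=CurveConfig(kind="linear_up"),
        green_curve=CurveConfig(kind="knee_down", knee=0.3),
        control_range=(0.0, 1.0),
    )


def _wratten15_config() -> FilterConfig:
    import math
    t_max, slope = 0.92, 0.25
    cuton = 590.0 + math.log(t_max / 0.90 - 1.0) / slope
    return FilterConfig(cuton_nm=cuton, slope_per_nm=slope, t_max=t_max)


def _oculus_config() -> InstrumentConfig:
    return InstrumentConfig(
        name="oculus",
        red=PrimaryConfig(peak_nm=670.0, fwhm_nm=20.0),
        green=PrimaryConfig(peak_nm=545.0, fwhm_nm=20.0),
        amber=PrimaryConfig(peak_nm=589.0, fwhm_nm=14.0),
        red_curve=CurveConfig(kind="linear_up"),
        green_curve=CurveConfig(kind="linear_down"),
        control_range=(0.0, 73.0),
    )


def _nagel_config() -> InstrumentConfig:
    return InstrumentConfig(
        name="nagel",
        red=PrimaryConfig(peak_nm=666.0, fwhm_nm=10.0),
        green=PrimaryConfig(peak_nm=537.0, fwhm_nm=10.0),
        amber=PrimaryConfig(peak_nm=589.0, fwhm_nm=10.0),
        red_curve=CurveConfig(kind="linear_up"),
        green_curve=CurveConfig(kind="linear_down"),
        control_range=(0.0, 73.0),
    )


PRESETS = {"penn": _penn_config, "oculus": _oculus_config, "nagel": _nagel_config}


def _build_primary(cfg: PrimaryConfig, curve: OutputCurve,
                   grid: WavelengthGrid) -> PrimaryChannel:
    spd = synthesize_led_spd(
        cfg.peak_nm, cfg.fwhm_nm, grid,
        shoulder_peak_nm=cfg.shoulder_peak_nm,
        shoulder_fwhm_nm=cfg.shoulder_fwhm_nm,
        shoulder_amplitude=cfg.shoulder_amplitude,
    )
    for f in cfg.filters:
        t = synthesize_cuton_filter(f.cuton_nm, f.slope_per_nm, f.t_max, grid)
        spd = apply_filter(spd, t)
    # channels are peak-normalized; absolute scale lives in the output curve
    return PrimaryChannel(Spectrum(grid, spd.values / spd.values.max()), curve)


def make_instrument(
    preset: str | None = None,
    config: InstrumentConfig | dict | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Instrument:
    """Build an instrument from a named preset or a validated config.

    Malformed dict configs are rejected by pydantic with the offending
    field path in the error.
    """
    if (preset is None) == (config is None):
        raise ValueError("give exactly one of preset or config")
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        cfg = PRESETS[preset]()
    else:
        cfg = config if isinstance(config, InstrumentConfig) else InstrumentConfig(**config)
    lo, hi = cfg.control_range
    red_curve = OutputCurve(cfg.red_curve.kind, lo, hi, cfg.red_curve.knee)
    green_curve = OutputCurve(cfg.green_curve.kind, lo, hi, cfg.green_curve.knee)
    amber_curve = OutputCurve("identity", *cfg.amber_range)
    return Instrument(
        name=cfg.name,
        red=_build_primary(cfg.red, red_curve, grid),
        green=_build_primary(cfg.green, green_curve, grid),
        amber=_build_primary(cfg.amber, amber_curve, grid),
        control_range=cfg.control_range,
        amber_range=cfg.amber_range,
    )


def _check_setting(value, interval, what):
    lo, hi = interval
    if not (lo <= value <= hi):
        raise ValueError(f"{what} {value} outside [{lo}, {hi}]")


def mixture_spd(instrument: Instrument, lambda_setting: float) -> Spectrum:
    """SPD of the red/green mixture field at a control setting."""
    _check_setting(lambda_setting, instrument.control_range, "mixture setting")
    r = instrument.red.output_curve(lambda_setting)
    g = instrument.green.output_curve(lambda_setting)
    return Spectrum(
        instrument.grid,
        r * instrument.red.spd.values + g * instrument.green.spd.values,
    )


def reference_spd(instrument: Instrument, amber_intensity: float) -> Spectrum:
    """SPD of the amber reference field at a given intensity control value."""
    _check_setting(amber_intensity, instrument.amber_range, "amber intensity")
    out = instrument.amber.output_curve(amber_intensity)
    return Spectrum(instrument.grid, out * instrument.amber.spd.values)


def with_amber_spd(instrument: Instrument, spd: Spectrum) -> Instrument:
    """A copy of the instrument with its amber channel SPD replaced.

    Useful for physical-identity checks: setting the amber field equal to a
    mixture SPD makes the match observer-independent.
    """
    if spd.grid != instrument.grid:
        raise GridMismatchError("replacement SPD grid differs from instrument grid")
    amber = replace(instrument.amber, spd=spd)
    return replace(instrument, amber=amber)
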