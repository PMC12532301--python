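"""Synthetic cohorts and repeated anomaloscope sessions.

The generator mirrors the structure of a two-visit instrument-comparison
study: a cohort of mostly normal observers plus smaller protanomalous and
deuteranomalous groups, each observer making >= 3 independent settings per
session, two sessions on the primary instrument and one on the comparison
instrument.

Between-observer variation is produced *spectrally* — anomalous observers
draw their pigment shift from a class-specific normal distribution, and
normal observers receive a small frequency jitter on the L pigment — rather
than by adding offsets on the instrument scale.  Cross-instrument structure
therefore emerges mechanistically from observer metamerism: the same
pigments are multiplied into each instrument's own primaries.

Within-observer variation is homoscedastic Gaussian adjustment noise on the
mixture-setting scale, clipped (and flagged) at the scale ends.  Observers
whose predicted match falls off an instrument's scale are recorded with an
exclusion flag, mirroring the exclusion of extreme anomalous participants.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import MatchIndeterminateError, NoMatchInRangeError
from .instrument import Instrument
from .matching import brightness_match_intensity, predict_match
from .observers import (
    ConeSensitivity,
    Observer,
    PrereceptoralFilter,
    build_normal_fundamentals,
    default_prereceptoral,
    make_anomalous_observer,
    make_normal_observer,
)
from .spectra import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "CohortSpec",
    "CohortMember",
    "STUDY_COLUMNS",
    "sample_cohort",
    "simulate_session",
    "simulate_study",
    "calibrate_normal_jitter",
    "write_study_csv",
    "read_study_csv",
]


class CohortSpec(BaseModel):
    """Cohort composition and noise structure of a simulated study.

    Defaults emulate the reference study conditions: 24 normal and 8
    anomalous trichromats (split evenly protan/deutan), three settings per
    session.  Class shift means (protan -300, deutan +300 cm^-1, i.e. the
    variant pigment displaced roughly 8-9 nm toward the other pigment) were
    calibrated once against the model's own match predictions so that the
    class-average matches are clearly displaced from the normal match yet
    comfortably inside both preset instruments' scales; the normal jitter
    SD (60 cm^-1, about 1.9 nm at the L peak — polymorphism-scale
    variation) preserves realistic individual differences among normals.
    ``setting_noise_sd`` is the within-observer adjustment SD *per unit of
    control-range span* (0.005 means 0.005 on the Penn's unit scale and
    0.365 on a 0-73 scale); real per-setting SDs are not published, so this
    is a plausible placeholder exposed in the spec.
    """

    n_normal: int = Field(default=24, ge=0)
    n_protan: int = Field(default=4, ge=0)
    n_deutan: int = Field(default=4, ge=0)
    protan_shift_mean_cm1: float = -300.0
    protan_shift_sd_cm1: float = Field(default=60.0, ge=0)
    deutan_shift_mean_cm1: float = 300.0
    deutan_shift_sd_cm1: float = Field(default=80.0, ge=0)
    normal_jitter_sd_cm1: float = Field(default=60.0, ge=0)
    setting_noise_sd: float = Field(default=0.005, ge=0)
    amber_noise_frac: float = Field(default=0.02, ge=0)
    settings_per_session: int = Field(default=3, ge=1)
    seed: int = 0


@dataclass(frozen=True)
class CohortMember:
    observer_id: str
    true_label: str
    observer: Observer
    noise_sd: float


STUDY_COLUMNS = [
    "observer_id", "true_label", "instrument", "session", "repetition",
    "lambda", "amber_intensity", "clipped", "excluded",
]


def sample_cohort(
    spec: CohortSpec,
    normal_set: dict[str, ConeSensitivity] | None = None,
    pre: PrereceptoralFilter | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> list[CohortMember]:
    """Draw a cohort of observers; fully reproducible from ``spec.seed``."""
    if pre is None:
        pre = default_prereceptoral(grid)
    if normal_set is None:
        normal_set = build_normal_fundamentals(grid, pre=pre)
    rng = np.random.default_rng(spec.seed)
    jitters = rng.normal(0.0, spec.normal_jitter_sd_cm1, spec.n_normal)
    protan_shifts = rng.normal(spec.protan_shift_mean_cm1, spec.protan_shift_sd_cm1,
                               spec.n_protan)
    deutan_shifts = rng.normal(spec.deutan_shift_mean_cm1, spec.deutan_shift_sd_cm1,
                               spec.n_deutan)
    members: list[CohortMember] = []
    for i, j in enumerate(jitters, start=1):
        obs = make_normal_observer(normal_set, float(j), pre)
        members.append(CohortMember(f"N{i:03d}", "normal", obs, spec.setting_noise_sd))
    for i, s in enumerate(protan_shifts, start=1):
        obs = make_anomalous_observer(normal_set, "protanomalous", float(s), pre)
        members.append(CohortMember(f"P{i:03d}", "protanomalous", obs,
                                    spec.setting_noise_sd))
    for i, s in enumerate(deutan_shifts, start=1):
        obs = make_anomalous_observer(normal_set, "deuteranomalous", float(s), pre)
        members.append(CohortMember(f"D{i:03d}", "deuteranomalous", obs,
                                    spec.setting_noise_sd))
    return members


def _session_rng(master_seed: int, observer_id: str, instrument_name: str,
                 session: int) -> np.random.Generator:
    """A reproducible per-(observer, instrument, session) random stream."""
    tag = zlib.crc32(f"{observer_id}|{instrument_name}|{session}".encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed & 0x7FFFFFFF, tag]))


def simulate_session(
    observer: Observer,
    instrument: Instrument,
    n_settings: int,
    noise_sd: float,
    seed: int | np.random.Generator,
    amber_noise_frac: float = 0.02,
    lambda_star: float | None = None,
):
    """Simulate one session: independent settings around the predicted match.

    Each setting is lambda* plus Gaussian adjustment noise, clipped to the
    control range (with a flag); the recorded amber intensity is the
    brightness-matching intensity at that setting, perturbed proportionally.
    Returns ``(settings, amber_intensities, clipped_flags)`` arrays.
    Propagates the no-match error when the observer cannot match on this
    instrument (the extreme-anomalous case).
    """
    if n_settings < 1:
        raise ValueError("need at least one setting")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if lambda_star is None:
        lambda_star = predict_match(instrument, observer).lambda_star
    lo, hi = instrument.control_range
    raw = lambda_star + rng.normal(0.0, noise_sd, n_settings)
    clipped = (raw < lo) | (raw > hi)
    settings = np.clip(raw, lo, hi)
    ambers = np.empty(n_settings)
    for k, lam in enumerate(settings):
        base = brightness_match_intensity(instrument, observer, float(lam))
        ambers[k] = base * (1.0 + rng.normal(0.0, amber_noise_frac))
    a_lo, a_hi = instrument.amber_range
    ambers = np.clip(ambers, a_lo, a_hi)
    return settings, ambers, clipped


def simulate_study(
    cohort: list[CohortMember],
    instruments: list[Instrument],
    spec: CohortSpec,
    plan: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Simulate a full study table.

    ``plan`` is a list of (instrument index, session number) cells; the
    default mirrors a two-visit comparison design: instrument 0 in sessions
    1 and 2, instrument 1 (when present) in session 1 only.  Observers who
    cannot match on one of their planned instruments are carried through
    with ``excluded=True`` and NaN settings.

    The per-setting noise SD is ``spec.setting_noise_sd`` scaled by each
    instrument's control-range span, so the *relative* adjustment precision
    is the same on a unit scale and on a 0-73 scale.
    """
    if not instruments:
        raise ValueError("need at least one instrument")
    if plan is None:
        plan = [(0, 1), (0, 2)]
        if len(instruments) > 1:
            plan = [(0, 1), (1, 1), (0, 2)]
    rows = []
    for member in cohort:
        stars: dict[int, float | None] = {}
        excluded = False
        for idx in {i for i, _ in plan}:
            try:
                stars[idx] = predict_match(instruments[idx], member.observer).lambda_star
            except (NoMatchInRangeError, MatchIndeterminateError):
                stars[idx] = None
                excluded = True
        for idx, session in plan:
            inst = instruments[idx]
            if excluded:
                for rep in range(1, spec.settings_per_session + 1):
                    rows.append((member.observer_id, member.true_label, inst.name,
                                 session, rep, np.nan, np.nan, False, True))
                continue
            rng = _session_rng(spec.seed, member.observer_id, inst.name, session)
            span = inst.control_range[1] - inst.control_range[0]
            settings, ambers, clipped = simulate_session(
                member.observer, inst, spec.settings_per_session,
                member.noise_sd * span, rng, spec.amber_noise_frac,
                lambda_star=stars[idx],
            )
            for rep in range(spec.settings_per_session):
                rows.append((member.observer_id, member.true_label, inst.name,
                             session, rep + 1, settings[rep], ambers[rep],
                             bool(clipped[rep]), False))
    return pd.DataFrame(rows, columns=STUDY_COLUMNS)


def calibrate_normal_jitter(
    instrument: Instrument,
    normal_set: dict[str, ConeSensitivity],
    pre: PrereceptoralFilter,
    target_lambda_sd: float,
    probe_cm1: float = 100.0,
) -> float:
    """Jitter SD (cm^-1) that yields a target between-observer match SD.

    Uses the local linearization of the match setting in the L-pigment
    frequency jitter: the slope d lambda*/d s is estimated by a symmetric
    finite difference at +/- ``probe_cm1``.
    """
    lam_plus = predict_match(instrument, make_normal_observer(normal_set, probe_cm1, pre)).lambda_star
    lam_minus = predict_match(instrument, make_normal_observer(normal_set, -probe_cm1, pre)).lambda_star
    slope = (lam_plus - lam_minus) / (2.0 * probe_cm1)
    if slope == 0:
        raise ValueError("match setting is insensitive to the jitter probe")
    return float(target_lambda_sd / abs(slope))


def write_study_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_study_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV missing columns: {missing}")
    return df
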