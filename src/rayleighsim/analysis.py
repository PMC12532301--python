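"""Reliability and agreement analysis of (simulated or measured) study tables.

Session means are the analysis unit: per (observer, instrument, session) the
mean and SD of the repeated settings are computed, excluded observers are
carried with a flag but dropped from correlations, and reliability is
quantified by Pearson and Spearman correlations over session-mean pairs —
test-retest within an instrument, or cross-instrument on the two raw scales
(no anomalous-quotient transform: those are only meaningful between
instruments sharing primaries).

Phenotype classification is model-anchored: the normal reference point and
the side on which each anomalous class falls are *computed* from the
package's own match predictions for the normal observer and for moderate
protan/deutan archetypes on the instrument at hand, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instrument import Instrument
from .matching import predict_match
from .observers import (
    ConeSensitivity,
    PrereceptoralFilter,
    make_anomalous_observer,
    make_normal_observer,
)

__all__ = [
    "ReliabilityReport",
    "CrossInstrumentReport",
    "ClassificationReference",
    "LABELS",
    "summarize_sessions",
    "correlation",
    "make_classification_reference",
    "classify_observer",
    "classify_summaries",
    "reliability_report",
    "cross_instrument_report",
    "plot_reliability",
]

LABELS = ["normal", "protan-side", "deutan-side", "unclassifiable"]


def summarize_sessions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(observer, instrument, session) mean/SD/n of the settings.

    SDs use the sample (n-1) convention.  ``n`` counts non-missing settings;
    excluded observers keep their rows (with ``excluded=True``) so that
    downstream reports can count them, but they carry no usable means.
    """
    if table is None or len(table) == 0:
        raise ValueError("empty study table")
    g = table.groupby(["observer_id", "true_label", "instrument", "session"],
                      sort=True)
    out = g.agg(
        mean_lambda=("lambda", "mean"),
        sd_lambda=("lambda", lambda s: s.std(ddof=1)),
        n=("lambda", "count"),
        excluded=("excluded", "any"),
    ).reset_index()
    return out


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p-value.

    ``pearson`` is the product-moment coefficient; ``spearman`` is Pearson on
    midrank-transformed data.  p-values use the t approximation with n-2
    degrees of freedom.  Vectors of unequal length, fewer than 3 points,
    non-finite values or zero variance are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    return float(r.statistic), float(r.pvalue)


@dataclass(frozen=True)
class ReliabilityReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_observers: int
    subset: str
    pairs: pd.DataFrame = field(repr=False)


@dataclass(frozen=True)
class ClassificationReference:
    """Model-derived classification anchor for one instrument.

    ``normal_lambda`` is the predicted normal match; settings within
    ``halfwidth`` of it (closed interval) are 'normal'.  The side carried by
    each anomalous class is the sign of the displacement of that class's
    archetype match; when the model puts both archetypes on the same side the
    nearest archetype decides instead.
    """

    instrument_name: str
    normal_lambda: float
    halfwidth: float
    protan_lambda: float
    deutan_lambda: float

    @property
    def protan_sign(self) -> float:
        return float(np.sign(self.protan_lambda - self.normal_lambda))

    @property
    def deutan_sign(self) -> float:
        return float(np.sign(self.deutan_lambda - self.normal_lambda))


def make_classification_reference(
    instrument: Instrument,
    normal_set: dict[str, ConeSensitivity],
    pre: PrereceptoralFilter,
    halfwidth: float | None = None,
    normal_lambda_sd: float | None = None,
    jitter_sd_cm1: float = 60.0,
    protan_archetype_cm1: float = -300.0,
    deutan_archetype_cm1: float = 300.0,
) -> ClassificationReference:
    """Derive the normal range and anomalous sides from the model itself.

    The default halfwidth is 4x the normals' between-observer match SD on
    this instrument's scale, itself propagated from the normal jitter SD
    through the model's local match sensitivity.
    """
    normal_lam = predict_match(instrument, make_normal_observer(normal_set)).lambda_star
    protan_lam = predict_match(
        instrument, make_anomalous_observer(normal_set, "protanomalous",
                                            protan_archetype_cm1, pre)).lambda_star
    deutan_lam = predict_match(
        instrument, make_anomalous_observer(normal_set, "deuteranomalous",
                                            deutan_archetype_cm1, pre)).lambda_star
    if halfwidth is None:
        if normal_lambda_sd is None:
            probe = 100.0
            lam_p = predict_match(instrument,
                                  make_normal_observer(normal_set, probe, pre)).lambda_star
            lam_m = predict_match(instrument,
                                  make_normal_observer(normal_set, -probe, pre)).lambda_star
            normal_lambda_sd = abs(lam_p - lam_m) / (2 * probe) * jitter_sd_cm1
        halfwidth = 4.0 * normal_lambda_sd
    return ClassificationReference(instrument.name, normal_lam, float(halfwidth),
                                   protan_lam, deutan_lam)


def classify_observer(mean_lambda: float, reference: ClassificationReference) -> str:
    """Label a session-mean setting as normal / protan-side / deutan-side.

    The normal interval is closed: a mean exactly on the boundary is normal.
    Missing means (excluded observers) are unclassifiable.
    """
    if mean_lambda is None or not np.isfinite(mean_lambda):
        return "unclassifiable"
    d = mean_lambda - reference.normal_lambda
    # closed interval; the tiny slack keeps means computed as
    # normal_lambda + halfwidth on the 'normal' side despite fp rounding
    if abs(d) <= reference.halfwidth * (1 + 1e-12):
        return "normal"
    if reference.protan_sign != reference.deutan_sign:
        return "protan-side" if np.sign(d) == reference.protan_sign else "deutan-side"
    # degenerate model geometry: fall back to the nearer archetype
    dp = abs(mean_lambda - reference.protan_lambda)
    dd = abs(mean_lambda - reference.deutan_lambda)
    return "protan-side" if dp <= dd else "deutan-side"


def classify_summaries(
    summaries: pd.DataFrame,
    instrument_name: str,
    reference: ClassificationReference,
) -> pd.Series:
    """Per-observer label on one instrument (mean of that instrument's session means)."""
    sub = summaries[summaries["instrument"] == instrument_name]
    if sub.empty:
        raise ValueError(f"no rows for instrument {instrument_name!r}")
    means = sub.groupby("observer_id")["mean_lambda"].mean()
    return means.apply(lambda m: classify_observer(m, reference)).rename("label")


def _session_mean_pairs(summaries, instrument_name, sessions, subset):
    sub = summaries[(summaries["instrument"] == instrument_name)
                    & (~summaries["excluded"])]
    if subset == "normals":
        sub = sub[sub["true_label"] == "normal"]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'normals'")
    wide = sub.pivot_table(index="observer_id", columns="session",
                           values="mean_lambda")
    missing = [s for s in sessions if s not in wide.columns]
    if missing:
        raise ValueError(f"sessions {missing} absent for instrument {instrument_name!r}")
    wide = wide[list(sessions)].dropna()
    return wide


def reliability_report(
    summaries: pd.DataFrame,
    instrument_name: str,
    sessions: tuple[int, int] = (1, 2),
    subset: str = "all",
) -> ReliabilityReport:
    """Test-retest correlation between two sessions' per-observer means."""
    wide = _session_mean_pairs(summaries, instrument_name, sessions, subset)
    if len(wide) < 3:
        raise ValueError(f"need >= 3 observers with both sessions, have {len(wide)}")
    x = wide[sessions[0]].to_numpy()
    y = wide[sessions[1]].to_numpy()
    r, p = correlation(x, y, "pearson")
    rho, p_s = correlation(x, y, "spearman")
    return ReliabilityReport(r, p, rho, p_s, len(wide), subset, wide.reset_index())


@dataclass(frozen=True)
class CrossInstrumentReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_observers: int
    agreement: pd.DataFrame = field(repr=False)
    contradictory_count: int = 0
    pairs: pd.DataFrame = field(repr=False, default=None)


def cross_instrument_report(
    summaries: pd.DataFrame,
    instrument_a: str,
    instrument_b: str,
    reference_a: ClassificationReference | None = None,
    reference_b: ClassificationReference | None = None,
    session: int = 1,
) -> CrossInstrumentReport:
    """Correlate and cross-tabulate the same observers on two instruments.

    Correlations are computed on the two instruments' raw scales from the
    chosen session's per-observer means.  When classification references are
    supplied, a 3x3 agreement matrix over {normal, protan-side, deutan-side}
    is added; the contradictory-diagnosis count is the number of observers
    labeled on *opposite anomalous sides* by the two instruments.
    """
    sub = summaries[(~summaries["excluded"]) & (summaries["session"] == session)]
    wide = sub.pivot_table(index="observer_id", columns="instrument",
                           values="mean_lambda")
    for name in (instrument_a, instrument_b):
        if name not in wide.columns:
            raise ValueError(f"no session-{session} data for instrument {name!r}")
    wide = wide[[instrument_a, instrument_b]].dropna()
    if len(wide) < 3:
        raise ValueError(f"need >= 3 observers on both instruments, have {len(wide)}")
    x = wide[instrument_a].to_numpy()
    y = wide[instrument_b].to_numpy()
    r, p = correlation(x, y, "pearson")
    rho, p_s = correlation(x, y, "spearman")
    agreement = pd.DataFrame()
    contradictory = 0
    if reference_a is not None and reference_b is not None:
        la = wide[instrument_a].apply(lambda m: classify_observer(m, reference_a))
        lb = wide[instrument_b].apply(lambda m: classify_observer(m, reference_b))
        cats = ["normal", "protan-side", "deutan-side"]
        agreement = pd.crosstab(la, lb).reindex(index=cats, columns=cats,
                                                fill_value=0)
        contradictory = int((((la == "protan-side") & (lb == "deutan-side"))
                             | ((la == "deutan-side") & (lb == "protan-side"))).sum())
    return CrossInstrumentReport(r, p, rho, p_s, len(wide), agreement,
                                 contradictory, wide.reset_index())


def plot_reliability(report, ax=None, xlabel="session 1 mean", ylabel="session 2 mean"):
    """Scatter a reliability (or cross-instrument) report's session-mean pairs."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pairs = report.pairs.set_index("observer_id")
    cols = list(pairs.columns)
    ax.scatter(pairs[cols[0]], pairs[cols[1]], s=18, alpha=0.8)
    lo = min(pairs[cols[0]].min(), pairs[cols[1]].min())
    hi = max(pairs[cols[0]].max(), pairs[cols[1]].max())
    ax.plot([lo, hi], [lo, hi], lw=0.8, color="gray")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    r = getattr(report, "pearson_r", float("nan"))
    ax.set_title(f"R = {r:.3f} (n = {report.n_observers})")
    return ax
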