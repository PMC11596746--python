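"""Calibration curves, R²(t) trajectories, LOD, and metric selection.

The calibration model is an ordinary least-squares line of signal versus
log10(concentration) over the nonzero standards; the blank (0 ng/mL) is
excluded from the fit (log undefined) and used only for the limit of
detection.  R² is defined as 1 − SS_res/SS_tot so degenerate fits (zero
signal variance) are detectable rather than silently reported as perfect.

The limit of detection follows the blank-plus-3·SD convention: the blank
mean shifted by k·SD in the direction of increasing concentration is mapped
back through the fitted line.  For a decreasing-signal metric such as the
red-channel ratio the shift is downward.

Metric selection reproduces the replicate-chip concordance screen: a
candidate image metric is kept when (a) its coefficient of variation over
the concordant replicate chips stays under a bound (2% by default) and
(b) it singles out the same discordant chip as the reference optical
densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FitError
from .kinetics import KineticTrace, value_at

__all__ = [
    "CalibrationModel",
    "LODEstimate",
    "MetricReport",
    "coefficient_of_variation",
    "load_standards",
    "load_reference_ods",
    "fit_calibration",
    "r2_trajectory",
    "earliest_reliable_time",
    "estimate_lod",
    "compare_metrics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted signal-vs-log10(concentration) line at one read time.

    ``r_squared`` is None (and ``degenerate`` True) when the signals have
    zero variance, in which case slope/intercept describe the flat line.
    """

    t_read: float
    slope: float
    intercept: float
    r_squared: float | None
    metric: str | None = None
    n_points: int = 0
    degenerate: bool = False

    def predict(self, concentration: float) -> float:
        if concentration <= 0:
            raise DomainError("concentration must be > 0 to evaluate the log-linear curve")
        return self.slope * math.log10(concentration) + self.intercept

    def invert(self, signal: float) -> float:
        """Concentration (ng/mL) whose fitted signal equals ``signal``."""
        if abs(self.slope) < 1e-300:
            raise FitError("cannot invert a flat calibration curve")
        return 10.0 ** ((signal - self.intercept) / self.slope)


@dataclass(frozen=True)
class LODEstimate:
    """Limit of detection: blank mean ± k·SD mapped through the calibration curve."""

    lod: float
    blank_mean: float
    blank_sd: float
    k: float


@dataclass(frozen=True)
class MetricReport:
    """Concordance screen result for one candidate metric."""

    metric: str
    evaluable: bool
    cv: float | None
    cv_ok: bool | None
    trend_concordant: bool | None

    @property
    def passes(self) -> bool:
        return bool(self.evaluable and self.cv_ok and self.trend_concordant)


def load_standards(path) -> dict[str, float]:
    """Load ``chamber_id,concentration_ng_per_ml`` CSV into a mapping."""
    df = pd.read_csv(path)
    missing = {"chamber_id", "concentration_ng_per_ml"} - set(df.columns)
    if missing:
        raise DomainError(f"standards table {path} lacks column(s) {sorted(missing)}")
    return dict(zip(df["chamber_id"].astype(str), df["concentration_ng_per_ml"].astype(float)))


def load_reference_ods(path) -> dict[str, float]:
    """Load ``chip_id,od`` CSV into a mapping."""
    df = pd.read_csv(path)
    missing = {"chip_id", "od"} - set(df.columns)
    if missing:
        raise DomainError(f"reference OD table {path} lacks column(s) {sorted(missing)}")
    return dict(zip(df["chip_id"].astype(str), df["od"].astype(float)))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n−1 denominator) divided by the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def _nonzero_standards(standards: Mapping[str, float]) -> dict[str, float]:
    for cid, conc in standards.items():
        if conc < 0:
            raise DomainError(f"standard {cid}: concentration must be >= 0, got {conc}")
    return {cid: conc for cid, conc in standards.items() if conc > 0}


def fit_calibration(
    standards: Mapping[str, float],
    signals: Mapping[str, float],
    t_read: float,
    metric: str | None = None,
) -> CalibrationModel:
    """OLS of signal vs log10(concentration) over the nonzero standards.

    Requires signals for all nonzero standards and at least 3 distinct
    nonzero concentrations.  Zero signal variance yields a degenerate model
    with undefined R² rather than an exception.
    """
    nonzero = _nonzero_standards(standards)
    if len(set(nonzero.values())) < 3:
        raise FitError(
            f"calibration needs >= 3 distinct nonzero standard concentrations, "
            f"got {sorted(set(nonzero.values()))}"
        )
    missing = [cid for cid in nonzero if cid not in signals]
    if missing:
        raise FitError(f"missing signals for standard chamber(s) {missing}")
    x = np.log10([nonzero[cid] for cid in nonzero])
    y = np.array([float(signals[cid]) for cid in nonzero])
    if not np.all(np.isfinite(y)):
        raise FitError("non-finite signal values in calibration fit")
    if np.ptp(y) == 0.0:
        return CalibrationModel(
            t_read=t_read,
            slope=0.0,
            intercept=float(y[0]),
            r_squared=None,
            metric=metric,
            n_points=len(y),
            degenerate=True,
        )
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    model = CalibrationModel(
        t_read=t_read,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=1.0 - ss_res / ss_tot,
        metric=metric,
        n_points=len(y),
    )
    logger.info(
        "calibration at t=%.1f s: slope=%.5g intercept=%.5g R2=%.5f (n=%d)",
        t_read,
        model.slope,
        model.intercept,
        model.r_squared,
        model.n_points,
    )
    return model


def r2_trajectory(
    traces: Mapping[str, KineticTrace],
    standards: Mapping[str, float],
    time_grid: Sequence[float],
    metric: str | None = None,
) -> pd.DataFrame:
    """R² of the calibration fit at each grid time; columns ``time_s, r_squared``.

    Degenerate fits appear as NaN.  Fit errors are re-raised annotated with
    the offending time point.
    """
    rows = []
    for t in time_grid:
        signals = {cid: value_at(tr, t) for cid, tr in traces.items()}
        try:
            model = fit_calibration(standards, signals, t_read=t, metric=metric)
        except FitError as exc:
            raise FitError(f"at t={t}: {exc}") from exc
        rows.append((float(t), np.nan if model.degenerate else model.r_squared))
    return pd.DataFrame(rows, columns=["time_s", "r_squared"])


def earliest_reliable_time(
    r2_series: pd.DataFrame | Sequence[tuple[float, float]],
    threshold: float = 0.95,
) -> float | None:
    """Smallest grid time from which R² stays at/above ``threshold`` (sustained).

    A single-point crossing followed by a dip does not qualify.  Returns
    None when no sustained crossing exists.
    """
    if isinstance(r2_series, pd.DataFrame):
        times = r2_series["time_s"].to_numpy(dtype=float)
        r2 = r2_series["r_squared"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(r2_series), dtype=float)
        if arr.size == 0:
            raise DomainError("empty R² series")
        times, r2 = arr[:, 0], arr[:, 1]
    if len(times) == 0:
        raise DomainError("empty R² series")
    ok = (r2 >= threshold) & np.isfinite(r2)
    sustained = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(sustained)
    return float(times[idx[0]]) if idx.size else None


def estimate_lod(
    model: CalibrationModel,
    blank_signals: Sequence[float],
    k: float = 3.0,
) -> LODEstimate:
    """Blank mean ± k·SD inverted through the calibration curve.

    The shift is taken toward increasing concentration: added for a rising
    signal (positive slope), subtracted for a falling one such as the
    red-channel ratio.
    """
    blanks = np.asarray(blank_signals, dtype=float)
    if blanks.size < 2:
        raise DomainError("LOD needs at least 2 blank replicates")
    if model.degenerate or abs(model.slope) < 1e-300:
        raise FitError("LOD undefined for a flat calibration curve")
    blank_mean = float(blanks.mean())
    blank_sd = float(blanks.std(ddof=1))
    signal_at_lod = blank_mean + math.copysign(k * blank_sd, model.slope)
    return LODEstimate(
        lod=model.invert(signal_at_lod),
        blank_mean=blank_mean,
        blank_sd=blank_sd,
        k=k,
    )


def _extreme_chip(values: Mapping[str, float]) -> str:
    """Chip whose value deviates most from the median of all chips."""
    med = float(np.median(list(values.values())))
    return max(values, key=lambda cid: (abs(values[cid] - med), cid))


def compare_metrics(
    metric_signals: Mapping[str, Mapping[str, float]],
    reference: Mapping[str, float],
    cv_threshold: float = 0.02,
) -> list[MetricReport]:
    """Concordance screen of candidate metrics against reference ODs.

    The reference identifies one discordant chip (largest deviation from the
    median OD); the rest form the concordant set.  A metric passes when its
    CV over the concordant chips is below ``cv_threshold`` and it ranks the
    same chip as most discordant (direction-agnostic, since decreasing-color
    metrics anti-correlate with OD).
    """
    if len(reference) < 3:
        raise DomainError("need at least 3 reference chips")
    discordant = _extreme_chip(reference)
    concordant = [cid for cid in reference if cid != discordant]
    reports = []
    for metric, signals in metric_signals.items():
        if any(cid not in signals for cid in reference):
            reports.append(
                MetricReport(metric=metric, evaluable=False, cv=None, cv_ok=None, trend_concordant=None)
            )
            continue
        cv = coefficient_of_variation([signals[cid] for cid in concordant])
        trend = _extreme_chip({cid: signals[cid] for cid in reference}) == discordant
        reports.append(
            MetricReport(
                metric=metric,
                evaluable=True,
                cv=cv,
                cv_ok=abs(cv) < cv_threshold,
                trend_concordant=trend,
            )
        )
    return reports
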