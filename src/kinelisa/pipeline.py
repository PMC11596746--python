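"""End-to-end assay analysis: signals -> corrected traces -> calibration report."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration, kinetics, roi_signal
from .calibration import CalibrationModel, LODEstimate
from .errors import DomainError, FitError
from .kinetics import KineticTrace
from .roi_signal import ChamberROI, FrameRecord, SignalSeries

__all__ = ["AssayResult", "analyze_series", "analyze_assay", "series_from_frame"]


@dataclass
class AssayResult:
    """Everything the kinetic analysis produces for one assay and one metric."""

    metric: str
    traces: dict[str, KineticTrace]          # corrected + smoothed, per chamber
    r2_trajectory: pd.DataFrame              # columns time_s, r_squared
    earliest_reliable_time_s: float | None
    t_read: float
    model: CalibrationModel
    lod: LODEstimate | None

    def report_dict(self) -> dict:
        """JSON-serializable calibration report."""
        return {
            "metric": self.metric,
            "t_read_s": self.t_read,
            "slope": self.model.slope,
            "intercept": self.model.intercept,
            "r_squared": self.model.r_squared,
            "degenerate_fit": self.model.degenerate,
            "n_standards": self.model.n_points,
            "earliest_reliable_time_s": self.earliest_reliable_time_s,
            "lod_ng_per_ml": None if self.lod is None else self.lod.lod,
            "blank_mean": None if self.lod is None else self.lod.blank_mean,
            "blank_sd": None if self.lod is None else self.lod.blank_sd,
        }


def series_from_frame(signals: pd.DataFrame, metric: str) -> list[SignalSeries]:
    """Rebuild per-chamber :class:`SignalSeries` from a tidy signal table."""
    channel, transform = roi_signal.parse_metric(metric)
    sub = signals[signals["metric"] == metric]
    if sub.empty:
        raise DomainError(f"no rows for metric {metric!r} in the signal table")
    out = []
    for cid, grp in sub.groupby("chamber_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            SignalSeries(
                chamber_id=str(cid),
                channel=channel,
                transform=transform,
                times=grp["time_s"].to_numpy(),
                values=grp["value"].to_numpy(),
            )
        )
    return out


def analyze_series(
    series: Sequence[SignalSeries],
    standards: Mapping[str, float],
    *,
    max_rel_change_per_s: float = 0.05,
    window_s: float = 30.0,
    r2_threshold: float = 0.95,
    grid_step_s: float = 10.0,
    lod_k: float = 3.0,
    correction_mode: str = "interpolate",
) -> AssayResult:
    """Correct, smooth, locate the earliest reliable read time, calibrate, and
    estimate the LOD.

    The calibration is fitted at the earliest grid time from which R² stays
    at/above ``r2_threshold``; if no sustained crossing exists, the endpoint
    (last common time) is used and ``earliest_reliable_time_s`` is None.
    The LOD requires >= 2 blank (0 ng/mL) chambers; otherwise it is None.
    """
    if not series:
        raise DomainError("no signal series to analyze")
    metric = series[0].metric
    traces: dict[str, KineticTrace] = {}
    for s in series:
        corrected = kinetics.correct_artifacts(
            s, max_rel_change_per_s=max_rel_change_per_s, mode=correction_mode
        )
        traces[s.chamber_id] = kinetics.moving_average(corrected, window_s=window_s)

    t_first = max(tr.times[0] for tr in traces.values())
    t_last = min(tr.times[-1] for tr in traces.values())
    grid = np.arange(t_first, t_last + 1e-9, grid_step_s)
    if grid[-1] < t_last - 1e-9:
        grid = np.append(grid, t_last)

    trajectory = calibration.r2_trajectory(traces, standards, grid, metric=metric)
    earliest = calibration.earliest_reliable_time(trajectory, threshold=r2_threshold)
    t_read = earliest if earliest is not None else float(t_last)
    signals_at = {cid: kinetics.value_at(tr, t_read) for cid, tr in traces.items()}
    model = calibration.fit_calibration(standards, signals_at, t_read=t_read, metric=metric)

    blanks = [signals_at[cid] for cid, conc in standards.items() if conc == 0 and cid in signals_at]
    lod = None
    if len(blanks) >= 2 and not model.degenerate:
        try:
            lod = calibration.estimate_lod(model, blanks, k=lod_k)
        except FitError:
            lod = None
    return AssayResult(
        metric=metric,
        traces=traces,
        r2_trajectory=trajectory,
        earliest_reliable_time_s=earliest,
        t_read=t_read,
        model=model,
        lod=lod,
    )


def analyze_assay(
    frames: Sequence[FrameRecord],
    rois: Sequence[ChamberROI],
    standards: Mapping[str, float],
    metric: str = "R:ratio",
    *,
    reference_time: float | None = None,
    n_ref: int = 3,
    **kwargs,
) -> AssayResult:
    """Convenience wrapper: extraction plus :func:`analyze_series` in one call."""
    series = roi_signal.build_series(
        frames, rois, metric, reference_time=reference_time, n_ref=n_ref
    )
    return analyze_series(series, standards, **kwargs)
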