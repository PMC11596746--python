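"""Artifact correction and smoothing of chamber kinetic traces.

The strobe's flash-to-flash intensity varies, and occasional large flashes
produce single-frame excursions in the extracted signal.  Two stages clean a
trace:

1. **Artifact correction** — a sample is flagged when its relative change
   from the last accepted sample exceeds 5% per second (scaled by the actual
   time gap); flagged samples are replaced by linear interpolation between
   the nearest unflagged neighbours (or by holding the previous accepted
   value, configurable).
2. **Moving average** — a trailing (causal) 30-s window mean, so the smoothed
   value at time t uses only data already acquired, enabling real-time
   readout during an assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import CorrectionFailureError, DomainError, RangeError
from .roi_signal import SignalSeries

__all__ = ["KineticTrace", "correct_artifacts", "moving_average", "value_at", "traces_to_frame"]

logger = logging.getLogger(__name__)


@dataclass
class KineticTrace:
    """A corrected (and possibly smoothed) chamber time series.

    ``corrected_mask`` marks samples replaced by the artifact correction.
    """

    chamber_id: str
    times: np.ndarray
    values: np.ndarray
    corrected_mask: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.corrected_mask = np.asarray(self.corrected_mask, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.corrected_mask)):
            raise DomainError("times, values and corrected_mask must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")


def _trace_inputs(series) -> tuple[str, np.ndarray, np.ndarray]:
    if isinstance(series, (SignalSeries, KineticTrace)):
        return series.chamber_id, np.asarray(series.times, float), np.asarray(series.values, float)
    raise DomainError(f"expected SignalSeries or KineticTrace, got {type(series).__name__}")


def correct_artifacts(
    series,
    max_rel_change_per_s: float = 0.05,
    mode: str = "interpolate",
) -> KineticTrace:
    """Flag and repair samples that change faster than ``max_rel_change_per_s``.

    A sample is flagged when its absolute relative change from the last
    *accepted* sample exceeds the bound times the elapsed time since that
    sample; chains of consecutive flash frames are therefore all caught.
    Flagged samples are replaced by linear interpolation between the nearest
    unflagged neighbours (``mode="interpolate"``, default) or by the previous
    unflagged value (``mode="hold"``).

    Requires >= 2 samples with strictly positive values (a ratio-type
    metric).  Raises :class:`CorrectionFailureError` when every sample after
    the first is flagged.
    """
    chamber_id, t, v = _trace_inputs(series)
    if len(v) < 2:
        raise DomainError("artifact correction needs at least 2 samples")
    if np.any(v <= 0):
        raise DomainError("artifact correction expects strictly positive values (ratio metric)")
    if mode not in ("interpolate", "hold"):
        raise DomainError(f"unknown correction mode {mode!r}")
    if max_rel_change_per_s <= 0:
        raise DomainError("max_rel_change_per_s must be > 0")

    flagged = np.zeros(len(v), dtype=bool)
    last = 0  # index of last accepted sample
    for i in range(1, len(v)):
        bound = max_rel_change_per_s * (t[i] - t[last])
        if abs(v[i] - v[last]) / v[last] > bound:
            flagged[i] = True
        else:
            last = i
    if flagged[1:].all():
        raise CorrectionFailureError(
            f"chamber {chamber_id}: every sample after the first exceeds the "
            f"{max_rel_change_per_s:.3g}/s change bound; trace unusable"
        )

    corrected = v.copy()
    if flagged.any():
        keep = ~flagged
        if mode == "interpolate":
            corrected[flagged] = np.interp(t[flagged], t[keep], v[keep])
        else:
            # hold the most recent accepted value
            idx = np.maximum.accumulate(np.where(keep, np.arange(len(v)), -1))
            corrected[flagged] = v[idx[flagged]]
        logger.info(
            "chamber %s: corrected %d/%d samples at t=%s",
            chamber_id,
            int(flagged.sum()),
            len(v),
            np.round(t[flagged], 3).tolist(),
        )
    return KineticTrace(chamber_id=chamber_id, times=t, values=corrected, corrected_mask=flagged)


def moving_average(trace: KineticTrace, window_s: float = 30.0) -> KineticTrace:
    """Trailing-window mean: each output is the mean over timestamps in (t - w, t].

    The window always contains the current sample, so the output is defined
    everywhere and the timestamps are unchanged.
    """
    if window_s <= 0:
        raise DomainError("window_s must be > 0")
    t, v = trace.times, trace.values
    starts = np.searchsorted(t, t - window_s, side="right")
    # Anchoring at the current sample keeps a locally constant trace exact.
    smoothed = np.array(
        [v[i] + np.mean(v[s : i + 1] - v[i]) for i, s in enumerate(starts)]
    )
    return KineticTrace(
        chamber_id=trace.chamber_id,
        times=t,
        values=smoothed,
        corrected_mask=trace.corrected_mask.copy(),
    )


def value_at(trace: KineticTrace, t_query: float) -> float:
    """Linear interpolation of the trace at ``t_query`` (no extrapolation)."""
    t = trace.times
    if len(t) == 0:
        raise DomainError("empty trace")
    if not (t[0] <= t_query <= t[-1]):
        raise RangeError(
            f"chamber {trace.chamber_id}: query t={t_query} outside trace span [{t[0]}, {t[-1]}]"
        )
    return float(np.interp(t_query, t, trace.values))


def traces_to_frame(traces: Iterable[KineticTrace]) -> pd.DataFrame:
    """Tidy table ``chamber_id,time_s,value,corrected`` for CSV export."""
    parts = [
        pd.DataFrame(
            {
                "chamber_id": tr.chamber_id,
                "time_s": tr.times,
                "value": tr.values,
                "corrected": tr.corrected_mask,
            }
        )
        for tr in traces
    ]
    if not parts:
        return pd.DataFrame(columns=["chamber_id", "time_s", "value", "corrected"])
    return pd.concat(parts, ignore_index=True)
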