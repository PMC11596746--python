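"""Frame-sequence reading, per-chamber ROI averaging, and signal transforms.

A chamber signal is the mean pixel value over a circular region of interest,
taken per frame and per color channel (RGB, or CIELAB L*/a*/b*/h after
conversion of the ROI-mean color).  Three transforms are supported:

``raw``
    the per-frame channel value itself;
``difference``
    value minus the initial value;
``ratio``
    value divided by the initial value.

The initial ("reference") value is the mean of the first ``n_ref`` frames at
or after the reference time — the moment the chromogenic substrate enters the
chamber.  The ratio transform is the illumination-robust metric: a static,
chamber-position-dependent illumination factor multiplies every frame equally
and cancels exactly in the ratio.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import colorspace
from .errors import (
    DegenerateReferenceError,
    DomainError,
    GeometryError,
    LoadError,
)

__all__ = [
    "CHANNELS",
    "TRANSFORMS",
    "FrameRecord",
    "ChamberROI",
    "SignalSeries",
    "parse_metric",
    "load_rois",
    "read_frame_sequence",
    "roi_mean",
    "roi_mean_table",
    "build_series",
    "series_to_frame",
]

CHANNELS = ("R", "G", "B", "L", "a", "b", "h")
TRANSFORMS = ("raw", "difference", "ratio")


@dataclass(frozen=True)
class FrameRecord:
    """One timestamped RGB image of the disk.

    ``image`` is H x W x 3; integer dtypes are interpreted as 8-bit values
    (divided by 255 on averaging), float dtypes as values already in [0, 1].
    """

    t: float
    image: np.ndarray

    def __post_init__(self):
        img = self.image
        if img.ndim != 3 or img.shape[2] != 3:
            raise LoadError(f"frame at t={self.t}: expected H x W x 3 image, got shape {img.shape}")
        if self.t < 0:
            raise LoadError(f"frame timestamp must be non-negative, got {self.t}")


@dataclass(frozen=True)
class ChamberROI:
    """Circular pixel region of one reaction chamber (0-based row/col center)."""

    chamber_id: str
    center_row: float
    center_col: float
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError(f"ROI {self.chamber_id}: radius must be > 0")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose center lies within ``radius`` of the ROI center."""
        h, w = shape
        if (
            self.center_row - self.radius < -0.5
            or self.center_col - self.radius < -0.5
            or self.center_row + self.radius > h - 0.5
            or self.center_col + self.radius > w - 0.5
        ):
            raise GeometryError(
                f"ROI {self.chamber_id} (center ({self.center_row}, {self.center_col}), "
                f"radius {self.radius}) does not fit inside a {h} x {w} frame"
            )
        rows = np.arange(h)[:, None] - self.center_row
        cols = np.arange(w)[None, :] - self.center_col
        return rows * rows + cols * cols <= self.radius * self.radius


@dataclass
class SignalSeries:
    """One chamber x one metric time series."""

    chamber_id: str
    channel: str
    transform: str
    times: np.ndarray
    values: np.ndarray
    reference_value: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DomainError("times and values must have equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise DomainError(f"series {self.chamber_id}: times must be strictly increasing")
        if self.channel not in CHANNELS:
            raise DomainError(f"unknown channel {self.channel!r}")
        if self.transform not in TRANSFORMS:
            raise DomainError(f"unknown transform {self.transform!r}")

    @property
    def metric(self) -> str:
        return f"{self.channel}:{self.transform}"


def parse_metric(metric: str) -> tuple[str, str]:
    """Split a metric string like ``"R:ratio"`` into (channel, transform)."""
    try:
        channel, transform = metric.split(":")
    except ValueError:
        raise DomainError(f"metric must look like 'R:ratio', got {metric!r}") from None
    if channel not in CHANNELS or transform not in TRANSFORMS:
        raise DomainError(
            f"metric {metric!r}: channel must be one of {CHANNELS}, transform one of {TRANSFORMS}"
        )
    return channel, transform


def load_rois(path) -> list[ChamberROI]:
    """Load chamber ROIs from a YAML/JSON list of {chamber_id, center_row, center_col, radius}."""
    import yaml

    if not os.path.exists(path):
        raise LoadError(f"ROI config not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise LoadError(f"ROI config {path} must be a list of mappings")
    try:
        return [ChamberROI(**entry) for entry in data]
    except TypeError as exc:
        raise LoadError(f"ROI config {path}: {exc}") from None


def read_frame_sequence(directory_path, manifest_path) -> list[FrameRecord]:
    """Load the frames listed in a ``filename,time_s`` CSV manifest, time-sorted.

    Raises :class:`LoadError` naming the offending frame on a missing file,
    an unparseable timestamp, or inconsistent image dimensions.
    """
    manifest = pd.read_csv(manifest_path)
    missing_cols = {"filename", "time_s"} - set(manifest.columns)
    if missing_cols:
        raise LoadError(f"manifest {manifest_path} lacks column(s) {sorted(missing_cols)}")
    records: list[FrameRecord] = []
    for row in manifest.itertuples(index=False):
        path = os.path.join(directory_path, str(row.filename))
        try:
            t = float(row.time_s)
        except (TypeError, ValueError):
            raise LoadError(f"frame {row.filename}: unparseable timestamp {row.time_s!r}") from None
        if not np.isfinite(t):
            raise LoadError(f"frame {row.filename}: unparseable timestamp {row.time_s!r}")
        if not os.path.exists(path):
            raise LoadError(f"frame {row.filename}: file not found at {path}")
        img = iio.imread(path)
        if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        if img.ndim != 3 or img.shape[2] != 3:
            raise LoadError(f"frame {row.filename}: expected RGB image, got shape {img.shape}")
        records.append(FrameRecord(t=t, image=img))
    records.sort(key=lambda fr: fr.t)
    shapes = {fr.image.shape for fr in records}
    if len(shapes) > 1:
        raise LoadError(f"frames have inconsistent dimensions: {sorted(shapes)}")
    times = [fr.t for fr in records]
    if len(set(times)) != len(times):
        raise LoadError("manifest contains duplicate timestamps")
    return records


def _image_as_unit_float(image: np.ndarray) -> np.ndarray:
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(float) / 255.0
    return image.astype(float)


def roi_mean(frame: FrameRecord, roi: ChamberROI) -> np.ndarray:
    """Per-channel arithmetic mean over the circular ROI, scaled to [0, 1]."""
    mask = roi.mask(frame.image.shape[:2])
    pixels = _image_as_unit_float(frame.image)[mask]
    return pixels.mean(axis=0)


def roi_mean_table(frames: Sequence[FrameRecord], rois: Sequence[ChamberROI]) -> dict[str, np.ndarray]:
    """Mean RGB per frame for each ROI: chamber_id -> array of shape (n_frames, 3).

    Masks are computed once per ROI; all frames must share dimensions.
    """
    if not frames:
        raise DomainError("empty frame sequence")
    shape = frames[0].image.shape[:2]
    masks = {roi.chamber_id: roi.mask(shape) for roi in rois}
    out = {cid: np.empty((len(frames), 3)) for cid in masks}
    for i, fr in enumerate(frames):
        img = _image_as_unit_float(fr.image)
        for cid, mask in masks.items():
            out[cid][i] = img[mask].mean(axis=0)
    return out


def _wrap_degrees(delta: np.ndarray) -> np.ndarray:
    """Map angular differences to (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(delta, dtype=float), 360.0)


def _channel_series(mean_rgb: np.ndarray, channel: str) -> np.ndarray:
    if channel in "RGB":
        return mean_rgb[:, "RGB".index(channel)]
    lab = colorspace.xyz_to_lab(colorspace.rgb_to_xyz(mean_rgb))
    if channel == "h":
        return np.asarray(colorspace.hue_angle(lab[:, 1], lab[:, 2]), dtype=float)
    return lab[:, "Lab".index(channel)]


def build_series(
    frames: Sequence[FrameRecord],
    rois: Sequence[ChamberROI],
    metric: str,
    reference_time: float | None = None,
    n_ref: int = 3,
) -> list[SignalSeries]:
    """Extract one :class:`SignalSeries` per ROI for the requested metric.

    ``reference_time`` defaults to the first frame's timestamp.  The reference
    value is the mean of the first ``n_ref`` frames at/after that time
    (averaging suppresses single-frame strobe jitter in the denominator).
    Hue difference/ratio use the wrapped angular difference in (-180, 180]
    to avoid the 0/360 branch cut.
    """
    channel, transform = parse_metric(metric)
    times = np.array([fr.t for fr in frames], dtype=float)
    if len(times) == 0:
        raise DomainError("empty frame sequence")
    if np.any(np.diff(times) <= 0):
        raise DomainError("frames must be strictly time-ordered; use read_frame_sequence")
    if reference_time is None:
        reference_time = float(times[0])
    if not (times[0] <= reference_time <= times[-1]):
        raise DomainError(
            f"reference_time {reference_time} outside the sequence span [{times[0]}, {times[-1]}]"
        )
    if n_ref < 1:
        raise DomainError("n_ref must be >= 1")
    ref_idx = np.flatnonzero(times >= reference_time)[: n_ref]

    table = roi_mean_table(frames, rois)
    out = []
    for roi in rois:
        values = _channel_series(table[roi.chamber_id], channel)
        v0 = float(np.mean(values[ref_idx]))
        if transform == "raw":
            series_values = values
        elif transform == "difference":
            delta = _wrap_degrees(values - v0) if channel == "h" else values - v0
            series_values = delta
        else:  # ratio
            if v0 == 0.0:
                raise DegenerateReferenceError(
                    f"chamber {roi.chamber_id}: reference value is zero for metric {metric}"
                )
            if channel == "h":
                series_values = (v0 + _wrap_degrees(values - v0)) / v0
            else:
                series_values = values / v0
        out.append(
            SignalSeries(
                chamber_id=roi.chamber_id,
                channel=channel,
                transform=transform,
                times=times,
                values=series_values,
                reference_value=v0,
            )
        )
    return out


def series_to_frame(series: Iterable[SignalSeries]) -> pd.DataFrame:
    """Tidy table ``chamber_id,time_s,metric,value`` for CSV export."""
    parts = [
        pd.DataFrame(
            {
                "chamber_id": s.chamber_id,
                "time_s": s.times,
                "metric": s.metric,
                "value": s.values,
            }
        )
        for s in series
    ]
    if not parts:
        return pd.DataFrame(columns=["chamber_id", "time_s", "metric", "value"])
    return pd.concat(parts, ignore_index=True)
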