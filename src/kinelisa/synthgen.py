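"""Synthetic disk-image assay generator with known ground truth.

Emulates the imaging of reaction chambers on a spinning disk during TMB
color development: each chamber turns from colorless toward blue at a
concentration-dependent rate, so its red channel falls while the blue
channel stays put.  The optical confounds of the real instrument are
modeled explicitly:

* a **static illumination factor** per chamber (lateral strobe placement
  makes brightness depend on chamber position) multiplying all channels;
* **frame-to-frame strobe jitter**, a global multiplicative lognormal
  factor per frame, with occasional large single-frame flashes;
* additive Gaussian pixel noise, clipped to the 8-bit range.

Kinetics: the fractional red-channel drop saturates exponentially,

    ratio(t; c) = 1 - A(c) * (1 - exp(-k t)),   A(c) = A_max * c / (c + c50),

a Langmuir-type dose dependence whose half-saturation c50 sits near the
geometric center of the 1–1000 ng/mL standards, making the dose response
approximately linear in log10(c) over the four decades — the regime in
which a log-linear calibration curve is appropriate.  The defaults give a
development time constant of ~8 minutes, so color is still developing at
100 s but approaches its endpoint on the conventional 15-minute scale.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .roi_signal import ChamberROI, FrameRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ChamberTruth",
    "TraceSample",
    "default_chambers",
    "default_standards",
    "dose_amplitude",
    "ratio_trace",
    "generate_assay",
    "simulate_trace",
    "write_fixture",
    "config_from_dict",
]


def default_chambers() -> list[ChamberROI]:
    """Six chambers in a row: two blanks plus the 1/10/100/1000 ng/mL standards."""
    ids = ["blank_a", "blank_b", "std_1", "std_10", "std_100", "std_1000"]
    return [
        ChamberROI(chamber_id=cid, center_row=30.0, center_col=30.0 + 60.0 * i, radius=12.0)
        for i, cid in enumerate(ids)
    ]


def default_standards() -> dict[str, float]:
    return {
        "blank_a": 0.0,
        "blank_b": 0.0,
        "std_1": 1.0,
        "std_10": 10.0,
        "std_100": 100.0,
        "std_1000": 1000.0,
    }


def _default_illumination(chambers: Sequence[ChamberROI]) -> dict[str, float]:
    # lateral strobe: brightness falls off with chamber position
    return {roi.chamber_id: 1.0 - 0.05 * i for i, roi in enumerate(chambers)}


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic assay; the seed fixes every byte."""

    frame_height: int = 60
    frame_width: int = 360
    chambers: list[ChamberROI] = field(default_factory=default_chambers)
    standards: dict[str, float] = field(default_factory=default_standards)
    frame_interval_s: float = 1.0
    duration_s: float = 600.0
    a_max: float = 0.6               # asymptotic fractional red drop at saturating antigen
    c50_ng_per_ml: float = 30.0      # half-saturation concentration
    rate_per_s: float = 0.002        # exponential development rate (tau ~ 8 min)
    green_fraction: float = 0.5      # green drop as a fraction of the red drop
    base_rgb: tuple[float, float, float] = (0.92, 0.94, 0.95)
    background: float = 0.25
    illumination: dict[str, float] | None = None  # chamber_id -> static factor in (0, 1]
    jitter_sd: float = 0.01          # lognormal sigma of per-frame strobe jitter
    flash_probability: float = 0.02  # per-frame chance of a large flash
    flash_amplitude: float = 0.2     # fractional brightness excursion of a flash
    pixel_noise_sd: float = 0.004    # additive Gaussian noise, [0, 1] units
    quantize: bool = True            # round to 8-bit (False keeps exact floats)
    seed: int = 0

    def __post_init__(self):
        if self.illumination is None:
            self.illumination = _default_illumination(self.chambers)
        self._validate()

    def _validate(self):
        if not (0 <= self.flash_probability <= 1):
            raise ConfigError("flash_probability must be in [0, 1]")
        if not 0 <= self.a_max < 1:
            raise ConfigError("a_max must be in [0, 1)")
        for p, name in [
            (self.frame_interval_s, "frame_interval_s"),
            (self.duration_s, "duration_s"),
            (self.c50_ng_per_ml, "c50_ng_per_ml"),
            (self.rate_per_s, "rate_per_s"),
        ]:
            if p <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.jitter_sd < 0 or self.pixel_noise_sd < 0 or self.flash_amplitude < 0:
            raise ConfigError("noise amplitudes must be >= 0")
        ids = [roi.chamber_id for roi in self.chambers]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate chamber ids")
        for roi in self.chambers:
            roi.mask((self.frame_height, self.frame_width))  # raises GeometryError if outside
            if roi.chamber_id not in self.standards:
                raise ConfigError(f"chamber {roi.chamber_id} missing from standards")
            factor = self.illumination.get(roi.chamber_id)
            if factor is None or not (0 < factor <= 1):
                raise ConfigError(f"chamber {roi.chamber_id}: illumination factor must be in (0, 1]")
        for i, r1 in enumerate(self.chambers):
            for r2 in self.chambers[i + 1 :]:
                d = np.hypot(r1.center_row - r2.center_row, r1.center_col - r2.center_col)
                if d <= r1.radius + r2.radius:
                    raise ConfigError(f"ROIs {r1.chamber_id} and {r2.chamber_id} overlap")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 0.5 * self.frame_interval_s, self.frame_interval_s)


def dose_amplitude(concentration: float, a_max: float, c50: float) -> float:
    """Langmuir dose term A(c): asymptotic fractional red drop at concentration c."""
    return a_max * concentration / (concentration + c50)


def ratio_trace(times, concentration: float, a_max: float, c50: float, rate: float) -> np.ndarray:
    """Noise-free red-channel ratio trace 1 - A(c)(1 - e^{-kt})."""
    t = np.asarray(times, dtype=float)
    return 1.0 - dose_amplitude(concentration, a_max, c50) * (1.0 - np.exp(-rate * t))


@dataclass
class ChamberTruth:
    concentration: float
    illumination: float
    ratio_trace: np.ndarray  # noise-free red ratio at each frame time


@dataclass
class SyntheticTruth:
    """Everything the generator knows: per-chamber kinetics and the noise draws."""

    times: np.ndarray
    chambers: dict[str, ChamberTruth]
    jitter: np.ndarray           # per-frame global multiplicative factor (flashes included)
    flash_frames: list[int]
    config: SyntheticConfig

    @property
    def saturation_time_s(self) -> float:
        """Endpoint readout time: the final frame of the simulated development."""
        return float(self.times[-1])

    def endpoint_signals(self, at_time: float | None = None) -> dict[str, float]:
        """Noise-free red ratio per chamber at ``at_time`` (default: endpoint)."""
        if at_time is None:
            at_time = self.saturation_time_s
        return {
            cid: float(np.interp(at_time, self.times, ch.ratio_trace))
            for cid, ch in self.chambers.items()
        }

    def loglinear_slope(self, at_time: float | None = None) -> float:
        """OLS slope of the noise-free ratio vs log10(c) over nonzero standards."""
        signals = self.endpoint_signals(at_time)
        x, y = [], []
        for cid, ch in self.chambers.items():
            if ch.concentration > 0:
                x.append(np.log10(ch.concentration))
                y.append(signals[cid])
        return float(np.polyfit(x, y, 1)[0])


def generate_assay(config: SyntheticConfig) -> tuple[list[FrameRecord], SyntheticTruth]:
    """Render the frame sequence and return it with its ground truth.

    The same config and seed reproduce the output byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    times = config.times
    n = len(times)
    shape = (config.frame_height, config.frame_width)
    masks = {roi.chamber_id: roi.mask(shape) for roi in config.chambers}

    jitter = np.exp(rng.normal(0.0, config.jitter_sd, n)) if config.jitter_sd > 0 else np.ones(n)
    flash_mask = rng.random(n) < config.flash_probability
    jitter = jitter * np.where(flash_mask, 1.0 + config.flash_amplitude, 1.0)
    flash_frames = np.flatnonzero(flash_mask).tolist()

    chambers: dict[str, ChamberTruth] = {}
    for roi in config.chambers:
        conc = config.standards[roi.chamber_id]
        chambers[roi.chamber_id] = ChamberTruth(
            concentration=conc,
            illumination=config.illumination[roi.chamber_id],
            ratio_trace=ratio_trace(
                times, conc, config.a_max, config.c50_ng_per_ml, config.rate_per_s
            ),
        )

    base = np.asarray(config.base_rgb, dtype=float)
    frames: list[FrameRecord] = []
    for i, t in enumerate(times):
        img = np.full((*shape, 3), config.background, dtype=float)
        for roi in config.chambers:
            ch = chambers[roi.chamber_id]
            red = ch.ratio_trace[i]
            drop = 1.0 - red  # fractional red drop so far
            rgb = base * np.array([red, 1.0 - config.green_fraction * drop, 1.0])
            img[masks[roi.chamber_id]] = rgb * ch.illumination
        img *= jitter[i]
        if config.pixel_noise_sd > 0:
            img += rng.normal(0.0, config.pixel_noise_sd, img.shape)
        np.clip(img, 0.0, 1.0, out=img)
        if config.quantize:
            image = np.round(img * 255.0).astype(np.uint8)
        else:
            image = img
        frames.append(FrameRecord(t=float(t), image=image))

    truth = SyntheticTruth(
        times=times, chambers=chambers, jitter=jitter, flash_frames=flash_frames, config=config
    )
    return frames, truth


@dataclass
class TraceSample:
    """One synthetic ratio trace with strobe jitter and injected flashes."""

    times: np.ndarray
    truth: np.ndarray      # noise-free ratio trace
    observed: np.ndarray   # truth x jitter x flash excursions
    flash_frames: list[int]


def simulate_trace(
    concentration: float,
    seed: int | np.random.Generator,
    *,
    duration_s: float = 600.0,
    interval_s: float = 1.0,
    a_max: float = 0.6,
    c50: float = 30.0,
    rate: float = 0.002,
    jitter_sd: float = 0.01,
    flash_probability: float = 0.02,
    flash_amplitude: tuple[float, float] = (0.1, 0.3),
) -> TraceSample:
    """Trace-level simulator for testing artifact correction and smoothing.

    Flashes are uniform in ``flash_amplitude`` and placed at frame indices
    >= 1: a flash on the reference frame corrupts the whole ratio series
    through the denominator and is invisible to a frame-to-frame rule, so it
    is not part of what the correction stage can be asked to detect.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    truth = ratio_trace(times, concentration, a_max, c50, rate)
    observed = truth * np.exp(rng.normal(0.0, jitter_sd, len(times)))
    flash = np.zeros(len(times), dtype=bool)
    flash[1:] = rng.random(len(times) - 1) < flash_probability
    amps = rng.uniform(*flash_amplitude, size=int(flash.sum()))
    observed[flash] *= 1.0 + amps
    return TraceSample(
        times=times, truth=truth, observed=observed, flash_frames=np.flatnonzero(flash).tolist()
    )


def _frames_as_uint8(frames: Sequence[FrameRecord]) -> list[np.ndarray]:
    out = []
    for fr in frames:
        img = fr.image
        if not np.issubdtype(img.dtype, np.integer):
            img = np.round(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
        out.append(img)
    return out


def write_fixture(
    frames: Sequence[FrameRecord],
    truth: SyntheticTruth,
    directory,
    image_format: str = "png",
    jpeg_quality: int = 95,
) -> dict[str, str]:
    """Write a self-contained fixture: frames, manifest, ROI config, standards, truth.

    PNG (lossless, default) round-trips pixel-identically through
    ``read_frame_sequence``; JPEG emulates the instrument's storage format.
    Returns the paths written.
    """
    if image_format not in ("png", "jpeg"):
        raise ConfigError(f"image_format must be 'png' or 'jpeg', got {image_format!r}")
    ext = "png" if image_format == "png" else "jpg"
    frames_dir = os.path.join(directory, "frames")
    os.makedirs(frames_dir, exist_ok=True)
    images = _frames_as_uint8(frames)

    rows = []
    for i, (fr, img) in enumerate(zip(frames, images)):
        name = f"frame_{i:04d}.{ext}"
        path = os.path.join(frames_dir, name)
        if image_format == "jpeg":
            iio.imwrite(path, img, quality=jpeg_quality)
        else:
            iio.imwrite(path, img)
        rows.append((name, fr.t))
    manifest_path = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows, columns=["filename", "time_s"]).to_csv(manifest_path, index=False)

    rois_path = os.path.join(directory, "rois.yaml")
    with open(rois_path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "chamber_id": roi.chamber_id,
                    "center_row": float(roi.center_row),
                    "center_col": float(roi.center_col),
                    "radius": float(roi.radius),
                }
                for roi in truth.config.chambers
            ],
            fh,
            sort_keys=False,
        )

    standards_path = os.path.join(directory, "standards.csv")
    pd.DataFrame(
        sorted(truth.config.standards.items()),
        columns=["chamber_id", "concentration_ng_per_ml"],
    ).to_csv(standards_path, index=False)

    truth_path = os.path.join(directory, "truth.json")
    cfg = dataclasses.asdict(truth.config)
    cfg["chambers"] = [dataclasses.asdict(roi) for roi in truth.config.chambers]
    payload = {
        "times": truth.times.tolist(),
        "jitter": truth.jitter.tolist(),
        "flash_frames": truth.flash_frames,
        "chambers": {
            cid: {
                "concentration": ch.concentration,
                "illumination": ch.illumination,
                "ratio_trace": ch.ratio_trace.tolist(),
            }
            for cid, ch in truth.chambers.items()
        },
        "params": cfg,
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)

    return {
        "frames_dir": frames_dir,
        "manifest": manifest_path,
        "rois": rois_path,
        "standards": standards_path,
        "truth": truth_path,
    }


def config_from_dict(data: Mapping | None, **overrides) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a parsed YAML/JSON mapping.

    ``chambers`` entries may be mappings with the ChamberROI field names.
    Keyword overrides win over the mapping; unknown keys raise
    :class:`ConfigError`.
    """
    merged = dict(data or {})
    merged.update({k: v for k, v in overrides.items() if v is not None})
    if "chambers" in merged:
        merged["chambers"] = [
            roi if isinstance(roi, ChamberROI) else ChamberROI(**roi) for roi in merged["chambers"]
        ]
    if "base_rgb" in merged:
        merged["base_rgb"] = tuple(merged["base_rgb"])
    known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(merged) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return SyntheticConfig(**merged)
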