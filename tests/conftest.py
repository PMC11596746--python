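"""Shared fixtures and independent scalar-math reference conversions."""

from __future__ import annotations

import math

import numpy as np
import pytest

from kinelisa.roi_signal import ChamberROI
from kinelisa.synthgen import SyntheticConfig


def reference_lab(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Independent scalar CIELAB reference: same matrix and white point as the
    package, but a separate plain-``math`` code path (oracle for the vectorized
    implementation)."""
    m = (
        (0.4124, 0.3576, 0.1805),
        (0.2126, 0.7152, 0.0722),
        (0.0193, 0.1192, 0.9505),
    )
    x = m[0][0] * r + m[0][1] * g + m[0][2] * b
    y = m[1][0] * r + m[1][1] * g + m[1][2] * b
    z = m[2][0] * r + m[2][1] * g + m[2][2] * b

    def f(t: float) -> float:
        if t > (24.0 / 116.0) ** 3:
            return math.pow(t, 1.0 / 3.0)
        return (841.0 / 108.0) * t + 16.0 / 116.0

    fx, fy, fz = f(x / 0.9505), f(y / 1.0), f(z / 1.089)
    return 116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)


def ols_normal_equations(x, y) -> tuple[float, float, float]:
    """Closed-form simple OLS via normal equations; returns (slope, intercept, R²)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1.0 - (resid @ resid) / ss_tot


@pytest.fixture
def twin_chamber_config():
    """Two chambers with identical chemistry, illumination 1.0 vs 0.7, no noise."""

    def make(concentration: float = 100.0, duration_s: float = 60.0) -> SyntheticConfig:
        chambers = [
            ChamberROI("twin_bright", 20.0, 25.0, 10.0),
            ChamberROI("twin_dim", 20.0, 75.0, 10.0),
        ]
        return SyntheticConfig(
            frame_height=40,
            frame_width=100,
            chambers=chambers,
            standards={"twin_bright": concentration, "twin_dim": concentration},
            illumination={"twin_bright": 1.0, "twin_dim": 0.7},
            duration_s=duration_s,
            jitter_sd=0.0,
            flash_probability=0.0,
            pixel_noise_sd=0.0,
            quantize=False,
            seed=0,
        )

    return make


@pytest.fixture
def quiet_config():
    """Small noise-free assay config for fast exact tests."""

    def make(**overrides) -> SyntheticConfig:
        defaults = dict(
            frame_height=40,
            frame_width=240,
            chambers=[
                ChamberROI("blank_a", 20.0, 20.0, 8.0),
                ChamberROI("std_1", 20.0, 60.0, 8.0),
                ChamberROI("std_10", 20.0, 100.0, 8.0),
                ChamberROI("std_100", 20.0, 140.0, 8.0),
                ChamberROI("std_1000", 20.0, 180.0, 8.0),
            ],
            standards={"blank_a": 0.0, "std_1": 1.0, "std_10": 10.0, "std_100": 100.0, "std_1000": 1000.0},
            duration_s=60.0,
            jitter_sd=0.0,
            flash_probability=0.0,
            pixel_noise_sd=0.0,
            quantize=False,
            seed=0,
        )
        defaults.update(overrides)
        return SyntheticConfig(**defaults)

    return make
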