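"""RGB -> XYZ -> CIELAB conversion and hue angle.

The conversion is applied directly to 8-bit pixel values scaled to [0, 1]:
no gamma (sRGB transfer-function) decoding is performed, because the
instrument's analysis chain treats the stored JPEG pixel values as the
signal.  Gamma decoding can be enabled per call for sensitivity checks.

The RGB->XYZ matrix is the linear-sRGB/D65 matrix; the CIELAB white point
is (Xn, Yn, Zn) = (0.9505, 1.0, 1.089), i.e. the row sums of that matrix,
so equal-RGB grays map exactly onto the achromatic axis (a* = b* = 0).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import DomainError, UndefinedHueError

__all__ = [
    "RGB_TO_XYZ_MATRIX",
    "WHITE_POINT",
    "LabColor",
    "rgb_to_xyz",
    "xyz_to_lab",
    "rgb_to_lab",
    "hue_angle",
]

#: Linear-sRGB to CIE XYZ matrix (D65 reference white).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

#: CIELAB reference white (Xn, Yn, Zn): the row sums of RGB_TO_XYZ_MATRIX.
WHITE_POINT = np.array([0.9505, 1.0, 1.089])

# CIE piecewise lightness function parameters.
_F_THRESHOLD = (24.0 / 116.0) ** 3  # ~0.008856
_F_SLOPE = 841.0 / 108.0
_F_OFFSET = 16.0 / 116.0


class LabColor(NamedTuple):
    """CIELAB coordinates plus hue angle in degrees ([0, 360), NaN if achromatic)."""

    L: float
    a: float
    b: float
    h: float


def _as_triples(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    if out.shape[-1:] != (3,):
        raise DomainError(f"{name} must have a trailing axis of length 3, got shape {out.shape}")
    return out


def rgb_to_xyz(rgb, *, gamma_decode: bool = False) -> np.ndarray:
    """Convert RGB in [0, 1] (shape ``(..., 3)``) to CIE XYZ tristimulus values.

    Parameters
    ----------
    rgb
        Pixel values divided by 255; each component must lie in [0, 1].
    gamma_decode
        If True, apply the sRGB electro-optical transfer function before the
        matrix.  Off by default: the analysis operates on stored pixel values.
    """
    rgb = _as_triples(rgb, "rgb")
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise DomainError("RGB components must lie in [0, 1]")
    if gamma_decode:
        rgb = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    return rgb @ RGB_TO_XYZ_MATRIX.T


def _f(t: np.ndarray) -> np.ndarray:
    """CIE piecewise cube-root function used by the L*, a*, b* formulas."""
    t = np.asarray(t, dtype=float)
    return np.where(t > _F_THRESHOLD, np.cbrt(np.maximum(t, 0.0)), _F_SLOPE * t + _F_OFFSET)


def xyz_to_lab(xyz) -> np.ndarray:
    """Convert XYZ (shape ``(..., 3)``, all components >= 0) to CIELAB.

    Returns an array of the same shape holding (L*, a*, b*).
    """
    xyz = _as_triples(xyz, "xyz")
    if np.any(xyz < 0):
        raise DomainError("XYZ components must be non-negative")
    fx, fy, fz = np.moveaxis(_f(xyz / WHITE_POINT), -1, 0)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def hue_angle(a, b):
    """Hue angle h = atan2(b*, a*) in degrees, mapped to [0, 360).

    Scalar inputs with a = b = 0 raise :class:`UndefinedHueError` (achromatic
    pixel); in array inputs such entries become NaN.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    achromatic = (a_arr == 0) & (b_arr == 0)
    if a_arr.ndim == 0 and b_arr.ndim == 0:
        if achromatic:
            raise UndefinedHueError("hue undefined for a* = b* = 0")
        return float(np.degrees(np.arctan2(b_arr, a_arr)) % 360.0)
    h = np.degrees(np.arctan2(b_arr, a_arr)) % 360.0
    return np.where(achromatic, np.nan, h)


def rgb_to_lab(rgb, *, gamma_decode: bool = False) -> LabColor:
    """Convenience: one RGB triple to :class:`LabColor` (with hue, NaN if gray)."""
    lab = xyz_to_lab(rgb_to_xyz(rgb, gamma_decode=gamma_decode))
    L, a, b = (float(v) for v in np.asarray(lab).reshape(3))
    h = np.nan if (a == 0 and b == 0) else hue_angle(a, b)
    return LabColor(L, a, b, h)
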