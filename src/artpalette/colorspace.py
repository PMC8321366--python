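"""Colour representations and conversions.

Images are interpreted as sRGB (D65 white point, 2° observer); the working
representation for all colourimetric analysis is CIELAB.  Two derived
coordinate systems are provided:

* polar CIELAB coordinates — chroma ``C*ab = sqrt(a*^2 + b*^2)`` and hue
  ``h_ab = atan2(b*, a*)`` in degrees, folded to [0, 360);
* the RG/BY opponent plane computed directly from sRGB values,
  ``RG = (R - G)/sqrt(2)`` and ``BY = (R + G - 2B)/sqrt(6)``, with colour
  angles ``theta = atan2(BY, RG)``.

The opponent transform is applied to non-linear sRGB values as given
(no linearization), matching its use in the efficient-coding analysis.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "AchromaticError",
    "srgb_to_lab",
    "lab_to_srgb",
    "lab_to_polar",
    "polar_to_ab",
    "rgb_to_opponent",
    "opponent_angle",
    "opponent_angles",
    "delta_e",
    "validate_rgb",
]

_SQRT2 = np.sqrt(2.0)
_SQRT6 = np.sqrt(6.0)


class AchromaticError(ValueError):
    """Raised when a colour direction is requested for an achromatic input."""


def validate_rgb(rgb: np.ndarray) -> np.ndarray:
    """Coerce to float64 and reject channel values outside [0, 1]."""
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of size 3, got shape {arr.shape}")
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError(
            f"RGB channels must lie in [0, 1]; got range "
            f"[{arr.min():.4g}, {arr.max():.4g}]"
        )
    return arr


def srgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB (channels in [0, 1]) to CIELAB under D65/2°.

    Accepts a single triplet, an (N, 3) list of colours or an (H, W, 3)
    image; the output has the same leading shape.
    """
    arr = validate_rgb(rgb)
    return _skcolor.rgb2lab(arr)


def lab_to_srgb(lab: np.ndarray, clip: bool = True) -> np.ndarray:
    """Convert CIELAB to sRGB.  Out-of-gamut values are clipped to [0, 1]."""
    arr = np.asarray(lab, dtype=np.float64)
    rgb = _skcolor.lab2rgb(arr)
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def lab_to_polar(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polar decomposition of CIELAB colours.

    Returns ``(chroma, hue_deg, achromatic)``.  Hue is measured
    counter-clockwise from +a* in degrees, folded to [0, 360).  Exactly
    achromatic colours (a* = b* = 0) get hue 0 by convention and are marked
    in the boolean ``achromatic`` mask so histograms stay well-defined.
    """
    arr = np.asarray(lab, dtype=np.float64)
    a, b = arr[..., 1], arr[..., 2]
    chroma = np.hypot(a, b)
    achromatic = chroma == 0.0
    hue = np.degrees(np.arctan2(b, a)) % 360.0
    hue = np.where(achromatic, 0.0, hue)
    return chroma, hue, achromatic


def polar_to_ab(chroma: np.ndarray, hue_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`lab_to_polar` for the (a*, b*) plane."""
    h = np.radians(np.asarray(hue_deg, dtype=np.float64))
    c = np.asarray(chroma, dtype=np.float64)
    return c * np.cos(h), c * np.sin(h)


def rgb_to_opponent(rgb: np.ndarray) -> np.ndarray:
    """Project sRGB triplets onto the (RG, BY) opponent plane.

    RG = (R - G)/sqrt(2), BY = (R + G - 2B)/sqrt(6).  Input shape (..., 3),
    output shape (..., 2).  Greys map exactly to the origin.
    """
    arr = validate_rgb(rgb)
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    rg = (r - g) / _SQRT2
    by = (r + g - 2.0 * b) / _SQRT6
    return np.stack([rg, by], axis=-1)


def opponent_angle(opponent: np.ndarray, fold: bool = False) -> float:
    """Colour angle theta = atan2(BY, RG) of a single opponent-plane point.

    Degrees; signed in (-180, 180] by default, or folded to [0, 360) with
    ``fold=True``.  Raises :class:`AchromaticError` at the origin, where no
    direction is defined.
    """
    rg, by = float(np.asarray(opponent)[0]), float(np.asarray(opponent)[1])
    if rg == 0.0 and by == 0.0:
        raise AchromaticError("achromatic: colour angle undefined at the opponent origin")
    theta = np.degrees(np.arctan2(by, rg))
    if fold:
        theta %= 360.0
    return float(theta)


def opponent_angles(opponent: np.ndarray, fold: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised colour angles; returns ``(angle_deg, achromatic_mask)``.

    Achromatic entries get angle 0 and are flagged rather than raising.
    """
    arr = np.asarray(opponent, dtype=np.float64)
    rg, by = arr[..., 0], arr[..., 1]
    achromatic = (rg == 0.0) & (by == 0.0)
    theta = np.degrees(np.arctan2(by, rg))
    if fold:
        theta = theta % 360.0
    return np.where(achromatic, 0.0, theta), achromatic


def delta_e(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """Euclidean CIELAB colour difference ΔE*ab (broadcasting)."""
    d = np.asarray(lab1, dtype=np.float64) - np.asarray(lab2, dtype=np.float64)
    return np.sqrt(np.sum(d * d, axis=-1))
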