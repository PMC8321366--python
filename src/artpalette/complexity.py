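"""PHOG-style image-complexity metrics.

Four descriptors computed from a pyramid of oriented-gradient histograms
(HOG) over recursive 2x2 spatial splits of the image:

self-similarity
    Histogram-intersection kernel between each level-3 sub-image histogram
    and the whole-image (level-0) histogram, aggregated by the median over
    the 64 sub-images.  1 means every part looks like the whole.
complexity
    Mean gradient-magnitude over the image, on the 0-255 intensity scale.
birkhoff
    The order/complexity ratio self_similarity / complexity.
anisotropy
    Variance of the pooled level-3 histogram bin values; low when gradient
    orientations are evenly used everywhere.

Gradients use a 3x3 Sobel operator per channel (normalised so a ramp of
slope s per pixel has gradient magnitude s); each pixel takes the channel
with the largest magnitude; orientations are folded to [0, 180) and
accumulated into 16 bins weighted by magnitude; histograms are
L1-normalised.  Each of these conventions is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "HOGPyramid",
    "ComplexityReport",
    "gradient_field",
    "hog_pyramid",
    "self_similarity",
    "complexity",
    "anisotropy",
    "birkhoff",
    "complexity_report",
]

# derivative-normalised Sobel: ramp of slope s -> gradient s
_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 8.0
_SOBEL_Y = _SOBEL_X.T


@dataclass
class HOGPyramid:
    """Orientation histograms per sub-image per pyramid level.

    ``levels[k]`` is a (4**k, bins) array: level 0 covers the whole image,
    level k splits it into a 2**k x 2**k grid (row-major order).  Histograms
    are L1-normalised; an all-zero row marks a gradient-free sub-image.
    """

    levels: list[np.ndarray]
    bins: int

    def zero_mask(self, level: int) -> np.ndarray:
        return self.levels[level].sum(axis=1) == 0.0


@dataclass(frozen=True)
class ComplexityReport:
    self_similarity: float
    complexity: float
    birkhoff: float  # NaN when complexity is 0
    anisotropy: float

    def to_row(self) -> dict:
        return {
            "Self-Similarity": self.self_similarity,
            "Complexity": self.complexity,
            "Anisotropy": self.anisotropy,
            "Birkhoff Metric": self.birkhoff,
        }


def gradient_field(rgb: np.ndarray, mode: str = "reflect") -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude (0-255 scale) and orientation in [0, 180).

    Sobel gradients are computed per channel; each pixel takes the channel
    whose magnitude is largest (first channel wins ties), and the
    orientation comes from that channel's (gx, gy).
    """
    img = np.asarray(rgb, dtype=np.float64) * 255.0
    if img.ndim == 2:
        img = img[..., None]
    gx = np.stack([convolve(img[..., k], _SOBEL_X, mode=mode) for k in range(img.shape[-1])], axis=-1)
    gy = np.stack([convolve(img[..., k], _SOBEL_Y, mode=mode) for k in range(img.shape[-1])], axis=-1)
    mag = np.hypot(gx, gy)
    best = np.argmax(mag, axis=-1)
    ii, jj = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    bx, by = gx[ii, jj, best], gy[ii, jj, best]
    magnitude = mag[ii, jj, best]
    orientation = np.degrees(np.arctan2(by, bx)) % 180.0
    return magnitude, orientation


def _block_bounds(n: int, parts: int) -> list[tuple[int, int]]:
    return [(i * n // parts, (i + 1) * n // parts) for i in range(parts)]


def hog_pyramid(
    rgb: np.ndarray, bins: int = 16, max_level: int = 3, mode: str = "reflect"
) -> HOGPyramid:
    """Magnitude-weighted orientation histograms over the spatial pyramid."""
    arr = np.asarray(rgb, dtype=np.float64)
    h, w = arr.shape[:2]
    parts = 2**max_level
    if h < 2 * parts or w < 2 * parts:
        raise ValueError(
            f"image {w}x{h} too small: level-{max_level} sub-images need >= 2x2 pixels"
        )
    magnitude, orientation = gradient_field(arr, mode=mode)
    bin_idx = np.minimum((orientation / 180.0 * bins).astype(np.int64), bins - 1)
    levels = []
    for k in range(max_level + 1):
        p = 2**k
        hists = np.zeros((p * p, bins))
        for bi, (r0, r1) in enumerate(_block_bounds(h, p)):
            for bj, (c0, c1) in enumerate(_block_bounds(w, p)):
                idx = bin_idx[r0:r1, c0:c1].ravel()
                wts = magnitude[r0:r1, c0:c1].ravel()
                hist = np.bincount(idx, weights=wts, minlength=bins)
                s = hist.sum()
                hists[bi * p + bj] = hist / s if s > 0 else hist
        levels.append(hists)
    return HOGPyramid(levels=levels, bins=bins)


def self_similarity(pyramid: HOGPyramid, aggregate: str = "median") -> float:
    """Median histogram-intersection kernel of level-3 histograms vs level 0.

    HIK(h, g) = sum_i min(h_i, g_i) is 1 for identical normalised
    histograms.  Returns NaN when the whole image is gradient-free.
    """
    if len(pyramid.levels) < 4:
        raise ValueError("pyramid must reach level 3")
    g0 = pyramid.levels[0][0]
    if g0.sum() == 0.0:
        return float("nan")
    hik = np.minimum(pyramid.levels[3], g0[None, :]).sum(axis=1)
    if aggregate == "median":
        return float(np.median(hik))
    if aggregate == "mean":
        return float(np.mean(hik))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def complexity(rgb: np.ndarray, mode: str = "reflect") -> float:
    """Mean gradient magnitude over the image, on the 0-255 scale."""
    magnitude, _ = gradient_field(rgb, mode=mode)
    return float(magnitude.mean())


def anisotropy(pyramid: HOGPyramid) -> float:
    """Variance of all level-3 histogram bin values pooled together."""
    if len(pyramid.levels) < 4:
        raise ValueError("pyramid must reach level 3")
    return float(np.var(pyramid.levels[3].ravel()))


def birkhoff(self_sim: float, cx: float) -> float:
    """Order/complexity ratio; NaN (flagged undefined) when complexity is 0."""
    if cx == 0.0:
        return float("nan")
    return self_sim / cx


def complexity_report(rgb: np.ndarray, bins: int = 16, mode: str = "reflect") -> ComplexityReport:
    pyr = hog_pyramid(rgb, bins=bins, mode=mode)
    ss = self_similarity(pyr)
    cx = complexity(rgb, mode=mode)
    return ComplexityReport(
        self_similarity=ss,
        complexity=cx,
        birkhoff=birkhoff(ss, cx),
        anisotropy=anisotropy(pyr),
    )
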