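"""Per-image colourimetric gamut descriptors.

For an image in CIELAB this module computes:

* the number of discernible colours (NDC): the count of occupied unit cells
  after binning colours on an integer grid — two colours whose difference is
  within one unit cell are treated as indiscernible.  The default grid is the
  3-D unit-cube binning of (L*, a*, b*); a 2-D (a*, b*) unit-square mode is
  also available;
* the colour volume: volume of the convex hull of the CIELAB point cloud
  (default), or the count of occupied unit cubes;
* the gamut ellipse: a direct least-squares (ellipse-constrained conic) fit
  to the (a*, b*) scatter, summarised by centre, semi-axes, area, axis ratio
  and the orientation of the longer axis measured from +a* in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "EllipseParams",
    "VolumeResult",
    "GamutSummary",
    "count_discernible_colors",
    "gamut_volume",
    "fit_gamut_ellipse",
    "summarize_gamut",
]


@dataclass(frozen=True)
class EllipseParams:
    """Geometric parameters of a fitted gamut ellipse in the (a*, b*) plane."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # orientation of the longer axis vs +a*, degrees in [0, 180)

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("requires semi_major >= semi_minor > 0")

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)

    @property
    def axis_ratio(self) -> float:
        return float(self.semi_minor / self.semi_major)


@dataclass(frozen=True)
class VolumeResult:
    volume: float
    degenerate: bool = False


@dataclass
class GamutSummary:
    """Descriptor bundle for one image (one row of a descriptor table)."""

    n_discernible: int
    volume: VolumeResult
    ellipse: EllipseParams | None
    ellipse_error: str | None
    mean_L: float
    mean_a: float
    mean_b: float

    def to_row(self) -> dict:
        """Flat dict with the descriptor table's column names."""
        e = self.ellipse
        return {
            "NDC": self.n_discernible,
            "L*": self.mean_L,
            "a*": self.mean_a,
            "b*": self.mean_b,
            "Angle": e.angle if e else float("nan"),
            "Ratio": e.axis_ratio if e else float("nan"),
            "Area": e.area if e else float("nan"),
            "Volume": self.volume.volume,
        }


def _as_points(lab: np.ndarray) -> np.ndarray:
    pts = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    if pts.size == 0:
        raise ValueError("empty image")
    return pts


def count_discernible_colors(lab, mode: str = "lab-3d") -> int:
    """Count occupied unit cells of the CIELAB binning grid.

    ``mode='lab-3d'`` bins (L*, a*, b*) into unit cubes; ``mode='ab-2d'``
    bins only (a*, b*) into unit squares.  Cell index is the floor of each
    coordinate (half-open cells; boundary colours belong to the lower cell).
    """
    pts = _as_points(lab)
    if mode == "lab-3d":
        cells = np.floor(pts).astype(np.int64)
    elif mode == "ab-2d":
        cells = np.floor(pts[:, 1:]).astype(np.int64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(np.unique(cells, axis=0).shape[0])


def gamut_volume(lab, mode: str = "hull") -> VolumeResult:
    """Volume of the colour cloud in CIELAB cubic units.

    ``mode='hull'`` (default) returns the convex-hull volume; a degenerate
    (coplanar/collinear/constant) cloud yields volume 0 with the degeneracy
    flag set.  ``mode='cells'`` counts occupied unit cubes instead.
    """
    pts = _as_points(lab)
    if mode == "cells":
        return VolumeResult(float(count_discernible_colors(pts, mode="lab-3d")))
    if mode != "hull":
        raise ValueError(f"unknown mode {mode!r}")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 4:
        return VolumeResult(0.0, degenerate=True)
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        return VolumeResult(0.0, degenerate=True)
    return VolumeResult(float(hull.volume))


def _fit_conic_halir_flusser(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Ellipse-constrained direct least-squares conic fit.

    Numerically stable partitioned formulation: minimise the algebraic
    residual subject to 4ac - b^2 = 1, which guarantees an ellipse.
    Returns conic coefficients (a, b, c, d, e, f).
    """
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    # premultiply by inv(C1), C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    eigval, eigvec = np.linalg.eig(M)
    # the ellipse solution satisfies 4ac - b^2 > 0
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    idx = np.where(cond > 0)[0]
    if idx.size == 0:
        raise ValueError("degenerate conic: no ellipse solution")
    a1 = np.real(eigvec[:, idx[0]])
    return np.concatenate([a1, T @ a1])


def _conic_to_ellipse(coef: np.ndarray) -> EllipseParams:
    a, b, c, d, e, f = coef
    A = np.array([[a, b / 2.0], [b / 2.0, c]])
    try:
        center = np.linalg.solve(A, -np.array([d / 2.0, e / 2.0]))
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate conic: singular quadratic form") from exc
    # conic value at the centre; ellipse is (p-c)^T A (p-c) = -f_c
    f_c = float(np.array([d / 2.0, e / 2.0]) @ center + f)
    lam, vec = np.linalg.eigh(A)
    if not np.all(lam * (-f_c) > 0):
        raise ValueError("degenerate conic: not an ellipse")
    axes = np.sqrt(-f_c / lam)  # semi-axis along each eigenvector
    order = np.argsort(axes)[::-1]
    semi_major, semi_minor = float(axes[order[0]]), float(axes[order[1]])
    major_vec = vec[:, order[0]]
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0)
    return EllipseParams(
        center=(float(center[0]), float(center[1])),
        semi_major=semi_major,
        semi_minor=semi_minor,
        angle=angle,
    )


def fit_gamut_ellipse(lab_or_ab) -> EllipseParams:
    """Fit an ellipse to the (a*, b*) scatter of an image or point list.

    Accepts an (..., 3) CIELAB array (the a*/b* columns are used) or an
    (N, 2) array of (a*, b*) points.  Requires at least 5 distinct points;
    raises ``ValueError`` for degenerate inputs.
    """
    arr = np.asarray(lab_or_ab, dtype=np.float64)
    if arr.shape[-1] == 3:
        pts = arr.reshape(-1, 3)[:, 1:]
    elif arr.shape[-1] == 2:
        pts = arr.reshape(-1, 2)
    else:
        raise ValueError("expected (..., 3) CIELAB or (N, 2) a*b* points")
    uniq = np.unique(pts, axis=0)
    if uniq.shape[0] < 5:
        raise ValueError("ellipse fit needs at least 5 distinct (a*, b*) points")
    # centre/scale for conditioning; an isotropic scale preserves the angle
    mu = pts.mean(axis=0)
    scale = float(np.mean(pts.std(axis=0)))
    if scale == 0.0:
        raise ValueError("degenerate point cloud for ellipse fit")
    q = (pts - mu) / scale
    coef = _fit_conic_halir_flusser(q[:, 0], q[:, 1])
    ell = _conic_to_ellipse(coef)
    return EllipseParams(
        center=(ell.center[0] * scale + mu[0], ell.center[1] * scale + mu[1]),
        semi_major=ell.semi_major * scale,
        semi_minor=ell.semi_minor * scale,
        angle=ell.angle,
    )


def summarize_gamut(lab, ndc_mode: str = "lab-3d", volume_mode: str = "hull") -> GamutSummary:
    """Assemble the full descriptor bundle for one image."""
    pts = _as_points(lab)
    try:
        ellipse: EllipseParams | None = fit_gamut_ellipse(pts)
        ellipse_error = None
    except ValueError as exc:
        ellipse = None
        ellipse_error = f"degenerate: {exc}"
    means = pts.mean(axis=0)
    return GamutSummary(
        n_discernible=count_discernible_colors(pts, mode=ndc_mode),
        volume=gamut_volume(pts, mode=volume_mode),
        ellipse=ellipse,
        ellipse_error=ellipse_error,
        mean_L=float(means[0]),
        mean_a=float(means[1]),
        mean_b=float(means[2]),
    )
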