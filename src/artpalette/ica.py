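"""Efficient-coding analysis: ICA of image patches and preferred colour directions.

The pipeline mirrors the classic natural-image-statistics recipe: sample
p x p x 3 patches at random locations, centre and whiten them (eigendecomposition
of the sample covariance, with the dewhitening map retained so learned bases can
be expressed in pixel space), run fixed-point ICA on the whitened vectors, and
read each mixing-matrix column as one basis function.  Bases are ordered by
energy (L2 norm before normalisation) and unit-normalised.

Each basis gets a *preferred colour direction*: its p^2 pixels are treated as
points in RGB space, the first principal component of that cloud is projected
onto the (RG, BY) opponent plane, and the resulting angle is folded to
[0, 180) — a principal axis has no sign.  Bases whose principal axis is
(near-)achromatic carry no direction and are flagged instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .colorspace import _SQRT2, _SQRT6

__all__ = [
    "PatchSet",
    "WhitenedData",
    "ICABasis",
    "ICAResult",
    "DirectionHistogram",
    "ICAConvergenceError",
    "sample_patches",
    "whiten",
    "fit_ica",
    "order_and_normalize",
    "basis_color_direction",
    "direction_histogram",
]


class ICAConvergenceError(RuntimeError):
    pass


@dataclass
class PatchSet:
    """Flattened p x p x 3 patches, one row per patch (length 3 p^2).

    Row layout: pixel-major, channel-minor (``patch.reshape(-1)`` of an
    (p, p, 3) array), so ``vectors[i].reshape(p, p, 3)`` restores the patch.
    """

    vectors: np.ndarray  # (n, 3 p^2)
    p: int
    sources: list = field(default_factory=list)  # (image_idx, row, col) per patch

    @property
    def n(self) -> int:
        return int(self.vectors.shape[0])


@dataclass
class WhitenedData:
    vectors: np.ndarray  # (n, d) decorrelated, unit-variance components
    mean: np.ndarray  # (D,) removed before whitening
    whitening: np.ndarray  # (d, D): z = whitening @ (x - mean)
    dewhitening: np.ndarray  # (D, d): x - mean ~= dewhitening @ z


@dataclass
class ICABasis:
    vector: np.ndarray  # pixel-space basis function, length 3 p^2
    energy: float  # L2 norm before normalisation
    p: int
    rank: int | None = None  # 1-based position in decreasing-energy order

    def patch(self) -> np.ndarray:
        return self.vector.reshape(self.p, self.p, 3)


@dataclass
class ICAResult:
    bases: list[ICABasis]
    converged: bool
    n_iter: int
    max_kurtosis: float = float("nan")  # max |excess kurtosis| across sources

    @property
    def reliable(self) -> bool:
        """False when no source is detectably non-Gaussian (ICA is then
        non-identifiable: any rotation of the whitened data fits equally)
        or when the fixed-point iteration did not converge."""
        return self.converged and self.max_kurtosis >= 0.3


def sample_patches(
    images: list[np.ndarray], n_per_image: int, p: int = 8, seed: int | None = None
) -> PatchSet:
    """Uniformly random, fully interior, possibly overlapping patches.

    Images smaller than p x p are skipped with a warning.  Deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    vectors, sources = [], []
    for idx, img in enumerate(images):
        arr = np.asarray(img, dtype=np.float64)
        h, w = arr.shape[:2]
        if h < p or w < p:
            warnings.warn(f"image {idx} ({w}x{h}) smaller than patch {p}x{p}; skipped")
            continue
        rows = rng.integers(0, h - p + 1, size=n_per_image)
        cols = rng.integers(0, w - p + 1, size=n_per_image)
        for r, c in zip(rows, cols):
            vectors.append(arr[r : r + p, c : c + p].reshape(-1))
            sources.append((idx, int(r), int(c)))
    if not vectors:
        raise ValueError("no patches sampled")
    return PatchSet(vectors=np.array(vectors), p=p, sources=sources)


def whiten(
    patches: PatchSet, n_components: int | None = None, rank_tol: float = 1e-10
) -> WhitenedData:
    """Centre and decorrelate patch vectors to identity covariance.

    Eigendecomposition of the sample covariance (ddof=0); eigenvalues below
    ``rank_tol`` times the largest are dropped (rank-deficient data reduce
    to their numerical rank, with a warning).  ``n_components`` caps the
    retained dimension at the strongest components.
    """
    X = patches.vectors
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more patches ({X.shape[0]}) than dimensions ({X.shape[1]})"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    C = Xc.T @ Xc / X.shape[0]
    w, U = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    if w[0] <= 0.0:
        raise ValueError("zero-variance data: covariance has no positive eigenvalues")
    keep = w > rank_tol * w[0]
    if not np.all(keep):
        warnings.warn(
            f"rank-deficient covariance: reducing dimension to {int(keep.sum())}"
        )
    w, U = w[keep], U[:, keep]
    if n_components is not None:
        w, U = w[:n_components], U[:, :n_components]
    whitening = (U / np.sqrt(w)).T
    dewhitening = U * np.sqrt(w)
    return WhitenedData(
        vectors=Xc @ whitening.T, mean=mean, whitening=whitening, dewhitening=dewhitening
    )


def fit_ica(
    data: WhitenedData,
    n_components: int | None = None,
    seed: int | None = None,
    fun: str = "cube",
    max_iter: int = 400,
    tol: float = 1e-5,
    p: int = 8,
    strict: bool = False,
) -> ICAResult:
    """Fixed-point ICA (symmetric decorrelation) on whitened vectors.

    The cubic nonlinearity is the default; ``fun='logcosh'`` selects tanh.
    ``n_components`` defaults to the whitened dimension (reduce at the
    whitening stage to learn fewer components).  Mixing columns are mapped
    back through the dewhitening matrix, so each basis lives in pixel space.
    Non-convergence sets ``converged=False`` (or raises with ``strict=True``).
    """
    d = data.vectors.shape[1]
    if n_components is None:
        n_components = d
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds whitened dimension {d}")
    if n_components < d:
        # FastICA with whiten=False is square; shrink the space first
        raise ValueError(
            "reduce dimensionality in whiten(n_components=...) to learn fewer components"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        whiten=False,
        fun=fun,
        max_iter=max_iter,
        tol=tol,
        random_state=np.random.RandomState(seed),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(data.vectors)
        if any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = False
    if not converged and strict:
        raise ICAConvergenceError(
            f"FastICA did not converge within {max_iter} iterations (tol={tol})"
        )
    A_white = np.linalg.pinv(ica.components_)  # (d, m) mixing in whitened space
    A_pixel = data.dewhitening @ A_white  # (D, m)
    bases = [
        ICABasis(vector=A_pixel[:, j].copy(), energy=float(np.linalg.norm(A_pixel[:, j])), p=p)
        for j in range(A_pixel.shape[1])
    ]
    S = ica.transform(data.vectors)
    Sn = (S - S.mean(axis=0)) / S.std(axis=0)
    kurt = float(np.max(np.abs((Sn**4).mean(axis=0) - 3.0)))
    return ICAResult(bases=bases, converged=converged, n_iter=int(ica.n_iter_), max_kurtosis=kurt)


def order_and_normalize(bases: list[ICABasis]) -> list[ICABasis]:
    """Sort by decreasing energy (stable), unit-normalise, assign ranks."""
    ordered = sorted(
        range(len(bases)), key=lambda i: -bases[i].energy
    )  # Python sort is stable: equal energies keep original order
    out = []
    for rank, i in enumerate(ordered, start=1):
        b = bases[i]
        norm = np.linalg.norm(b.vector)
        vec = b.vector / norm if norm > 0 else b.vector
        out.append(ICABasis(vector=vec, energy=b.energy, p=b.p, rank=rank))
    return out


def basis_color_direction(
    basis: ICABasis, achromatic_tol: float = 0.05
) -> float | None:
    """Preferred colour direction of one basis, in degrees folded to [0, 180).

    The basis patch is read as p^2 points in RGB space; the first principal
    component of that cloud is the dominant colour-variation axis.  Its
    projection onto (RG, BY) gives the direction; when the projection norm
    falls below ``achromatic_tol`` (relative to the unit axis) the basis is
    achromatic — no chromatic direction — and None is returned.
    """
    pts = basis.patch().reshape(-1, 3)
    pts = pts - pts.mean(axis=0)
    if not np.any(pts):
        return None
    # first right singular vector = first principal axis
    _, s, Vt = np.linalg.svd(pts, full_matrices=False)
    if s[0] == 0.0:
        return None
    v = Vt[0]
    rg = (v[0] - v[1]) / _SQRT2
    by = (v[0] + v[1] - 2.0 * v[2]) / _SQRT6
    if np.hypot(rg, by) < achromatic_tol:
        return None
    return float(np.degrees(np.arctan2(by, rg)) % 180.0)


@dataclass
class DirectionHistogram:
    bin_edges: np.ndarray  # degrees
    counts: np.ndarray
    folded: bool
    n_achromatic: int  # flagged entries excluded from the counts


def direction_histogram(
    angles: list[float | None], bin_width: float = 10.0, folded: bool = True
) -> DirectionHistogram:
    """Histogram colour-direction angles; None entries (achromatic) are
    excluded from the counts and reported separately.

    Folded histograms cover [0, 180) (axis-valued basis directions);
    unfolded ones cover [0, 360) (vector-valued relevant-colour angles).
    """
    top = 180.0 if folded else 360.0
    edges = np.arange(0.0, top + bin_width, bin_width)
    vals = np.array([a for a in angles if a is not None], dtype=np.float64) % top
    counts, _ = np.histogram(vals, bins=edges)
    return DirectionHistogram(
        bin_edges=edges,
        counts=counts,
        folded=folded,
        n_achromatic=sum(1 for a in angles if a is None),
    )
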