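"""Relevant-colour palettes: subjective (observer clicks) and computational.

Two routes lead to a palette of "relevant colours" — the handful of colours
an observer would say make up a painting:

* **subjective** — each observer click is averaged over the 25 pixels of a
  centred 5x5 window, and each selection counts as one relevant colour
  (optionally, near-duplicates can be merged by single-linkage clustering);
* **computational** — a reconstruction of the density-ranked greedy
  algorithm: histogram the image into CIELAB unit cells, rank cells by
  pixel count, and accept a cell's mean colour when it passes lightness,
  chroma and density gates and sits at least ``delta_e_min`` away from every
  colour accepted so far.  The large-ΔE maximin step is what keeps the
  palette small; the L*/chroma gates drop near-black/near-white and
  near-achromatic candidates.

Descriptive statistics (hue/chroma tables) and the overlap between a
computational and a subjective palette complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .colorspace import delta_e, lab_to_polar, lab_to_srgb

__all__ = [
    "Selection",
    "Palette",
    "PaletteConfig",
    "OverlapReport",
    "aggregate_click",
    "extract_relevant_colors",
    "subjective_palette",
    "hue_chroma_table",
    "palette_overlap",
]

WINDOW = 5  # click windows are centred 5x5 squares (25 pixels)


@dataclass(frozen=True)
class Selection:
    """One observer click: pixel coordinates plus the 5x5 window mean colour."""

    x: int  # column
    y: int  # row
    color: np.ndarray  # CIELAB mean of the 25-pixel window


@dataclass
class Palette:
    """An ordered set of relevant colours with provenance.

    ``colors`` is an (N, 3) CIELAB array; ``sources`` records, per entry,
    the pixel location(s) it came from (may be empty for derived palettes).
    """

    colors: np.ndarray
    provenance: str  # "computational" | "subjective"
    sources: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.colors = np.atleast_2d(np.asarray(self.colors, dtype=np.float64))
        if self.colors.shape[0] < 1 or self.colors.shape[1] != 3:
            raise ValueError("palette needs at least one (L*, a*, b*) colour")
        if self.provenance not in ("computational", "subjective", "truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def size(self) -> int:
        return int(self.colors.shape[0])

    def to_dict(self) -> dict:
        rgb = lab_to_srgb(self.colors)
        hexes = [
            "#%02x%02x%02x" % tuple(int(round(255 * v)) for v in row) for row in rgb
        ]
        return {
            "provenance": self.provenance,
            "colors_lab": self.colors.tolist(),
            "colors_hex": hexes,
            "sources": [list(map(int, np.ravel(s))) if s is not None else None for s in self.sources]
            if self.sources
            else [],
        }


@dataclass(frozen=True)
class PaletteConfig:
    """Gates for the computational relevant-colour extraction.

    delta_e_min : minimum CIELAB ΔE*ab between accepted palette entries
                  (must exceed the 1-unit discernibility cell).
    L_range     : admissible lightness interval [L_low, L_high].
    chroma_min  : minimum C*ab; near-greys are never "relevant colours".
    density_min : minimum fraction of image pixels a candidate cell must hold.
    """

    delta_e_min: float = 15.0
    L_range: tuple[float, float] = (5.0, 95.0)
    chroma_min: float = 5.0
    density_min: float = 0.001

    def __post_init__(self) -> None:
        if not self.delta_e_min > 1.0:
            raise ValueError("delta_e_min must exceed the 1-unit discernibility cell")
        if not (0.0 <= self.density_min < 1.0):
            raise ValueError("density_min must lie in [0, 1)")
        if not self.L_range[0] < self.L_range[1]:
            raise ValueError("L_range must be increasing")


def aggregate_click(lab_image: np.ndarray, x: int, y: int) -> Selection:
    """Average the centred 5x5 window around a click into one Selection.

    ``x`` is the column, ``y`` the row.  The window must lie fully inside
    the image: observers click areas, not edges — re-click otherwise.
    """
    img = np.asarray(lab_image, dtype=np.float64)
    h, w = img.shape[:2]
    r = WINDOW // 2
    if not (r <= x < w - r and r <= y < h - r):
        raise ValueError(
            f"click ({x}, {y}): 5x5 window crosses the image border "
            f"({w}x{h}); re-click inside the area"
        )
    window = img[y - r : y + r + 1, x - r : x + r + 1]
    return Selection(x=int(x), y=int(y), color=window.reshape(-1, 3).mean(axis=0))


def _cell_table(lab_pixels: np.ndarray):
    """Group pixels by CIELAB unit cell; return (cells, counts, means)."""
    cells = np.floor(lab_pixels).astype(np.int64)
    uniq, inverse, counts = np.unique(cells, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((uniq.shape[0], 3))
    np.add.at(sums, inverse, lab_pixels)
    return uniq, counts, sums / counts[:, None]


def extract_relevant_colors(lab_image: np.ndarray, config: PaletteConfig | None = None) -> Palette:
    """Computational relevant-colour extraction (density-ranked greedy maximin).

    Deterministic for a given image and config: cells are scanned in
    decreasing pixel count, ties broken by lexicographic (L, a, b) cell
    index; a cell's mean colour is accepted when it passes the L*/chroma/
    density gates and is >= ``delta_e_min`` from every accepted colour.
    """
    if config is None:
        config = PaletteConfig()
    pixels = np.asarray(lab_image, dtype=np.float64).reshape(-1, 3)
    if pixels.size == 0:
        raise ValueError("empty image")
    cells, counts, means = _cell_table(pixels)
    # sort: count descending, then lexicographic cell index for ties
    order = np.lexsort((cells[:, 2], cells[:, 1], cells[:, 0], -counts))
    n = pixels.shape[0]
    lo, hi = config.L_range
    # a candidate "represents" the pixels within half the palette spacing of
    # its mean colour; per-pixel noise spreads a paint colour over many unit
    # cells, so the cell's own count understates its support
    radius = config.delta_e_min / 2.0
    accepted: list[np.ndarray] = []
    accepted_cells: list[np.ndarray] = []
    for i in order:
        c = means[i]
        chroma = float(np.hypot(c[1], c[2]))
        if not (lo <= c[0] <= hi) or chroma < config.chroma_min:
            continue
        if accepted and float(np.min(delta_e(np.array(accepted), c))) < config.delta_e_min:
            continue
        if config.density_min > 0:
            support = float(np.mean(delta_e(pixels, c) <= radius))
            if support < config.density_min:
                continue
        accepted.append(c)
        accepted_cells.append(cells[i])
    if not accepted:
        raise ValueError("no relevant colours under this configuration")
    return Palette(
        colors=np.array(accepted),
        provenance="computational",
        sources=[tuple(map(int, c)) for c in accepted_cells],
    )


def subjective_palette(selections: list[Selection], merge_delta_e: float | None = None) -> Palette:
    """Aggregate observer selections into a subjective palette.

    By default every selection stays a distinct palette entry — observers
    were free to pick similar colours at different locations, and each pick
    counts.  With ``merge_delta_e`` set, entries closer than that ΔE are
    merged by single-linkage clustering, each cluster replaced by its mean.
    """
    if not selections:
        raise ValueError("no selections")
    colors = np.array([s.color for s in selections], dtype=np.float64)
    sources: list = [(s.x, s.y) for s in selections]
    if merge_delta_e is not None and colors.shape[0] > 1:
        Z = linkage(colors, method="single", metric="euclidean")
        labels = fcluster(Z, t=merge_delta_e, criterion="distance")
        merged, merged_sources = [], []
        for lab in np.unique(labels):
            mask = labels == lab
            merged.append(colors[mask].mean(axis=0))
            merged_sources.append([sources[j] for j in np.where(mask)[0]])
        colors, sources = np.array(merged), merged_sources
    return Palette(colors=colors, provenance="subjective", sources=sources)


def hue_chroma_table(
    palette_or_image, hue_bin: float = 10.0, chroma_bin: float = 1.0
) -> dict:
    """Polar decomposition plus binned hue/chroma histograms.

    Accepts a :class:`Palette` or any (..., 3) CIELAB array.  Returns a dict
    with per-colour ``(hue, chroma)`` pairs and histogram counts over 10°
    hue bins on [0, 360) and unit chroma bins by default.
    """
    if isinstance(palette_or_image, Palette):
        lab = palette_or_image.colors
    else:
        lab = np.asarray(palette_or_image, dtype=np.float64).reshape(-1, 3)
    chroma, hue, achromatic = lab_to_polar(lab)
    hue_edges = np.arange(0.0, 360.0 + hue_bin, hue_bin)
    cmax = max(float(chroma.max()), chroma_bin) if chroma.size else chroma_bin
    chroma_edges = np.arange(0.0, np.ceil(cmax / chroma_bin) * chroma_bin + chroma_bin, chroma_bin)
    return {
        "hue": hue,
        "chroma": chroma,
        "achromatic": achromatic,
        "pairs": list(zip(hue.tolist(), chroma.tolist())),
        "hue_edges": hue_edges,
        "hue_counts": np.histogram(hue, bins=hue_edges)[0],
        "chroma_edges": chroma_edges,
        "chroma_counts": np.histogram(chroma, bins=chroma_edges)[0],
    }


@dataclass(frozen=True)
class OverlapReport:
    """Agreement between a computational and a subjective palette."""

    subjective_covered: float  # fraction of subjective colours within tol of a computational one
    computational_covered: float  # symmetric counterpart
    hull_iou: float | None  # (a*, b*) convex-hull intersection / union, if defined


def _hull_polygon(ab: np.ndarray):
    from shapely.geometry import MultiPoint

    hull = MultiPoint([tuple(p) for p in ab]).convex_hull
    return hull if hull.area > 0 else None


def palette_overlap(computational: Palette, subjective: Palette, tol: float = 10.0) -> OverlapReport:
    """Fraction of each palette covered by the other within ``tol`` ΔE*ab,
    plus the intersection-over-union of the two (a*, b*) convex hulls.

    The hull measure is unavailable (None) when either palette has fewer
    than 3 distinct chromaticities.
    """
    d = cdist(subjective.colors, computational.colors)
    subj_cov = float(np.mean(d.min(axis=1) <= tol))
    comp_cov = float(np.mean(d.min(axis=0) <= tol))
    hull_iou = None
    pa = _hull_polygon(computational.colors[:, 1:])
    pb = _hull_polygon(subjective.colors[:, 1:])
    if pa is not None and pb is not None:
        union = pa.union(pb).area
        if union > 0:
            hull_iou = float(pa.intersection(pb).area / union)
    return OverlapReport(subj_cov, comp_cov, hull_iou)
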