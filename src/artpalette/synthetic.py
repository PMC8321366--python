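"""Synthetic paintings, simulated observers and planted-direction patch sets.

These generators emulate the statistical structure the analysis pipeline
assumes, so every stage can be exercised against a known ground truth:

* :func:`generate_painting` — a canvas partitioned into Voronoi regions,
  each filled with one of K well-separated CIELAB colours, plus optional
  per-pixel CIELAB noise and a low-frequency lightness shading field.  The
  truth palette, the per-pixel region->colour map and all parameters are
  retained.  Irregular Voronoi boundaries (rather than rectangles) make
  nearest-colour segmentation work on painting-like region shapes.
* :func:`simulate_observer` — clicks once inside a region of each truth
  colour (with configurable probability, spatial jitter, and a chroma-bias
  exponent that favours colourful regions, mimicking how human observers
  rarely pick near-greys).  Every click's 5x5 window is guaranteed to lie
  inside a single region.
* :func:`generate_opponent_patches` — patch sets whose chromatic content
  varies along a planted axis of the (RG, BY) opponent plane, mixed with
  achromatic-gradient distractor sources, for end-to-end ICA direction
  recovery tests.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .colorspace import delta_e, lab_to_srgb, srgb_to_lab
from .palette import Palette, Selection, aggregate_click

__all__ = [
    "PaintingParams",
    "SyntheticPainting",
    "ObserverPolicy",
    "generate_painting",
    "simulate_observer",
    "generate_opponent_patches",
    "opponent_axis_rgb",
]

_SQRT2 = np.sqrt(2.0)
_SQRT6 = np.sqrt(6.0)


@dataclass(frozen=True)
class PaintingParams:
    """Generator settings; defaults mirror the regime the analysis targets
    (palettes of ~21 colours, mild per-pixel noise and shading)."""

    K: int = 21
    delta_e_sep: float = 30.0
    noise_sigma: float = 3.0
    n_regions: int = 64
    shading_amplitude: float = 5.0
    width: int = 128
    height: int = 128
    seed: int = 0
    # admissibility gates for sampled palette colours: keep them well inside
    # the sRGB gamut, away from black/white, and clearly chromatic
    L_range: tuple[float, float] = (20.0, 85.0)
    chroma_range: tuple[float, float] = (12.0, 80.0)
    min_color_frac: float = 0.005  # every colour's minimum pixel share


@dataclass
class SyntheticPainting:
    rgb: np.ndarray  # (H, W, 3) sRGB in [0, 1]
    lab: np.ndarray  # the noisy CIELAB field the rgb was rendered from
    truth_palette: Palette  # K generator colours (provenance "truth")
    region_map: np.ndarray  # (H, W) truth-colour index per pixel
    params: PaintingParams
    clip_fraction: float = 0.0  # pixels altered by sRGB gamut clipping


def _sample_truth_colors(params: PaintingParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample K CIELAB colours, pairwise >= delta_e_sep apart."""
    accepted: list[np.ndarray] = []
    lo, hi = params.L_range
    cmin, cmax = params.chroma_range
    for _ in range(40):  # batches of candidates
        if len(accepted) == params.K:
            break
        rgb = rng.uniform(0.0, 1.0, size=(512, 3))
        lab = srgb_to_lab(rgb)
        chroma = np.hypot(lab[:, 1], lab[:, 2])
        # require headroom inside the gamut so noise rarely clips
        ok = (
            (lab[:, 0] >= lo)
            & (lab[:, 0] <= hi)
            & (chroma >= cmin)
            & (chroma <= cmax)
            & np.all(rgb >= 0.02, axis=1)
            & np.all(rgb <= 0.98, axis=1)
        )
        for cand in lab[ok]:
            if len(accepted) == params.K:
                break
            if accepted and float(np.min(delta_e(np.array(accepted), cand))) < params.delta_e_sep:
                continue
            accepted.append(cand)
    if len(accepted) < params.K:
        raise ValueError(
            f"could not place K={params.K} colours at separation "
            f">= {params.delta_e_sep} ΔE inside the sRGB gamut"
        )
    return np.array(accepted)


def _voronoi_region_map(
    h: int, w: int, n_regions: int, rng: np.random.Generator
) -> np.ndarray:
    sites = np.column_stack(
        [rng.uniform(0, h, size=n_regions), rng.uniform(0, w, size=n_regions)]
    )
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    d2 = ((pix[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).reshape(h, w)


def _assign_colors(n_regions: int, K: int, rng: np.random.Generator) -> np.ndarray:
    assign = np.concatenate(
        [np.arange(K), rng.integers(0, K, size=max(0, n_regions - K))]
    )
    rng.shuffle(assign)
    return assign


def _balance_colors(
    region_map: np.ndarray, assign: np.ndarray, K: int, floor: int
) -> np.ndarray:
    """Reassign regions until every colour holds at least ``floor`` pixels."""
    region_sizes = np.bincount(region_map.ravel(), minlength=assign.size)
    for _ in range(4 * K):
        shares = np.bincount(assign, weights=region_sizes, minlength=K)
        starving = int(np.argmin(shares))
        if shares[starving] >= floor:
            break
        # donate the largest region of the best-endowed multi-region colour
        donors = [
            r
            for r in np.argsort(region_sizes)[::-1]
            if np.sum(assign == assign[r]) > 1 and assign[r] != starving
        ]
        if not donors:
            break
        assign[donors[0]] = starving
    return assign


def generate_painting(params: PaintingParams | None = None, **overrides) -> SyntheticPainting:
    """Generate one palette-structured synthetic painting.

    Deterministic per seed.  The generator retries the spatial layout (with
    sub-seeds derived from the main seed) until every colour holds at least
    ``min_color_frac`` of the canvas and owns a region with a 5x5-erodible
    interior, so downstream density gates and click windows are feasible.
    """
    if params is None:
        params = PaintingParams(**overrides)
    elif overrides:
        raise ValueError("pass either params or keyword overrides, not both")
    if params.K < 1 or params.delta_e_sep <= 0:
        raise ValueError("need K >= 1 and delta_e_sep > 0")
    n_regions = max(params.n_regions, params.K)
    rng = np.random.default_rng(params.seed)
    truth = _sample_truth_colors(params, rng)
    h, w = params.height, params.width
    floor = int(np.ceil(params.min_color_frac * h * w))
    struct = np.ones((5, 5), dtype=bool)
    color_map = None
    for attempt in range(20):
        layout_rng = np.random.default_rng((params.seed, 1, attempt))
        region_map = _voronoi_region_map(h, w, n_regions, layout_rng)
        assign = _assign_colors(n_regions, params.K, layout_rng)
        assign = _balance_colors(region_map, assign, params.K, floor)
        cmap = assign[region_map]
        shares = np.bincount(cmap.ravel(), minlength=params.K)
        if shares.min() < floor:
            continue
        eroded_ok = all(
            binary_erosion(cmap == k, structure=struct, border_value=0).any()
            for k in range(params.K)
        )
        if eroded_ok:
            color_map = cmap
            break
    if color_map is None:
        raise ValueError("could not lay out regions satisfying the area constraints")

    lab = truth[color_map].astype(np.float64)
    noise_rng = np.random.default_rng((params.seed, 2))
    if params.noise_sigma > 0:
        lab = lab + noise_rng.normal(0.0, params.noise_sigma, size=lab.shape)
    if params.shading_amplitude > 0:
        theta = noise_rng.uniform(0, 2 * np.pi)
        phase = noise_rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
        lab[..., 0] = lab[..., 0] + params.shading_amplitude * np.sin(
            2 * np.pi * u + phase
        )
    rgb = lab_to_srgb(lab)
    clip_fraction = float(np.mean(np.any(np.abs(srgb_to_lab(rgb) - lab) > 0.5, axis=-1)))
    truth_palette = Palette(colors=truth, provenance="truth")
    assert float(np.min(_pairwise_min_delta_e(truth))) >= params.delta_e_sep
    return SyntheticPainting(
        rgb=rgb,
        lab=lab,
        truth_palette=truth_palette,
        region_map=color_map,
        params=params,
        clip_fraction=clip_fraction,
    )


def _pairwise_min_delta_e(colors: np.ndarray) -> np.ndarray:
    d = np.sqrt(((colors[:, None, :] - colors[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) if colors.shape[0] > 1 else np.array([np.inf])


@dataclass(frozen=True)
class ObserverPolicy:
    """Click behaviour of the simulated observer.

    p_click      : probability of clicking each truth colour at all.
    jitter       : if True, the click position is drawn uniformly from the
                   admissible interior of the colour's regions; if False,
                   the first admissible pixel (row-major) is used.
    chroma_bias  : exponent >= 0; the per-colour click probability is scaled
                   by (chroma / max chroma) ** chroma_bias, so strong bias
                   suppresses low-chroma selections.
    """

    p_click: float = 1.0
    jitter: bool = True
    chroma_bias: float = 0.0


def simulate_observer(
    painting: SyntheticPainting,
    policy: ObserverPolicy | None = None,
    seed: int | None = None,
) -> list[Selection]:
    """Simulate one observer's clicks on a synthetic painting.

    For each truth colour, with the policy's probability, one click is
    placed at a pixel whose whole 5x5 window lies inside that colour's
    regions.  Colours whose regions are too small for a window are skipped
    with a warning.  Returns Selections built from the painting's sRGB
    image (converted to CIELAB), exactly as real clicks would be processed.
    """
    if policy is None:
        policy = ObserverPolicy()
    rng = np.random.default_rng(seed)
    lab_img = srgb_to_lab(painting.rgb)
    truth = painting.truth_palette.colors
    chroma = np.hypot(truth[:, 1], truth[:, 2])
    cmax = float(chroma.max()) if chroma.max() > 0 else 1.0
    struct = np.ones((5, 5), dtype=bool)
    selections: list[Selection] = []
    for k in range(truth.shape[0]):
        p = policy.p_click * (chroma[k] / cmax) ** policy.chroma_bias
        if rng.uniform() >= p:
            continue
        admissible = binary_erosion(
            painting.region_map == k, structure=struct, border_value=0
        )
        ys, xs = np.nonzero(admissible)
        if ys.size == 0:
            warnings.warn(f"colour {k}: regions too small for a 5x5 click window; skipped")
            continue
        j = int(rng.integers(0, ys.size)) if policy.jitter else 0
        selections.append(aggregate_click(lab_img, int(xs[j]), int(ys[j])))
    return selections


def opponent_axis_rgb(angle_deg: float) -> np.ndarray:
    """Unit RGB direction whose (RG, BY) projection sits at ``angle_deg``.

    The opponent transform has orthonormal rows r1 = (1,-1,0)/sqrt(2) and
    r2 = (1,1,-2)/sqrt(6), so d = cos(a) r1 + sin(a) r2 projects exactly to
    (cos a, sin a).
    """
    a = np.radians(angle_deg)
    r1 = np.array([1.0, -1.0, 0.0]) / _SQRT2
    r2 = np.array([1.0, 1.0, -2.0]) / _SQRT6
    return np.cos(a) * r1 + np.sin(a) * r2


def generate_opponent_patches(
    n: int,
    p: int = 8,
    planted_angle: float = 30.0,
    noise_sigma: float = 0.005,
    seed: int | None = None,
    chromatic_scale: float = 0.10,
    achromatic_scale: float = 0.04,
    n_achromatic_sources: int = 4,
):
    """Patch set with one planted chromatic-opponent source.

    Each patch is mid-grey plus a linear mixture of sources with
    heavy-tailed (Laplacian) amplitudes: one chromatic source — an oriented
    spatial grating modulating the RGB axis at ``planted_angle`` in the
    opponent plane — and several achromatic-gradient distractors.  The
    chromatic source carries the largest amplitude, so it should surface as
    the highest-energy ICA basis.  Returns a :class:`PatchSet`.
    """
    from .ica import PatchSet

    if n <= 3 * p * p:
        raise ValueError(f"need n > 3 p^2 = {3 * p * p} patches")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:p, 0:p].astype(np.float64) / p

    def grating(freq: float, phi: float, phase: float) -> np.ndarray:
        g = np.sin(2 * np.pi * freq * (xx * np.cos(phi) + yy * np.sin(phi)) + phase)
        return g / np.linalg.norm(g)

    d_chrom = opponent_axis_rgb(planted_angle)
    g_chrom = grating(1.5, np.pi / 5, 0.3)
    chrom_pattern = (g_chrom[..., None] * d_chrom).reshape(-1)

    achrom = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
    distractors = []
    for j in range(n_achromatic_sources):
        g = grating(1.0 + 0.7 * j, np.pi * (0.1 + 0.22 * j), 1.1 * j)
        distractors.append((g[..., None] * achrom).reshape(-1))

    D = 3 * p * p
    patches = np.full((n, D), 0.5)
    amp_c = rng.laplace(0.0, chromatic_scale, size=n)
    patches += amp_c[:, None] * chrom_pattern[None, :]
    for pat in distractors:
        amp = rng.laplace(0.0, achromatic_scale, size=n)
        patches += amp[:, None] * pat[None, :]
    if noise_sigma > 0:
        patches += rng.normal(0.0, noise_sigma, size=patches.shape)
    patches = np.clip(patches, 0.0, 1.0)
    return PatchSet(vectors=patches, p=p, sources=[])
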