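# Methods

This note records the models, conventions and numerical choices behind
`artpalette`, in the order the pipeline runs them.

## Colour representation

All colourimetric analysis happens in CIELAB.  Input images are interpreted
as sRGB with the D65 white point and the 2° standard observer — image files
in painting databases carry no calibration data, so the standard encoding is
the only defensible assumption.  8-bit values are divided by 255 exactly.
Conversions go through scikit-image (linearize, matrix to XYZ, CIELAB); the
test suite cross-checks them against an independently hand-coded converter
and requires round-trip errors below 1e−6 ΔE\*ab on a 9×9×9 RGB grid.

Hue is measured counter-clockwise from +a\* in degrees, folded to [0, 360).
Exactly achromatic colours (a\* = b\* = 0) get hue 0 plus an explicit flag
rather than NaN, so histograms stay well defined.

The opponent plane used by the ICA analysis is RG = (R−G)/√2,
BY = (R+G−2B)/√6, applied to *non-linear* sRGB values as given — the plane
is a device-space construction, not a colourimetric one, and linearizing
first would change the angles it produces.  The two defining vectors are
orthonormal, which makes planting a direction exact: the RGB axis
cos θ·r₁ + sin θ·r₂ projects to angle θ with no residual.

## Gamut descriptors

**Discernible colours.**  Colours are binned on an integer grid (floor of
each coordinate, half-open cells); two colours in one cell count as
indiscernible (≤ 1 ΔE in each component).  The default is 3-D unit-cube
binning of (L\*, a\*, b\*); a 2-D a\*b\* unit-square mode is kept as an
alternative, and the 2-D count can never exceed the 3-D count.  Floor
binning makes the operation deterministic and trivially oracle-checkable.

**Colour volume.**  The default is the convex-hull volume of the L\*a\*b\*
point cloud (scipy's Qhull); degenerate clouds (fewer than four distinct
non-coplanar points) return volume 0 with a flag.  A unit-cube occupancy
count is available as a sensitivity mode, since "volume of a colour
distribution" admits both readings.

**Gamut ellipse.**  The (a\*, b\*) scatter is fitted with the
ellipse-constrained direct least-squares conic fit (the stable partitioned
formulation that imposes 4ac − b² = 1), not an unconstrained conic fit
(which can return hyperbolas) and not a geometric fit (iterative, slower,
and unnecessary at the point counts involved).  Points are centred and
isotropically scaled before fitting for conditioning; an isotropic scale
preserves the recovered angle.  The reported angle is the orientation of the
longer semi-axis against +a\*, folded to [0, 180).  Recovery accuracy, by
construction tests: exact (1e−6) on noise-free samples, all parameters
within 2% under σ = 0.5 coordinate noise on 1000 points.

## Relevant-colour extraction

The computational extractor is a density-ranked greedy maximin over the
CIELAB unit-cell histogram:

1. bin pixels into unit cells and rank cells by pixel count (ties broken by
   lexicographic (L, a, b) cell index, for reproducibility);
2. scan the ranking, accepting a cell's mean colour when it
   - lies inside `L_range` and has chroma ≥ `chroma_min`,
   - sits ≥ `delta_e_min` (Euclidean ΔE\*ab) from every accepted colour,
   - and *represents* at least `density_min` of the image's pixels.

Defaults: `delta_e_min` 15, `L_range` [5, 95], `chroma_min` 5,
`density_min` 0.001.  The large-ΔE step keeps the palette small; the gates
drop near-black/near-white and near-achromatic candidates.

A candidate's *density* is measured as the fraction of image pixels within
`delta_e_min`/2 of its mean colour — the pixels that entry would stand for —
rather than the raw count of its own unit cell.  With per-pixel noise a
single paint colour spreads over hundreds of unit cells and no individual
cell holds a meaningful share, so a literal per-cell threshold would reject
everything; the ball count reduces to the per-cell count in the noise-free
case (where each colour occupies one cell and competitors are ≥ 2 cells
away) and degrades gracefully under noise.  The half-spacing radius also
keeps spurious between-cluster candidates out: a cell sitting ≥ `delta_e_min`
from every accepted colour captures only noise-tail pixels in its ball.

On noise-free mosaics whose K colours pass the gates and are ≥ 2·`delta_e_min`
apart, the extractor provably returns exactly K colours (each cluster is one
cell; every cell passes; all other cells of a cluster are suppressed by the
maximin step).  Under the noisy default regime (σ = 3) palettes come out
larger (~30–37 for K = 21) because noise widens each cluster into several
acceptable modes; the extra entries only improve downstream segmentation.

**Subjective palettes.**  Each observer click is averaged over the centred
5×5 window (25 pixels; clicks whose window crosses the border are rejected —
observers click areas, not edges).  Every selection stays one palette entry
by default, since similar colours picked at different locations are distinct
observations; optional merging collapses entries closer than a threshold by
single-linkage clustering (scipy), each cluster replaced by its mean.

**Overlap.**  Two palettes are compared by (a) the fraction of each covered
within a ΔE tolerance by the other and (b) the intersection-over-union of
their (a\*, b\*) convex hulls (shapely); the hull measure is reported as
unavailable when a palette has fewer than three distinct chromaticities.

## Palette segmentation

Nearest-colour lookup: each pixel takes the palette colour minimising
ΔE\*ab, ties to the lowest palette index.  CIELAB is the default distance
space (the perceptually uniform choice); plain sRGB distance is available
for sensitivity checks.  The reconstruction keeps the palette's exact CIELAB
values, so palette-exact inputs reconstruct bit-identically and the
operation is a fixed point under repetition.  Fidelity is the mean Pearson
correlation of the three RGB planes; a constant plane (in either image) has
no defined correlation and is excluded with a flag.

## Complexity metrics

Gradients: per-channel 3×3 Sobel, normalised by 1/8 so a ramp of slope *s*
per pixel responds exactly *s*; computed on the 0–255 intensity scale with
reflected borders; each pixel takes the channel with the largest magnitude.
Orientations are folded to [0, 180) and accumulated, weighted by magnitude,
into 16 bins — none of these conventions is canonical in the PHOG
literature, so bin count, border mode and aggregation are all parameters.

The pyramid splits the image into 2ᵏ×2ᵏ sub-images at level k (integer
block edges, so non-power-of-two sizes work).  Self-similarity is the
median histogram-intersection kernel between the 64 level-3 histograms and
the level-0 histogram; complexity is the mean gradient magnitude; anisotropy
is the variance of all pooled level-3 bin values; the Birkhoff-like metric
is exactly self-similarity/complexity (flagged undefined at complexity 0).
With 16 bins spanning 180°, a 90° rotation shifts orientations by exactly
8 bins, so all four metrics are invariant under 90° rotations — a property
the tests assert.

## ICA colour directions

Patches (default 8×8×3) are sampled uniformly at fully interior positions,
centred, and whitened by eigendecomposition of the sample covariance;
eigenvalues below 1e−10 of the largest are dropped (numerical rank), and the
dewhitening map is retained so learned bases can be expressed in pixel
space.  Dimensionality reduction happens at the whitening stage; the ICA
step itself is square.

The ICA is the fixed-point algorithm with symmetric decorrelation and the
cubic nonlinearity (scikit-learn's FastICA with `whiten=False` on our
whitened vectors; tanh available by option).  Mixing columns are mapped back
through the dewhitening matrix, ordered by decreasing L2 norm (energy,
stable sort for ties) and unit-normalised.  Besides the convergence flag,
each fit carries a reliability diagnostic: the maximum |excess kurtosis|
across estimated sources.  Gaussian data make ICA non-identifiable — the
algorithm can "converge" to an arbitrary rotation — and near-zero kurtosis
(< 0.3) flags exactly that case.

A basis's preferred colour direction treats its p² pixels as points in RGB,
takes the first principal component (SVD), projects it onto (RG, BY) and
folds the angle to [0, 180) — a principal axis has no sign.  When the
projection norm falls below 0.05 (relative to the unit principal axis) the
basis is flagged achromatic and excluded from direction histograms, which
report the excluded count.

## Synthetic generators

**Paintings.**  K CIELAB colours are rejection-sampled inside the sRGB gamut
(with 2% channel headroom so noise rarely clips) subject to pairwise
ΔE ≥ `delta_e_sep`, lightness in [20, 85] and chroma in [12, 80] — the range
where paint colours live and where the extractor's gates cannot silently
drop a truth colour.  The canvas (default 128×128, a size at which every
stage runs in well under a second while leaving ~780 pixels per colour) is
partitioned into Voronoi cells of 64 random sites; irregular region
boundaries exercise nearest-colour segmentation the way real paintings do.
Every colour is used at least once; a deterministic reassignment loop plus
bounded layout retries guarantee each colour at least 0.5% of the canvas
and one region with a 5×5-erodible interior, so the extractor's density
gate and the observer's click window are feasible by construction.  Noise
is Gaussian in CIELAB (perceptually uniform), shading is a single
low-frequency sinusoid on L\*, and the rendered sRGB image records the
fraction of pixels altered by gamut clipping.  Defaults (K = 21, σ = 3,
shading 5) put the generator in the regime where palettes of ~20 colours
and segmentation correlations ≥ 0.94 are the expected behaviour.

**Observer.**  For each truth colour, with probability
`p_click`·(chroma/max chroma)^`chroma_bias`, one click lands at a uniformly
chosen pixel whose whole 5×5 window lies inside that colour's regions
(binary erosion of the region mask).  The chroma-bias exponent reproduces
the scarcity of low-chroma selections in human data; bias 0 clicks every
colour with equal probability.

**Opponent patch sets.**  One chromatic source (a fixed oriented grating
modulating the RGB axis planted at the requested opponent angle) plus four
achromatic-gradient distractor gratings, mixed with heavy-tailed Laplacian
amplitudes around mid-grey, with the chromatic amplitude largest so it
surfaces as the highest-energy basis.  Laplacian amplitudes give ICA the
non-Gaussianity it needs; the identical recipe with Gaussian amplitudes
would be non-identifiable.

## What the synthetic regime does and does not show

The generators reproduce the *structural* assumptions of the analysis —
palette-structured images, well-separated colours, perceptual noise,
click-based selection — not the look of paintings: no texture, brushwork,
gradients between pigments, or semantic saliency.  Passing tests therefore
certify the machinery (descriptors, extraction, segmentation, ICA recovery)
and its closure properties, not any claim about specific artworks; published
per-dataset values depend on image sets this repository does not ship.
Problem sizes in the tests and the acceptance script (10 paintings of
128×128, 5000-patch ICA runs at whitened dimension 6, 20 seeds) were chosen
as the smallest sizes at which each property is stable.

## Known limitations

- The computational extractor is a reconstruction from its documented
  constraints (large colour differences, L\*/chroma restrictions, density
  ranking); the historical algorithm's exact stopping rule is not published,
  so parameter defaults — not the structure — carry the uncertainty.
- Hull-based gamut volume is sensitive to single outlier pixels; the
  cell-count mode is the robust alternative.
- The ellipse fit's algebraic criterion has a known low-eccentricity bias,
  negligible at the noise levels tested (< 2% at σ = 0.5 on axes 10–20).
- Whitened dimension for ICA must be chosen by the caller; retaining many
  noise-dominated dimensions slows convergence and can leave the fixed-point
  iteration short of its tolerance (reported via the convergence flag).
- The opponent plane operates on non-linear sRGB; cone-excitation (LMS)
  analyses are out of scope.
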