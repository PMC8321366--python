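# artpalette

How many colours make up a painting, as far as a human glancing at it is
concerned?  Counting *discernible* colours in CIELAB (unit-cell occupancy of
the L\*a\*b\* histogram) gives tens of thousands per image, yet observers
asked to click on the colours that "stand out" report only on the order of
twenty.  `artpalette` implements the computational side of that question for
researchers in colour vision and computational aesthetics: extracting a small
set of **relevant colours** from an image, comparing it with observer
selections, and testing whether such a palette suffices to reconstruct the
image.

The package covers five analyses, each backed by a synthetic ground-truth
generator so every stage is verifiable without proprietary painting datasets:

1. **Gamut descriptors** — number of discernible colours (NDC, unit cubes in
   L\*a\*b\* or unit squares in a\*b\*), convex-hull colour volume, and a
   direct least-squares ellipse fit to the (a\*, b\*) gamut (area, axis
   ratio, orientation of the long axis from +a\*).
2. **Relevant colours** — a computational route (cells of the CIELAB
   histogram ranked by density, accepted greedily subject to
   ΔE\*ab ≥ `delta_e_min` maximin separation plus L\* and chroma gates) and a
   subjective route (observer clicks averaged over a centred 5×5 pixel
   window, one palette entry per selection), with overlap measures between
   the two.
3. **Palette segmentation** — every pixel reassigned to its nearest palette
   colour (ΔE\*ab in CIELAB), scored by the mean Pearson correlation between
   original and reconstructed R, G, B planes.
4. **Complexity metrics** — PHOG self-similarity (histogram-intersection
   kernel between level-3 sub-image HOGs and the level-0 HOG), mean gradient
   complexity, anisotropy (variance of level-3 HOG values) and the
   Birkhoff-like order/complexity ratio.
5. **ICA colour directions** — 8×8×3 patches, eigendecomposition whitening,
   fixed-point ICA (I = A·s); each basis function's preferred colour
   direction is the first principal component of its pixels projected onto
   the opponent plane RG = (R−G)/√2, BY = (R+G−2B)/√6, with angle
   θ = atan2(BY, RG) folded to [0°, 180°).

## Worked example

Generate a synthetic "painting" (21 CIELAB colours ≥ 30 ΔE apart on Voronoi
regions, per-pixel noise σ = 3, lightness shading), extract its palette, and
rebuild the image from it:

```python
import numpy as np
from artpalette import colorspace as cs, palette as pal, segmentation as seg
from artpalette import synthetic as syn

painting = syn.generate_painting(seed=0)           # K=21, sigma=3, shading 5
lab = cs.srgb_to_lab(painting.rgb)
extracted = pal.extract_relevant_colors(lab)
segmented = seg.segment_with_palette(lab, extracted)
report = seg.plane_correlation(painting.rgb, segmented.rendered_rgb)
print(extracted.size, round(report.mean_r, 4))
```

prints

```
37 0.9804
```

— a 37-colour palette suffices to reconstruct the noisy 128×128 image with a
mean per-plane correlation of 0.98: almost all of the image's colour
structure lives in a palette two orders of magnitude smaller than its
~12,000 discernible colours.  On the noise-free counterpart
(`noise_sigma=0, shading_amplitude=0`) the extractor returns exactly the 21
generator colours, each within 1 ΔE of truth.

The same pipeline is run as a narrative sequence by the numbered scripts in
`analysis/` (synthesize → describe → palettes → segmentation → complexity →
ICA), which write their tables under `results/`.  The command-line interface
exposes each stage on single images:

```sh
artpalette synth --k 21 --seed 7 --out run
artpalette palette run/painting.png --out run
artpalette segment run/painting.png run/palette.json --out run
```

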