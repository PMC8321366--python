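"""ICA colour directions of the synthetic painting set.

Samples 8x8 patches from all synthetic paintings, whitens them, learns ICA
basis functions, orders them by energy, and histograms each basis's
preferred colour direction (first principal component of its pixels,
projected to the RG/BY opponent plane, folded to [0, 180)).  Then compares
that distribution with the colour angles of the subjective relevant
colours: under efficient coding, observer-selected colours should populate
the directions the image statistics prefer.

Writes results/ica_directions.csv, results/ica_basis_montage.png and
results/relevant_color_angles.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from artpalette import colorspace as cs, ica, io as io_mod, palette as pal
from artpalette.cli import _basis_montage

ROOT = Path(__file__).resolve().parent.parent / "results"
N_COMPONENTS = 48
PATCHES_PER_IMAGE = 2000


def main(seed: int = 0) -> None:
    synth = ROOT / "synthetic"
    paintings = sorted(synth.glob("painting_*.png"))
    if not paintings:
        raise SystemExit("run 01_synthesize_paintings.py first")
    images = [io_mod.read_image(p) for p in paintings]
    patches = ica.sample_patches(images, PATCHES_PER_IMAGE, p=8, seed=seed)
    white = ica.whiten(patches, n_components=N_COMPONENTS)
    result = ica.fit_ica(white, seed=seed, p=8)
    bases = ica.order_and_normalize(result.bases)
    angles = [ica.basis_color_direction(b) for b in bases]
    hist = ica.direction_histogram(angles, bin_width=10.0)
    pd.DataFrame(
        {
            "bin_start": hist.bin_edges[:-1],
            "bin_end": hist.bin_edges[1:],
            "count": hist.counts,
        }
    ).to_csv(ROOT / "ica_directions.csv", index=False)
    io_mod.write_image(ROOT / "ica_basis_montage.png", _basis_montage(bases, 8))

    # colour angles of the subjective relevant colours, unfolded (vectors)
    rc_angles = []
    for path in paintings:
        stem = path.stem.split("_")[1]
        lab = cs.srgb_to_lab(io_mod.read_image(path))
        clicks = io_mod.read_clicks_csv(synth / f"clicks_{stem}.csv")
        subj = pal.subjective_palette(
            [pal.aggregate_click(lab, int(r.x), int(r.y)) for r in clicks.itertuples()]
        )
        rgb = cs.lab_to_srgb(subj.colors)
        opp = cs.rgb_to_opponent(rgb)
        ang, ach = cs.opponent_angles(opp, fold=True)
        rc_angles.extend(ang[~ach].tolist())
    pd.DataFrame({"angle": rc_angles}).to_csv(
        ROOT / "relevant_color_angles.csv", index=False
    )

    n_chromatic = sum(a is not None for a in angles)
    print(
        f"{len(bases)} bases learned from {patches.n} patches "
        f"({n_chromatic} chromatic, {hist.n_achromatic} achromatic); "
        f"converged={result.converged}, reliable={result.reliable}"
    )
    occupied = hist.bin_edges[:-1][hist.counts > 0]
    print(f"occupied direction bins (deg): {occupied.astype(int).tolist()}")
    folded_rc = np.array(rc_angles) % 180.0
    print(
        f"{len(rc_angles)} relevant-colour angles; their folded directions "
        f"span bins {sorted({int(b) * 10 for b in folded_rc // 10})}"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
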