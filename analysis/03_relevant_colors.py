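"""Computational vs subjective relevant colours.

For each synthetic painting: extract the computational palette
(density-ranked greedy maximin with L*/chroma gates), build the subjective
palette from the simulated observer's clicks, and measure their agreement —
the fraction of each palette covered by the other within 10 ΔE and the
intersection-over-union of the two (a*, b*) convex hulls.  Also tabulates
hue/chroma statistics of the subjective selections.

Writes results/palettes.csv and results/hue_chroma.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from artpalette import colorspace as cs, io as io_mod, palette as pal

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    synth = ROOT / "synthetic"
    paintings = sorted(synth.glob("painting_*.png"))
    if not paintings:
        raise SystemExit("run 01_synthesize_paintings.py first")
    rows, all_hue, all_chroma = [], [], []
    for path in paintings:
        stem = path.stem.split("_")[1]
        lab = cs.srgb_to_lab(io_mod.read_image(path))
        comp = pal.extract_relevant_colors(lab)
        clicks = io_mod.read_clicks_csv(synth / f"clicks_{stem}.csv")
        selections = [
            pal.aggregate_click(lab, int(r.x), int(r.y)) for r in clicks.itertuples()
        ]
        subj = pal.subjective_palette(selections)
        truth = io_mod.palette_from_json(synth / f"truth_{stem}.json")
        overlap = pal.palette_overlap(comp, subj, tol=10.0)
        vs_truth = pal.palette_overlap(truth, subj, tol=5.0)
        table = pal.hue_chroma_table(subj)
        all_hue.extend(table["hue"].tolist())
        all_chroma.extend(table["chroma"].tolist())
        rows.append(
            {
                "image": path.name,
                "n_computational": comp.size,
                "n_subjective": subj.size,
                "subjective_covered": overlap.subjective_covered,
                "computational_covered": overlap.computational_covered,
                "hull_iou": overlap.hull_iou,
                "subjective_vs_truth": vs_truth.subjective_covered,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "palettes.csv", index=False)
    pd.DataFrame({"hue": all_hue, "chroma": all_chroma}).to_csv(
        ROOT / "hue_chroma.csv", index=False
    )
    print(df.to_string(index=False))
    print(
        f"\ncomputational palettes: {df.n_computational.mean():.1f} +/- "
        f"{df.n_computational.std():.1f} colours; subjective: "
        f"{df.n_subjective.mean():.1f} +/- {df.n_subjective.std():.1f}"
    )
    print(
        f"subjective colours within 10 dE of a computational colour: "
        f"{df.subjective_covered.mean():.2f}"
    )
    chroma = np.array(all_chroma)
    print(
        f"fraction of subjective selections below chroma 35: "
        f"{np.mean(chroma < 35):.2f} (chroma bias pushes observers to "
        f"colourful picks)"
    )


if __name__ == "__main__":
    main()
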