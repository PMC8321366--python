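"""File formats: images, palettes, click lists, descriptor tables, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorspace import validate_rgb
from .palette import Palette

__all__ = [
    "read_image",
    "write_image",
    "palette_to_json",
    "palette_from_json",
    "read_clicks_csv",
    "write_clicks_csv",
    "write_manifest",
]


def read_image(path) -> np.ndarray:
    """Decode PNG/TIFF/JPEG to an (H, W, 3) float array in [0, 1].

    8-bit images are divided by 255 exactly; 16-bit by 65535.  Alpha
    channels are dropped; greyscale is broadcast to three channels.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64)
    return validate_rgb(arr)


def write_image(path, rgb: np.ndarray) -> None:
    """Write an (H, W, 3) float [0, 1] array as an 8-bit PNG."""
    arr = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (np.round(arr * 255.0)).astype(np.uint8))


def palette_to_json(palette: Palette, path) -> None:
    Path(path).write_text(json.dumps(palette.to_dict(), indent=2))


def palette_from_json(path) -> Palette:
    d = json.loads(Path(path).read_text())
    return Palette(
        colors=np.array(d["colors_lab"]),
        provenance=d["provenance"],
        sources=[tuple(s) if s is not None else None for s in d.get("sources", [])],
    )


def read_clicks_csv(path) -> pd.DataFrame:
    """Click list with columns image_id, observer_id, x, y."""
    df = pd.read_csv(path)
    missing = {"image_id", "observer_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"clicks CSV missing columns: {sorted(missing)}")
    return df


def write_clicks_csv(path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=["image_id", "observer_id", "x", "y"]).to_csv(
        path, index=False
    )


def write_manifest(path, config: dict, outputs: list[str]) -> None:
    """One JSON manifest per run: inputs, parameters, seeds and artifacts."""
    import artpalette

    Path(path).write_text(
        json.dumps(
            {"config": config, "outputs": outputs, "version": artpalette.__version__},
            indent=2,
            sort_keys=True,
        )
    )
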