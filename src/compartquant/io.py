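"""TIFF and manifest I/O.

Images are written as single-page 16-bit unsigned TIFFs (values rounded
and clipped); label masks likewise.  A manifest CSV with columns
``field_id, condition, replicate, channel, path`` ties the files of one
experiment together.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import tifffile

from .containers import DEFAULT_PIXEL_AREA, CompartmentMasks, FieldImage

MASK_LAYERS = ("cell", "nucleus", "nucleolus", "cytoplasm")


def write_image(path: str | Path, image: np.ndarray) -> None:
    data = np.clip(np.round(np.asarray(image, dtype=float)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def write_masks(outdir: str | Path, field_id: str, masks: CompartmentMasks) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in MASK_LAYERS:
        arr = getattr(masks, f"{layer}_labels")
        tifffile.imwrite(str(outdir / f"{field_id}_labels_{layer}.tif"),
                         arr.astype(np.uint16))


def read_masks(indir: str | Path, field_id: str) -> CompartmentMasks:
    indir = Path(indir)
    layers = {layer: tifffile.imread(str(indir / f"{field_id}_labels_{layer}.tif"))
              .astype(np.int32) for layer in MASK_LAYERS}
    return CompartmentMasks(layers["cell"], layers["nucleus"],
                            layers["nucleolus"], layers["cytoplasm"])


def read_manifest(manifest_path: str | Path,
                  pixel_area: float = DEFAULT_PIXEL_AREA
                  ) -> Iterator[FieldImage]:
    """Yield one :class:`FieldImage` per field listed in the manifest.

    Relative paths in the manifest resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    table = pd.read_csv(manifest_path)
    required = {"field_id", "condition", "replicate", "channel", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest missing columns: {required - set(table.columns)}")
    for (field_id, condition, replicate), group in table.groupby(
            ["field_id", "condition", "replicate"], sort=False):
        channels = {}
        for row in group.itertuples():
            p = Path(row.path)
            channels[row.channel] = read_image(p if p.is_absolute() else root / p)
        yield FieldImage(channels, pixel_area=pixel_area, condition=str(condition),
                         replicate=str(replicate), field_id=str(field_id))


def manifest_conditions(manifest_path: str | Path) -> list[str]:
    table = pd.read_csv(manifest_path)
    return list(pd.unique(table["condition"]))
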