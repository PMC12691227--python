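"""Reading and writing the pipeline's on-disk artifacts.

Label grids go to single-channel integer TIFF (category index per cell,
mask as a second page) with a JSON sidecar carrying the category vocabulary
and provenance; tissue maps and patch stacks to compressed ``.npz`` with a
JSON manifest; survival tables and feature tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .sampling import PatchStack
from .tissue_map import TissueLabelGrid, TissueMap

__all__ = [
    "save_label_grid", "load_label_grid", "save_tissue_map", "load_tissue_map",
    "save_patch_stack", "load_patch_stack", "save_survival", "load_survival",
    "save_tile_png",
]


def save_label_grid(grid: TissueLabelGrid, path, provenance: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.stack([grid.labels.astype(np.uint8),
                                     grid.mask.astype(np.uint8)]))
    sidecar = {
        "categories": list(grid.categories),
        "patch_size_px": list(grid.patch_size_px),
        "pages": ["labels", "mask"],
        "provenance": provenance or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_label_grid(path) -> TissueLabelGrid:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return TissueLabelGrid(labels=pages[0].astype(np.int64),
                           mask=pages[1].astype(bool),
                           patch_size_px=tuple(meta["patch_size_px"]),
                           categories=tuple(meta["categories"]))


def save_tissue_map(tm: TissueMap, path) -> None:
    np.savez_compressed(path, channels=tm.channels, mode=np.array(tm.mode),
                        meta=np.array(json.dumps(tm.meta)))


def load_tissue_map(path) -> TissueMap:
    with np.load(path) as z:
        return TissueMap(channels=z["channels"], mode=str(z["mode"]),
                         meta=json.loads(str(z["meta"])))


def save_patch_stack(stack: PatchStack, path) -> None:
    path = Path(path)
    np.savez_compressed(path, tiles=stack.tiles,
                        slot_categories=stack.slot_categories,
                        coords=stack.coords)
    manifest = {
        "strategy": stack.strategy,
        "rng_seed": int(stack.rng_seed),
        "slots": [
            {"slot": i, "category": int(z), "cell": [int(r), int(c)]}
            for i, (z, (r, c)) in enumerate(zip(stack.slot_categories,
                                                stack.coords))
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_patch_stack(path) -> PatchStack:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        return PatchStack(tiles=z["tiles"], slot_categories=z["slot_categories"],
                          coords=z["coords"], strategy=manifest["strategy"],
                          rng_seed=manifest["rng_seed"])


def save_survival(df: pd.DataFrame, path, ground_truth: bool = False) -> None:
    cols = ["patient_id", "time", "event"]
    if ground_truth:
        cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def load_survival(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_tile_png(tile: np.ndarray, path) -> None:
    iio.imwrite(Path(path), (np.clip(tile, 0, 1) * 255).astype(np.uint8))
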