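"""Tissue-label grids and multi-channel tissue-organization maps.

A whole-slide image is compressed into a coarse grid by classifying each
non-overlapping patch (224x224 px at 20x by convention) into one of eight
tissue categories. The grid is then expanded into an 8-channel spatial map
with one indicator (or probability) channel per category — the macro-branch
input. Grid coordinates are patch indices, 0-based ``(row, col)``, row-major.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.transform import resize as _sk_resize

from .categories import N_CATEGORIES, TISSUE_CATEGORIES

__all__ = [
    "TissueLabelGrid", "TissueMap", "PatchClassifier", "ClassifierInterfaceError",
    "tissue_mask", "classify_grid", "build_tissue_map", "resize_tissue_map",
    "stack_maps",
]


class ClassifierInterfaceError(ValueError):
    """A patch classifier violated its output contract."""


@dataclass
class TissueLabelGrid:
    """Per-patch tissue category labels plus a tissue-presence mask.

    ``labels[r, c]`` is a category index in ``[0, 7]`` wherever
    ``mask[r, c]`` is True; masked-out cells carry no tissue.
    """

    labels: np.ndarray
    mask: np.ndarray
    patch_size_px: tuple[int, int] = (224, 224)
    categories: tuple[str, ...] = TISSUE_CATEGORIES

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must have equal shapes")
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        lab = self.labels[self.mask]
        if lab.size and (lab.min() < 0 or lab.max() >= len(self.categories)):
            raise ValueError("unmasked labels must lie in the category range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_tissue_cells(self) -> int:
        return int(self.mask.sum())

    def category_counts(self) -> np.ndarray:
        """Histogram of labels over unmasked cells, length 8."""
        return np.bincount(self.labels[self.mask], minlength=N_CATEGORIES)

    def cells_of(self, category: int) -> np.ndarray:
        """(k, 2) array of (row, col) coordinates labeled `category`."""
        return np.argwhere(self.mask & (self.labels == category))


@dataclass
class TissueMap:
    """8-channel spatial map: channel z indicates (or scores) category z.

    In ``one_hot`` mode each unmasked cell is a one-hot vector over channels
    and masked cells are all-zero; ``soft`` mode carries classifier
    probabilities. ``meta`` records resize provenance so attribution maps can
    be projected back onto the source grid.
    """

    channels: np.ndarray  # (H, W, 8)
    mode: str = "one_hot"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[2] != N_CATEGORIES:
            raise ValueError("tissue map must be (H, W, 8)")
        if self.mode not in ("one_hot", "soft"):
            raise ValueError("mode must be 'one_hot' or 'soft'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[:2]

    def channel_sums(self) -> np.ndarray:
        return self.channels.sum(axis=(0, 1))

    def argmax_grid(self) -> TissueLabelGrid:
        """Collapse back to a label grid (mask = any nonzero channel)."""
        mask = self.channels.sum(axis=2) > 0
        labels = np.argmax(self.channels, axis=2)
        labels[~mask] = 0
        return TissueLabelGrid(labels=labels, mask=mask)


class PatchClassifier(Protocol):
    """Pluggable patch-level tissue classifier.

    ``classify(tile)`` returns a probability vector over the 8 categories:
    non-negative, summing to 1 within 1e-6. A pre-trained network can be
    wrapped behind this interface; synthetic grids can bypass it entirely.
    """

    def classify(self, tile: np.ndarray) -> np.ndarray: ...


def _validate_probs(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_CATEGORIES,):
        raise ClassifierInterfaceError(
            f"classifier must return {N_CATEGORIES} probabilities, got shape {p.shape}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ClassifierInterfaceError("probabilities must be non-negative and sum to 1")
    return p


def tissue_mask(thumbnail: np.ndarray, min_object_area: int = 16,
                channel: str = "gray") -> np.ndarray:
    """Foreground tissue mask of an RGB (or grayscale) thumbnail.

    Otsu threshold on the grayscale (tissue is darker than glass) or on the
    HSV saturation channel (tissue is more saturated); connected components
    below ``min_object_area`` pixels are dropped. A fully uniform image
    yields an all-false mask rather than an error.
    """
    img = np.asarray(thumbnail, dtype=np.float64)
    if img.ndim == 3:
        if channel == "gray":
            score = 1.0 - img.mean(axis=2) / max(img.max(), 1e-12)
        elif channel == "saturation":
            mx = img.max(axis=2)
            mn = img.min(axis=2)
            score = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-12), 0.0)
        else:
            raise ValueError("channel must be 'gray' or 'saturation'")
    else:
        score = 1.0 - img / max(img.max(), 1e-12)
    if np.ptp(score) < 1e-12:
        return np.zeros(score.shape, dtype=bool)
    thr = threshold_otsu(score)
    mask = score > thr
    if min_object_area > 1:
        mask = remove_small_objects(mask, max_size=min_object_area - 1)
    return mask


def classify_grid(tile_provider: Callable[[int, int], np.ndarray],
                  mask: np.ndarray,
                  classifier: PatchClassifier,
                  patch_size_px: tuple[int, int] = (224, 224),
                  return_probabilities: bool = False):
    """Label every masked-in grid cell by the classifier's argmax.

    Ties are broken toward the lowest category index (argmax convention).
    Cells outside the tissue mask are never classified.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int64)
    probs = np.zeros(mask.shape + (N_CATEGORIES,)) if return_probabilities else None
    for r, c in np.argwhere(mask):
        p = _validate_probs(classifier.classify(tile_provider(r, c)))
        labels[r, c] = int(np.argmax(p))
        if return_probabilities:
            probs[r, c] = p
    grid = TissueLabelGrid(labels=labels, mask=mask, patch_size_px=patch_size_px)
    if return_probabilities:
        return grid, probs
    return grid


def build_tissue_map(grid: TissueLabelGrid, mode: str = "one_hot",
                     probabilities: np.ndarray | None = None) -> TissueMap:
    """Expand a label grid into the 8-channel map.

    One-hot mode places a 1 in channel z exactly where the label is z; soft
    mode stores the supplied per-cell probability vectors. Masked cells are
    all-zero in either mode.
    """
    h, w = grid.shape
    if mode == "one_hot":
        ch = np.zeros((h, w, N_CATEGORIES))
        rr, cc = np.nonzero(grid.mask)
        ch[rr, cc, grid.labels[rr, cc]] = 1.0
    elif mode == "soft":
        if probabilities is None:
            raise ValueError("soft mode requires per-cell probabilities")
        ch = np.asarray(probabilities, dtype=np.float64).copy()
        if ch.shape != (h, w, N_CATEGORIES):
            raise ValueError("probabilities must be (H, W, 8)")
        ch[~grid.mask] = 0.0
    else:
        raise ValueError("mode must be 'one_hot' or 'soft'")
    return TissueMap(channels=ch, mode=mode)


def resize_tissue_map(tm: TissueMap, target: tuple[int, int]) -> TissueMap:
    """Aspect-preserving rescale then zero-pad to ``target`` (H, W).

    Nearest-neighbor interpolation in one-hot mode (values stay in {0,1});
    bilinear in soft mode. The scale factor and pad offsets are stored in
    ``meta`` so maps computed on the resized grid can be projected back.
    """
    th, tw = target
    if th < 8 or tw < 8:
        raise ValueError("target must be at least 8x8")
    h, w = tm.shape
    if (h, w) == (th, tw):
        return TissueMap(channels=tm.channels.copy(), mode=tm.mode,
                         meta={"scale": 1.0, "offset": (0, 0), "source_shape": (h, w)})
    scale = min(th / h, tw / w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    order = 0 if tm.mode == "one_hot" else 1
    scaled = _sk_resize(tm.channels, (nh, nw), order=order, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    out = np.zeros((th, tw, N_CATEGORIES))
    oy, ox = (th - nh) // 2, (tw - nw) // 2
    out[oy:oy + nh, ox:ox + nw] = scaled
    return TissueMap(channels=out, mode=tm.mode,
                     meta={"scale": scale, "offset": (oy, ox), "source_shape": (h, w)})


def stack_maps(maps: list[TissueMap]) -> np.ndarray:
    """Stack maps into a model batch ``(N, 8, H, W)``."""
    return np.stack([m.channels.transpose(2, 0, 1) for m in maps])
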