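"""Structure-aware stratified patch sampling.

From a tissue-label grid, compute slide-level category proportions, apportion
a fixed patch budget (default N = 27) across the eight categories in
proportion to tissue composition, draw cells accordingly, and stack the
corresponding RGB tiles into the micro-branch input tensor (27 tiles -> an
81-channel image). Comparison samplers (global random, tumor-only) and a
strategy/size sweep harness are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import N_CATEGORIES, TUMOR
from .tissue_map import TissueLabelGrid

__all__ = [
    "InsufficientTissueError", "compute_proportions", "allocate",
    "PatchStack", "sample_cells", "sample_patches", "sweep_harness",
    "DEFAULT_PATCH_BUDGET",
]

DEFAULT_PATCH_BUDGET = 27


class InsufficientTissueError(ValueError):
    """Fewer tissue patches available than the requested budget."""


class EmptySlideError(ValueError):
    """No unmasked cells on the slide."""


def compute_proportions(grid: TissueLabelGrid) -> np.ndarray:
    """Spatial proportion r_z of each category among unmasked cells.

    Non-negative, sums to exactly 1 when any tissue is present.
    """
    counts = grid.category_counts()
    total = counts.sum()
    if total == 0:
        raise EmptySlideError("slide has no tissue cells")
    return counts / total


def allocate(proportions: np.ndarray, n_total: int = DEFAULT_PATCH_BUDGET,
             availability: np.ndarray | None = None) -> np.ndarray:
    """Apportion ``n_total`` patch slots across categories.

    The raw quota r_z * N is generally non-integer; slots are assigned by
    Hamilton (largest-remainder) apportionment: each category first gets
    floor(r_z * N), then the remaining slots go to the largest fractional
    remainders (ties broken toward larger r_z, then lower index). Any
    allocation exceeding a category's availability is clipped and the
    shortfall reassigned to categories with spare patches, one slot at a
    time, each going to the category where it least increases the total
    deviation sum_z |n_z - r_z * N| (ties toward larger r_z, then lower
    index, so dominant tissue types absorb the compensation). The result
    attains the minimum total deviation among all feasible allocations.
    """
    r = np.asarray(proportions, dtype=np.float64)
    if r.shape != (N_CATEGORIES,):
        raise ValueError(f"proportions must have length {N_CATEGORIES}")
    if availability is None:
        avail = np.full(N_CATEGORIES, n_total, dtype=np.int64)
    else:
        avail = np.asarray(availability, dtype=np.int64)
    if avail.sum() < n_total:
        raise InsufficientTissueError(
            f"only {int(avail.sum())} patches available for a budget of {n_total}")

    quota = r * n_total
    n = np.floor(quota).astype(np.int64)
    remaining = n_total - int(n.sum())
    frac = quota - n
    order = sorted(range(N_CATEGORIES), key=lambda z: (-frac[z], -r[z], z))
    for z in order[:remaining]:
        n[z] += 1

    # clip to availability, reassign the deficit to dominant spare categories
    over = np.maximum(n - avail, 0)
    deficit = int(over.sum())
    n = np.minimum(n, avail)
    while deficit > 0:
        best = min(
            ((abs(n[z] + 1 - quota[z]) - abs(n[z] - quota[z]), -r[z], z)
             for z in range(N_CATEGORIES) if n[z] < avail[z]))
        n[best[2]] += 1
        deficit -= 1
    assert int(n.sum()) == n_total
    return n


@dataclass
class PatchStack:
    """Stacked sampled tiles with per-slot provenance.

    ``tiles`` has shape (S, tile, tile, 3); the encoder consumes
    ``channel_view`` of shape (3S, tile, tile). Slots are ordered by
    category index ascending, then draw order, so channel semantics are
    stable across patients. The flagship configuration uses S = 27
    (81 channels).
    """

    tiles: np.ndarray
    slot_categories: np.ndarray
    coords: np.ndarray                      # (S, 2) grid cells
    strategy: str = "category"
    rng_seed: int = 0
    plan: np.ndarray | None = None

    def __post_init__(self):
        self.tiles = np.asarray(self.tiles, dtype=np.float64)
        if self.tiles.ndim != 4 or self.tiles.shape[3] != 3:
            raise ValueError("tiles must be (S, h, w, 3)")

    @property
    def n_slots(self) -> int:
        return self.tiles.shape[0]

    @property
    def channel_view(self) -> np.ndarray:
        """(3S, h, w): tiles concatenated along the channel axis."""
        s, h, w, _ = self.tiles.shape
        return self.tiles.transpose(0, 3, 1, 2).reshape(s * 3, h, w)


def sample_cells(grid: TissueLabelGrid, n_total: int, strategy: str,
                 rng_seed: int, plan: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Choose grid cells per strategy; returns (coords (S,2), categories (S,)).

    * ``category``: n_z cells uniformly without replacement within each
      category, per the supplied (or freshly computed) allocation plan.
    * ``random``: n_total cells uniformly from all unmasked cells.
    * ``tumor_only``: n_total cells from tumor-labeled cells.

    Slots are ordered category-ascending then draw order; deterministic
    given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    if strategy == "category":
        if plan is None:
            plan = allocate(compute_proportions(grid), n_total,
                            grid.category_counts())
        coords, cats = [], []
        for z in range(N_CATEGORIES):
            k = int(plan[z])
            if k == 0:
                continue
            cells = grid.cells_of(z)
            if len(cells) < k:
                raise InsufficientTissueError(
                    f"category {z}: {len(cells)} cells available, {k} requested")
            pick = cells[rng.choice(len(cells), size=k, replace=False)]
            coords.append(pick)
            cats.append(np.full(k, z))
        return np.concatenate(coords), np.concatenate(cats)
    if strategy == "random":
        cells = np.argwhere(grid.mask)
        if len(cells) < n_total:
            raise InsufficientTissueError("fewer tissue cells than the budget")
        pick = cells[rng.choice(len(cells), size=n_total, replace=False)]
        return pick, grid.labels[pick[:, 0], pick[:, 1]]
    if strategy == "tumor_only":
        cells = grid.cells_of(TUMOR)
        if len(cells) == 0:
            raise ValueError("tumor_only sampling on a slide with no tumor cells")
        if len(cells) < n_total:
            raise InsufficientTissueError("fewer tumor cells than the budget")
        pick = cells[rng.choice(len(cells), size=n_total, replace=False)]
        return pick, np.full(n_total, TUMOR)
    raise ValueError(f"unknown strategy {strategy!r}")


def sample_patches(grid: TissueLabelGrid, tile_provider,
                   n_total: int = DEFAULT_PATCH_BUDGET,
                   strategy: str = "category", rng_seed: int = 0,
                   plan: np.ndarray | None = None) -> PatchStack:
    """Draw cells per strategy, fetch their tiles, and stack them."""
    coords, cats = sample_cells(grid, n_total, strategy, rng_seed, plan)
    tiles = np.stack([tile_provider(int(r), int(c)) for r, c in coords])
    return PatchStack(tiles=tiles, slot_categories=cats, coords=coords,
                      strategy=strategy, rng_seed=rng_seed, plan=plan)


def sweep_harness(cohort, strategies: list[str], sizes: list[int],
                  evaluate_fn, seeds: list[int] | None = None) -> pd.DataFrame:
    """Strategy x size comparison grid for the micro branch.

    ``evaluate_fn(cohort, strategy, size, seed)`` must train/evaluate the
    micro branch under the shared cross-validation protocol and return a
    list of fold-wise C-indices. Emits one row per (strategy, size, seed,
    fold) plus mean and 95% t-interval columns merged per cell.
    """
    from .survival import fold_summary  # local import to avoid cycle

    seeds = seeds or [0]
    rows = []
    for strategy in strategies:
        for size in sizes:
            scores = []
            for seed in seeds:
                fold_scores = evaluate_fn(cohort, strategy, size, seed)
                for k, s in enumerate(fold_scores):
                    rows.append({"strategy": strategy, "size": size,
                                 "seed": seed, "fold": k, "c_index": s})
                scores.extend(fold_scores)
            mean, lo, hi = fold_summary(scores)
            for row in rows:
                if row["strategy"] == strategy and row["size"] == size:
                    row.update(mean_c_index=mean, ci_lower=lo, ci_upper=hi)
    return pd.DataFrame(rows)
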