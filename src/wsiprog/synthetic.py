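"""Synthetic whole-slide cohorts with known ground truth.

Emulates, at desk scale, the inputs the dual-branch pipeline consumes:

* spatially coherent tissue-label grids — an elliptical tumor core inside a
  normal-liver field, a fibrosis band at the tumor margin and/or inside the
  core, necrosis blobs in the core with a per-patient target area fraction,
  and scattered minor components (lymphocytes, hemorrhage, debris);
* procedural H&E-like RGB tiles whose nuclear texture (blob density,
  staining-intensity ceiling, shape dispersion) increases monotonically with
  a latent malignancy level for tumor-category tiles;
* survival outcomes drawn from a proportional-hazards model whose log-hazard
  is a known linear function of the slide's structural parameters
  (necrosis ratio, interior fibrosis, margin fibrosis) and, optionally, the
  latent malignancy.

Everything is deterministic given ``rng_seed``: per-patient streams are
spawned as ``default_rng([rng_seed, patient_index, stream_tag])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .categories import (BACKGROUND, DEBRIS, FIBROSIS, HEMORRHAGE, LYMPHOCYTE,
                         N_CATEGORIES, NECROSIS, NORMAL, TUMOR)
from .tissue_map import TissueLabelGrid

__all__ = [
    "SyntheticCohortConfig", "GroundTruth", "SyntheticCohort", "SizingError",
    "generate_label_grid", "generate_tile", "TileProvider", "OracleClassifier",
    "generate_survival", "generate_cohort", "nuclear_stain_intensity",
]

# default hazard coefficients: Table-like sign pattern (+, +, -) on the
# fraction scale, magnitudes chosen for realistic hazard ratios across the
# observed parameter ranges
_DEFAULT_COEFFS = {"n_ratio": 2.4, "fib_center": 1.4, "fib_edge": -2.5}


class SizingError(ValueError):
    """Grid too small to place the tumor core."""


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    ``hazard_coefficients`` maps structural-parameter names (``n_ratio``,
    ``fib_center``, ``fib_edge``, optionally ``malignancy``) to log-hazard
    weights. ``baseline_hazard`` is in events per month; with the default
    0.02 the median event time is roughly three years, matching long-term
    hepatocellular-carcinoma follow-up.
    """

    n_patients: int = 200
    grid_height: int = 64
    grid_width: int = 64
    category_count: int = 8
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFS))
    censoring_rate: float = 0.3
    baseline_hazard: float = 0.02
    rng_seed: int = 0
    tile_size: int = 224
    # latent distributions (chosen once; see docs/methods.md)
    necrosis_beta: tuple[float, float] = (2.0, 8.0)  # mean 0.2, sd 0.12
    necrosis_target: float | None = None             # fixed fraction overrides the Beta
    fibrosis_edge_range: tuple[float, float] = (0.05, 0.9)
    fibrosis_center_range: tuple[float, float] = (0.0, 0.5)
    band_thickness: int = 6                          # grid cells
    event_time_dist: str = "exponential"             # or "weibull"
    weibull_shape: float = 1.0

    def __post_init__(self):
        if self.category_count != N_CATEGORIES:
            raise ValueError("category_count is fixed at 8")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if min(self.grid_height, self.grid_width) < 16:
            raise SizingError("grid dimensions must be at least 16 cells")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not all(np.isfinite(list(self.hazard_coefficients.values()) or [0.0])):
            raise ValueError("hazard_coefficients must be finite")


@dataclass
class GroundTruth:
    """Per-patient generative truth.

    ``log_hazard`` always equals the dot product of the configured hazard
    coefficients with ``params`` (plus the malignancy term when configured).
    """

    patient_id: int
    params: dict[str, float]       # n_ratio, fib_center, fib_edge in [0, 1]
    malignancy: float              # latent in [0, 1]
    log_hazard: float


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    truths: list[GroundTruth]
    survival: pd.DataFrame                       # patient_id, time, event
    grids: list[TissueLabelGrid] | None = None

    def tile_provider(self, patient_index: int) -> "TileProvider":
        if self.grids is None:
            raise ValueError("cohort was generated without grids")
        return TileProvider(self.grids[patient_index],
                            self.truths[patient_index].malignancy,
                            rng_seed=self.config.rng_seed,
                            patient_index=patient_index,
                            tile_size=self.config.tile_size)


def _rng(config: SyntheticCohortConfig, patient_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, patient_index, tag])


@dataclass
class _Latents:
    necrosis_target: float
    p_edge: float
    p_center: float
    malignancy: float


def _draw_latents(config: SyntheticCohortConfig, i: int) -> _Latents:
    rng = _rng(config, i, 0)
    if config.necrosis_target is not None:
        nec = float(config.necrosis_target)
    else:
        a, b = config.necrosis_beta
        nec = float(rng.beta(a, b))
    lo, hi = config.fibrosis_edge_range
    p_edge = float(rng.uniform(lo, hi))
    lo, hi = config.fibrosis_center_range
    p_center = float(rng.uniform(lo, hi))
    mal = float(rng.uniform(0.0, 1.0))
    return _Latents(nec, p_edge, p_center, mal)


def _ellipse_mask(shape, center, axes, rng=None, jitter=0.0) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    d = ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2
    if jitter and rng is not None:
        d = d + rng.normal(0, jitter, size=d.shape)
    return d <= 1.0


def generate_label_grid(config: SyntheticCohortConfig, patient_index: int
                        ) -> tuple[TissueLabelGrid, dict[str, float], _Latents]:
    """Render one patient's label grid; returns (grid, true params, latents).

    True structural parameters are measured against the generator's exact
    tumor-core ellipse (not a morphological estimate), so downstream
    estimators can be validated against them. Deterministic given
    (rng_seed, patient_index).
    """
    if patient_index >= config.n_patients:
        raise IndexError("patient_index out of range")
    lat = _draw_latents(config, patient_index)
    rng = _rng(config, patient_index, 1)
    h, w = config.grid_height, config.grid_width

    # tissue ellipse (slightly jittered boundary), outside = background
    tissue = _ellipse_mask(
        (h, w), ((h - 1) / 2 + rng.normal(0, h * 0.02), (w - 1) / 2 + rng.normal(0, w * 0.02)),
        (h * 0.47, w * 0.47), rng, jitter=0.05)
    labels = np.full((h, w), BACKGROUND, dtype=np.int64)
    labels[tissue] = NORMAL

    # minor components sprinkled through the normal field (~5% of tissue)
    for cat, frac in ((LYMPHOCYTE, 0.02), (HEMORRHAGE, 0.02), (DEBRIS, 0.01)):
        cand = np.argwhere(tissue & (labels == NORMAL))
        k = int(round(frac * tissue.sum()))
        if k and len(cand):
            pick = cand[rng.choice(len(cand), size=min(k, len(cand)), replace=False)]
            labels[pick[:, 0], pick[:, 1]] = cat

    # tumor core ellipse
    ay = rng.uniform(0.22, 0.34) * h
    ax = rng.uniform(0.22, 0.34) * w
    if min(ay, ax) < 3.0:
        raise SizingError("grid too small to place a tumor core")
    cy = (h - 1) / 2 + rng.normal(0, h * 0.04)
    cx = (w - 1) / 2 + rng.normal(0, w * 0.04)
    core = _ellipse_mask((h, w), (cy, cx), (ay, ax)) & tissue
    if core.sum() < 9:
        raise SizingError("tumor core does not fit inside the tissue region")
    labels[core] = TUMOR

    # margin band and interior from the exact core geometry
    half = max(1, config.band_thickness // 2)
    dist_out = ndimage.distance_transform_edt(~core)
    dist_in = ndimage.distance_transform_edt(core)
    outer_ring = (~core) & (dist_out <= half) & tissue
    inner_ring = core & (dist_in <= half)
    band = outer_ring | inner_ring
    interior = core & ~inner_ring

    # fibrosis: Bernoulli per cell at the latent band/interior probabilities
    for region, p in ((band, lat.p_edge), (interior, lat.p_center)):
        cells = np.argwhere(region)
        if len(cells) and p > 0:
            hit = rng.random(len(cells)) < p
            sel = cells[hit]
            labels[sel[:, 0], sel[:, 1]] = FIBROSIS

    # necrosis blobs grown inside the interior until the target fraction of
    # ALL tissue cells is necrotic (may overwrite tumor/fibrosis there)
    n_tissue = int(tissue.sum())
    target_cells = int(round(lat.necrosis_target * n_tissue))
    target_cells = min(target_cells, int(interior.sum()))
    if target_cells > 0:
        nec = np.zeros((h, w), dtype=bool)
        inter_cells = np.argwhere(interior)
        n_seeds = max(1, target_cells // 40)
        seeds = inter_cells[rng.choice(len(inter_cells), size=n_seeds, replace=False)]
        nec[seeds[:, 0], seeds[:, 1]] = True
        struct = ndimage.generate_binary_structure(2, 1)
        while nec.sum() < target_cells:
            grown = ndimage.binary_dilation(nec, structure=struct) & interior
            added = np.argwhere(grown & ~nec)
            need = target_cells - int(nec.sum())
            if len(added) == 0:  # interior exhausted
                break
            if len(added) > need:
                added = added[rng.choice(len(added), size=need, replace=False)]
            nec[added[:, 0], added[:, 1]] = True
        labels[nec] = NECROSIS

    grid = TissueLabelGrid(labels=labels, mask=tissue,
                           patch_size_px=(config.tile_size, config.tile_size))

    # realized structural parameters against the exact geometry
    fib = labels == FIBROSIS
    params = {
        "n_ratio": float((labels == NECROSIS).sum()) / n_tissue,
        "fib_center": float(fib[interior].sum()) / max(int(interior.sum()), 1),
        "fib_edge": float(fib[band].sum()) / max(int(band.sum()), 1),
    }
    return grid, params, lat


# ---------------------------------------------------------------------------
# procedural tiles

_BASE_COLORS = {
    TUMOR: (0.78, 0.62, 0.74),
    NECROSIS: (0.86, 0.72, 0.66),
    FIBROSIS: (0.90, 0.70, 0.80),
    LYMPHOCYTE: (0.55, 0.45, 0.70),
    NORMAL: (0.85, 0.68, 0.78),
    HEMORRHAGE: (0.75, 0.40, 0.45),
    DEBRIS: (0.80, 0.75, 0.72),
    BACKGROUND: (0.97, 0.97, 0.97),
}

# nuclei per (32x32-equivalent) tile area at malignancy 0, by category
_BASE_DENSITY = {
    TUMOR: 6.0, NECROSIS: 1.0, FIBROSIS: 3.0, LYMPHOCYTE: 14.0,
    NORMAL: 6.0, HEMORRHAGE: 2.0, DEBRIS: 1.5, BACKGROUND: 0.0,
}


def generate_tile(category: int, malignancy: float, tile_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """One procedural RGB tile, float64 in [0, 1], shape (S, S, 3).

    For tumor tiles, nucleus count, staining depth ceiling and nuclear shape
    dispersion all increase monotonically with ``malignancy``; other
    categories ignore it. Nuclei are dark elliptical blobs on a category-
    colored background — sufficient to carry texture and intensity signal,
    not photorealistic H&E.
    """
    if not (0.0 <= malignancy <= 1.0):
        raise ValueError("malignancy must lie in [0, 1]")
    s = tile_size
    base = np.array(_BASE_COLORS[category])
    tile = np.clip(base[None, None, :] + rng.normal(0, 0.02, size=(s, s, 3)), 0, 1)

    area_scale = (s / 32.0) ** 2
    dens = _BASE_DENSITY[category]
    if category == TUMOR:
        dens = dens * (1.0 + 2.0 * malignancy)
        depth = 0.45 + 0.45 * malignancy        # staining-intensity ceiling
        ecc_spread = 0.15 + 0.55 * malignancy   # shape dispersion
        size_spread = 0.2 + 0.6 * malignancy
    else:
        depth, ecc_spread, size_spread = 0.45, 0.15, 0.2
    n_nuclei = rng.poisson(dens * area_scale)
    yy, xx = np.mgrid[0:s, 0:s]
    stain = np.zeros((s, s))
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, s, size=2)
        r0 = max(1.2, s / 16.0) * np.exp(rng.normal(0, size_spread))
        ecc = np.clip(1.0 + rng.normal(0, ecc_spread), 0.4, 2.5)
        th = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(th) + dx * np.sin(th)
        v = -dy * np.sin(th) + dx * np.cos(th)
        d2 = (u / (r0 * ecc)) ** 2 + (v / (r0 / ecc)) ** 2
        amp = depth * rng.uniform(0.7, 1.0)
        stain = np.maximum(stain, amp * np.exp(-0.5 * d2 * 4.0) * (d2 <= 1.5))
    # hematoxylin-like: darken toward blue-purple where stain is high
    nucleus_color = np.array([0.25, 0.20, 0.50])
    tile = tile * (1 - stain[:, :, None]) + nucleus_color[None, None, :] * stain[:, :, None]
    return np.clip(tile, 0.0, 1.0)


def nuclear_stain_intensity(tile: np.ndarray) -> float:
    """Mean nuclear-stain proxy: 1 - grayscale (darker nuclei score higher)."""
    return float((1.0 - np.asarray(tile).mean(axis=2)).mean())


class TileProvider:
    """Lazy per-cell tile factory for one patient's grid.

    Tiles are deterministic given (rng_seed, patient_index, row, col);
    requesting a masked-out cell raises ``KeyError``.
    """

    def __init__(self, grid: TissueLabelGrid, malignancy: float,
                 rng_seed: int = 0, patient_index: int = 0, tile_size: int = 224):
        self.grid = grid
        self.malignancy = float(malignancy)
        self.rng_seed = rng_seed
        self.patient_index = patient_index
        self.tile_size = tile_size

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def __call__(self, row: int, col: int) -> np.ndarray:
        if not self.grid.mask[row, col]:
            raise KeyError(f"cell ({row}, {col}) is masked out")
        rng = np.random.default_rng(
            [self.rng_seed, self.patient_index, 7, int(row), int(col)])
        return generate_tile(int(self.grid.labels[row, col]), self.malignancy,
                             self.tile_size, rng)


class OracleClassifier:
    """Patch classifier that knows the generator's true labels.

    With ``flip_rate`` > 0 a cell's returned distribution is, with that
    probability, a one-hot on a uniformly chosen wrong category — a stand-in
    for an imperfect pre-trained tissue classifier. Tiles are matched to
    cells by procedural fingerprint-free lookup: the classifier is
    constructed per patient and queried through ``classify_cell``.
    """

    def __init__(self, grid: TissueLabelGrid, flip_rate: float = 0.0, seed: int = 0):
        self.grid = grid
        self.flip_rate = flip_rate
        self._rng = np.random.default_rng(seed)

    def probabilities_for(self, row: int, col: int) -> np.ndarray:
        true = int(self.grid.labels[row, col])
        lab = true
        if self.flip_rate and self._rng.random() < self.flip_rate:
            lab = int(self._rng.integers(0, N_CATEGORIES - 1))
            if lab >= true:
                lab += 1
        p = np.zeros(N_CATEGORIES)
        p[lab] = 1.0
        return p

    def as_cell_classifier(self):
        """Adapter matching the (tile_provider, classifier) calling pattern
        by caching position: returns an object whose ``classify`` consumes
        tiles produced by a position-tagging provider."""
        return _CellOracle(self)


class _CellOracle:
    def __init__(self, oracle: OracleClassifier):
        self.oracle = oracle
        self._queue: list[tuple[int, int]] = []

    def provider(self, row: int, col: int) -> np.ndarray:
        self._queue.append((row, col))
        return np.empty(0)

    def classify(self, tile: np.ndarray) -> np.ndarray:
        row, col = self._queue.pop(0)
        return self.oracle.probabilities_for(row, col)


# ---------------------------------------------------------------------------
# survival

def _log_hazard(config: SyntheticCohortConfig, params: dict[str, float],
                malignancy: float) -> float:
    values = dict(params)
    values["malignancy"] = malignancy
    return float(sum(coef * values[name]
                     for name, coef in config.hazard_coefficients.items()))


def _calibrate_censoring_rate(config: SyntheticCohortConfig,
                              n_pilot: int = 10_000) -> float:
    """Exponential censoring rate matched so P(C < T) ~= censoring_rate.

    Quantile matching on a pilot draw of patient rates: with independent
    exponential censoring at rate c, P(censored | lambda) = c / (c + lambda);
    bisection on the pilot average closes the loop without simulation noise.
    """
    if config.censoring_rate == 0:
        return 0.0
    rng = np.random.default_rng([config.rng_seed, 1 << 20])
    a, b = config.necrosis_beta
    lam = np.empty(n_pilot)
    lo_e, hi_e = config.fibrosis_edge_range
    lo_c, hi_c = config.fibrosis_center_range
    for i in range(n_pilot):
        nec = config.necrosis_target if config.necrosis_target is not None \
            else rng.beta(a, b)
        params = {"n_ratio": nec,
                  "fib_center": rng.uniform(lo_c, hi_c),
                  "fib_edge": rng.uniform(lo_e, hi_e)}
        lam[i] = config.baseline_hazard * np.exp(
            _log_hazard(config, params, rng.uniform()))

    def frac_censored(c):
        return float(np.mean(c / (c + lam)))

    lo, hi = 1e-12, float(lam.mean())
    while frac_censored(hi) < config.censoring_rate:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac_censored(mid) < config.censoring_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_survival(truths: list[GroundTruth],
                      config: SyntheticCohortConfig) -> pd.DataFrame:
    """Observed times and event indicators under proportional hazards.

    Event times are exponential (or Weibull) with rate
    ``baseline_hazard * exp(log_hazard)``; censoring times are independent
    exponentials whose rate is calibrated on a 10,000-draw pilot so the
    realized censoring fraction approximates ``censoring_rate``.
    """
    c_rate = _calibrate_censoring_rate(config)
    rows = []
    for truth in truths:
        rng = _rng(config, truth.patient_id, 2)
        lam = config.baseline_hazard * np.exp(truth.log_hazard)
        u = rng.uniform()
        t_event = -np.log(u) / lam
        if config.event_time_dist == "weibull":
            t_event = (-np.log(u) / lam) ** (1.0 / config.weibull_shape)
        if c_rate > 0:
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = np.inf
        t = min(t_event, t_cens)
        rows.append({"patient_id": truth.patient_id,
                     "time": float(max(t, 1e-9)),
                     "event": int(t_event <= t_cens),
                     "log_hazard": truth.log_hazard})
    return pd.DataFrame(rows)


def generate_cohort(config: SyntheticCohortConfig,
                    render_grids: bool = True) -> SyntheticCohort:
    """Full synthetic cohort: truths, survival table and (optionally) grids.

    With ``render_grids=False`` the structural parameters are the latent
    targets themselves (no rendering) — handy for survival-only studies.
    """
    truths: list[GroundTruth] = []
    grids: list[TissueLabelGrid] | None = [] if render_grids else None
    for i in range(config.n_patients):
        if render_grids:
            grid, params, lat = generate_label_grid(config, i)
            grids.append(grid)
        else:
            lat = _draw_latents(config, i)
            params = {"n_ratio": lat.necrosis_target,
                      "fib_center": lat.p_center,
                      "fib_edge": lat.p_edge}
        truths.append(GroundTruth(
            patient_id=i, params=params, malignancy=lat.malignancy,
            log_hazard=_log_hazard(config, params, lat.malignancy)))
    survival = generate_survival(truths, config)
    return SyntheticCohort(config=config, truths=truths, survival=survival,
                           grids=grids)
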