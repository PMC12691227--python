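"""Interpretability: what drives the macro and micro risk scores.

Macro side
----------
* Occlusion sensitivity: slide a window over the tissue-organization map,
  zero the channels inside it (zero = "no tissue" in one-hot maps, the
  natural ablation), and record the risk change. Map value =
  risk(original) - risk(occluded), so positive cells are risk-elevating.
* Structural parameters per slide: necrosis fraction of tissue (N-ratio),
  fibrosis fraction in the tumor interior (FIB-center) and in a fixed-
  thickness band at the tumor margin (FIB-edge), with the margin defined by
  a distance transform of the tumor support.
* A multivariable proportional-hazards fit of survival on the three
  parameters validates the occlusion patterns statistically.

Micro side
----------
* A compact nuclear-morphometry extractor (threshold + watershed
  segmentation; shape, intensity and GLCM texture families, aggregated as
  mean/median/SD per tile) whose feature tables are round-trippable with
  externally produced morphometry CSV exports.
* Dual-criterion feature selection: features with a nonzero Lasso
  coefficient at the cross-validated penalty AND a Benjamini-Hochberg-
  adjusted Mann-Whitney p-value below alpha, taking the intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import ndimage, stats
from skimage.feature import graycomatrix, peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.segmentation import watershed
from sklearn.linear_model import LassoCV
from statsmodels.stats.multitest import multipletests

from .categories import FIBROSIS, NECROSIS, TUMOR
from .tissue_map import TissueLabelGrid, TissueMap

__all__ = [
    "OcclusionMap", "StructuralParams", "occlusion_map", "structural_params",
    "structural_cox", "extract_nuclear_features", "dual_criterion_select",
    "risk_extremes",
]


# ---------------------------------------------------------------------------
# occlusion sensitivity

@dataclass
class OcclusionMap:
    """Per-cell risk attribution aligned to the map's spatial grid.

    ``values[r, c]`` averages risk(original) - risk(occluded) over every
    window that covered the cell; cells never occluded stay exactly zero.
    """

    values: np.ndarray
    window: int
    stride: int
    baseline_risk: float


def occlusion_map(risk_fn, tm: TissueMap, window: int = 16, stride: int = 8,
                  fill: float = 0.0) -> OcclusionMap:
    """Occlusion sensitivity of ``risk_fn`` over the tissue map.

    ``risk_fn`` maps a (H, W, 8) channel array to a scalar risk. All eight
    channels inside each window are set to ``fill`` (default zero). Windows
    are anchored every ``stride`` cells and clipped at the borders so the
    whole grid is covered.
    """
    h, w = tm.shape
    if window > min(h, w):
        raise ValueError("occlusion window larger than the grid")
    base = float(risk_fn(tm.channels))
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    rows = list(range(0, max(h - window, 0) + 1, stride))
    cols = list(range(0, max(w - window, 0) + 1, stride))
    if rows[-1] != h - window:
        rows.append(h - window)
    if cols[-1] != w - window:
        cols.append(w - window)
    for r0 in rows:
        for c0 in cols:
            occluded = tm.channels.copy()
            occluded[r0:r0 + window, c0:c0 + window, :] = fill
            delta = base - float(risk_fn(occluded))
            acc[r0:r0 + window, c0:c0 + window] += delta
            cnt[r0:r0 + window, c0:c0 + window] += 1
    values = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return OcclusionMap(values=values, window=window, stride=stride,
                        baseline_risk=base)


# ---------------------------------------------------------------------------
# structural parameters

@dataclass
class StructuralParams:
    """Slide-level region fractions, all in [0, 1].

    ``n_ratio``: necrosis cells / all tissue cells. ``fib_center``:
    fibrosis fraction of the tumor interior. ``fib_edge``: fibrosis
    fraction of the margin band (inner + outer ring of ``band_thickness``
    total width around the tumor-support boundary). Interior and margin
    are disjoint by construction.
    """

    n_ratio: float
    fib_center: float
    fib_edge: float
    band_thickness: int

    def as_dict(self) -> dict[str, float]:
        return {"n_ratio": self.n_ratio, "fib_center": self.fib_center,
                "fib_edge": self.fib_edge}


class NoTumorError(ValueError):
    pass


def structural_params(grid: TissueLabelGrid, band_thickness: int = 10
                      ) -> StructuralParams:
    """Estimate N-ratio / FIB-center / FIB-edge from a label grid.

    Tumor support = tumor-labeled cells after morphological closing and
    hole filling (enclosed necrosis/fibrosis counts as part of the tumor
    when locating the margin). The margin band collects cells within
    ``band_thickness / 2`` of the support boundary on each side (outside
    ring restricted to tissue); the interior is the support minus the inner
    ring.
    """
    tumor = grid.mask & (grid.labels == TUMOR)
    if not tumor.any():
        raise NoTumorError("no tumor cells on the slide")
    support = _closing(tumor, footprint=disk(2))
    support = ndimage.binary_fill_holes(support)
    half = max(1, band_thickness // 2)
    dist_out = ndimage.distance_transform_edt(~support)
    dist_in = ndimage.distance_transform_edt(support)
    outer = (~support) & (dist_out <= half) & grid.mask
    inner = support & (dist_in <= half)
    band = outer | inner
    interior = support & ~inner & grid.mask

    fib = grid.mask & (grid.labels == FIBROSIS)
    nec = grid.mask & (grid.labels == NECROSIS)
    n_tissue = grid.n_tissue_cells
    return StructuralParams(
        n_ratio=float(nec.sum()) / n_tissue,
        fib_center=float(fib[interior].sum()) / max(int(interior.sum()), 1),
        fib_edge=float(fib[band].sum()) / max(int(band.sum()), 1),
        band_thickness=band_thickness,
    )


def structural_cox(params: pd.DataFrame, times, events) -> pd.DataFrame:
    """Multivariable proportional-hazards fit on the structural parameters.

    ``params``: one row per patient, columns are the covariates. Returns a
    table with Coef, Se_Coef, HR, CI_Lower, CI_Upper, p_Value per covariate
    (established Newton-Raphson solver behind the scenes).
    """
    df = params.copy()
    df["time"] = np.asarray(times, dtype=np.float64)
    df["event"] = np.asarray(events, dtype=np.int64)
    if df["event"].sum() < 1 or len(df) < 30:
        raise ValueError("need at least 30 patients with events")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # pragma: no cover - diagnostics path
        x = df.drop(columns=["time", "event"]).to_numpy()
        cond = np.linalg.cond(np.cov(x, rowvar=False))
        raise RuntimeError(
            f"proportional-hazards fit failed (design condition number "
            f"{cond:.3g}): {exc}") from exc
    summ = cph.summary
    return pd.DataFrame({
        "Covariate": summ.index,
        "Coef": summ["coef"].to_numpy(),
        "Se_Coef": summ["se(coef)"].to_numpy(),
        "HR": summ["exp(coef)"].to_numpy(),
        "CI_Lower": summ["exp(coef) lower 95%"].to_numpy(),
        "CI_Upper": summ["exp(coef) upper 95%"].to_numpy(),
        "p_Value": summ["p"].to_numpy(),
    }).reset_index(drop=True)


# ---------------------------------------------------------------------------
# nuclear morphometrics

def _glcm_stats(patch_u8: np.ndarray) -> tuple[float, float]:
    """(variance, angular second moment) of the gray-level co-occurrence
    matrix at distance 1, averaged over 4 directions, 32 gray levels."""
    q = (patch_u8 // 8).astype(np.uint8)  # 256 -> 32 levels
    glcm = graycomatrix(q, distances=[1],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=32, symmetric=True, normed=True)
    p = glcm[:, :, 0, :].mean(axis=2)
    i = np.arange(32)[:, None]
    mu = float((p * i).sum())
    var = float((p * (i - mu) ** 2).sum())
    asm = float((p ** 2).sum())
    return var, asm


def _segment_nuclei(stain: np.ndarray, min_area: int = 4) -> np.ndarray:
    """Label image of nuclei from a stain-intensity channel in [0, 1].

    Otsu-like fixed-fraction threshold, small-object removal, watershed
    split on the distance transform to separate touching nuclei.
    """
    thr = stain.mean() + 0.5 * stain.std()
    fg = stain > max(thr, 0.15)
    if not fg.any():
        return np.zeros(stain.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(dist, min_distance=2, labels=fg)
    if len(peaks) == 0:
        return cc_label(fg)
    markers = np.zeros(stain.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    lab = watershed(-dist, markers, mask=fg)
    # drop specks
    for r in regionprops(lab):
        if r.area < min_area:
            lab[lab == r.label] = 0
    return lab


_MEASURES = ("area", "perimeter", "orientation", "eccentricity", "extent",
             "max_intensity", "mean_intensity", "glcm_variance", "glcm_asm")
_AGGS = ("mean", "median", "std")


def extract_nuclear_features(tile: np.ndarray) -> dict[str, float]:
    """Per-tile nuclear morphometry row.

    Nuclei are segmented on the stain-intensity proxy (1 - grayscale);
    per-nucleus measures cover shape (area, perimeter, orientation,
    eccentricity, extent = area / bounding-box area), staining intensity
    (max, mean) and GLCM texture (variance, angular second moment); the
    tile row aggregates each as mean, median and SD. A tile with zero
    detected nuclei returns an all-NaN row flagged for cleaning.
    """
    tile = np.asarray(tile, dtype=np.float64)
    stain = 1.0 - tile.mean(axis=2)
    stain = stain - stain.min()
    lab = _segment_nuclei(stain)
    props = regionprops(lab, intensity_image=stain)
    row = {f"{m}_{a}": np.nan for m in _MEASURES for a in _AGGS}
    row["n_nuclei"] = float(len(props))
    if not props:
        return row
    stain_u8 = np.clip(stain * 255, 0, 255).astype(np.uint8)
    per_nucleus = {m: [] for m in _MEASURES}
    for p in props:
        per_nucleus["area"].append(p.area)
        per_nucleus["perimeter"].append(p.perimeter)
        per_nucleus["orientation"].append(p.orientation)
        per_nucleus["eccentricity"].append(p.eccentricity)
        per_nucleus["extent"].append(p.extent)
        per_nucleus["max_intensity"].append(p.intensity_max)
        per_nucleus["mean_intensity"].append(p.intensity_mean)
        r0, c0, r1, c1 = p.bbox
        var, asm = _glcm_stats(stain_u8[r0:r1, c0:c1])
        per_nucleus["glcm_variance"].append(var)
        per_nucleus["glcm_asm"].append(asm)
    for m, vals in per_nucleus.items():
        v = np.asarray(vals, dtype=np.float64)
        row[f"{m}_mean"] = float(v.mean())
        row[f"{m}_median"] = float(np.median(v))
        row[f"{m}_std"] = float(v.std(ddof=0))
    return row


# ---------------------------------------------------------------------------
# dual-criterion feature selection

def dual_criterion_select(table: pd.DataFrame, group_col: str = "group",
                          alpha: float = 0.05, cv: int = 5,
                          seed: int = 0) -> pd.DataFrame:
    """Features selected by both Lasso and Mann-Whitney criteria.

    Criterion 1: nonzero coefficient in a Lasso regression of the binary
    group label (high_risk = 1) on the standardized features, at the
    cross-validated penalty. Criterion 2: Benjamini-Hochberg-adjusted
    Mann-Whitney p < alpha. The result is their intersection, with the
    Lasso coefficient and adjusted p-value per selected feature; an empty
    intersection returns an empty table with a warning, not an error.
    """
    groups = table[group_col]
    if set(groups.unique()) - {"high_risk", "low_risk"}:
        raise ValueError("group labels must be 'high_risk'/'low_risk'")
    feats = table.drop(columns=[group_col]).dropna(axis=1, how="any")
    names = list(feats.columns)
    x = feats.to_numpy(dtype=np.float64)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    names = [n for n, k in zip(names, keep) if k]
    y = (groups == "high_risk").to_numpy(dtype=np.float64)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 tiles per group")

    lasso = LassoCV(cv=cv, random_state=seed, alphas=50, max_iter=5000)
    lasso.fit(x, y)
    coefs = dict(zip(names, lasso.coef_))
    lasso_set = {n for n, c in coefs.items() if c != 0.0}

    pvals = []
    for j in range(x.shape[1]):
        _, p = stats.mannwhitneyu(x[y == 1, j], x[y == 0, j],
                                  alternative="two-sided")
        pvals.append(p)
    _, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    mw_set = {n for n, p in zip(names, p_adj) if p < alpha}

    selected = sorted(lasso_set & mw_set)
    if not selected:
        warnings.warn("dual-criterion selection is empty", RuntimeWarning)
    padj = dict(zip(names, p_adj))
    return pd.DataFrame({
        "feature": selected,
        "lasso_coef": [coefs[n] for n in selected],
        "mw_p_adjusted": [padj[n] for n in selected],
    })


def risk_extremes(risks, fraction: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the top and bottom ``fraction`` of patients by risk.

    The top fraction is labeled high-risk, the bottom low-risk; ties are
    broken by stable sort order. ``fraction = 0.5`` is a median split.
    """
    r = np.asarray(risks, dtype=np.float64)
    k = int(round(fraction * len(r)))
    if k == 0:
        raise ValueError("fraction yields an empty extreme set")
    order = np.argsort(r, kind="stable")
    return order[-k:][::-1], order[:k]
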