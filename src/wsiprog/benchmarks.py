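"""Canonical synthetic validation studies.

Each function runs one self-contained study on generated cohorts with known
ground truth and returns the measured quantities. The study conditions
(cohort sizes, planted effect sizes, training protocol for the tiny
backbone) are fixed here as the package's reference benchmark settings —
see docs/methods.md for the rationale behind each choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categories import N_CATEGORIES, NECROSIS, NORMAL
from .interpret import dual_criterion_select, occlusion_map, structural_cox
from .models import EncoderSpec, MacroNet
from .sampling import allocate
from .survival import (TrainConfig, concordance, cox_loss, cross_validate,
                       train_branch)
from .synthetic import SyntheticCohortConfig, generate_cohort
from .tissue_map import build_tissue_map, resize_tissue_map, stack_maps

__all__ = [
    "apportionment_oracle", "allocation_oracle_study", "random_score_c_index",
    "sign_recovery_study", "learnability_study", "null_calibration_study",
    "feature_selection_study",
]


def apportionment_oracle(proportions, n_total, availability) -> np.ndarray:
    """Exact minimizer of sum_z |n_z - r_z * N| s.t. sum n_z = N, n_z <= a_z.

    Greedy one-slot-at-a-time assignment: the marginal cost
    |n+1 - q| - |n - q| of adding a slot to a category is non-decreasing in
    n (the per-category objective is convex), so greedily taking the
    cheapest marginal slot is exact for this separable convex program —
    an independent construction against which the largest-remainder
    allocator can be checked.
    """
    r = np.asarray(proportions, dtype=np.float64)
    q = r * n_total
    avail = np.asarray(availability, dtype=np.int64)
    n = np.zeros(N_CATEGORIES, dtype=np.int64)
    for _ in range(n_total):
        best, best_cost = -1, np.inf
        for z in range(N_CATEGORIES):
            if n[z] >= avail[z]:
                continue
            cost = abs(n[z] + 1 - q[z]) - abs(n[z] - q[z])
            if cost < best_cost - 1e-12:
                best, best_cost = z, cost
        n[best] += 1
    return n


def allocation_oracle_study(seed: int, n_instances: int = 200,
                            n_total: int = 27) -> dict:
    """Fraction of random instances where the allocator attains the oracle's
    optimal total deviation (multiple optima are common, so objective values
    are compared) while satisfying the budget and availability constraints."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        r = rng.dirichlet(np.full(N_CATEGORIES, rng.uniform(0.2, 2.0)))
        avail = rng.integers(0, 41, size=N_CATEGORIES)
        while avail.sum() < n_total:
            avail = rng.integers(0, 41, size=N_CATEGORIES)
        n = allocate(r, n_total, avail)
        m = apportionment_oracle(r, n_total, avail)
        ok = (n.sum() == n_total and (n <= avail).all()
              and abs(np.abs(n - r * n_total).sum()
                      - np.abs(m - r * n_total).sum()) < 1e-9)
        agree += ok
    return {"agreement_rate": agree / n_instances, "n": n_instances}


def random_score_c_index(seed: int, n: int = 1000) -> dict:
    """C-index of pure-noise risk scores on a censored cohort (null ~ 0.5)."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(10.0, size=n)
    d = (rng.random(n) < 0.7).astype(int)
    c = concordance(t, d, rng.normal(size=n))
    return {"c_index": c, "n": n}


def cox_worked_example() -> float:
    """Hand-checkable partial likelihood: 3 patients, equal scores, all
    events at distinct times -> log 3 + log 2."""
    return cox_loss([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [1, 1, 1])


def sign_recovery_study(seed: int, n_repeats: int = 20,
                        n_patients: int = 1000) -> dict:
    """Fraction of replicate cohorts where a multivariable proportional-
    hazards fit on the true structural parameters recovers the planted
    coefficient sign pattern (+, +, -) for (N-ratio, FIB-center, FIB-edge)
    simultaneously."""
    ok = 0
    for rep in range(n_repeats):
        cfg = SyntheticCohortConfig(n_patients=n_patients,
                                    rng_seed=seed * 1000 + rep)
        coh = generate_cohort(cfg, render_grids=False)
        params = pd.DataFrame([tr.params for tr in coh.truths])
        tab = structural_cox(params, coh.survival["time"], coh.survival["event"])
        co = dict(zip(tab["Covariate"], tab["Coef"]))
        ok += int(co["n_ratio"] > 0 and co["fib_center"] > 0
                  and co["fib_edge"] < 0)
    return {"recovery_rate": ok / n_repeats, "n": n_repeats}


# reference settings for the tiny-backbone learnability benchmark: a strong
# single-factor hazard on the necrosis fraction (log-hazard sd ~ 1.6, oracle
# C-index ~ 0.75), no censoring, map input 32x32, Adam 1e-2 for 30 epochs
_LEARNABILITY = dict(n_patients=120, censoring_rate=0.0,
                     necrosis_beta=(2.0, 10.0),
                     hazard_coefficients={"n_ratio": 16.0})
_MAP_TARGET = 32


def _macro_inputs(cohort):
    return stack_maps([resize_tissue_map(build_tissue_map(g),
                                         (_MAP_TARGET, _MAP_TARGET))
                       for g in cohort.grids])


def learnability_study(seed: int, n_model_seeds: int = 3,
                       max_epochs: int = 30) -> dict:
    """Train the tiny macro branch on a necrosis-driven cohort.

    Returns the median (over model initializations) best validation C-index
    reached within ``max_epochs``, and the occlusion-map contrast between
    necrosis and normal cells of the first five slides under the best model.
    """
    cfg = SyntheticCohortConfig(rng_seed=seed, **_LEARNABILITY)
    coh = generate_cohort(cfg)
    x = _macro_inputs(coh)
    t = coh.survival["time"].to_numpy()
    d = coh.survival["event"].to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.permutation(cfg.n_patients)
    val_idx, train_idx = idx[:40], idx[40:]
    scores, best_model, best_c = [], None, -np.inf
    for k in range(n_model_seeds):
        net = MacroNet(EncoderSpec(backbone="tiny_test", in_channels=8),
                       seed=seed * 17 + k)
        tc = TrainConfig(learning_rate=1e-2, max_epochs=max_epochs,
                         seed=seed * 17 + k)
        hist = train_branch(net, x, t, d, tc, train_idx, val_idx)
        scores.append(hist["best_val_c_index"])
        if scores[-1] > best_c:
            best_c, best_model = scores[-1], net
    nec_vals, norm_vals = [], []
    for i in range(5):
        tm = resize_tissue_map(build_tissue_map(coh.grids[i]),
                               (_MAP_TARGET, _MAP_TARGET))
        om = occlusion_map(
            lambda ch: best_model.predict_risk(ch.transpose(2, 0, 1)[None])[0],
            tm, window=8, stride=4)
        labels = tm.argmax_grid()
        nec = labels.mask & (labels.labels == NECROSIS)
        norm = labels.mask & (labels.labels == NORMAL)
        nec_vals.append(om.values[nec])
        norm_vals.append(om.values[norm])
    return {
        "val_c_index": float(np.median(scores)),
        "val_c_index_all": scores,
        "occlusion_necrosis_mean": float(np.concatenate(nec_vals).mean()),
        "occlusion_normal_mean": float(np.concatenate(norm_vals).mean()),
        "n": cfg.n_patients,
    }


def null_calibration_study(seed: int, n_seeds: int = 5,
                           n_patients: int = 200, k: int = 5) -> dict:
    """Cross-validated C-index when the hazard is independent of the images
    (all hazard coefficients zero); pooled over cohort seeds, ~ 0.5."""
    means = []
    for s in range(n_seeds):
        cfg = SyntheticCohortConfig(n_patients=n_patients,
                                    rng_seed=seed * 100 + s,
                                    hazard_coefficients={},
                                    censoring_rate=0.2)
        coh = generate_cohort(cfg)
        x = _macro_inputs(coh)
        t = coh.survival["time"].to_numpy()
        d = coh.survival["event"].to_numpy()
        tc = TrainConfig(learning_rate=1e-2, max_epochs=8, seed=seed * 100 + s)
        folds = cross_validate(
            lambda fold: MacroNet(EncoderSpec(backbone="tiny_test",
                                              in_channels=8),
                                  seed=seed * 100 + s + fold),
            x, t, d, k=k, seed=seed * 100 + s, config=tc)
        means.append(float(np.mean([f.c_index for f in folds])))
    return {"c_index": float(np.mean(means)), "per_seed": means,
            "n": n_patients}


def feature_selection_study(seed: int, n_repeats: int = 50, n_tiles: int = 100,
                            n_features: int = 20) -> dict:
    """Planted-feature recovery and null behavior of the dual-criterion
    selector: one feature separates the groups by 2 SD, the rest are noise;
    the permuted-label control should select nothing."""
    rng = np.random.default_rng(seed)
    names = [f"feat_{j}" for j in range(n_features)]
    hits = exact = null_empty = 0
    half = n_tiles // 2
    y = np.array(["high_risk"] * half + ["low_risk"] * (n_tiles - half))
    for rep in range(n_repeats):
        x = rng.normal(size=(n_tiles, n_features))
        x[:half, 3] += 2.0
        df = pd.DataFrame(x, columns=names)
        df["group"] = y
        sel = list(dual_criterion_select(df, seed=seed + rep)["feature"])
        hits += int("feat_3" in sel)
        exact += int(sel == ["feat_3"])
        dfp = pd.DataFrame(rng.normal(size=(n_tiles, n_features)),
                           columns=names)
        dfp["group"] = rng.permutation(y)
        null_empty += int(len(dual_criterion_select(dfp, seed=seed + rep)) == 0)
    return {"planted_recovery_rate": hits / n_repeats,
            "planted_exact_rate": exact / n_repeats,
            "null_empty_rate": null_empty / n_repeats,
            "n": n_repeats}
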