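"""Cox training objective and the survival evaluation protocol.

The training objective is the negative log partial likelihood of the Cox
proportional-hazards model with Breslow handling of tied event times,

    L = - sum_{i: d_i = 1} [ s_i - log sum_{j: t_j >= t_i} exp(s_j) ],

where ``s`` are model risk scores, ``t`` observed times and ``d`` event
indicators. Evaluation covers Harrell's concordance index, the IPCW
integrated Brier score with Breslow-baseline survival curves, the IPCW
mean absolute error on normalized times, median-split Kaplan-Meier risk
stratification with a two-group log-rank test, and fold-level statistics
(t-based 95% intervals with df = folds - 1, paired t-tests, one-way
repeated-measures ANOVA) under stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from . import nn

__all__ = [
    "SurvivalRecord", "TrainConfig", "FoldResult", "NoEventsError",
    "NoComparablePairsError", "cox_loss", "cox_loss_grad", "concordance",
    "breslow_baseline", "predict_survival_matrix", "censoring_survival",
    "integrated_brier", "ipcw_mae", "predicted_median_times", "logrank",
    "stratify_km", "fold_summary", "paired_fold_tests",
    "repeated_measures_anova", "stratified_folds", "train_branch",
    "cross_validate",
]


class NoEventsError(ValueError):
    """A batch with zero events carries no partial-likelihood signal."""


class NoComparablePairsError(ValueError):
    pass


@dataclass
class SurvivalRecord:
    """One patient's follow-up: observed time (months), event flag, risk."""

    patient_id: int | str
    time: float
    event: int
    risk: float = np.nan

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("observed time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


def _as_arrays(times, events, scores=None):
    t = np.asarray(times, dtype=np.float64)
    d = np.asarray(events, dtype=np.int64)
    if scores is None:
        return t, d
    s = np.asarray(scores, dtype=np.float64)
    return t, d, s


# ---------------------------------------------------------------------------
# Cox partial likelihood

def _cox_terms(scores, times, events):
    t, d, s = _as_arrays(times, events, scores)
    if d.sum() == 0:
        raise NoEventsError("no events in batch")
    order = np.argsort(-t, kind="stable")  # descending time
    s_ord, t_ord, d_ord = s[order], t[order], d[order]
    smax = s_ord.max()
    exp_s = np.exp(s_ord - smax)
    cum = np.cumsum(exp_s)
    # Breslow ties: every member of a tie group shares the risk set
    # {j : t_j >= t_i}; extend the cumulative sum across equal times.
    log_den = np.empty_like(cum)
    i = 0
    n = len(t_ord)
    while i < n:
        j = i
        while j + 1 < n and t_ord[j + 1] == t_ord[i]:
            j += 1
        log_den[i:j + 1] = np.log(cum[j]) + smax
        i = j + 1
    return order, s_ord, d_ord, exp_s, cum, log_den, smax, t_ord


def cox_loss(scores, times, events) -> float:
    """Negative log partial likelihood (Breslow ties, stable log-sum-exp)."""
    _, s_ord, d_ord, _, _, log_den, _, _ = _cox_terms(scores, times, events)
    ev = d_ord == 1
    return float(-(s_ord[ev] - log_den[ev]).sum())


def cox_loss_grad(scores, times, events) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the risk scores.

    dL/ds_k = sum_{i events} exp(s_k) 1(t_k >= t_i) / sum_{j in R_i} exp(s_j)
              - d_k.
    """
    order, s_ord, d_ord, exp_s, cum, log_den, smax, t_ord = \
        _cox_terms(scores, times, events)
    n = len(s_ord)
    # events grouped by tie: each group at time t_g contributes mass
    # (#events at t_g) / denominator_g to every k with t_k >= t_g; in the
    # descending-time ordering those are positions 0..end-of-group, so a
    # reverse cumulative sum of per-group masses gives each position's total.
    acc = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_ord[j + 1] == t_ord[i]:
            j += 1
        n_ev = int(d_ord[i:j + 1].sum())
        if n_ev:
            acc[j] += n_ev / cum[j]
        i = j + 1
    mass = np.cumsum(acc[::-1])[::-1]  # positions k..end cover t_k >= t_group
    grad_ord = exp_s * mass - d_ord
    ev = d_ord == 1
    loss = float(-(s_ord[ev] - log_den[ev]).sum())
    grad = np.empty(n)
    grad[order] = grad_ord
    return loss, grad


# ---------------------------------------------------------------------------
# discrimination

def concordance(times, events, risks) -> float:
    """Harrell's C-index: higher risk should pair with shorter survival.

    Comparable pairs are those where the shorter observed time ends in an
    event; risk ties count 0.5. Raises when no pair is comparable.
    """
    t, d, r = _as_arrays(times, events, risks)
    # pair (i, j) comparable if t_i < t_j and d_i = 1 (and symmetric)
    ti = t[:, None]
    di = d[:, None]
    comparable = (ti < t[None, :]) & (di == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise NoComparablePairsError("no comparable pairs")
    ri = r[:, None]
    conc = comparable & (ri > r[None, :])
    ties = comparable & (ri == r[None, :])
    return float((conc.sum() + 0.5 * ties.sum()) / n_comp)


# ---------------------------------------------------------------------------
# survival-curve construction and calibration metrics

def breslow_baseline(times, events, scores) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard.

    Returns (event_times, H0) as a right-continuous step function:
    H0(t) = sum_{t_i <= t, d_i = 1} d_i / sum_{t_j >= t_i} exp(s_j).
    """
    t, d, s = _as_arrays(times, events, scores)
    order = np.argsort(t, kind="stable")
    t, d, s = t[order], d[order], s[order]
    exp_s = np.exp(s - s.max())
    rev_cum = np.cumsum(exp_s[::-1])[::-1] * np.exp(s.max())
    uniq = np.unique(t[d == 1])
    h0 = np.zeros(len(uniq))
    for k, tt in enumerate(uniq):
        at_risk = rev_cum[np.searchsorted(t, tt, side="left")]
        h0[k] = d[t == tt].sum() / at_risk
    return uniq, np.cumsum(h0)


def _step_eval(xs, ys, q, side="right"):
    """Right- (or left-) continuous step evaluation, 0-valued before xs[0]."""
    idx = np.searchsorted(xs, q, side=side)
    out = np.where(idx > 0, ys[np.maximum(idx - 1, 0)], 0.0)
    return out


def predict_survival_matrix(scores, baseline, grid) -> np.ndarray:
    """S_i(t) = exp(-H0(t) * exp(s_i)) on the time grid; shape (n, len(grid))."""
    bt, bh = baseline
    h0 = _step_eval(bt, bh, np.asarray(grid, dtype=np.float64))
    return np.exp(-np.outer(np.exp(np.asarray(scores, dtype=np.float64)), h0))


def censoring_survival(times, events) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier estimate G(t) of the censoring distribution.

    Censorings are the 'events' here; observed deaths are censorings of the
    censoring process. Returns a right-continuous step function (times, G).
    """
    t, d = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, c = t[order], 1 - d[order]
    uniq = np.unique(t)
    g = np.empty(len(uniq))
    surv = 1.0
    for k, tt in enumerate(uniq):
        at_risk = (t >= tt).sum()
        n_c = c[t == tt].sum()
        surv *= 1.0 - n_c / at_risk
        g[k] = surv
    return uniq, g


def _g_at(gfun, q, before=False):
    xs, ys = gfun
    side = "left" if before else "right"
    idx = np.searchsorted(xs, q, side=side)
    return np.where(idx > 0, ys[np.maximum(idx - 1, 0)], 1.0)


def integrated_brier(times, events, surv_matrix, grid) -> float:
    """IPCW-weighted Brier score integrated over the grid (trapezoid rule),
    normalized by the grid span.

    At each grid time t: events by t contribute S(t)^2 / G(t-); patients
    still under observation contribute (1 - S(t))^2 / G(t).
    """
    t, d = _as_arrays(times, events)
    grid = np.asarray(grid, dtype=np.float64)
    s_mat = np.asarray(surv_matrix, dtype=np.float64)
    gfun = censoring_survival(t, d)
    n = len(t)
    bs = np.empty(len(grid))
    g_tm = _g_at(gfun, t, before=True)
    for k, tau in enumerate(grid):
        had_event = (t <= tau) & (d == 1)
        at_risk = t > tau
        g_tau = float(_g_at(gfun, np.array([tau]))[0])
        if g_tau <= 0 or np.any(g_tm[had_event] <= 0):
            import warnings
            warnings.warn("censoring survival reaches zero inside the grid; "
                          "contributions truncated", RuntimeWarning)
        w_event = np.where(had_event & (g_tm > 0), 1.0 / np.maximum(g_tm, 1e-300), 0.0)
        w_risk = (1.0 / g_tau) if g_tau > 0 else 0.0
        sq = s_mat[:, k]
        bs[k] = (np.sum(w_event * sq ** 2)
                 + w_risk * np.sum((1.0 - sq[at_risk]) ** 2)) / n
    if len(grid) == 1:
        return float(bs[0])
    span = grid[-1] - grid[0]
    return float(np.trapezoid(bs, grid) / span)


def predicted_median_times(scores, baseline, horizon) -> np.ndarray:
    """Median of each predicted survival curve: first t with S(t) <= 0.5.

    Curves that never cross 0.5 before ``horizon`` are assigned the horizon.
    """
    bt, bh = baseline
    grid = np.unique(np.concatenate([bt, [horizon]]))
    s_mat = predict_survival_matrix(scores, baseline, grid)
    out = np.empty(len(s_mat))
    for i, row in enumerate(s_mat):
        idx = np.nonzero(row <= 0.5)[0]
        out[i] = grid[idx[0]] if len(idx) else horizon
    return out


def ipcw_mae(times, events, predicted_times, normalize: bool = True) -> float:
    """IPCW mean absolute error over events.

    w_i = 1 / G(t_i-) with G the censoring Kaplan-Meier; times are divided
    by the cohort's maximum follow-up first (so the score is scale-free),
    matching the convention of reporting errors on normalized time.
    """
    t, d = _as_arrays(times, events)
    pred = np.asarray(predicted_times, dtype=np.float64)
    scale = t.max() if normalize else 1.0
    gfun = censoring_survival(t, d)
    g_tm = _g_at(gfun, t, before=True)
    ev = (d == 1) & (g_tm > 0)
    if not ev.any():
        raise NoEventsError("no uncensored observations for the MAE")
    w = 1.0 / g_tm[ev]
    return float(np.sum(w * np.abs(t[ev] - pred[ev]) / scale) / np.sum(w))


# ---------------------------------------------------------------------------
# stratification

def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p-value)."""
    t, d = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("log-rank test requires exactly two groups")
    in1 = g == labels[1]
    obs1, exp1, var = 0.0, 0.0, 0.0
    for tt in np.unique(t[d == 1]):
        at_risk = t >= tt
        n_tot = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d_tot = ((t == tt) & (d == 1)).sum()
        d1 = ((t == tt) & (d == 1) & in1).sum()
        obs1 += d1
        exp1 += d_tot * n1 / n_tot
        if n_tot > 1:
            var += d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / (n_tot - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs1 - exp1) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def stratify_km(times, events, risks):
    """Median split on risk into high/low groups plus the log-rank test.

    Risk ties at the median go to the low-risk group. Returns a dict with
    the group mask (True = high risk), Kaplan-Meier curves per group, and
    the log-rank chi-square and p-value.
    """
    t, d, r = _as_arrays(times, events, risks)
    if len(t) < 4:
        raise ValueError("need at least 4 patients to stratify")
    med = np.median(r)
    high = r > med
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("degenerate stratification: one group is empty")
    chi2, p = logrank(t, d, high.astype(int))
    curves = {}
    for name, m in (("low", ~high), ("high", high)):
        xs, g = _km_curve(t[m], d[m])
        curves[name] = (xs, g)
    return {"high_risk": high, "chi2": chi2, "p_value": p, "curves": curves}


def _km_curve(times, events):
    t, d = _as_arrays(times, events)
    uniq = np.unique(t)
    s = np.empty(len(uniq))
    surv = 1.0
    for k, tt in enumerate(uniq):
        at_risk = (t >= tt).sum()
        n_ev = ((t == tt) & (d == 1)).sum()
        surv *= 1.0 - n_ev / at_risk
        s[k] = surv
    return uniq, s


# ---------------------------------------------------------------------------
# fold statistics

def fold_summary(scores) -> tuple[float, float, float]:
    """Mean and 95% t-interval (df = k - 1) of fold-wise scores."""
    x = np.asarray(scores, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need at least 2 folds")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(len(x)))
    tcrit = float(stats.t.ppf(0.975, df=len(x) - 1))
    return mean, mean - tcrit * se, mean + tcrit * se


def paired_fold_tests(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise paired t-tests between models on fold-wise scores.

    ``score_table``: rows = folds, columns = models. A model compared with
    itself (zero differences) is reported with p = NaN and flagged.
    """
    models = list(score_table.columns)
    rows = []
    for i, a in enumerate(models):
        for b in models[i + 1:]:
            diff = score_table[a].to_numpy() - score_table[b].to_numpy()
            if np.allclose(diff, 0):
                rows.append({"model_a": a, "model_b": b, "t": np.nan,
                             "p_value": np.nan, "identical": True})
                continue
            tstat, p = stats.ttest_rel(score_table[a], score_table[b])
            rows.append({"model_a": a, "model_b": b, "t": float(tstat),
                         "p_value": float(p), "identical": False})
    return pd.DataFrame(rows)


def repeated_measures_anova(score_table: pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA across folds (subjects = folds).

    Returns (F, p) with df = (k_models - 1, (k_models - 1)(n_folds - 1)).
    """
    x = score_table.to_numpy(dtype=np.float64)
    n, k = x.shape
    if k < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 models")
    grand = x.mean()
    ss_model = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_model - ss_subj
    df_m, df_e = k - 1, (k - 1) * (n - 1)
    f = (ss_model / df_m) / (ss_err / df_e)
    return float(f), float(stats.f.sf(f, df_m, df_e))


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainConfig:
    """Optimization protocol: Adam, initial LR 1e-4, weight decay 1e-5,
    up to 100 epochs, LR cut by 10x when the validation C-index plateaus
    (no improvement > 1e-4 for 10 epochs). ``batch_size=None`` uses the full
    cohort per step (cohort-wide risk sets); mini-batches use batch-local
    risk sets, a standard but slightly biased approximation.
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 100
    lr_decay_factor: float = 0.1
    plateau_patience: int = 10
    plateau_min_delta: float = 1e-4
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate < 0 or self.weight_decay < 0:
            raise ValueError("rates must be non-negative")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def _model_inputs(x, idx):
    if isinstance(x, tuple):
        return tuple(xi[idx] for xi in x)
    return x[idx]


def train_branch(model, x, times, events, config: TrainConfig,
                 train_idx, val_idx) -> dict:
    """Optimize the Cox loss; plateau LR decay and best-checkpoint return.

    ``model`` exposes forward/backward/params/state/load_state (branch or
    fused); ``x`` is the model's input batch array (or a pair for the fused
    model). Returns a history dict; the model is left at its best-validation
    checkpoint. Fully deterministic given ``config.seed``.
    """
    t, d = _as_arrays(times, events)
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation patients must be disjoint")
    opt = nn.Adam(model.params(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    best_c, best_state = -np.inf, model.state()
    since_improve = 0
    history = {"train_loss": [], "val_c_index": [], "lr": []}
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        bs = config.batch_size or len(order)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), bs):
            batch = order[start:start + bs]
            xb = _model_inputs(x, batch)
            out = model.forward(xb, train=True)
            risk = out[-1]
            try:
                loss, grad = cox_loss_grad(risk, t[batch], d[batch])
            except NoEventsError:
                continue  # skip-batch signal
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_risk = model.predict_risk(_model_inputs(x, val_idx))
        try:
            val_c = concordance(t[val_idx], d[val_idx], val_risk)
        except NoComparablePairsError:
            val_c = 0.5
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_c_index"].append(val_c)
        history["lr"].append(opt.lr)
        if val_c > best_c + config.plateau_min_delta:
            best_c, best_state = val_c, model.state()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.plateau_patience:
                opt.lr *= config.lr_decay_factor
                since_improve = 0
    model.load_state(best_state)
    history["best_val_c_index"] = best_c
    return history


def stratified_folds(events, k: int = 5, seed: int = 0):
    """Patient-level splits stratified by event indicator (shared seed so
    every compared model sees identical folds). Falls back to unstratified
    folds with a warning when a stratum is smaller than k."""
    d = np.asarray(events, dtype=np.int64)
    n = len(d)
    if min((d == 0).sum(), (d == 1).sum()) < k:
        import warnings
        warnings.warn("stratum smaller than the fold count; "
                      "falling back to unstratified folds", RuntimeWarning)
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n)))
    kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n), d))


@dataclass
class FoldResult:
    fold: int
    c_index: float
    ibs: float
    ipcw_mae: float


def cross_validate(model_factory, x, times, events, k: int = 5, seed: int = 0,
                   config: TrainConfig | None = None,
                   val_fraction: float = 0.2) -> list[FoldResult]:
    """k-fold stratified cross-validation of a Cox-trained model.

    Each fold trains on the remaining patients (a further event-stratified
    slice held out for plateau detection and checkpoint selection) and is
    scored on its test patients with the three metrics. ``model_factory(fold)``
    must return a freshly initialized model.
    """
    t, d = _as_arrays(times, events)
    config = config or TrainConfig()
    results = []
    for fold, (trainval_idx, test_idx) in enumerate(stratified_folds(d, k, seed)):
        rng = np.random.default_rng([seed, fold])
        tv = rng.permutation(trainval_idx)
        n_val = max(2, int(round(val_fraction * len(tv))))
        val_idx, train_idx = tv[:n_val], tv[n_val:]
        model = model_factory(fold)
        train_branch(model, x, t, d, config, train_idx, val_idx)
        risk = model.predict_risk(_model_inputs(x, test_idx))
        c = concordance(t[test_idx], d[test_idx], risk)
        train_risk = model.predict_risk(_model_inputs(x, train_idx))
        base = breslow_baseline(t[train_idx], d[train_idx], train_risk)
        t_test = t[test_idx]
        grid = np.quantile(t_test, np.linspace(0.1, 0.8, 8))
        s_mat = predict_survival_matrix(risk, base, grid)
        ibs = integrated_brier(t_test, d[test_idx], s_mat, grid)
        pred_t = predicted_median_times(risk, base, horizon=t.max())
        mae = ipcw_mae(t_test, d[test_idx], pred_t)
        results.append(FoldResult(fold=fold, c_index=c, ibs=ibs, ipcw_mae=mae))
    return results
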