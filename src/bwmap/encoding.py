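"""Single-neuron linear encoding model.

Spike counts in 20-ms bins across trials are regressed on task events
represented by raised-cosine "bump" bases laid out in log-warped time
(fast, narrow bumps near the event; slow, wide bumps later).  Stimulus
kernels are scaled by a saturating function of contrast, h(c) =
tanh(5c)/tanh(5); wheel-movement and wheel-speed kernels are anticausal
(their support strictly precedes the event) to capture preparatory
activity.  Fitting is ridge regression (intercept unpenalized) with the
penalty chosen by cross-validation over uniform-random trial folds, and
the contribution of each regressor group is measured by the drop in
cross-validated R-squared when the group is removed (delta R^2).

The design matrix built here is also the one the synthetic spike
generator drives its firing rates with, so the generator and the fitter
share a single definition of every event effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BIN_S = 0.020
#: per-trial analysis window relative to stimulus onset (seconds)
TRIAL_WINDOW = (-0.4, 1.1)

#: regressor registry: (bases, kernel span s, causal?)
KERNEL_SPECS = {
    "stim_left": (5, 0.400, True),
    "stim_right": (5, 0.400, True),
    "feedback_correct": (5, 0.400, True),
    "feedback_incorrect": (5, 0.400, True),
    "move_left": (3, 0.200, False),
    "move_right": (3, 0.200, False),
    "move_init": (3, 0.300, False),
    "wheel_speed": (3, 0.300, False),
}


def contrast_height(c) -> np.ndarray | float:
    """Saturating contrast gain h(c) = tanh(5c)/tanh(5); h(0)=0, h(1)=1."""
    return np.tanh(5.0 * np.asarray(c, dtype=float)) / np.tanh(5.0)


@dataclass
class BasisSet:
    """Raised-cosine bases sampled on the 20-ms lag grid.

    ``lags`` holds bin-centre lag times: non-negative for causal sets,
    strictly negative for anticausal sets (support precedes the event).
    ``values`` is (n_lag_bins, B); each basis peaks at 1.
    """

    lags: np.ndarray
    values: np.ndarray
    span: float
    causal: bool

    @property
    def n_bases(self) -> int:
        return self.values.shape[1]


def make_basis(n_bases: int, span: float, causal: bool = True,
               log_offset: float = 0.05, bin_s: float = BIN_S) -> BasisSet:
    """Raised cosines equally spaced in log(t + offset), mapped to linear time.

    Centres are placed so the first basis peaks at lag 0 and the last
    support ends at the kernel span, giving even coverage of the span
    (the sum of bases is positive everywhere on it).
    """
    if n_bases < 1 or span <= 0 or log_offset <= 0:
        raise ValueError("need n_bases >= 1, span > 0, log_offset > 0")
    n_lags = int(round(span / bin_s))
    t = (np.arange(n_lags) + 0.5) * bin_s

    def warp(x):
        return np.log(x + log_offset)

    a, e = warp(0.0), warp(span)
    spacing = (e - a) / n_bases
    centres = a + spacing * np.arange(n_bases)
    arg = (warp(t)[:, None] - centres[None, :]) / spacing
    vals = np.where(np.abs(arg) < 1.0, 0.5 * (1.0 + np.cos(np.pi * arg)), 0.0)
    if causal:
        lags = t
    else:
        # time-reverse: value at negative lag -u equals the causal value
        # at +u, so the fast bases sit just before the event
        lags = -t[::-1]
        vals = vals[::-1]
    return BasisSet(lags=lags, values=vals, span=span, causal=causal)


@dataclass
class DesignMatrix:
    """Stacked per-trial design: (n_trials * n_bins_per_trial, n_columns)."""

    X: np.ndarray
    groups: dict[str, slice]
    n_trials: int
    n_bins: int
    bin_s: float = BIN_S
    clipped_events: list = field(default_factory=list)

    @property
    def trial_of_row(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_trials), self.n_bins)


def _event_bin(t_event: float, t0: float, bin_s: float) -> int:
    return int(np.floor((t_event - t0) / bin_s + 1e-9))


def movement_onsets(wheel: pd.DataFrame, v_threshold: float = 0.5,
                    still_s: float = 0.15) -> np.ndarray:
    """Wheel-movement onset times detected from the velocity trace.

    An onset is a crossing of the speed threshold preceded by at least
    ``still_s`` of stillness, so one trial can contribute several
    movement-initiation events (first movement plus corrective turns).
    """
    t = wheel["time_s"].to_numpy(float)
    speed = np.abs(wheel["velocity_rad_s"].to_numpy(float))
    moving = speed > v_threshold
    if t.size < 2:
        return np.array([])
    dt = t[1] - t[0]
    k = max(1, int(round(still_s / dt)))
    n = t.size
    c = np.cumsum(np.r_[0, moving])           # c[i] = #moving among [:i]
    idx = np.arange(n)
    past = c[idx] - c[np.maximum(0, idx - k)]  # moving samples just before i
    onset = moving & (past == 0)
    return t[onset]


def build_design_matrix(trials: pd.DataFrame,
                        wheel: pd.DataFrame | None = None,
                        bin_s: float = BIN_S,
                        window: tuple[float, float] = TRIAL_WINDOW,
                        log_offset: float = 0.05) -> DesignMatrix:
    """Assemble the per-trial design matrix on the 20-ms bin grid.

    Event regressors are delta trains convolved with their basis set (a
    copy of every basis at the event bin); the wheel-speed regressor is
    the speed trace convolved with the anticausal wheel bases; the block
    probability enters as a per-trial step.  Events falling outside a
    trial's window are clipped and logged.  Deterministic.
    """
    n_trials = len(trials)
    n_bins = int(round((window[1] - window[0]) / bin_s))
    bases = {name: make_basis(b, span, causal, log_offset, bin_s)
             for name, (b, span, causal) in KERNEL_SPECS.items()}
    names = list(KERNEL_SPECS) + ["block_prob"]
    groups: dict[str, slice] = {}
    col = 0
    for name in names:
        width = bases[name].n_bases if name in bases else 1
        groups[name] = slice(col, col + width)
        col += width
    X = np.zeros((n_trials * n_bins, col))
    clipped = []

    stim_on = trials["stim_on_s"].to_numpy(float)
    t0 = stim_on + window[0]
    h = contrast_height(trials["contrast"].to_numpy(float))

    def place_kernel(l, t_event, name, g=1.0):
        bs = bases[name]
        sl = groups[name]
        ib = _event_bin(t_event, t0[l], bin_s)
        if bs.causal:
            lo, hi = ib, ib + len(bs.lags)
        else:
            lo, hi = ib - len(bs.lags), ib
        if lo >= n_bins or hi <= 0:
            clipped.append((int(l), name))
            return
        src_lo, src_hi = max(0, -lo), len(bs.lags) - max(0, hi - n_bins)
        X[l * n_bins + max(0, lo): l * n_bins + min(n_bins, hi), sl] += \
            g * bs.values[src_lo:src_hi]

    def add_event(name, event_times, rows_ok, gain=None):
        for l in np.flatnonzero(rows_ok):
            place_kernel(l, event_times[l], name,
                         1.0 if gain is None else gain[l])

    side = trials["stim_side"].to_numpy(float)
    add_event("stim_left", stim_on, side < 0, gain=h)
    add_event("stim_right", stim_on, side > 0, gain=h)
    fb_t = trials["feedback_s"].to_numpy(float)
    fb = trials["feedback"].to_numpy(float)
    add_event("feedback_correct", fb_t, fb > 0)
    add_event("feedback_incorrect", fb_t, fb < 0)
    mv_t = trials["first_move_s"].to_numpy(float)
    choice = trials["choice"].to_numpy(float)
    ok = np.isfinite(mv_t)
    add_event("move_left", mv_t, ok & (choice < 0))
    add_event("move_right", mv_t, ok & (choice > 0))
    # movement initiation: every wheel-movement onset (first movement
    # plus any corrective turns detected from the trace); without a
    # wheel trace, the first movements stand in
    if wheel is not None and len(wheel):
        order = np.argsort(t0, kind="stable")
        t0_sorted = t0[order]
        for onset in movement_onsets(wheel):
            pos = np.searchsorted(t0_sorted, onset, side="right") - 1
            if pos < 0:
                continue
            l = int(order[pos])
            if onset < t0[l] + n_bins * bin_s:
                place_kernel(l, onset, "move_init")
    else:
        add_event("move_init", mv_t, ok)

    # wheel speed convolved with the anticausal wheel bases
    if wheel is not None and len(wheel):
        bs = bases["wheel_speed"]
        sl = groups["wheel_speed"]
        wt = wheel["time_s"].to_numpy(float)
        speed = np.abs(wheel["velocity_rad_s"].to_numpy(float))
        centres_rel = window[0] + (np.arange(n_bins) + 0.5) * bin_s
        k_lag = len(bs.lags)
        for l in range(n_trials):
            sp = np.interp(stim_on[l] + centres_rel, wt, speed,
                           left=0.0, right=0.0)
            for j in range(bs.n_bases):
                colv = np.zeros(n_bins)
                for k in range(1, k_lag + 1):
                    v = bs.values[k_lag - k, j]   # value at lag -k bins
                    if v != 0.0:
                        colv[:n_bins - k] += v * sp[k:]
                X[l * n_bins:(l + 1) * n_bins, sl.start + j] = colv

    X[:, groups["block_prob"]] = np.repeat(
        trials["p_right_block"].to_numpy(float), n_bins)[:, None]
    return DesignMatrix(X=X, groups=groups, n_trials=n_trials, n_bins=n_bins,
                        bin_s=bin_s, clipped_events=clipped)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

DEFAULT_ALPHA_GRID = (1e-2, 1e-1, 1.0, 10.0, 100.0)


@dataclass
class EncodingFit:
    beta: np.ndarray
    beta0: float
    alpha: float
    r2: float
    r2_folds: np.ndarray
    fold_of_trial: np.ndarray
    groups: dict[str, slice]
    delta_r2: dict[str, float] = field(default_factory=dict)


def _ridge_solve(gram, xty, x_mean, y_mean, alpha):
    p = gram.shape[0]
    beta = np.linalg.solve(gram + alpha * np.eye(p), xty)
    return beta, y_mean - x_mean @ beta


class _FoldCache:
    """Per-fold sufficient statistics for fast ridge CV.

    Caches the training-fold Gram matrix, cross-products and means once,
    so a new penalty (or a column subset for a leave-one-group-out
    refit) only costs a p x p solve per fold.
    """

    def __init__(self, X, y, trial_of_row, fold_of_trial):
        self.X, self.y = X, y
        self.row_fold = fold_of_trial[trial_of_row]
        self.n_folds = int(fold_of_trial.max()) + 1
        g_all = X.T @ X
        xty_all = X.T @ y
        xsum_all = X.sum(axis=0)
        self.folds = []
        for k in range(self.n_folds):
            te = self.row_fold == k
            Xte = X[te]
            g_tr = g_all - Xte.T @ Xte
            xty_tr = xty_all - Xte.T @ y[te]
            xsum_tr = xsum_all - Xte.sum(axis=0)
            n_tr = X.shape[0] - int(te.sum())
            self.folds.append((te, g_tr, xty_tr, xsum_tr, n_tr,
                               y[~te].sum()))

    def cv_r2(self, alpha, cols=None):
        """Pooled held-out R^2 and per-fold R^2 for one penalty."""
        y = self.y
        pred = np.empty_like(y)
        r2_folds = np.empty(self.n_folds)
        for k, (te, g, xty, xsum, n_tr, ysum) in enumerate(self.folds):
            xm = xsum / n_tr
            ym = ysum / n_tr
            if cols is not None:
                gc = g[np.ix_(cols, cols)] - n_tr * np.outer(xm[cols],
                                                             xm[cols])
                xtyc = xty[cols] - ysum * xm[cols]
                beta, beta0 = _ridge_solve(gc, xtyc, xm[cols], ym, alpha)
                pred[te] = self.X[te][:, cols] @ beta + beta0
            else:
                gc = g - n_tr * np.outer(xm, xm)
                xtyc = xty - ysum * xm
                beta, beta0 = _ridge_solve(gc, xtyc, xm, ym, alpha)
                pred[te] = self.X[te] @ beta + beta0
            ss_res = np.sum((y[te] - pred[te]) ** 2)
            ss_tot = np.sum((y[te] - y[te].mean()) ** 2)
            r2_folds[k] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return r2, r2_folds


def fit_encoding(counts: np.ndarray, dm: DesignMatrix,
                 alpha_grid=DEFAULT_ALPHA_GRID, n_folds: int = 5,
                 seed: int | None = 0) -> EncodingFit:
    """Ridge fit with CV penalty selection over uniform-random trial folds.

    ``counts`` is the neuron's spike count per 20-ms bin, flattened in
    the same trial-major order as the design matrix rows.  The intercept
    is not regularized (data are centred before solving).
    """
    y = np.asarray(counts, dtype=float).ravel()
    if y.size != dm.X.shape[0]:
        raise ValueError("counts length does not match design matrix rows")
    rng = np.random.default_rng(seed)
    fold_of_trial = rng.permutation(
        np.arange(dm.n_trials) % n_folds)
    cache = _FoldCache(dm.X, y, dm.trial_of_row, fold_of_trial)
    scores = [cache.cv_r2(a)[0] for a in alpha_grid]
    best = int(np.argmax(scores))
    alpha = float(alpha_grid[best])
    r2, r2_folds = cache.cv_r2(alpha)
    # final coefficients on all data (reported, not scored)
    xm, ym = dm.X.mean(axis=0), y.mean()
    Xc = dm.X - xm
    beta, beta0 = _ridge_solve(Xc.T @ Xc, Xc.T @ (y - ym), xm, ym, alpha)
    fit = EncodingFit(beta=beta, beta0=float(beta0), alpha=alpha, r2=r2,
                      r2_folds=r2_folds, fold_of_trial=fold_of_trial,
                      groups=dict(dm.groups))
    fit._cache = cache
    return fit


def delta_r2(counts: np.ndarray, dm: DesignMatrix, fit: EncodingFit,
             group: str) -> float:
    """Drop in cross-validated R^2 when one regressor group is removed.

    The omission model is refit on the same folds with the same selected
    penalty; delta R^2 = R^2_full - R^2_without_group.
    """
    if group not in dm.groups:
        raise KeyError(group)
    y = np.asarray(counts, dtype=float).ravel()
    sl = dm.groups[group]
    keep = np.r_[0:sl.start, sl.stop:dm.X.shape[1]]
    cache = getattr(fit, "_cache", None)
    if cache is None or cache.X is not dm.X or not np.array_equal(cache.y, y):
        cache = _FoldCache(dm.X, y, dm.trial_of_row, fit.fold_of_trial)
        fit._cache = cache
    r2_minus, _ = cache.cv_r2(fit.alpha, cols=keep)
    d = fit.r2 - r2_minus
    fit.delta_r2[group] = d
    return d


def all_delta_r2(counts, dm, fit) -> dict[str, float]:
    return {g: delta_r2(counts, dm, fit, g) for g in dm.groups}


def pair_sensitivity(delta_a: float, delta_b: float) -> float:
    """log10 |delta R^2_A - delta R^2_B|; symmetric in its arguments."""
    diff = abs(delta_a - delta_b)
    if diff == 0.0:
        return -np.inf
    return float(np.log10(diff))


#: regressor pairs reported as sensitivities
SENSITIVITY_PAIRS = (
    ("stim_right", "stim_left"),
    ("move_right", "move_left"),
    ("feedback_correct", "feedback_incorrect"),
)
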