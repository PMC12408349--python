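"""Nested cross-validated population decoding of task variables.

Binary targets (stimulus side, choice, feedback) are decoded from
single-window spike counts with class-weighted, L1-regularized logistic
regression and scored by balanced accuracy; continuous targets (wheel
speed/velocity in 20-ms bins) are decoded from a causal lagged window of
W+1 bins with Lasso linear regression and scored by R^2.  Model
selection is nested: 5 interleaved outer folds, each with 5 inner folds
choosing the regularization strength from a fixed grid; the outer-train
refit predicts the held-out fold and the concatenated test predictions
are scored once.  The whole procedure is repeated over several fold
seedings and averaged, and then again for every null target, so the
observed score is compared to nulls that went through the identical
pipeline.

The logistic solver is an in-package FISTA proximal-gradient routine
(numba-compiled) minimizing ``||beta||_1 + C * sum_i w_i *
log(1 + exp(-y_i (x_i beta + b)))`` with an unpenalized intercept; at
the problem sizes used here it is two orders of magnitude faster than a
general-purpose library call, which matters because every decode is
repeated M+1 times against its null ensemble.  Its solutions are
checked against scikit-learn's liblinear implementation in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from . import aggregate, nulls
from .core_data import DEFAULT_WINDOWS, SessionBundle, WindowSpec, bin_spikes

#: regularization grids (sklearn parametrization: C for logistic,
#: alpha for Lasso)
C_GRID_BINARY = tuple(10.0 ** np.arange(-5, 2))          # 7 values
ALPHA_GRID_CONTINUOUS = tuple(10.0 ** np.arange(-5, 0))  # 5 values

N_RUNS_BINARY = 10
N_RUNS_CONTINUOUS = 2
N_FOLDS = 5
MIN_CLASS_TRIALS = 5
FOLD_RESAMPLE_CAP = 100

#: continuous-target window: 20-ms bins, -200 ms to +1000 ms around the
#: first wheel movement, with a causal history of W bins
WHEEL_WINDOW = WindowSpec("first_move", -0.200, 1.000, 0.020)
W_LAGS = 10


class InsufficientClassError(ValueError):
    """A binary target class has too few trials to decode."""


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# fast weighted L1 logistic solver
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fista_logistic(X, y, sw, C, max_iter, tol, beta_init, b_init):
    n, p = X.shape
    beta = beta_init.copy()
    b = b_init
    zb = beta_init.copy()
    zint = b_init
    # Lipschitz constant from the top eigenvalue of X' W X (power
    # iteration, then a 10% safety margin)
    v = np.ones(p) / np.sqrt(p)
    lam = 1e-12
    for _ in range(12):
        u = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for j in range(p):
                acc += X[i, j] * v[j]
            u[i] = sw[i] * acc
        w_vec = np.zeros(p)
        for i in range(n):
            for j in range(p):
                w_vec[j] += X[i, j] * u[i]
        lam = np.sqrt(np.sum(w_vec * w_vec))
        if lam < 1e-12:
            break
        v = w_vec / lam
    L = 0.25 * C * lam * 1.1 + 1e-12
    Lb = 0.25 * C * np.sum(sw) + 1e-12
    tk = 1.0
    for _ in range(max_iter):
        # gradient of the smooth part at (zb, zint)
        g = np.zeros(p)
        gb = 0.0
        for i in range(n):
            m = 0.0
            for j in range(p):
                m += X[i, j] * zb[j]
            m = y[i] * (m + zint)
            s = 1.0 / (1.0 + np.exp(m))
            coef = -C * sw[i] * y[i] * s
            for j in range(p):
                g[j] += coef * X[i, j]
            gb += coef
        new_beta = np.empty(p)
        thr = 1.0 / L
        for j in range(p):
            v = zb[j] - g[j] / L
            if v > thr:
                new_beta[j] = v - thr
            elif v < -thr:
                new_beta[j] = v + thr
            else:
                new_beta[j] = 0.0
        new_b = zint - gb / Lb
        # adaptive restart: reset momentum when it points uphill
        restart = (zint - new_b) * (new_b - b)
        for j in range(p):
            restart += (zb[j] - new_beta[j]) * (new_beta[j] - beta[j])
        if restart > 0.0:
            tk = 1.0
        tk1 = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        mom = (tk - 1.0) / tk1
        delta = abs(new_b - b)
        for j in range(p):
            d = abs(new_beta[j] - beta[j])
            if d > delta:
                delta = d
        zb = new_beta + mom * (new_beta - beta)
        zint = new_b + mom * (new_b - b)
        beta = new_beta
        b = new_b
        tk = tk1
        if delta < tol:
            break
    return beta, b


def fit_l1_logistic(X, y_pm, sample_weight, C, max_iter=1000, tol=1e-4,
                    warm_start=None):
    """Weighted L1 logistic regression; labels in {-1, +1}.

    ``warm_start`` may carry (beta, intercept) from a neighbouring
    penalty on the same data (used along the regularization path).
    """
    p = X.shape[1]
    if warm_start is None:
        beta0, b0 = np.zeros(p), 0.0
    else:
        beta0, b0 = np.asarray(warm_start[0], np.float64), float(warm_start[1])
    return _fista_logistic(np.ascontiguousarray(X, dtype=np.float64),
                           np.ascontiguousarray(y_pm, dtype=np.float64),
                           np.ascontiguousarray(sample_weight, np.float64),
                           float(C), max_iter, tol, beta0, b0)


def class_weights(y_pm: np.ndarray) -> np.ndarray:
    """Inverse class-frequency weights 1 / (2 * P_class)."""
    n = y_pm.size
    p_pos = np.mean(y_pm > 0)
    w = np.where(y_pm > 0, 1.0 / (2.0 * p_pos), 1.0 / (2.0 * (1.0 - p_pos)))
    return w


def balanced_accuracy(y_true_pm, y_pred_pm) -> float:
    accs = []
    for cls in (-1, 1):
        sel = y_true_pm == cls
        if np.any(sel):
            accs.append(np.mean(y_pred_pm[sel] == cls))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def _interleaved_folds(n, n_folds, rng):
    """Random interleaved assignment: fold_of_trial array."""
    return rng.permutation(np.arange(n) % n_folds)


def make_folds(y_pm, n_folds, rng, require_classes=True,
               cap=FOLD_RESAMPLE_CAP):
    """Interleaved random folds; resampled (up to a cap) until every
    training set contains both classes."""
    n = len(y_pm)
    for _ in range(cap):
        fold = _interleaved_folds(n, n_folds, rng)
        if not require_classes:
            return fold
        ok = True
        for k in range(n_folds):
            train = y_pm[fold != k]
            if not (np.any(train > 0) and np.any(train < 0)):
                ok = False
                break
        if ok:
            return fold
    raise InsufficientClassError(
        f"could not build {n_folds} folds with both classes in every "
        f"training set after {cap} resamples")


# ---------------------------------------------------------------------------
# binary decoding
# ---------------------------------------------------------------------------

def _decode_binary_once(X, y_pm, c_grid, rng):
    """One full nested-CV pass; returns balanced accuracy of the
    concatenated outer-test predictions."""
    n = len(y_pm)
    outer = make_folds(y_pm, N_FOLDS, rng)
    pred = np.zeros(n)
    for k in range(N_FOLDS):
        tr = np.flatnonzero(outer != k)
        te = np.flatnonzero(outer == k)
        ytr = y_pm[tr]
        inner = make_folds(ytr, N_FOLDS, rng)
        # validation predictions per C, concatenated over inner folds
        val_pred = np.zeros((len(c_grid), len(tr)))
        for ki in range(N_FOLDS):
            itr = tr[inner != ki]
            iva = np.flatnonzero(inner == ki)
            Xi, yi = X[itr], y_pm[itr]
            swi = class_weights(yi)
            warm = None
            for ci, C in enumerate(c_grid):   # path: weakest penalty last
                beta, b = fit_l1_logistic(Xi, yi, swi, C, warm_start=warm)
                warm = (beta, b)
                val_pred[ci, iva] = np.where(
                    X[tr[iva]] @ beta + b >= 0, 1, -1)
        scores = [balanced_accuracy(ytr, val_pred[ci])
                  for ci in range(len(c_grid))]
        best_c = c_grid[int(np.argmax(scores))]
        sw = class_weights(ytr)
        beta, b = fit_l1_logistic(X[tr], ytr, sw, best_c)
        pred[te] = np.where(X[te] @ beta + b >= 0, 1, -1)
    return balanced_accuracy(y_pm, pred)


def decode_binary(counts: np.ndarray, target, c_grid=C_GRID_BINARY,
                  n_runs: int = N_RUNS_BINARY, seed=None) -> float:
    """Multirun nested-CV balanced accuracy for a binary target.

    ``counts`` is trials x neurons; ``target`` is coded in {-1, +1}.
    Raises :class:`InsufficientClassError` when a class has fewer than
    5 trials (the session is then skipped with that reason).
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim == 3:
        X = X.sum(axis=2)
    # centring columns is an exact reparametrization here (the intercept
    # is unpenalized) and conditions the solver much better
    X = X - X.mean(axis=0)
    y = np.asarray(target)
    y_pm = np.where(y > 0, 1, -1)
    if min(np.sum(y_pm > 0), np.sum(y_pm < 0)) < MIN_CLASS_TRIALS:
        raise InsufficientClassError("a class has fewer than "
                                     f"{MIN_CLASS_TRIALS} trials")
    ss = _seed_seq(seed)
    scores = [
        _decode_binary_once(X, y_pm, c_grid, np.random.default_rng(child))
        for child in ss.spawn(n_runs)
    ]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# continuous decoding
# ---------------------------------------------------------------------------

def build_lagged_design(counts_bins: np.ndarray, target_bins: np.ndarray,
                        w_lags: int = W_LAGS):
    """Causal lagged design for wheel decoding.

    For each trial and each bin t with a full history, the predictor row
    is the spike counts in bins t-W..t for every neuron (width
    (W+1) * n_neurons); the response is the wheel value of bin t.
    Returns (X, y, trial_of_row).
    """
    n_trials, n_neurons, n_bins = counts_bins.shape
    if target_bins.shape != (n_trials, n_bins):
        raise ValueError("target shape does not match binned counts")
    rows, ys, tor = [], [], []
    for t in range(w_lags, n_bins):
        lagged = counts_bins[:, :, t - w_lags:t + 1]
        rows.append(lagged.reshape(n_trials, n_neurons * (w_lags + 1)))
        ys.append(target_bins[:, t])
        tor.append(np.arange(n_trials))
    X = np.concatenate(rows, axis=0)
    y = np.concatenate(ys)
    trial_of_row = np.concatenate(tor)
    return X.astype(float), y.astype(float), trial_of_row


def _r2(y, pred) -> float:
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 0.0
    return float(1.0 - np.sum((y - pred) ** 2) / ss_tot)


def _decode_continuous_once(X, y, trial_of_row, n_trials, alpha_grid, rng):
    from sklearn.linear_model import Lasso

    outer = _interleaved_folds(n_trials, N_FOLDS, rng)
    pred = np.zeros_like(y)
    for k in range(N_FOLDS):
        tr_trials = np.flatnonzero(outer != k)
        inner = _interleaved_folds(len(tr_trials), N_FOLDS, rng)
        fold_of_trial = np.full(n_trials, -1)
        fold_of_trial[tr_trials] = inner
        tr_rows = np.isin(trial_of_row, tr_trials)
        val_pred = np.zeros((len(alpha_grid), tr_rows.sum()))
        y_tr = y[tr_rows]
        row_inner = fold_of_trial[trial_of_row[tr_rows]]
        for ki in range(N_FOLDS):
            fit_rows = tr_rows & (fold_of_trial[trial_of_row] != ki) \
                & (fold_of_trial[trial_of_row] >= 0)
            va = row_inner == ki
            for ai, a in enumerate(alpha_grid):
                m = Lasso(alpha=a, max_iter=1000, tol=1e-3)
                m.fit(X[fit_rows], y[fit_rows])
                val_pred[ai, va] = m.predict(X[tr_rows][va])
        scores = [_r2(y_tr, val_pred[ai]) for ai in range(len(alpha_grid))]
        best = alpha_grid[int(np.argmax(scores))]
        m = Lasso(alpha=best, max_iter=1000, tol=1e-3)
        m.fit(X[tr_rows], y[tr_rows])
        te_rows = ~tr_rows
        pred[te_rows] = m.predict(X[te_rows])
    return _r2(y, pred)


def decode_continuous(counts_bins: np.ndarray, target_bins: np.ndarray,
                      w_lags: int = W_LAGS,
                      alpha_grid=ALPHA_GRID_CONTINUOUS,
                      n_runs: int = N_RUNS_CONTINUOUS, seed=None) -> float:
    """Multirun nested-CV R^2 for a continuous per-bin target."""
    X, y, trial_of_row = build_lagged_design(counts_bins, target_bins, w_lags)
    n_trials = counts_bins.shape[0]
    ss = _seed_seq(seed)
    scores = [
        _decode_continuous_once(X, y, trial_of_row, n_trials, alpha_grid,
                                np.random.default_rng(child))
        for child in ss.spawn(n_runs)
    ]
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# scoring against nulls and region aggregation
# ---------------------------------------------------------------------------

@dataclass
class SessionDecodingResult:
    session_id: str
    region: str
    score: float
    ensemble: nulls.NullEnsemble
    p: float = field(init=False)
    corrected: float = field(init=False)

    def __post_init__(self):
        self.p, self.corrected = score_session(self.score,
                                               self.ensemble)


def score_session(observed: float, ensemble: nulls.NullEnsemble):
    """Session p-value and median-corrected decoding score."""
    p = nulls.null_pvalue(ensemble)
    corrected = observed - float(np.median(ensemble.null_scores))
    return p, corrected


def aggregate_region(session_results: list[SessionDecodingResult],
                     analysis: str = "decoding") -> aggregate.RegionResult:
    """Fisher-combined region p, median corrected score as effect size,
    and the fraction of individually significant sessions.  The
    significance flag is set later by across-region FDR."""
    if not session_results:
        raise ValueError("no sessions to aggregate")
    region = session_results[0].region
    ps = [r.p for r in session_results]
    eff = float(np.median([r.corrected for r in session_results]))
    return aggregate.RegionResult(
        region=region, analysis=analysis, effect_size=eff,
        p_combined=aggregate.fisher_combine(ps),
        n_sessions=len(session_results),
        extra={"frac_sessions_sig": float(np.mean(np.array(ps) < 0.05))},
    )


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

BINARY_TARGETS = {"stimulus": "stim_side", "choice": "choice",
                  "feedback": "feedback"}


def extract_binary_target(trials: pd.DataFrame, variable: str):
    """Target vector and trial mask for a binary decoding variable
    (zero-contrast trials are excluded for the stimulus target)."""
    col = BINARY_TARGETS[variable]
    mask = np.ones(len(trials), dtype=bool)
    if variable == "stimulus":
        mask &= trials["contrast"].to_numpy(float) > 0
    return trials[col].to_numpy()[mask], mask


def wheel_target_bins(bundle: SessionBundle, trials: pd.DataFrame,
                      kind: str = "wheel_speed",
                      window: WindowSpec = WHEEL_WINDOW) -> np.ndarray:
    """Per-trial, per-bin wheel speed (|v|) or signed velocity."""
    wt = bundle.wheel["time_s"].to_numpy(float)
    v = bundle.wheel["velocity_rad_s"].to_numpy(float)
    if kind == "wheel_speed":
        v = np.abs(v)
    align = trials["first_move_s"].to_numpy(float)
    edges = window.bin_edges()
    centres = 0.5 * (edges[:-1] + edges[1:])
    out = np.empty((len(trials), len(centres)))
    for i, a in enumerate(align):
        out[i] = np.interp(a + centres, wt, v, left=0.0, right=0.0)
    return out


def decode_session_binary(bundle: SessionBundle, region: str, variable: str,
                          M: int = 200, seed=None,
                          n_runs: int = N_RUNS_BINARY,
                          window: WindowSpec | None = None,
                          trials: pd.DataFrame | None = None,
                          cfg=None) -> SessionDecodingResult:
    """Decode one binary variable from one region of one session and
    score it against its variable-appropriate null ensemble
    (pseudo-sessions for stimulus, synthetic sessions for choice and
    feedback)."""
    from .core_data import filter_trials
    from .synthetic_data import TaskConfig

    cfg = cfg or TaskConfig()
    if trials is None:
        trials, _ = filter_trials(bundle.trials)
    window = window or DEFAULT_WINDOWS[variable]
    counts = bin_spikes(bundle, window, region=region, trials=trials).single
    target, mask = extract_binary_target(trials, variable)
    ss = _seed_seq(seed)
    s_obs, s_nulls, s_tgt = ss.spawn(3)
    observed = decode_binary(counts[mask], target, n_runs=n_runs, seed=s_obs)

    if variable == "stimulus":
        pseudo = nulls.make_pseudo_targets(cfg, len(trials), M, s_tgt)
        null_targets = [p["stim_side"].to_numpy()[mask] for p in pseudo]
    else:
        fit = nulls.fit_action_kernel(trials)
        synth = nulls.make_synthetic_targets(trials, fit, M, s_tgt, cfg=cfg)
        col = BINARY_TARGETS[variable]
        null_targets = [t[col].to_numpy()[mask] for t in synth]
    null_scores = []
    for tgt, child in zip(null_targets, s_nulls.spawn(M)):
        try:
            null_scores.append(decode_binary(counts[mask], tgt,
                                             n_runs=n_runs, seed=child))
        except InsufficientClassError:
            continue   # disallow degenerate pseudo/synthetic sessions
    if not null_scores:
        raise InsufficientClassError("all null sessions degenerate")
    kind = "pseudo" if variable == "stimulus" else "synthetic"
    ens = nulls.NullEnsemble(observed_score=observed,
                             null_scores=np.array(null_scores), kind=kind)
    return SessionDecodingResult(session_id=bundle.session_id, region=region,
                                 score=observed, ensemble=ens)


def decode_session_continuous(bundle: SessionBundle, region: str,
                              pool: list[SessionBundle],
                              variable: str = "wheel_speed",
                              M: int = 100, seed=None,
                              n_runs: int = N_RUNS_CONTINUOUS,
                              window: WindowSpec = WHEEL_WINDOW,
                              w_lags: int = W_LAGS) -> SessionDecodingResult:
    """Decode a wheel variable from one region against imposter nulls.

    The imposter pool holds *other* sessions; each null target is the
    per-trial binned wheel variable of L consecutive trials drawn from
    the pool's concatenation, decoded through the identical multirun
    nested-CV pipeline.
    """
    from .core_data import filter_trials

    if any(b.session_id == bundle.session_id for b in pool):
        raise ValueError("imposter pool must exclude the session under test")
    trials, _ = filter_trials(bundle.trials)
    counts = bin_spikes(bundle, window, region=region, trials=trials).counts
    target = wheel_target_bins(bundle, trials, variable, window)
    L = len(trials)
    # concatenated per-trial wheel matrices of the pool
    pool_rows = []
    for other in pool:
        o_trials, _ = filter_trials(other.trials)
        pool_rows.append(wheel_target_bins(other, o_trials, variable, window))
    cat = np.concatenate(pool_rows, axis=0)
    if cat.shape[0] < L:
        raise ValueError(f"imposter pool has {cat.shape[0]} trials, "
                         f"fewer than L={L}")
    ss = _seed_seq(seed)
    s_obs, s_null, s_pick = ss.spawn(3)
    observed = decode_continuous(counts, target, w_lags=w_lags,
                                 n_runs=n_runs, seed=s_obs)
    pick = np.random.default_rng(s_pick)
    null_scores = []
    for child in s_null.spawn(M):
        start = int(pick.integers(0, cat.shape[0] - L + 1))
        null_scores.append(decode_continuous(counts, cat[start:start + L],
                                             w_lags=w_lags, n_runs=n_runs,
                                             seed=child))
    ens = nulls.NullEnsemble(observed_score=observed,
                             null_scores=np.array(null_scores),
                             kind="imposter")
    return SessionDecodingResult(session_id=bundle.session_id, region=region,
                                 score=observed, ensemble=ens)
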