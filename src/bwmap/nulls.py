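"""Bespoke null distributions for neural-correlate statistics.

Slow drift in chronic recordings creates temporal correlation across
trials, so naive shuffles wildly overstate significance.  Each class of
task variable therefore gets its own null:

* pseudo-sessions — fresh draws from the task's known generative
  process (stimulus side and blocks), for behaviour-independent
  discrete variables;
* synthetic sessions — an action-kernel behavioural model fitted to the
  session's choices, replayed on pseudo-stimuli, for behaviour-dependent
  discrete variables (choice, feedback);
* imposter sessions — contiguous chunks of trials taken from other
  sessions, for continuous behavioural variables (wheel speed/velocity);
* the linear-shift test for point-by-point spike/behaviour correlation.

An observed score plus its null scores form a :class:`NullEnsemble`;
:func:`null_pvalue` converts it to a permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.signal import lfilter
from scipy.special import expit, logit

from .synthetic_data import (AgentParams, TaskConfig, generate_trial_sequence,
                             signed_evidence, simulate_agent)


@dataclass
class NullEnsemble:
    """Observed score plus M null scores with provenance."""

    observed_score: float
    null_scores: np.ndarray
    kind: str

    def __post_init__(self):
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        if self.null_scores.size < 1:
            raise ValueError("need at least one null score")
        if self.kind not in ("pseudo", "synthetic", "imposter",
                             "permutation", "linear_shift"):
            raise ValueError(f"unknown null kind {self.kind!r}")

    @property
    def M(self) -> int:
        return self.null_scores.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "kind": self.kind,
            "observed": self.observed_score,
            "null_idx": np.arange(self.M),
            "null_score": self.null_scores,
        })


def null_pvalue(ens: NullEnsemble, add_one: bool = True) -> float:
    """Permutation p-value of the observed score against its nulls.

    Default is the add-one form (1 + #{null >= obs}) / (M + 1), which is
    a valid, strictly positive p-value; ``add_one=False`` gives the raw
    percentile form 1 - rho used in the original analyses (which can be
    exactly zero).  Ties count against the observed score.
    """
    ge = int(np.sum(ens.null_scores >= ens.observed_score))
    if add_one:
        return (1.0 + ge) / (ens.M + 1.0)
    return ge / ens.M


# ---------------------------------------------------------------------------
# pseudo-sessions
# ---------------------------------------------------------------------------

def make_pseudo_targets(cfg: TaskConfig, n_trials: int, M: int,
                        seed=None) -> list[pd.DataFrame]:
    """M pseudo trial sequences drawn from the task's generative process,
    truncated (or regenerated longer, then truncated) to ``n_trials``."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    out = []
    use_cfg = cfg
    if cfg.session_length < n_trials:
        from dataclasses import replace
        use_cfg = replace(cfg, session_length=n_trials)
    for child in ss.spawn(M):
        t = generate_trial_sequence(use_cfg, np.random.default_rng(child))
        out.append(t.iloc[:n_trials].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# action-kernel fit and synthetic sessions
# ---------------------------------------------------------------------------

@dataclass
class ActionKernelFit:
    alpha: float
    params: AgentParams
    nll: float
    converged: bool = True


def _pi_trace(choices: np.ndarray, alpha: float, pi0: float) -> np.ndarray:
    """Prior value used on each trial, given the realized action sequence."""
    n = choices.size
    ind = (choices > 0).astype(float)
    if alpha == 0.0:
        return np.full(n, pi0)
    u = lfilter([alpha], [1.0, -(1.0 - alpha)], ind)
    pi = np.empty(n)
    pi[0] = pi0
    if n > 1:
        decay = (1.0 - alpha) ** np.arange(1, n)
        pi[1:] = u[:-1] + decay * pi0
    return pi


def action_kernel_nll(theta, choices, evidence, pi0: float = 0.5) -> float:
    """Negative log-likelihood of choices under prior update + policy."""
    alpha, slope, w, lapse = theta
    pi = _pi_trace(choices, alpha, pi0)
    z = np.clip(pi, 1e-6, 1.0 - 1e-6)
    p_r = lapse / 2.0 + (1.0 - lapse) * expit(slope * evidence + w * logit(z))
    p_r = np.clip(p_r, 1e-12, 1.0 - 1e-12)
    ll = np.where(choices > 0, np.log(p_r), np.log(1.0 - p_r))
    return -float(np.sum(ll))


_FIT_BOUNDS = [(0.0, 1.0), (0.0, 50.0), (0.0, 10.0), (0.0, 0.5)]
_FIT_STARTS = [
    (0.15, 3.0, 0.7, 0.02),
    (0.05, 1.0, 1.5, 0.10),
    (0.40, 6.0, 0.2, 0.02),
]


def fit_action_kernel(trials: pd.DataFrame, pi0: float = 0.5,
                      n_grid: int = 21) -> ActionKernelFit:
    """Maximum-likelihood learning rate of the action-kernel model.

    The policy's nuisance parameters (contrast slope, prior weight,
    lapse) are co-fitted by multi-start L-BFGS-B; the fit is then
    polished from the best point of a uniform grid over alpha to guard
    against local minima in the learning rate.
    """
    choices = trials["choice"].to_numpy(float)
    if choices.size < 2:
        raise ValueError("need at least two choices to fit")
    ev = signed_evidence(trials["stim_side"].to_numpy(float),
                         trials["contrast"].to_numpy(float))
    if np.all(choices == choices[0]):
        warnings.warn("all choices identical; learning rate is not "
                      "identified, returning the boundary value")
        a = 1.0 if choices[0] > 0 else 0.0
        theta = (a, 0.0, 0.0, 0.0)
        return ActionKernelFit(alpha=a, params=AgentParams(
            alpha=a, pi0=pi0, policy_slope=0.0, policy_prior_weight=0.0,
            lapse=0.0), nll=action_kernel_nll(theta, choices, ev, pi0),
            converged=False)

    best = None
    for x0 in _FIT_STARTS:
        res = optimize.minimize(action_kernel_nll, x0=np.array(x0),
                                args=(choices, ev, pi0), method="L-BFGS-B",
                                bounds=_FIT_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    # polish from the best alpha on a coarse grid, nuisance from `best`
    _, slope, w, lapse = best.x
    grid = np.linspace(0.0, 1.0, n_grid)
    grid_nll = [action_kernel_nll((a, slope, w, lapse), choices, ev, pi0)
                for a in grid]
    a_start = grid[int(np.argmin(grid_nll))]
    res = optimize.minimize(action_kernel_nll,
                            x0=np.array([a_start, slope, w, lapse]),
                            args=(choices, ev, pi0), method="L-BFGS-B",
                            bounds=_FIT_BOUNDS)
    if res.fun < best.fun:
        best = res
    alpha, slope, w, lapse = best.x
    params = AgentParams(alpha=float(alpha), pi0=pi0,
                         policy_slope=float(slope),
                         policy_prior_weight=float(w), lapse=float(lapse))
    return ActionKernelFit(alpha=float(alpha), params=params,
                           nll=float(best.fun), converged=bool(best.success))


def make_synthetic_targets(trials: pd.DataFrame, fit: ActionKernelFit,
                           M: int, seed=None,
                           cfg: TaskConfig = TaskConfig()) -> list[pd.DataFrame]:
    """M synthetic sessions: fitted agent replayed on pseudo-stimuli.

    Each element carries mutually consistent stim_side / choice /
    feedback columns (feedback is +1 iff the synthetic choice matches
    the pseudo stimulus side).
    """
    ss = np.random.SeedSequence(seed)
    pseudo = make_pseudo_targets(cfg, len(trials), M, ss.spawn(1)[0])
    out = []
    for p, child in zip(pseudo, ss.spawn(M)):
        t, _ = simulate_agent(p, fit.params, np.random.default_rng(child))
        out.append(t)
    return out


# ---------------------------------------------------------------------------
# imposter sessions
# ---------------------------------------------------------------------------

def make_imposter_targets(pool: list[pd.DataFrame], L: int, M: int,
                          seed=None) -> list[pd.DataFrame]:
    """M imposters: L consecutive trials from the concatenated pool.

    The pool must exclude the session under test; an imposter may span a
    session boundary of the concatenation but is always contiguous in
    the concatenated trial ordering.
    """
    if not pool:
        raise ValueError("empty imposter pool")
    cat = pd.concat(pool, ignore_index=True)
    if len(cat) < L:
        raise ValueError(
            f"imposter pool has {len(cat)} trials, fewer than L={L}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(M):
        start = int(rng.integers(0, len(cat) - L + 1))
        out.append(cat.iloc[start:start + L].reset_index(drop=True))
    return out


# ---------------------------------------------------------------------------
# linear-shift test
# ---------------------------------------------------------------------------

def _shift_correlations(spikes: np.ndarray, behav: np.ndarray,
                        n_trim: int) -> np.ndarray:
    """Correlations of the central behaviour segment with the spike
    series at all integer shifts -n..n (index n is the unshifted r)."""
    N = spikes.size
    L = N - 2 * n_trim
    b = behav[n_trim:N - n_trim].astype(float)
    b = b - b.mean()
    nb = np.sqrt(np.sum(b * b))
    windows = np.lib.stride_tricks.sliding_window_view(
        spikes.astype(float), L)          # (2n+1, L), window k = shift k-n
    wc = windows - windows.mean(axis=1, keepdims=True)
    nw = np.sqrt(np.sum(wc * wc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (wc @ b) / (nw * nb)
    return np.nan_to_num(r, nan=0.0)


def linear_shift_test(spike_series, behav_series, n_trim: int = 20,
                      alpha: float = 0.05):
    """Linear-shift control for nonsense correlation between two series.

    Both series are trimmed by ``n_trim`` samples at each end; the
    squared Pearson correlation of the central segments is ranked among
    the 2n+1 correlations obtained by integer shifts of the spike
    series.  The null is rejected when the unshifted r^2 lands in the
    top floor(alpha * (2n+1)) values (= 2 of 41 for the defaults), with
    rank ties broken against rejection.

    Returns (r_squared, p, reject).
    """
    spikes = np.asarray(spike_series, dtype=float)
    behav = np.asarray(behav_series, dtype=float)
    if spikes.shape != behav.shape or spikes.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if spikes.size <= 2 * n_trim + 1:
        raise ValueError("series too short for the requested trim")
    r = _shift_correlations(spikes, behav, n_trim)
    r2 = r ** 2
    r2_obs = r2[n_trim]
    others = np.delete(r2, n_trim)
    rank = 1 + int(np.sum(others >= r2_obs))
    n_shifts = 2 * n_trim + 1
    k = int(np.floor(alpha * n_shifts))
    return float(r2_obs), rank / n_shifts, rank <= k
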