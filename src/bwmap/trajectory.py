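"""Population-trajectory distance analysis.

For a binary task variable, every cell recorded in a region — pooled
across sessions at the cell level into a "supersession" — contributes a
trial-averaged response per condition on a fine time grid (12.5-ms bins,
2-ms stride).  The time-resolved separation of the two condition
trajectories is the Euclidean distance between the population mean
vectors normalized by sqrt(N cells), in spikes/s; its modulation
amplitude is A = max_t d(t) - min_t d(t) and the latency is the first
time the curve climbs 70% of the way from its minimum to its maximum.
Significance comes from pseudo-trials: condition labels are permuted
only among trials sharing the other task variables within each session
(for feedback, pseudo-choices are compared with the true stimulus sides
to derive pseudo-feedback), the supersession is rebuilt and the
amplitude recomputed M times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import aggregate
from .core_data import ALIGN_EVENTS, SessionBundle, filter_trials

BIN_LENGTH_S = 0.0125
STRIDE_S = 0.002
MIN_CELLS = 20
DEFAULT_WINDOW = (0.0, 0.150)
M_PSEUDO = 1000

#: per-variable: (condition column, alignment event, stratum columns)
VARIABLE_SPEC = {
    "stimulus": ("stim_side", "stim_on", ("choice", "block_idx")),
    "choice": ("choice", "first_move", ("stim_side", "block_idx")),
    "feedback": ("feedback", "feedback", ("stim_side", "block_idx")),
}


def overlapping_bin_starts(window=DEFAULT_WINDOW, bin_s=BIN_LENGTH_S,
                           stride=STRIDE_S) -> np.ndarray:
    """Bin start times; the final partial bin is dropped."""
    starts = []
    t = window[0]
    while t + bin_s <= window[1] + 1e-12:
        starts.append(t)
        t += stride
    return np.asarray(starts)


def _trial_cell_rates(bundle: SessionBundle, trials: pd.DataFrame,
                      align_col: str, starts: np.ndarray,
                      bin_s: float, region: str) -> np.ndarray:
    """(n_trials, n_cells, n_bins) firing rates in overlapping bins."""
    align = trials[align_col].to_numpy(float)
    cells = bundle.neuron_ids(region=region)
    out = np.zeros((len(trials), len(cells), starts.size))
    lo_edges = align[:, None] + starts[None, :]
    for j, nid in enumerate(cells):
        t = bundle.spike_times(nid)
        if t.size == 0:
            continue
        lo = np.searchsorted(t, lo_edges, side="left")
        hi = np.searchsorted(t, lo_edges + bin_s, side="left")
        out[:, j, :] = (hi - lo) / bin_s
    return out


@dataclass
class SessionCache:
    """Per-session ingredients of a supersession, kept for the null."""

    rates: np.ndarray          # trials x cells x bins
    labels: np.ndarray         # condition column, in {-1, +1}
    strata: np.ndarray         # trials x k stratum variables
    stim_side: np.ndarray      # needed for derived pseudo-feedback


@dataclass
class Supersession:
    """Pair of cells x time matrices of trial-averaged rates."""

    cond_neg: np.ndarray
    cond_pos: np.ndarray
    times: np.ndarray
    region: str
    variable: str
    sessions: list[SessionCache]
    excluded_cells: int = 0

    @property
    def n_cells(self) -> int:
        return self.cond_neg.shape[0]


def _session_means(rates, labels):
    """Per-cell trial-averaged rates for each condition, or None if a
    condition has no trials."""
    neg = labels < 0
    pos = labels > 0
    if not (np.any(neg) and np.any(pos)):
        return None
    return rates[neg].mean(axis=0), rates[pos].mean(axis=0)


def build_supersession(ensemble: list[SessionBundle], region: str,
                       variable: str, window=DEFAULT_WINDOW,
                       bin_s=BIN_LENGTH_S, stride=STRIDE_S,
                       min_cells: int = MIN_CELLS) -> Supersession:
    """Pool trial-averaged condition responses across sessions.

    Sessions whose trials cover only one condition contribute no cells
    (they are counted in ``excluded_cells``).  Raises when the pooled
    supersession has fewer than ``min_cells`` rows.
    """
    cond_col, align_event, strata_cols = VARIABLE_SPEC[variable]
    align_col = ALIGN_EVENTS[align_event]
    starts = overlapping_bin_starts(window, bin_s, stride)
    neg_rows, pos_rows, caches = [], [], []
    excluded = 0
    for bundle in ensemble:
        if region not in bundle.regions:
            continue
        trials, _ = filter_trials(bundle.trials)
        rates = _trial_cell_rates(bundle, trials, align_col, starts, bin_s,
                                  region)
        labels = trials[cond_col].to_numpy()
        means = _session_means(rates, labels)
        if means is None:
            excluded += rates.shape[1]
            continue
        neg_rows.append(means[0])
        pos_rows.append(means[1])
        caches.append(SessionCache(
            rates=rates, labels=labels,
            strata=trials[list(strata_cols)].to_numpy(),
            stim_side=trials["stim_side"].to_numpy()))
    if not neg_rows:
        raise ValueError(f"region {region!r} has no usable sessions")
    neg = np.concatenate(neg_rows, axis=0)
    pos = np.concatenate(pos_rows, axis=0)
    if neg.shape[0] < min_cells:
        raise ValueError(f"region {region!r} has {neg.shape[0]} cells, "
                         f"fewer than {min_cells}")
    return Supersession(cond_neg=neg, cond_pos=pos, times=starts,
                        region=region, variable=variable, sessions=caches,
                        excluded_cells=excluded)


# ---------------------------------------------------------------------------
# distance, amplitude, latency
# ---------------------------------------------------------------------------

def distance_curve(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """d(t) = ||m_a(t) - m_b(t)||_2 / sqrt(N); units spikes/s."""
    if cond_a.shape != cond_b.shape:
        raise ValueError("condition matrices must share shape")
    n = cond_a.shape[0]
    return np.linalg.norm(cond_a - cond_b, axis=0) / np.sqrt(n)


def amplitude_latency(times: np.ndarray, d: np.ndarray,
                      frac: float = 0.7):
    """Modulation amplitude A = max - min of d, and the first time the
    curve reaches min + frac * A.  A flat curve has A = 0 and an
    undefined (nan) latency."""
    d = np.asarray(d, dtype=float)
    a = float(d.max() - d.min())
    if a <= 0:
        return 0.0, float("nan")
    thresh = d.min() + frac * a
    idx = int(np.argmax(d >= thresh - 1e-12))
    return a, float(times[idx])


# ---------------------------------------------------------------------------
# pseudo-trial null
# ---------------------------------------------------------------------------

def _permute_within_strata(labels, strata_codes, rng):
    out = labels.copy()
    for c in np.unique(strata_codes):
        idx = np.flatnonzero(strata_codes == c)
        if idx.size > 1:
            out[idx] = labels[idx[rng.permutation(idx.size)]]
    return out


def _amplitude_from_sessions(sessions: list[SessionCache], labels_list):
    neg_rows, pos_rows = [], []
    for cache, labels in zip(sessions, labels_list):
        means = _session_means(cache.rates, labels)
        if means is None:
            continue
        neg_rows.append(means[0])
        pos_rows.append(means[1])
    if not neg_rows:
        return None
    d = distance_curve(np.concatenate(neg_rows), np.concatenate(pos_rows))
    return float(d.max() - d.min())


def pseudo_trial_null(ss: Supersession, M: int = M_PSEUDO, seed=None):
    """Permutation p-value for the modulation amplitude.

    Labels are shuffled within strata of the other task variables inside
    each session; for the feedback variable the *choice* labels are
    shuffled and compared with the true stimulus sides to obtain
    pseudo-feedback.  p = (n + 1) / (M + 1) with n the number of null
    amplitudes exceeding the observed one.
    """
    rng = np.random.default_rng(seed)
    d_obs = distance_curve(ss.cond_neg, ss.cond_pos)
    a_obs = float(d_obs.max() - d_obs.min())
    strata_codes = []
    for cache in ss.sessions:
        _, codes = np.unique(cache.strata, axis=0, return_inverse=True)
        strata_codes.append(codes)
    null_a = np.empty(M)
    for m in range(M):
        labels_list = []
        for cache, codes in zip(ss.sessions, strata_codes):
            if ss.variable == "feedback":
                # permute choices, derive pseudo-feedback from true sides
                choices = np.where(cache.labels > 0, cache.stim_side,
                                   -cache.stim_side)
                perm_choice = _permute_within_strata(choices, codes, rng)
                labels_list.append(np.where(perm_choice == cache.stim_side,
                                            1, -1))
            else:
                labels_list.append(
                    _permute_within_strata(cache.labels, codes, rng))
        a = _amplitude_from_sessions(ss.sessions, labels_list)
        null_a[m] = a if a is not None else 0.0
    n_exceed = int(np.sum(null_a > a_obs))
    p = (n_exceed + 1.0) / (M + 1.0)
    return p, a_obs, null_a


def trajectory_region_test(ensemble, region, variable, M: int = M_PSEUDO,
                           seed=None, window=DEFAULT_WINDOW,
                           min_cells: int = MIN_CELLS) -> aggregate.RegionResult:
    """Full per-region trajectory analysis: amplitude, latency, null p."""
    ss = build_supersession(ensemble, region, variable, window=window,
                            min_cells=min_cells)
    d = distance_curve(ss.cond_neg, ss.cond_pos)
    a, lat = amplitude_latency(ss.times, d)
    p, _, _ = pseudo_trial_null(ss, M=M, seed=seed)
    return aggregate.RegionResult(
        region=region, analysis=f"trajectory_{variable}", effect_size=a,
        p_combined=p, n_sessions=len(ss.sessions),
        extra={"latency_s": lat, "n_cells": ss.n_cells})


# ---------------------------------------------------------------------------
# visualization projection
# ---------------------------------------------------------------------------

def pca_project(ss: Supersession, n_components: int = 3):
    """Project both condition trajectories onto the first principal
    components of the concatenated pair (visualization only).

    Components follow a fixed sign convention: the largest-magnitude
    cell loading is positive.  Returns (traj_neg, traj_pos,
    explained_variance_ratio), trajectories as time x components.
    """
    from sklearn.decomposition import PCA

    data = np.concatenate([ss.cond_neg, ss.cond_pos], axis=1).T  # time x cells
    n_components = min(n_components, min(data.shape))
    pca = PCA(n_components=n_components)
    pca.fit(data)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    centred_neg = ss.cond_neg.T - pca.mean_
    centred_pos = ss.cond_pos.T - pca.mean_
    return (centred_neg @ comps.T, centred_pos @ comps.T,
            pca.explained_variance_ratio_)
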