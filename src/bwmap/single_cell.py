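"""Single-neuron correlates of task variables.

Selectivity of a neuron for a binary task variable is measured with the
Mann-Whitney U statistic expressed as an ROC area, both pooled over all
trials ("simple MW") and combined across conditions that hold the other
task variables fixed ("condition-combined MW", CCMW).  Significance
comes from a within-block permutation test: the tested label is
shuffled only among trials that share the values of the other task
variables inside each individual block, which controls jointly for
variable correlations and for slow temporal drift.  A neuron is called
sensitive when the simple-MW permutation p < 0.001 AND the CCMW
permutation p < 0.05; per-region fractions of sensitive neurons are
then referred to a Binomial(N_i, alpha_MW * alpha_CCMW) false-positive
model per session, Fisher-combined across sessions, and FDR-corrected
across regions.

The module also provides the task-responsiveness rank-sum tests, the
time-shift test for correlations with continuous behaviour traces, and
receptive-field mapping against the sparse-noise stimulus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from . import aggregate
from .core_data import (DEFAULT_WINDOWS, SessionBundle, WindowSpec,
                        bin_spikes, seed_sequence)
from .synthetic_data import RFStimulus, rf_transition_maps

ALPHA_MW = 0.001
ALPHA_CCMW = 0.05
N_PERMUTATIONS = 3000
#: dual-criterion false-positive rate assumed by the binomial model
ALPHA_SENSITIVE = ALPHA_MW * ALPHA_CCMW


# ---------------------------------------------------------------------------
# Mann-Whitney statistics
# ---------------------------------------------------------------------------

def mw_statistic(x, y):
    """Mann-Whitney U (min-folded) and its ROC-area form P = U/(n1 n2).

    Midranks are used for ties; P lies in [0, 0.5] with 0.5 meaning
    fully overlapping rate distributions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one observation")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    return u, u / (n1 * n2)


def ccmw_statistic(conditions, per_condition_min: bool = False):
    """Condition-combined Mann-Whitney ROC area.

    ``conditions`` is a sequence of (x_j, y_j) trial-rate pairs, one per
    combination of the other task variables.  Per-condition U statistics
    are oriented consistently for the first group before summation and
    the min-fold is applied to the sums, so exactly opposing effects in
    two conditions cancel to 0.5 rather than reinforcing.  Conditions
    with an empty side are excluded.  With ``per_condition_min`` the
    (directionless) literal per-condition fold is used instead.
    """
    u1_sum = u2_sum = denom = 0.0
    used = 0
    for x, y in conditions:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n1, n2 = x.size, y.size
        if n1 < 1 or n2 < 1:
            continue
        ranks = stats.rankdata(np.concatenate([x, y]))
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        u2 = n1 * n2 - u1
        if per_condition_min:
            u1_sum += min(u1, u2)
            u2_sum += min(u1, u2)
        else:
            u1_sum += u1
            u2_sum += u2
        denom += n1 * n2
        used += 1
    if used == 0:
        raise ValueError("no condition has observations on both sides")
    return min(u1_sum, u2_sum) / denom


# ---------------------------------------------------------------------------
# within-block permutation test
# ---------------------------------------------------------------------------

def _strata_indices(strata) -> list[np.ndarray]:
    strata = np.asarray(strata)
    if strata.ndim == 1:
        strata = strata[:, None]
    # integer-encode tuples of stratum variables
    _, codes = np.unique(strata, axis=0, return_inverse=True)
    return [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]


def _perm_statistics(rates, labels, strata_idx, n_perm, rng):
    """Observed and permuted (MW, CCMW) ROC areas under within-stratum
    label shuffles, vectorized over permutations.

    Returns (p_mw_obs, p_ccmw_obs, p_mw_perm, p_ccmw_perm) where each
    perm array has length n_perm.  Strata with a single trial (or with
    one side empty) contribute nothing to the statistic and are left
    unpermuted by construction.
    """
    rates = np.asarray(rates, dtype=float)
    pos = np.asarray(labels) > 0
    g_ranks = stats.rankdata(rates)
    mw_u1 = np.zeros(n_perm + 1)       # slot 0 = observed
    cc_u1 = np.zeros(n_perm + 1)
    mw_denoms = 0.0
    cc_denom = 0.0
    n1_tot = 0
    n_tot = rates.size
    for idx in strata_idx:
        m = idx.size
        n1 = int(pos[idx].sum())
        n2 = m - n1
        n1_tot += n1
        loc_ranks = stats.rankdata(rates[idx])
        if n1 >= 1 and n2 >= 1:
            cc_denom += n1 * n2
        # observed
        mw_u1[0] += g_ranks[idx[pos[idx]]].sum()
        cc_u1[0] += loc_ranks[pos[idx]].sum() - n1 * (n1 + 1) / 2.0 \
            if (n1 and n2) else 0.0
        if n1 == 0 or n2 == 0 or m == 1:
            # nothing to permute; constant contribution
            mw_u1[1:] += g_ranks[idx[pos[idx]]].sum()
            continue
        keys = rng.random((n_perm, m))
        sel = np.argpartition(keys, n1 - 1, axis=1)[:, :n1]
        mw_u1[1:] += g_ranks[idx][sel].sum(axis=1)
        cc_u1[1:] += loc_ranks[sel].sum(axis=1) - n1 * (n1 + 1) / 2.0
    n2_tot = n_tot - n1_tot
    mw_u1 -= n1_tot * (n1_tot + 1) / 2.0
    mw_denom = n1_tot * n2_tot
    if mw_denom == 0:
        p_mw = np.full(n_perm + 1, 0.5)
    else:
        p_mw = np.minimum(mw_u1, mw_denom - mw_u1) / mw_denom
    if cc_denom == 0:
        p_cc = np.full(n_perm + 1, 0.5)
    else:
        p_cc = np.minimum(cc_u1, cc_denom - cc_u1) / cc_denom
    return p_mw[0], p_cc[0], p_mw[1:], p_cc[1:]


def _perm_pvalue(obs, perm) -> float:
    """Two-sided permutation p on the extremeness |P - 0.5| (add-one)."""
    e_obs = abs(obs - 0.5)
    e_perm = np.abs(perm - 0.5)
    return (1.0 + int(np.sum(e_perm >= e_obs - 1e-12))) / (perm.size + 1.0)


def within_block_permutation(rates, labels, strata,
                             n_perm: int = N_PERMUTATIONS, seed=None,
                             statistic: str = "ccmw") -> float:
    """Permutation p-value for one statistic under within-stratum shuffles."""
    strata_idx = _strata_indices(strata)
    rng = np.random.default_rng(seed)
    mw_obs, cc_obs, mw_perm, cc_perm = _perm_statistics(
        rates, labels, strata_idx, n_perm, rng)
    if statistic == "mw":
        return _perm_pvalue(mw_obs, mw_perm)
    if statistic == "ccmw":
        return _perm_pvalue(cc_obs, cc_perm)
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass
class CCMWResult:
    p_pooled: float                 # CCMW ROC area (Eq. form), observed
    p_mw_stat: float                # simple MW ROC area, observed
    perm_p_mw: float
    perm_p_ccmw: float
    significant_mw: bool = field(init=False)
    significant_ccmw: bool = field(init=False)
    sensitive: bool = field(init=False)

    def __post_init__(self):
        self.significant_mw = self.perm_p_mw < ALPHA_MW
        self.significant_ccmw = self.perm_p_ccmw < ALPHA_CCMW
        self.sensitive = self.significant_mw and self.significant_ccmw


def selectivity_test(rates, labels, strata, n_perm: int = N_PERMUTATIONS,
                     seed=None) -> CCMWResult:
    """Joint simple-MW and condition-combined test for one neuron.

    One pass of within-stratum permutations evaluates both statistics;
    the dual criterion (MW p < 0.001 and CCMW p < 0.05) defines a
    sensitive neuron.
    """
    strata_idx = _strata_indices(strata)
    rng = np.random.default_rng(seed)
    mw_obs, cc_obs, mw_perm, cc_perm = _perm_statistics(
        rates, labels, strata_idx, n_perm, rng)
    return CCMWResult(p_pooled=float(cc_obs), p_mw_stat=float(mw_obs),
                      perm_p_mw=_perm_pvalue(mw_obs, mw_perm),
                      perm_p_ccmw=_perm_pvalue(cc_obs, cc_perm))


#: which trial columns define the label and the conditioning strata for
#: each task variable (strata always include the block instance)
VARIABLE_SPEC = {
    "stimulus": ("stim_side", ("choice", "block_idx")),
    "choice": ("choice", ("stim_side", "block_idx")),
    "feedback": ("feedback", ("stim_side", "block_idx")),
}


def classify_sensitive(bundle: SessionBundle, trials: pd.DataFrame,
                       variable: str, n_perm: int = N_PERMUTATIONS,
                       seed=None, region: str | None = None) -> pd.DataFrame:
    """Sensitivity classification for every neuron of a session.

    Firing rates are taken in the variable's canonical window (stimulus
    0-100 ms post-onset, choice -100-0 ms pre-movement, feedback
    0-200 ms post-feedback).
    """
    label_col, strata_cols = VARIABLE_SPEC[variable]
    window = DEFAULT_WINDOWS[variable]
    counts = bin_spikes(bundle, window, region=region, trials=trials)
    labels = trials[label_col].to_numpy()
    strata = trials[list(strata_cols)].to_numpy()
    ss = seed_sequence(seed)
    rows = []
    for j, child in zip(range(counts.single.shape[1]), ss.spawn(counts.single.shape[1])):
        res = selectivity_test(counts.single[:, j], labels, strata,
                               n_perm=n_perm, seed=child)
        rows.append({
            "neuron_id": counts.neuron_index[j],
            "ccmw_P": res.p_pooled,
            "p_mw": res.perm_p_mw,
            "p_ccmw": res.perm_p_ccmw,
            "sensitive": res.sensitive,
        })
    return pd.DataFrame(rows)


def region_fraction_test(n_neurons_per_session, n_sensitive_per_session,
                         alpha: float = ALPHA_SENSITIVE):
    """Binomial false-positive test of per-session sensitive fractions.

    p_i = P(Binomial(N_i, alpha) >= k_i); the region p combines the
    session p-values with Fisher's method.
    """
    ps = []
    for n, k in zip(n_neurons_per_session, n_sensitive_per_session):
        ps.append(float(stats.binom.sf(k - 1, n, alpha)) if k > 0 else 1.0)
    return ps, aggregate.fisher_combine(ps)


# ---------------------------------------------------------------------------
# responsiveness
# ---------------------------------------------------------------------------

#: (name, alignment event, window) of the task-period rank-sum tests;
#: the baseline is -200..0 ms before stimulus onset
RESPONSIVENESS_WINDOWS = (
    ("stim_early", WindowSpec("stim_on", 0.050, 0.150)),
    ("stim_long", WindowSpec("stim_on", 0.0, 0.400)),
    ("move_early", WindowSpec("first_move", -0.100, 0.050)),
    ("move_late", WindowSpec("first_move", -0.050, 0.200)),
    ("reward", WindowSpec("feedback", 0.0, 0.150)),
)
BASELINE_WINDOW = WindowSpec("stim_on", -0.200, 0.0)


def responsiveness_tests(bundle: SessionBundle, trials: pd.DataFrame,
                         neuron_id) -> dict[str, float]:
    """Rank-sum p-values comparing each task window to baseline.

    Counts are converted to rates (spikes/s) so windows of unequal
    length are comparable; the reward window uses correct trials only.
    An empty spike train yields p = 1 everywhere, with a warning.
    """
    if bundle.spike_times(neuron_id).size == 0:
        warnings.warn(f"neuron {neuron_id} has no spikes; responsiveness "
                      "undefined, returning p = 1")
        return {name: 1.0 for name, _ in RESPONSIVENESS_WINDOWS}

    def rates(window, mask=None):
        t = trials if mask is None else trials[mask]
        c = bin_spikes(bundle, window, trials=t)
        j = int(np.flatnonzero(c.neuron_index == neuron_id)[0])
        return c.single[:, j] / (window.end - window.start)

    base = rates(BASELINE_WINDOW)
    out = {}
    for name, window in RESPONSIVENESS_WINDOWS:
        mask = trials["feedback"].to_numpy() > 0 if name == "reward" else None
        r = rates(window, mask)
        b = base if mask is None else base[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
        if np.all(r == r[0]) and np.all(b == b[0]) and r[0] == b[0]:
            out[name] = 1.0
            continue
        out[name] = float(stats.ranksums(r, b).pvalue)
    return out


# ---------------------------------------------------------------------------
# time-shift correlation with behaviour traces
# ---------------------------------------------------------------------------

def timeshift_correlation(spike_counts_50ms, behav_trace, k_shifts: int = 20):
    """Zero-lag Pearson r against a behaviour trace plus the time-shift
    significance test: 2K = 40 shifted correlations (offsets of 1..K
    bins = 50..1000 ms, both signs), p = m / (2K + 1) with m the number
    of shifted |r| exceeding the unshifted |r|.

    Returns (r, p); a constant trace gives (nan, nan) and a warning.
    """
    s = np.asarray(spike_counts_50ms, dtype=float)
    b = np.asarray(behav_trace, dtype=float)
    if s.shape != b.shape:
        raise ValueError("series must be equally long")
    if np.ptp(b) == 0 or np.ptp(s) == 0:
        warnings.warn("constant series; correlation undefined, excluded")
        return np.nan, np.nan
    K = k_shifts
    if s.size <= 2 * K + 1:
        raise ValueError("series too short for the requested shifts")
    centre_s = s[K:-K]
    centre_b = b[K:-K]
    r0 = np.corrcoef(centre_s, centre_b)[0, 1]
    m = 0
    for k in range(-K, K + 1):
        if k == 0:
            continue
        rk = np.corrcoef(s[K + k:s.size - K + k], centre_b)[0, 1]
        if abs(rk) > abs(r0):
            m += 1
    return float(r0), m / (2 * K + 1)


# ---------------------------------------------------------------------------
# receptive-field mapping
# ---------------------------------------------------------------------------

@dataclass
class RFMapResult:
    rf_on: np.ndarray
    rf_off: np.ndarray
    center_on: tuple | None
    center_off: tuple | None
    ve_on: float
    ve_off: float
    p_on: float
    p_off: float
    significant: bool


def _transition_rates(spike_times, trans, frame_rate, response_s=0.100):
    """Mean spike rate in the response window after each pixel's
    transitions of one polarity; (grid, grid) map."""
    g = trans.shape[1]
    out = np.zeros((g, g))
    st = np.asarray(spike_times, dtype=float)
    for i in range(g):
        for j in range(g):
            f = np.flatnonzero(trans[:, i, j]) + 1   # transition at frame f
            if f.size == 0:
                continue
            t0 = f / frame_rate
            lo = np.searchsorted(st, t0, side="left")
            hi = np.searchsorted(st, t0 + response_s, side="left")
            out[i, j] = np.mean(hi - lo) / response_s
    return out


def _gauss2d(coords, amp, cy, cx, width, offset):
    y, x = coords
    return (offset + amp * np.exp(-(((y - cy) ** 2 + (x - cx) ** 2)
                                    / (2.0 * width ** 2)))).ravel()


def fit_gaussian_rf(rf: np.ndarray):
    """2-D Gaussian fit; returns (variance explained, (cy, cx)) or
    (0, None) when the fit fails or the map is flat."""
    g = rf.shape[0]
    ss_tot = np.sum((rf - rf.mean()) ** 2)
    if ss_tot == 0:
        return 0.0, None
    yy, xx = np.mgrid[0:g, 0:g]
    peak = np.unravel_index(np.argmax(rf), rf.shape)
    p0 = (rf.max() - rf.min(), peak[0], peak[1], 1.5, rf.min())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss2d, (yy, xx), rf.ravel(), p0=p0,
                                method="lm", maxfev=400)
    except RuntimeError:
        return 0.0, None
    if not (popt[0] >= 0 and -2 <= popt[1] <= g + 1
            and -2 <= popt[2] <= g + 1):
        # diverged fit: no credible receptive field
        return 0.0, None
    pred = _gauss2d((yy, xx), *popt)
    ve = 1.0 - np.sum((rf.ravel() - pred) ** 2) / ss_tot
    return float(ve), (float(popt[1]), float(popt[2]))


def rf_map(spike_times, stim: RFStimulus, n_shuffles: int = 200,
           seed=None, response_s: float = 0.100,
           alpha: float = 0.01) -> RFMapResult:
    """On/off receptive fields with a spatial-shuffle significance test.

    The per-pixel response maps are fit with a 2-D Gaussian; the
    variance explained is compared with fits of maps whose pixel
    positions were randomly shuffled (which preserves the rate
    histogram).  A neuron has a significant RF when either polarity's
    shuffle p < 0.01.
    """
    rng = np.random.default_rng(seed)
    on, off = rf_transition_maps(stim)
    maps = {}
    ves = {}
    centers = {}
    ps = {}
    for name, trans in (("on", on), ("off", off)):
        rf = _transition_rates(spike_times, trans, stim.frame_rate,
                               response_s)
        ve, center = fit_gaussian_rf(rf)
        flat = rf.ravel()
        count = 0
        for _ in range(n_shuffles):
            shuf = flat[rng.permutation(flat.size)].reshape(rf.shape)
            ve_s, _ = fit_gaussian_rf(shuf)
            if ve_s >= ve:
                count += 1
        maps[name], ves[name], centers[name] = rf, ve, center
        ps[name] = (1.0 + count) / (n_shuffles + 1.0)
    return RFMapResult(rf_on=maps["on"], rf_off=maps["off"],
                       center_on=centers["on"], center_off=centers["off"],
                       ve_on=ves["on"], ve_off=ves["off"],
                       p_on=ps["on"], p_off=ps["off"],
                       significant=min(ps["on"], ps["off"]) < alpha)
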