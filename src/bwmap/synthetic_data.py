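"""Synthetic sessions of the IBL decision-making task with known ground truth.

The generator emulates every ingredient the downstream statistics
assume: the task's trial/block structure (90 unbiased trials with
2:2:2:2:1 contrast ratios, then 20:80 biased blocks whose lengths follow
a truncated exponential with scale 60 trials), an action-kernel agent
whose subjective prior is an exponential running average of its own past
actions, trial event times with first-movement latencies in
[0.08, 2.0] s, a rotary-encoder-like wheel trace, spike trains drawn
from an inhomogeneous Poisson process whose log-rate is a linear
function of the same design matrix the encoding model fits (plus slow
AR(1) multiplicative drift and an optional ~10 Hz post-reward
oscillation), and the sparse-noise receptive-field stimulus (15 x 15
grid, 3 luminance states, 60 Hz).

Seeding is hierarchical (session seed -> per-neuron seeds), so adding
neurons to a session never perturbs the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import encoding
from .core_data import SessionBundle


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class TaskConfig:
    """Parameters of the task's generative process."""

    n_unbiased_trials: int = 90
    contrast_levels: tuple = (1.0, 0.25, 0.125, 0.0625, 0.0)
    #: per-side counts of each contrast in the unbiased phase; the zero
    #: contrast count is the total (its side is assigned uniformly)
    unbiased_contrast_counts: tuple = (10, 10, 10, 10, 10)
    block_prior_right: tuple = (0.2, 0.8)
    block_length_scale: float = 60.0
    block_length_bounds: tuple = (20, 100)
    quiescence_bounds: tuple = (0.4, 0.7)
    session_length: int = 600

    def __post_init__(self):
        if abs(sum(self.block_prior_right) - 1.0) > 1e-12:
            raise ValueError("complementary block priors must sum to 1")
        if self.block_length_bounds[0] > self.block_length_bounds[1]:
            raise ValueError("block length bounds must satisfy min <= max")
        if self.block_length_scale <= 0:
            raise ValueError("block length scale must be positive")
        lv = self.contrast_levels
        if list(lv) != sorted(lv, reverse=True) or lv[-1] != 0.0:
            raise ValueError("contrast levels must be sorted descending, 0 last")
        if self.session_length < self.n_unbiased_trials:
            raise ValueError("session shorter than the unbiased phase")


@dataclass
class AgentParams:
    """Action-kernel agent: prior update rule plus decision policy.

    The subjective prior follows pi_{t+1} = (1 - alpha) pi_t +
    alpha * 1[a_t > 0].  The decision policy (a stand-in; the task paper
    defers it to a companion behavioural study) is
    p(right) = lapse/2 + (1 - lapse) * sigmoid(slope * e + w * logit(pi))
    with e = sign(side) * tanh(5c)/tanh(5) the signed saturating
    contrast evidence.
    """

    alpha: float = 0.15
    pi0: float = 0.5
    policy_slope: float = 4.5
    policy_prior_weight: float = 0.7
    lapse: float = 0.01

    def __post_init__(self):
        for name in ("alpha", "pi0", "lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.policy_slope < 0 or self.policy_prior_weight < 0:
            raise ValueError("policy weights must be non-negative")


@dataclass
class GroundTruthTuning:
    """Per-neuron generative tuning for a population of n neurons.

    ``amplitudes`` maps each kernel-group name of the encoding design
    (stim_left, ..., wheel_speed) to an (n,)-vector of gains; the gain
    scales a fixed decreasing weight profile over that group's bases.
    Drift is AR(1) on a per-trial log-gain.
    """

    baseline: np.ndarray
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    drift_coef: float = 0.0
    drift_sd: float = 0.0
    lick_freq_hz: float = 0.0
    lick_gain: float = 0.0

    def __post_init__(self):
        self.baseline = np.atleast_1d(np.asarray(self.baseline, float))
        if np.any(self.baseline <= 0):
            raise ValueError("baseline rates must be positive")
        if not 0.0 <= self.drift_coef < 1.0:
            raise ValueError("AR coefficient must lie in [0, 1)")
        if self.lick_gain and self.lick_freq_hz <= 0:
            raise ValueError("lick frequency must be positive when enabled")
        n = self.baseline.size
        for k, v in self.amplitudes.items():
            self.amplitudes[k] = np.broadcast_to(
                np.asarray(v, float), (n,)).copy()

    @property
    def n_neurons(self) -> int:
        return self.baseline.size


#: how a scalar kernel gain is spread over a group's bases (fast bases
#: weighted most; truncated to the group's basis count)
KERNEL_WEIGHT_PROFILE = np.array([1.0, 0.5, 0.25, 0.1, 0.05])


@dataclass
class RFStimulus:
    """Sparse-noise stimulus: (n_frames, 15, 15) luminance states."""

    states: np.ndarray            # int8, values {0 dark, 1 grey, 2 white}
    frame_rate: float = 60.0
    switch_prob: float = 1.0 / 6.0

    def __post_init__(self):
        if self.states.ndim != 3 or self.states.shape[0] < 1:
            raise ValueError("need at least one frame of grid states")
        if not set(np.unique(self.states)) <= {0, 1, 2}:
            raise ValueError("states must take values in {0, 1, 2}")


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# task structure
# ---------------------------------------------------------------------------

def sample_block_lengths(scale: float = 60.0, bounds=(20, 100),
                         n: int = 1, seed=None) -> np.ndarray:
    """Truncated-exponential block lengths, rounded to whole trials.

    Rejection sampling (redraw until inside the bounds) keeps the
    density shape intact rather than piling mass at the bounds; the
    draw is then rounded to the nearest integer.
    """
    if scale <= 0 or bounds[0] > bounds[1] or n < 1:
        raise ValueError("invalid scale, bounds or count")
    rng = _rng(seed)
    if bounds[0] == bounds[1]:
        return np.full(n, int(round(bounds[0])))
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.exponential(scale, size=todo.size)
        ok = (draw >= bounds[0]) & (draw <= bounds[1])
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    lengths = np.rint(out).astype(int)
    return np.clip(lengths, bounds[0], bounds[1])


def truncated_exponential_mean(scale: float, bounds=(20, 100)) -> float:
    """Closed-form mean of Exp(scale) conditioned on [a, b]."""
    a, b = bounds
    w = b - a
    return a + scale - w * np.exp(-w / scale) / (1.0 - np.exp(-w / scale))


def generate_trial_sequence(cfg: TaskConfig = TaskConfig(),
                            seed=None) -> pd.DataFrame:
    """Stimulus sides, contrasts and block labels (no behaviour yet).

    The unbiased phase has exact per-level, per-side contrast counts;
    biased blocks then alternate 20:80 / 80:20 with lengths from
    :func:`sample_block_lengths`, the first block side chosen uniformly.
    """
    rng = _rng(seed)
    sides, contrasts = [], []
    for level, count in zip(cfg.contrast_levels, cfg.unbiased_contrast_counts):
        if level == 0.0:
            sides += list(rng.choice([-1, 1], size=count))
            contrasts += [0.0] * count
        else:
            sides += [-1] * count + [1] * count
            contrasts += [level] * (2 * count)
    sides = np.array(sides)
    contrasts = np.array(contrasts)
    if sides.size != cfg.n_unbiased_trials:
        raise ValueError("unbiased contrast counts do not sum to the "
                         "configured number of unbiased trials")
    order = rng.permutation(sides.size)
    sides, contrasts = sides[order], contrasts[order]
    p_block = np.full(sides.size, 0.5)
    block_idx = np.zeros(sides.size, dtype=int)

    n_rest = cfg.session_length - cfg.n_unbiased_trials
    # contrast ratio 2:2:2:2:1 over (100, 25, 12.5, 6.25, 0)%
    weights = np.array([2.0] * (len(cfg.contrast_levels) - 1) + [1.0])
    weights /= weights.sum()
    first_prior = int(rng.integers(0, 2))
    b_idx = 1
    all_sides, all_contrasts, all_p, all_b = [sides], [contrasts], [p_block], [block_idx]
    n_done = 0
    while n_done < n_rest:
        length = int(sample_block_lengths(cfg.block_length_scale,
                                          cfg.block_length_bounds, 1, rng)[0])
        length = min(length, n_rest - n_done)
        p_right = float(cfg.block_prior_right[(first_prior + b_idx - 1) % 2])
        s = np.where(rng.random(length) < p_right, 1, -1)
        c = rng.choice(cfg.contrast_levels, size=length, p=weights)
        all_sides.append(s)
        all_contrasts.append(c)
        all_p.append(np.full(length, p_right))
        all_b.append(np.full(length, b_idx, dtype=int))
        n_done += length
        b_idx += 1
    trials = pd.DataFrame({
        "trial_idx": np.arange(cfg.session_length),
        "stim_side": np.concatenate(all_sides),
        "contrast": np.concatenate(all_contrasts),
        "p_right_block": np.concatenate(all_p),
        "block_idx": np.concatenate(all_b),
    })
    return trials


# ---------------------------------------------------------------------------
# agent behaviour
# ---------------------------------------------------------------------------

def update_prior(pi_t: float, a_t: int, alpha: float) -> float:
    """One step of the action-kernel prior update."""
    if a_t not in (-1, 1):
        raise ValueError("action must be -1 or +1")
    if not (0.0 <= pi_t <= 1.0 and 0.0 <= alpha <= 1.0):
        raise ValueError("pi and alpha must lie in [0, 1]")
    return (1.0 - alpha) * pi_t + alpha * (1.0 if a_t > 0 else 0.0)


def signed_evidence(side, contrast) -> np.ndarray:
    return np.sign(side) * encoding.contrast_height(contrast)


def policy_p_right(pi, evidence, params: AgentParams) -> np.ndarray:
    """Probability of a rightward choice given prior and evidence."""
    z = np.clip(pi, 1e-6, 1 - 1e-6)
    drive = params.policy_slope * evidence + params.policy_prior_weight * logit(z)
    return params.lapse / 2.0 + (1.0 - params.lapse) * expit(drive)


def simulate_agent(trials: pd.DataFrame, params: AgentParams = AgentParams(),
                   seed=None, rt_median_base: float = 0.28,
                   rt_contrast_slowing: float = 0.9, rt_sigma: float = 0.35):
    """Play the action-kernel agent through a trial sequence.

    Adds choices, feedback and event times; first-movement latencies are
    log-normal with a contrast-dependent median (slower at low
    contrast), clipped to [0.08, 2.0] s.  Returns the completed trial
    table and the prior trace pi_t (value used on each trial).
    """
    rng = _rng(seed)
    n = len(trials)
    side = trials["stim_side"].to_numpy(float)
    contrast = trials["contrast"].to_numpy(float)
    ev = signed_evidence(side, contrast)
    pi = params.pi0
    pi_trace = np.empty(n)
    choice = np.empty(n, dtype=int)
    for t in range(n):
        pi_trace[t] = pi
        p_r = policy_p_right(pi, ev[t], params)
        choice[t] = 1 if rng.random() < p_r else -1
        pi = update_prior(pi, choice[t], params.alpha)
    feedback = np.where(choice == side, 1, -1)

    h = encoding.contrast_height(contrast)
    med = rt_median_base * (1.0 + rt_contrast_slowing * (1.0 - h))
    rt = np.exp(np.log(med) + rt_sigma * rng.standard_normal(n))
    rt = np.clip(rt, 0.08, 2.0)
    quiescence = rng.uniform(*_quiescence_bounds(trials), size=n)
    move_dur = rng.uniform(0.2, 0.35, size=n)
    post = np.where(feedback == 1, 1.0, 2.0) + rng.uniform(0.5, 1.0, size=n)

    stim_on = np.empty(n)
    t_cursor = 2.0
    for t in range(n):
        stim_on[t] = t_cursor + quiescence[t]
        t_cursor = stim_on[t] + rt[t] + move_dur[t] + post[t]
    out = trials.copy()
    out["choice"] = choice
    out["feedback"] = feedback
    out["quiescence_s"] = quiescence
    out["stim_on_s"] = stim_on
    out["first_move_s"] = stim_on + rt
    out["feedback_s"] = stim_on + rt + move_dur
    return out, pi_trace


def _quiescence_bounds(trials) -> tuple:
    return (0.4, 0.7)


# ---------------------------------------------------------------------------
# wheel
# ---------------------------------------------------------------------------

def simulate_wheel(trials: pd.DataFrame, seed=None,
                   sample_rate: float = 100.0,
                   turn_amplitude: float = 3.0,
                   turn_duration: float = 0.3,
                   extra_move_prob: float = 0.35) -> pd.DataFrame:
    """Wheel trace with a smooth turn at each trial's first movement.

    Sign convention: positive velocity corresponds to the movement made
    for a rightward choice.  Velocity is zero during quiescence and
    between trials; position is the integral of velocity.  A fraction of
    trials carries a smaller secondary (corrective) movement after the
    first one, as real wheel traces do — so movement-initiation events
    are not one-to-one with first movements.
    """
    rng = _rng(seed)
    t_end = float(trials["feedback_s"].max()) + 2.0
    t = np.arange(0.0, t_end, 1.0 / sample_rate)
    v = np.zeros_like(t)

    def add_turn(t_on, direction, amp):
        sel = (t >= t_on) & (t < t_on + turn_duration)
        v[sel] += direction * amp * np.sin(
            np.pi * (t[sel] - t_on) / turn_duration)

    for mv, ch in zip(trials["first_move_s"].to_numpy(float),
                      trials["choice"].to_numpy(float)):
        if not np.isfinite(mv) or ch == 0:
            continue
        amp = turn_amplitude * np.exp(0.2 * rng.standard_normal())
        add_turn(mv, ch, amp)
        if rng.random() < extra_move_prob:
            direction = ch if rng.random() < 0.7 else -ch
            add_turn(mv + rng.uniform(0.4, 0.9), direction, 0.4 * amp)
    pos = np.cumsum(v) / sample_rate
    return pd.DataFrame({"time_s": t, "position_rad": pos,
                         "velocity_rad_s": v})


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

_LOG_RATE_CLIP = 4.0
_SUBBINS = 4   # 5-ms simulation subgrid inside each 20-ms design bin


def tuning_to_beta(tuning: GroundTruthTuning, groups: dict) -> np.ndarray:
    """Expand per-group scalar gains into design-matrix coefficients."""
    n_cols = max(sl.stop for sl in groups.values())
    beta = np.zeros((tuning.n_neurons, n_cols))
    for name, sl in groups.items():
        if name not in tuning.amplitudes:
            continue
        width = sl.stop - sl.start
        profile = KERNEL_WEIGHT_PROFILE[:width]
        beta[:, sl] = tuning.amplitudes[name][:, None] * profile[None, :]
    return beta


def simulate_spikes(trials: pd.DataFrame, wheel: pd.DataFrame | None,
                    tuning: GroundTruthTuning, duration: float | None = None,
                    seed=None, dm: encoding.DesignMatrix | None = None):
    """Inhomogeneous-Poisson spike trains for a tuned population.

    rate(t) = baseline * exp(clip(X beta) + drift_trial (+ lick
    oscillation after correct feedback)), where X is exactly the
    encoding design matrix for these trials.  Between trial windows the
    rate is baseline times the prevailing drift gain.  Returns
    (spikes DataFrame, info dict with the per-trial drift trace).
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    if dm is None:
        dm = encoding.build_design_matrix(trials, wheel)
    n_trials, n_bins, bin_s = dm.n_trials, dm.n_bins, dm.bin_s
    if duration is None:
        duration = float(trials["feedback_s"].max()) + 2.0
    beta = tuning_to_beta(tuning, dm.groups)
    drive = np.clip(dm.X @ beta.T, -_LOG_RATE_CLIP, _LOG_RATE_CLIP)
    drive = drive.reshape(n_trials, n_bins, tuning.n_neurons)

    stim_on = trials["stim_on_s"].to_numpy(float)
    t0 = stim_on + encoding.TRIAL_WINDOW[0]
    fb_t = trials["feedback_s"].to_numpy(float)
    correct = trials["feedback"].to_numpy(float) > 0

    # absolute 5-ms subgrid per trial window
    sub = bin_s / _SUBBINS
    rel_sub = (np.arange(n_bins * _SUBBINS) + 0.5) * sub
    abs_sub = t0[:, None] + rel_sub[None, :]

    # global inter-trial grid (20 ms), excluding trial windows
    g_edges = np.arange(0.0, duration + bin_s, bin_s)
    g_mid = 0.5 * (g_edges[:-1] + g_edges[1:])
    in_window = np.zeros(g_mid.size, dtype=bool)
    win_len = n_bins * bin_s
    for l in range(n_trials):
        in_window |= (g_mid >= t0[l]) & (g_mid < t0[l] + win_len)
    # drift gain lookup per global bin: value of the nearest trial at or
    # before the bin (first trial's value before the first trial)
    trial_of_gbin = np.clip(np.searchsorted(t0, g_mid, side="right") - 1,
                            0, n_trials - 1)

    child_seeds = ss.spawn(tuning.n_neurons + 1)
    drift_rng = np.random.default_rng(child_seeds[0])
    rows_id, rows_t = [], []
    drift_traces = np.zeros((tuning.n_neurons, n_trials))
    for i in range(tuning.n_neurons):
        rng = np.random.default_rng(child_seeds[i + 1])
        if tuning.drift_sd > 0:
            z = np.empty(n_trials)
            sd0 = tuning.drift_sd / np.sqrt(max(1e-12, 1 - tuning.drift_coef ** 2))
            z[0] = sd0 * rng.standard_normal()
            eps = rng.standard_normal(n_trials - 1) * tuning.drift_sd
            for l in range(1, n_trials):
                z[l] = tuning.drift_coef * z[l - 1] + eps[l - 1]
        else:
            z = np.zeros(n_trials)
        drift_traces[i] = z

        # rates on the per-trial 5-ms subgrid
        log_gain = drive[:, :, i] + z[:, None]
        rate = tuning.baseline[i] * np.exp(log_gain)
        rate_sub = np.repeat(rate, _SUBBINS, axis=1)
        if tuning.lick_gain and tuning.lick_freq_hz > 0:
            dt_fb = abs_sub - fb_t[:, None]
            osc = np.where(correct[:, None] & (dt_fb >= 0) & (dt_fb < 0.5),
                           tuning.lick_gain
                           * np.sin(2 * np.pi * tuning.lick_freq_hz * dt_fb),
                           0.0)
            rate_sub = rate_sub * np.exp(osc)
        counts = rng.poisson(rate_sub * sub)
        hit = np.nonzero(counts)
        if hit[0].size:
            reps = counts[hit]
            times = np.repeat(abs_sub[hit], reps)
            times = times + sub * (rng.random(times.size) - 0.5)
            rows_t.append(times)
            rows_id.append(np.full(times.size, i))

        # inter-trial bins at baseline x drift gain
        gap_rate = tuning.baseline[i] * np.exp(z[trial_of_gbin])
        gap_rate[in_window] = 0.0
        gcounts = rng.poisson(gap_rate * bin_s)
        hit = np.nonzero(gcounts)[0]
        if hit.size:
            reps = gcounts[hit]
            times = np.repeat(g_mid[hit], reps)
            times = times + bin_s * (rng.random(times.size) - 0.5)
            rows_t.append(times)
            rows_id.append(np.full(times.size, i))

    if rows_t:
        spikes = pd.DataFrame({
            "neuron_id": np.concatenate(rows_id),
            "time_s": np.concatenate(rows_t),
        })
        spikes = spikes[(spikes["time_s"] >= 0) & (spikes["time_s"] < duration)]
        spikes = spikes.sort_values(["neuron_id", "time_s"],
                                    kind="stable").reset_index(drop=True)
    else:
        spikes = pd.DataFrame({"neuron_id": np.array([], int),
                               "time_s": np.array([], float)})
    return spikes, {"drift": drift_traces, "beta": beta}


# ---------------------------------------------------------------------------
# RF stimulus and RF neuron
# ---------------------------------------------------------------------------

def generate_rf_stimulus(n_frames: int, switch_prob: float = 1.0 / 6.0,
                         frame_rate: float = 60.0, grid: int = 15,
                         seed=None) -> RFStimulus:
    """Sparse-noise grid: each pixel switches state with a fixed per-frame
    probability, moving to one of the other two luminance states."""
    rng = _rng(seed)
    states = np.empty((n_frames, grid, grid), dtype=np.int8)
    states[0] = rng.integers(0, 3, size=(grid, grid))
    for f in range(1, n_frames):
        cur = states[f - 1]
        switch = rng.random((grid, grid)) < switch_prob
        # jump to one of the two other states with equal probability
        step = rng.integers(1, 3, size=(grid, grid))
        states[f] = np.where(switch, (cur + step) % 3, cur)
    return RFStimulus(states=states, frame_rate=frame_rate,
                      switch_prob=switch_prob)


def rf_state_epochs(stim: RFStimulus) -> np.ndarray:
    """Durations (frames) of completed constant-state epochs, all pixels."""
    changed = np.diff(stim.states, axis=0) != 0
    durations = []
    g = stim.states.shape[1]
    for i in range(g):
        for j in range(g):
            idx = np.flatnonzero(changed[:, i, j])
            if idx.size >= 2:
                durations.append(np.diff(idx))
    if not durations:
        return np.array([], dtype=int)
    return np.concatenate(durations)


def rf_transition_maps(stim: RFStimulus):
    """Per-frame maps of brightness increases (on) and decreases (off)."""
    d = np.diff(stim.states.astype(np.int16), axis=0)
    on = (d > 0)
    off = (d < 0)
    return on, off


def gaussian_2d(grid: int, center: tuple, width: float) -> np.ndarray:
    yy, xx = np.mgrid[0:grid, 0:grid]
    cy, cx = center
    return np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * width ** 2)))


def simulate_rf_neuron(stim: RFStimulus, true_center: tuple,
                       true_width: float = 1.5, polarity: str = "on",
                       seed=None, base_rate: float = 2.0,
                       gain: float = 40.0,
                       response_s: float = 0.100) -> np.ndarray:
    """Spike times of a neuron driven by brightness transitions of one
    polarity, weighted by a 2-D Gaussian over pixel position."""
    rng = _rng(seed)
    on, off = rf_transition_maps(stim)
    trans = on if polarity == "on" else off
    g = stim.states.shape[1]
    w = gaussian_2d(g, true_center, true_width)
    drive = np.tensordot(trans.astype(float), w, axes=([1, 2], [0, 1]))
    # transitions elevate the rate for `response_s` after they occur
    k = max(1, int(round(response_s * stim.frame_rate)))
    kernel = np.ones(k) / k
    smooth = np.convolve(drive, kernel)[:drive.size]
    rate = base_rate + gain * smooth          # per frame index (offset by 1)
    dt = 1.0 / stim.frame_rate
    counts = rng.poisson(rate * dt)
    hit = np.flatnonzero(counts)
    times = np.repeat((hit + 1.5) * dt, counts[hit])
    return np.sort(times + dt * (rng.random(times.size) - 0.5))


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

#: default drift parameters for the null-drift scenario: slow AR(1) on
#: the per-trial log-gain, strong enough to induce nonsense correlations
NULL_DRIFT = {"drift_coef": 0.97, "drift_sd": 0.15}

#: default tuned-scenario gains per region (kernel-group gain applied to
#: every neuron of the region, jittered per neuron)
DEFAULT_TUNING_MAP = {
    "VIS": {"stim_right": 2.0, "stim_left": 0.3},
    "MOT": {"move_right": 1.5, "move_left": 0.3, "wheel_speed": 0.3},
    "FRP": {"feedback_correct": 1.5, "feedback_incorrect": 0.3},
}


def generate_session(session_id: str, cfg: TaskConfig, agent: AgentParams,
                     region_neurons: dict[str, int],
                     region_tuning: dict[str, dict[str, float]],
                     seed, drift: dict | None = None,
                     amplitude_jitter: float = 0.3) -> SessionBundle:
    """One full synthetic session with ground truth stored alongside."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    s_trials, s_agent, s_wheel, s_spk, s_amp = ss.spawn(5)
    trials = generate_trial_sequence(cfg, np.random.default_rng(s_trials))
    trials, pi = simulate_agent(trials, agent, np.random.default_rng(s_agent))
    wheel = simulate_wheel(trials, np.random.default_rng(s_wheel))

    amp_rng = np.random.default_rng(s_amp)
    regions, baselines, amps = [], [], []
    for region, n_neu in region_neurons.items():
        tun = region_tuning.get(region, {})
        for _ in range(n_neu):
            regions.append(region)
            baselines.append(amp_rng.uniform(3.0, 12.0))
            amps.append({k: v * np.exp(amplitude_jitter
                                       * amp_rng.standard_normal())
                         for k, v in tun.items()})
    n_total = len(regions)
    amplitudes = {}
    for k in set(key for a in amps for key in a):
        amplitudes[k] = np.array([a.get(k, 0.0) for a in amps])
    drift = drift or {}
    tuning = GroundTruthTuning(baseline=np.array(baselines),
                               amplitudes=amplitudes, **drift)
    spikes, info = simulate_spikes(trials, wheel, tuning, seed=s_spk)
    neurons = pd.DataFrame({
        "neuron_id": np.arange(n_total),
        "region": regions,
        "session_id": session_id,
        "well_isolated": True,
    })
    gt = {
        "agent": vars(agent).copy(),
        "pi_trace": pi,
        "baseline": tuning.baseline,
        "amplitudes": {k: v for k, v in tuning.amplitudes.items()},
        "drift_coef": tuning.drift_coef,
        "drift_sd": tuning.drift_sd,
        "drift_traces": info["drift"],
    }
    return SessionBundle(session_id=session_id, trials=trials, spikes=spikes,
                         neurons=neurons, wheel=wheel, ground_truth=gt)


def generate_ensemble(n_sessions: int, regions: list[str],
                      neurons_per_region=(5, 10),
                      scenario: str = "tuned", seed=None,
                      cfg: TaskConfig = TaskConfig(),
                      agent: AgentParams = AgentParams(),
                      tuning_map: dict | None = None) -> list[SessionBundle]:
    """A list of sessions recording the given regions.

    Scenarios: ``null-drift`` (no event tuning, AR(1) drift only),
    ``tuned`` (region gains from ``tuning_map``, drift on) and ``mixed``
    (half the sessions tuned, half drift-only).
    """
    if scenario not in ("null-drift", "tuned", "mixed"):
        raise ValueError(f"unknown scenario {scenario!r}")
    ss = np.random.SeedSequence(seed)
    session_seeds = ss.spawn(n_sessions + 1)
    pick = np.random.default_rng(session_seeds[0])
    tuning_map = DEFAULT_TUNING_MAP if tuning_map is None else tuning_map
    bundles = []
    for s in range(n_sessions):
        n_per = {r: int(pick.integers(neurons_per_region[0],
                                      neurons_per_region[1] + 1))
                 for r in regions}
        tuned = scenario == "tuned" or (scenario == "mixed" and s % 2 == 0)
        region_tuning = tuning_map if tuned else {}
        bundles.append(generate_session(
            session_id=f"synthetic-{s:03d}", cfg=cfg, agent=agent,
            region_neurons=n_per, region_tuning=region_tuning,
            seed=session_seeds[s + 1], drift=dict(NULL_DRIFT)))
    return bundles
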