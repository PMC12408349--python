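"""Shared data model: session bundles, inclusion filters, spike binning.

A :class:`SessionBundle` is the universal input of every analysis: a
trial table, a spike-event table, neuron metadata (region, isolation
flag) and the wheel trace.  Bundles round-trip through a set of small,
versioned CSV schemas so that user-supplied data can be analysed with
exactly the same code paths as synthetic sessions.

Conventions (documented once, used everywhere):

* times are seconds (float); trial alignment subtracts the event time;
* analysis windows and bins are half-open ``[start, end)`` so that
  partitioning a window into bins conserves spike counts;
* the trial first-movement-latency filter is a closed interval
  ``[0.08, 2.00]`` s;
* ``stim_side``, ``choice`` and ``feedback`` are coded in {-1, +1}
  (left/right, incorrect/correct).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: columns a trial table must provide before filtering
REQUIRED_TRIAL_COLUMNS = (
    "trial_idx", "stim_side", "contrast", "p_right_block",
    "choice", "feedback", "stim_on_s", "first_move_s", "feedback_s",
)

#: closed latency bounds (s) between stimulus onset and first wheel movement
LATENCY_BOUNDS = (0.08, 2.00)

#: session gates: minimum trials in the data release vs for analysis
RELEASE_MIN_TRIALS = 250
ANALYSIS_MIN_TRIALS = 400
MIN_INCORRECT_TRIALS = 3
MIN_PERFORMANCE_FULL_CONTRAST = 0.90

#: region gates: sessions with >=5 well-isolated neurons, >=2 such
#: sessions, >=20 neurons pooled
MIN_NEURONS_PER_SESSION = 5
MIN_SESSIONS_PER_REGION = 2
MIN_POOLED_NEURONS = 20

ALIGN_EVENTS = {
    "stim_on": "stim_on_s",
    "first_move": "first_move_s",
    "feedback": "feedback_s",
}


def seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce ints, Generators' seeds or SeedSequences to a SeedSequence."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass
class WindowSpec:
    """Alignment event plus a relative analysis window.

    ``bin`` is the bin width in seconds, or ``"single"`` for one count
    per trial spanning the whole window.
    """

    align_event: str
    start: float
    end: float
    bin: float | str = "single"

    def __post_init__(self):
        if self.align_event not in ALIGN_EVENTS:
            raise ValueError(f"unknown alignment event {self.align_event!r}")
        if not self.start < self.end:
            raise ValueError("window start must precede end")
        if self.bin != "single":
            if not 0 < float(self.bin) <= self.end - self.start:
                raise ValueError("bin must be positive and fit the window")

    @property
    def n_bins(self) -> int:
        if self.bin == "single":
            return 1
        return int(np.floor((self.end - self.start) / float(self.bin) + 1e-9))

    def bin_edges(self) -> np.ndarray:
        if self.bin == "single":
            return np.array([self.start, self.end])
        return self.start + float(self.bin) * np.arange(self.n_bins + 1)


#: default per-variable windows used by the decoding and single-cell
#: analyses (stimulus 0-100 ms post-onset, choice 100 ms pre-movement,
#: feedback 0-200 ms post-feedback)
DEFAULT_WINDOWS = {
    "stimulus": WindowSpec("stim_on", 0.0, 0.100),
    "choice": WindowSpec("first_move", -0.100, 0.0),
    "feedback": WindowSpec("feedback", 0.0, 0.200),
}


def windows_from_config(config) -> dict[str, WindowSpec]:
    """Per-analysis windows from a JSON file or mapping.

    ``config`` maps analysis names to ``{"align_event", "start", "end",
    "bin"}`` entries (``bin`` optional); unspecified analyses fall back
    to :data:`DEFAULT_WINDOWS`.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    out = dict(DEFAULT_WINDOWS)
    for name, spec in config.items():
        out[name] = WindowSpec(spec["align_event"], float(spec["start"]),
                               float(spec["end"]), spec.get("bin", "single"))
    return out


@dataclass
class SessionBundle:
    """One recording session: trials, spikes, neuron metadata, wheel."""

    session_id: str
    trials: pd.DataFrame
    spikes: pd.DataFrame          # columns: neuron_id, time_s
    neurons: pd.DataFrame         # columns: neuron_id, region, well_isolated
    wheel: pd.DataFrame | None = None   # columns: time_s, position_rad, velocity_rad_s
    ground_truth: dict | None = None

    def __post_init__(self):
        known = set(self.neurons["neuron_id"])
        seen = set(self.spikes["neuron_id"].unique())
        if not seen <= known:
            raise ValueError("spike table references unknown neuron ids")
        # per-neuron spike times must be non-decreasing
        s = self.spikes.sort_values(["neuron_id", "time_s"], kind="stable")
        if not np.array_equal(s.index.to_numpy(),
                              self.spikes.sort_values("neuron_id", kind="stable").index.to_numpy()):
            self.spikes = s.reset_index(drop=True)

    @property
    def regions(self) -> list[str]:
        return sorted(self.neurons["region"].unique())

    def neuron_ids(self, region: str | None = None,
                   well_isolated_only: bool = True) -> np.ndarray:
        meta = self.neurons
        if well_isolated_only and "well_isolated" in meta:
            meta = meta[meta["well_isolated"].astype(bool)]
        if region is not None:
            meta = meta[meta["region"] == region]
        return meta["neuron_id"].to_numpy()

    def spike_times(self, neuron_id) -> np.ndarray:
        return self.spikes.loc[self.spikes["neuron_id"] == neuron_id,
                               "time_s"].to_numpy()


@dataclass
class BinnedCounts:
    """Spike counts aligned to trial events: trials x neurons x bins."""

    counts: np.ndarray
    window: WindowSpec
    trial_index: np.ndarray
    neuron_index: np.ndarray

    def __post_init__(self):
        if self.counts.shape[:2] != (len(self.trial_index),
                                     len(self.neuron_index)):
            raise ValueError("counts shape inconsistent with index maps")

    @property
    def single(self) -> np.ndarray:
        """Trials x neurons matrix (bins summed)."""
        return self.counts.sum(axis=2)


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------

def filter_trials(trials: pd.DataFrame):
    """Drop trials with missing events or out-of-range movement latency.

    Latency is the time from stimulus onset to first wheel movement and
    must fall in the closed interval [0.08, 2.00] s.  Returns the kept
    rows and a machine-readable drop log (trial_idx, reason).
    """
    missing_cols = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials]
    if missing_cols:
        raise ValueError(f"trial table lacks columns {missing_cols}")
    reasons = []
    keep = np.ones(len(trials), dtype=bool)
    event_cols = ["stim_side", "contrast", "p_right_block", "choice",
                  "feedback", "stim_on_s", "first_move_s", "feedback_s"]
    missing = trials[event_cols].isna().any(axis=1).to_numpy()
    for idx in trials.index[missing]:
        reasons.append((trials.at[idx, "trial_idx"], "missing_event"))
    keep &= ~missing
    latency = (trials["first_move_s"] - trials["stim_on_s"]).to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad_lat = ~missing & ((latency < LATENCY_BOUNDS[0])
                              | (latency > LATENCY_BOUNDS[1]))
    for idx in trials.index[bad_lat]:
        reasons.append((trials.at[idx, "trial_idx"], "latency_out_of_range"))
    keep &= ~bad_lat
    log = pd.DataFrame(reasons, columns=["trial_idx", "reason"])
    return trials[keep].reset_index(drop=True), log


def filter_sessions(bundle: SessionBundle, min_trials: int = ANALYSIS_MIN_TRIALS):
    """Evaluate the session gates; returns (passed, reasons).

    The release gate (>=250 valid trials, >=3 incorrect, >=90% correct on
    100%-contrast trials in both biased block types) and the analysis
    gate (>=400 valid trials) are evaluated and reported separately.
    """
    trials, _ = filter_trials(bundle.trials)
    reasons = {}
    n = len(trials)
    reasons["release_min_trials"] = n >= RELEASE_MIN_TRIALS
    reasons["analysis_min_trials"] = n >= min_trials
    n_incorrect = int((trials["feedback"] == -1).sum())
    reasons["min_incorrect"] = n_incorrect >= MIN_INCORRECT_TRIALS
    perf_ok = True
    for p_right in (0.2, 0.8):
        sel = (trials["p_right_block"] == p_right) & (trials["contrast"] == 1.0)
        if sel.sum() == 0:
            perf_ok = False
            continue
        acc = float((trials.loc[sel, "feedback"] == 1).mean())
        perf_ok &= acc >= MIN_PERFORMANCE_FULL_CONTRAST
    reasons["performance_full_contrast"] = perf_ok
    passed = all(reasons.values())
    return passed, reasons


def filter_regions(ensemble: list[SessionBundle]) -> list[str]:
    """Canonical region set across an ensemble of sessions.

    A region is kept iff it has >=2 sessions contributing >=5
    well-isolated neurons each and >=20 well-isolated neurons pooled
    over those sessions.  Neurons are pooled across probes within a
    session (metadata carries no probe split).
    """
    per_region_sessions: dict[str, list[int]] = {}
    for bundle in ensemble:
        meta = bundle.neurons
        if "well_isolated" in meta:
            meta = meta[meta["well_isolated"].astype(bool)]
        for region, grp in meta.groupby("region"):
            per_region_sessions.setdefault(str(region), []).append(len(grp))
    kept = []
    for region, counts in per_region_sessions.items():
        qualifying = [c for c in counts if c >= MIN_NEURONS_PER_SESSION]
        if (len(qualifying) >= MIN_SESSIONS_PER_REGION
                and sum(qualifying) >= MIN_POOLED_NEURONS):
            kept.append(region)
    return sorted(kept)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_spikes(bundle: SessionBundle, window: WindowSpec,
               region: str | None = None,
               trials: pd.DataFrame | None = None) -> BinnedCounts:
    """Count spikes in event-aligned, half-open bins.

    A spike exactly at a bin's left edge is counted in that bin; a spike
    exactly at the window end is not counted.
    """
    if trials is None:
        trials = bundle.trials
    align = trials[ALIGN_EVENTS[window.align_event]].to_numpy(float)
    neuron_ids = bundle.neuron_ids(region=region)
    edges = window.bin_edges()
    n_bins = window.n_bins
    counts = np.zeros((len(trials), len(neuron_ids), n_bins), dtype=np.int64)
    spikes = bundle.spikes
    for j, nid in enumerate(neuron_ids):
        t = spikes.loc[spikes["neuron_id"] == nid, "time_s"].to_numpy(float)
        if t.size == 0:
            continue
        # absolute edge positions per trial; searchsorted('left') twice
        # implements the half-open convention
        abs_edges = align[:, None] + edges[None, :]
        pos = np.searchsorted(t, abs_edges, side="left")
        counts[:, j, :] = np.diff(pos, axis=1)
    return BinnedCounts(counts=counts, window=window,
                        trial_index=trials["trial_idx"].to_numpy(),
                        neuron_index=neuron_ids)


# ---------------------------------------------------------------------------
# CSV schema I/O
# ---------------------------------------------------------------------------

def save_session(bundle: SessionBundle, out_dir) -> Path:
    """Write a bundle to the documented CSV schemas (plus JSON sidecars)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.trials.to_csv(out / "trials.csv", index=False)
    bundle.spikes.to_csv(out / "spikes.csv", index=False)
    bundle.neurons.to_csv(out / "neurons.csv", index=False)
    if bundle.wheel is not None:
        bundle.wheel.to_csv(out / "wheel.csv", index=False)
    meta = {"schema_version": SCHEMA_VERSION, "session_id": bundle.session_id}
    (out / "session.json").write_text(json.dumps(meta))
    if bundle.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(bundle.ground_truth, default=_json_default))
    return out


def load_session(in_dir) -> SessionBundle:
    src = Path(in_dir)
    meta = json.loads((src / "session.json").read_text())
    wheel = None
    if (src / "wheel.csv").exists():
        wheel = pd.read_csv(src / "wheel.csv")
    gt = None
    if (src / "ground_truth.json").exists():
        gt = json.loads((src / "ground_truth.json").read_text())
    return SessionBundle(
        session_id=meta["session_id"],
        trials=pd.read_csv(src / "trials.csv"),
        spikes=pd.read_csv(src / "spikes.csv"),
        neurons=pd.read_csv(src / "neurons.csv"),
        wheel=wheel,
        ground_truth=gt,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
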