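"""Kernel-basis encoding model of single-neuron activity.

Fits the ridge regression of 20-ms spike counts on raised-cosine event
kernels (contrast-scaled stimulus kernels, anticausal movement and
wheel-speed kernels, block probability) for every neuron of the first
simulated session, and reports cross-validated R^2, leave-one-group-out
delta R^2 and the left/right and correct/incorrect pair sensitivities.
No significance is attached to encoding scores (there is no convenient
null); effect sizes only.

Writes results/encoding_neurons.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bwmap import core_data, encoding

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    bundle = core_data.load_session(sorted((ROOT / "data").iterdir())[0])
    trials, _ = core_data.filter_trials(bundle.trials)
    dm = encoding.build_design_matrix(trials, bundle.wheel)
    t0s = trials["stim_on_s"].to_numpy() + encoding.TRIAL_WINDOW[0]
    rows = []
    for nid in bundle.neuron_ids():
        t = bundle.spike_times(nid)
        counts = np.empty(dm.n_trials * dm.n_bins)
        for l in range(dm.n_trials):
            edges = t0s[l] + dm.bin_s * np.arange(dm.n_bins + 1)
            counts[l * dm.n_bins:(l + 1) * dm.n_bins] = np.diff(
                np.searchsorted(t, edges))
        fit = encoding.fit_encoding(counts, dm, seed=int(nid))
        deltas = encoding.all_delta_r2(counts, dm, fit)
        row = {"neuron_id": nid,
               "region": bundle.neurons.set_index("neuron_id").loc[
                   nid, "region"],
               "r2_full": fit.r2, "alpha": fit.alpha}
        row.update({f"dr2_{k}": v for k, v in deltas.items()})
        for a, b in encoding.SENSITIVITY_PAIRS:
            row[f"sens_{a}_vs_{b}"] = encoding.pair_sensitivity(
                deltas[a], deltas[b])
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "encoding_neurons.csv", index=False)
    cols = ["region", "r2_full"] + [c for c in table if c.startswith("dr2_")]
    print(table[cols].groupby("region").mean().round(4).to_string())


if __name__ == "__main__":
    main()
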