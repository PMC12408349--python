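"""Single-cell selectivity for stimulus side and region fractions.

Classifies every neuron of the simulated ensemble with the dual
criterion (simple Mann-Whitney permutation p < 0.001 AND
condition-combined p < 0.05, both under within-block label shuffles),
then refers each region's per-session fraction of sensitive neurons to
the Binomial(N, 5e-5) false-positive model, Fisher-combines sessions
and applies BH FDR across regions.

Writes results/single_cell_neurons.csv and results/single_cell_regions.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bwmap import aggregate, core_data, single_cell as sc

ROOT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 3000
SEED = 11


def main():
    ensemble = [core_data.load_session(p)
                for p in sorted((ROOT / "data").iterdir())]
    regions = core_data.filter_regions(ensemble)
    neuron_rows, region_rows = [], []
    ss = np.random.SeedSequence(SEED)
    for region, child in zip(regions, ss.spawn(len(regions))):
        session_n, session_k = [], []
        for bundle, c in zip(ensemble, child.spawn(len(ensemble))):
            if region not in bundle.regions:
                continue
            trials, _ = core_data.filter_trials(bundle.trials)
            df = sc.classify_sensitive(bundle, trials, "stimulus",
                                       n_perm=N_PERM, seed=c, region=region)
            df.insert(0, "session", bundle.session_id)
            df.insert(1, "region", region)
            neuron_rows.append(df)
            session_n.append(len(df))
            session_k.append(int(df["sensitive"].sum()))
        _, region_p = sc.region_fraction_test(session_n, session_k)
        region_rows.append({
            "region": region,
            "n_neurons": sum(session_n),
            "n_sensitive": sum(session_k),
            "fraction": sum(session_k) / max(1, sum(session_n)),
            "p_combined": region_p,
        })
    neurons = pd.concat(neuron_rows, ignore_index=True)
    regions_df = pd.DataFrame(region_rows)
    regions_df["significant"] = aggregate.fdr(
        regions_df["p_combined"].to_numpy(), q=0.01)
    neurons.to_csv(ROOT / "single_cell_neurons.csv", index=False)
    regions_df.to_csv(ROOT / "single_cell_regions.csv", index=False)
    print(regions_df.to_string(index=False))


if __name__ == "__main__":
    main()
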