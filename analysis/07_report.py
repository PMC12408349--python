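"""Cross-analysis comparison table.

Collects the region-level outcomes of the decoding, single-cell and
trajectory analyses, min-max-normalizes effect sizes within each
analysis, and writes the combined comparison table plus a heatmap.

Writes results/report.csv and results/report.png.
"""

from pathlib import Path

import pandas as pd

from bwmap import aggregate

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    results = []
    dec = pd.read_csv(ROOT / "decoding_stimulus.csv")
    for _, r in dec.iterrows():
        results.append(aggregate.RegionResult(
            r["region"], "decoding", r["effect_size"], r["p_combined"],
            int(r["n_sessions"]), bool(r["significant"])))
    cell = pd.read_csv(ROOT / "single_cell_regions.csv")
    for _, r in cell.iterrows():
        results.append(aggregate.RegionResult(
            r["region"], "single_cell", r["fraction"], r["p_combined"],
            1, bool(r["significant"])))
    traj = pd.read_csv(ROOT / "trajectory_stimulus.csv")
    for _, r in traj.iterrows():
        results.append(aggregate.RegionResult(
            r["region"], "trajectory", r["amplitude_sp_s"], r["p"],
            1, bool(r["significant"])))
    table = aggregate.build_report(results)
    table.to_csv(ROOT / "report.csv", index=False)
    aggregate.plot_report(table, ROOT / "report.png")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
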