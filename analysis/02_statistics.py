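#!/usr/bin/env python
"""Characterize every simulated dataset with the seven dataset indicators.

For each dataset written by 01_simulate.py and each cross-validation
scenario, computes size, activity ratio, the two activity-order indices
(AOIE, AOIC) and the mean top-5 protein / chemical similarities, after the
scenario's balance filter. Writes results/dataset_statistics.csv.
"""

from pathlib import Path

import pandas as pd

from ecipred import compute_statistics, load_dataset
from ecipred.evaluation import SCENARIOS

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "datasets"
RESULTS = ROOT / "results"


def main() -> None:
    rows = []
    for dataset_dir in sorted(SCRATCH.iterdir()):
        dataset = load_dataset(dataset_dir)
        for scenario in SCENARIOS:
            stats = compute_statistics(dataset, scenario)
            row = {"dataset": dataset_dir.name, "scenario": scenario}
            row.update(stats.as_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "dataset_statistics.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
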