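#!/usr/bin/env python
"""Relate dataset indicators to hold-out prediction performance.

For every dataset of the mutation-rate sweep, runs LPOT (held-out enzymes)
cross-validation with the full-descriptor model (rf_all) and records the
mean AUPR and AUROC. Those per-dataset scores are then correlated, across
datasets, with each dataset indicator computed by 02_statistics.py.

Writes results/suite_performance.csv, results/correlations.csv and
results/statistic_correlations.csv (the indicator-indicator matrix).
"""

import dataclasses
from pathlib import Path

import pandas as pd

from ecipred import (
    DescriptorSpec,
    correlate_statistics_with_performance,
    load_dataset,
    run_cv,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "datasets"
RESULTS = ROOT / "results"
SEEDS = (11, 23, 37)
STAT_COLUMNS = [
    "n_enzymes", "n_chemicals", "activity_ratio", "aoie", "aoic",
    "top5_protein_similarity", "top5_chemical_similarity",
]


def main() -> None:
    perf_rows = []
    for dataset_dir in sorted(SCRATCH.glob("sweep_*")):
        dataset = load_dataset(dataset_dir)
        result = run_cv(
            dataset,
            DescriptorSpec("composition50"),
            DescriptorSpec("chem_fingerprint"),
            variants=["rf_all"],
            scenario="LPOT",
            seeds=SEEDS,
            n_folds=10,
        )
        agg = result.aggregates().set_index("metric")
        perf_rows.append(
            {"dataset": dataset_dir.name,
             "aupr": agg.loc["aupr", "mean"], "auroc": agg.loc["auroc", "mean"]}
        )
        print(f"{dataset_dir.name}: AUPR {perf_rows[-1]['aupr']:.3f}, "
              f"AUROC {perf_rows[-1]['auroc']:.3f}")

    perf = pd.DataFrame(perf_rows).set_index("dataset")
    perf.to_csv(RESULTS / "suite_performance.csv")

    stats_all = pd.read_csv(RESULTS / "dataset_statistics.csv")
    stats = (
        stats_all[(stats_all.scenario == "LPOT")
                  & stats_all.dataset.str.startswith("sweep_")]
        .set_index("dataset")[STAT_COLUMNS]
    )
    # correlation is undefined for indicators that do not vary over the suite
    stats = stats.loc[:, stats.nunique() > 1]

    records, stat_corr = correlate_statistics_with_performance(stats, perf)
    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    table.to_csv(RESULTS / "correlations.csv", index=False)
    stat_corr.to_csv(RESULTS / "statistic_correlations.csv")
    print()
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
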