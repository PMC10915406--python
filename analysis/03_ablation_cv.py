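#!/usr/bin/env python
"""Descriptor-ablation cross-validation on the reference dataset.

Runs 10-fold cross-validation under all three hold-out scenarios (LOOT:
random pairs held out; LPOT: whole enzymes held out; LCOT: whole chemicals
held out) for the four Random-Forest ablation variants (rf_all, rf_protein,
rf_chemical, rf_none) and the two baselines, over three CV seeds. Enzymes
are described by the 50-dimensional composition descriptor, chemicals by
2048-bit Morgan fingerprints.

Writes, per scenario:
  results/cv_<scenario>_aggregates.csv   mean / sd / sem per variant x metric
  results/cv_<scenario>_comparisons.csv  pairwise t-tests with significance stars
"""

from pathlib import Path

import pandas as pd

from ecipred import DescriptorSpec, compare_models, load_dataset, run_cv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEEDS = (11, 23, 37)
RF_VARIANTS = ["rf_all", "rf_protein", "rf_chemical", "rf_none"]


def main() -> None:
    dataset = load_dataset(ROOT / "scratch" / "datasets" / "reference")
    enzyme_spec = DescriptorSpec("composition50")
    chemical_spec = DescriptorSpec("chem_fingerprint")

    for scenario in ("LOOT", "LPOT", "LCOT"):
        variants = RF_VARIANTS + ["random_baseline"]
        if scenario != "LOOT":  # the activity model needs held-out objects
            variants.append("activity_baseline")
        result = run_cv(
            dataset, enzyme_spec, chemical_spec,
            variants=variants, scenario=scenario, seeds=SEEDS, n_folds=10,
        )
        agg = result.aggregates()
        agg.to_csv(RESULTS / f"cv_{scenario}_aggregates.csv", index=False)

        comparisons = []
        for metric in ("aupr", "auroc"):
            for a, b in [("rf_all", "rf_none"), ("rf_protein", "rf_none"),
                         ("rf_chemical", "rf_none"), ("rf_all", "random_baseline")] + (
                        [("rf_all", "activity_baseline")] if scenario != "LOOT" else []):
                p, stars = compare_models(
                    result, result, metric=metric, variant_a=a, variant_b=b
                )
                comparisons.append(
                    {"scenario": scenario, "metric": metric,
                     "variant_a": a, "variant_b": b, "p_value": p, "stars": stars}
                )
        pd.DataFrame(comparisons).to_csv(
            RESULTS / f"cv_{scenario}_comparisons.csv", index=False
        )
        print(f"== {scenario} ==")
        show = agg[agg.metric.isin(["aupr", "auroc"])]
        print(show.pivot(index="variant", columns="metric", values="mean").round(3))
        if result.skips:
            print(f"({len(result.skips)} single-class folds skipped)")
        print()


if __name__ == "__main__":
    main()
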