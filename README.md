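# ecipred — descriptor-ablated prediction of enzyme–chemical activity

`ecipred` studies a deceptively simple question about machine-learned
enzyme–substrate prediction: when a model scores well, *which input is
actually doing the work?* Published pair-classification models trained on
activity screens report strong cross-validated AUPR, but a random split of
enzyme–chemical **pairs** lets the model see every enzyme and every
chemical during training — so memorized object identity, or the base-rate
structure of the screen itself, can masquerade as chemistry.

The package makes that failure mode measurable. It provides:

* **Hold-out scenarios that differ in what is truly unseen.** LOOT holds
  out random pairs; LPOT holds out whole enzymes; LCOT holds out whole
  chemicals. A balance filter drops chemicals (LPOT) or enzymes (LCOT)
  whose activity counts are below 10% or above 90% of the opposite axis,
  or ≤ 1, before splitting.
* **Randomization ablations instead of feature omission.** Four Random
  Forest variants train on identically shaped inputs: `rf_all` (both
  descriptor tables intact), `rf_protein` (chemical table rows permuted),
  `rf_chemical` (enzyme table permuted), `rf_none` (both permuted). A
  permuted table still supports identity memorization — which is the
  point: the gap between variants isolates genuine descriptor signal.
  Baselines bound the problem from below: i.i.d. Bernoulli scores at the
  training activity ratio, and an enzyme-blind **activity model** that
  labels the globally top-k most-active chemicals active for everyone.
* **Dataset indicators that predict difficulty.** Alongside size, activity
  ratio and mean top-5 Smith–Waterman / Tanimoto similarity, two
  activity-order indices, **AOIE** and **AOIC**, measure how far the screen
  is explained by one global promiscuity ordering: for each chemical
  (AOIE) the fraction of enzyme pairs whose within-column order agrees
  with their leave-one-out row-sum order (ties count 0.5), averaged over
  columns; AOIC is the transposed index. Random screens score 0.5,
  perfectly order-consistent screens score exactly 1, and *low* values
  flag the specific, interesting datasets.
* **Descriptors.** Enzymes: amino-acid composition (AAC), grouped
  composition (GAAC), grouped dipeptide composition (GDPC) and their 50-d
  concatenation; chemicals: 2048-bit Morgan fingerprints or an 8-value
  physicochemical panel; external tables accepted for either side.
* **A controllable synthetic screen generator** with family × class block
  affinity, per-object effects and Gaussian noise, exact target activity
  ratio, mutated-template family sequences and numeric or SMILES
  chemicals — so every claim above is testable against known ground truth.

See [docs/methods.md](docs/methods.md) for definitions, assumptions and
limitations.

## Worked example

Generate a screen with strong enzyme-family structure, characterize it,
and ask whether the model's LPOT performance survives descriptor ablation:

```python
from ecipred import (
    DescriptorSpec, SyntheticConfig, compare_models, compute_statistics,
    generate_dataset, run_cv,
)

config = SyntheticConfig(
    n_families=4, enzymes_per_family=8, n_classes=4, chemicals_per_class=5,
    sequence_length=120, mutation_rate=0.1, noise_sd=0.5, seed=42,
)
dataset, truth = generate_dataset(config)

stats = compute_statistics(dataset, scenario="LPOT")
print(f"{dataset.n_enzymes} enzymes x {dataset.n_chemicals} chemicals, "
      f"activity ratio {stats.activity_ratio:.2f}")
print(f"AOIE {stats.aoie:.3f}  AOIC {stats.aoic:.3f}  "
      f"top-5 protein similarity {stats.top5_protein_similarity:.3f}")

result = run_cv(
    dataset,
    enzyme_spec=DescriptorSpec("composition50"),
    chemical_spec=DescriptorSpec("external", {"table": truth.chemical_features}),
    variants=["rf_all", "rf_none", "activity_baseline"],
    scenario="LPOT", seeds=(11,), n_folds=8,
)
agg = result.aggregates()
print(agg[agg.metric == "aupr"][["variant", "mean", "sem"]].to_string(index=False))

p, stars = compare_models(result, result, metric="aupr",
                          variant_a="rf_all", variant_b="rf_none")
print(f"rf_all vs rf_none: p = {p:.2e} {stars}")
```

Output:

```
32 enzymes x 20 chemicals, activity ratio 0.30
AOIE 0.481  AOIC 0.513  top-5 protein similarity 0.780
          variant     mean      sem
activity_baseline 0.328577 0.018719
           rf_all 0.897400 0.016333
          rf_none 0.365641 0.034201
rf_all vs rf_none: p = 1.23e-09 ***
```

With both descriptor tables ablated the forest falls from AUPR 0.90 to
0.37 — barely above the enzyme-blind activity model — so on this screen
the performance really is carried by the descriptors, not by memorization.

## The analysis

Numbered drivers under `analysis/` regenerate every table in `results/`
(intermediate dataset directories go to `scratch/`, which is disposable):

```
python analysis/01_simulate.py         # reference screen + mutation-rate sweep
python analysis/02_statistics.py       # seven indicators per dataset x scenario
python analysis/03_ablation_cv.py      # full ablation CV, 3 scenarios (~15 min)
python analysis/04_descriptor_space.py # t-SNE embeddings + silhouettes
python analysis/05_correlate.py        # indicators vs LPOT performance (~5 min)
```

Headline numbers from the committed tables:

* The ablation pattern flips with the scenario, exactly as the logic
  predicts (`results/cv_*_aggregates.csv`, mean AUPR on the reference
  screen): under LOOT even `rf_chemical` — enzyme descriptors permuted —
  reaches 0.56 versus 0.29 for `rf_none`, because memorized identity still
  helps when every object was seen in training. Under LPOT only the
  protein-descriptor variants survive (`rf_protein` 0.93, `rf_chemical`
  0.32 ≈ `rf_none` 0.32), and under LCOT only the chemical-descriptor
  variants do (`rf_chemical` 0.57, `rf_protein` 0.31).
* Descriptor-space structure survives the right randomization and not the
  wrong one: mean enzyme-family silhouette is 0.51 for regular composition
  descriptors, 0.39 after within-sequence residue shuffling (composition is
  preserved by construction), and −0.09 after row permutation
  (`results/descriptor_silhouettes.csv`).
* Across a six-dataset sweep of within-family mutation rate, mean top-5
  protein similarity predicts LPOT AUPR of the full model at r = 0.97
  (p = 0.0013), and AOIC anti-predicts it at r = −0.95 — more
  order-consistent screens are easier for the *baseline* and leave less
  for descriptors to add (`results/correlations.csv`).

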