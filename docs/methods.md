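# Methods

This note records what `ecipred` computes, the modelling assumptions behind
it, the scope of the synthetic data generator, and the numerical choices
that affect results.

## Problem setting

The object of study is an enzyme–chemical activity screen: a matrix
`A ∈ {0, 1, NaN}^{E×C}` whose cell (i, j) records whether enzyme *i* showed
activity on chemical *j* (NaN = untested). Quantitative screens are reduced
to this form by strict thresholding (`value > threshold → 1`); a
log10(value + pseudocount) transform is available for regression use. The
prediction task is pair classification — given descriptors of the enzyme
and the chemical, predict the cell — evaluated under three hold-out
scenarios that differ in what the model has never seen:

* **LOOT** (leave objects out): random pairs held out; both the enzyme and
  the chemical of a test pair appear elsewhere in training.
* **LPOT** (leave proteins out): whole enzymes held out.
* **LCOT** (leave chemicals out): whole chemicals held out.

Before LPOT splitting, chemicals whose activity count is not between 10%
and 90% (inclusive) of the enzyme count, or is ≤ 1, are dropped; LCOT
applies the mirrored filter to enzymes. This removes near-constant columns
or rows whose hold-out performance would be dominated by base-rate effects.

## Dataset indicators

Seven indicators characterize a screen: enzyme and chemical counts,
activity ratio (fraction of tested cells active), the two activity-order
indices below, and mean top-5 protein / chemical similarity.

**AOIE / AOIC (activity-order indices).** AOIE asks: does the *global*
ranking of enzymes by overall activity predict their ranking within each
single chemical's column? For column *j*, every pair of enzymes with
non-missing cells is scored 1 if the sign of their within-column difference
matches the sign of their global-score difference, 0.5 on a tie in either
ordering, 0 otherwise; the column's concordance is the mean over pairs and
AOIE is the mean over columns. The global score of enzyme *i* used for
column *j* is the row sum of its non-missing cells **excluding cell
(i, j)**. The exclusion matters: if the scored cell is left inside the row
sum, the cell contributes its own value to the global score and pairs
become spuriously concordant — on i.i.d. Bernoulli(0.3) matrices of shape
50×20 the naive index averages ≈ 0.56 rather than 0.5. With the
leave-one-out form, random data scores 0.5 in expectation, and any matrix
whose rows induce one common ordering still scores exactly 1. AOIC is the
same index on the transposed matrix (does the global chemical ranking
predict each enzyme's substrate preferences?). Columns with fewer than two
non-missing cells contribute 0.5 (no order information). Low values mean
activity is *specific* — knowing that an enzyme is generally promiscuous
does not tell you which chemicals it accepts.

**Protein similarity** is normalized Smith–Waterman:
`SW(a,b) / sqrt(SW(a,a)·SW(b,b))` with BLOSUM62 and affine gaps costing
11 to open and 1 to extend (a gap of length k costs 11 + (k−1)·1),
computed with Biopython's `PairwiseAligner` in local mode. **Chemical
similarity** is Tanimoto on 2048-bit radius-2 chirality-aware Morgan
fingerprints (RDKit). The top-5 indicator averages, over objects, the mean
of each object's five largest off-diagonal similarities — a measure of how
redundant the library is, and hence how much a nearest-neighbour-like model
could exploit.

## Descriptors

Enzymes: amino-acid composition (AAC, 20-d over ACDEFGHIKLMNPQRSTVWY; `X`
residues excluded from the denominator), grouped composition (GAAC, 5-d:
aliphatic GAVLMI, aromatic FYW, positive KRH, negative DE, uncharged
STCPNQ), grouped dipeptide composition (GDPC, 25-d over adjacent group
pairs; dipeptides containing `X` dropped), and their 50-d concatenation
(`composition50`). Chemicals: Morgan fingerprints (as above) or an 8-value
physicochemical panel (MolWt, MolLogP, H-donors/acceptors, TPSA, ring
count, rotatable bonds, heavy atoms); arbitrary external tables are also
accepted. A pair's feature vector is the enzyme block concatenated with the
chemical block.

## Ablation design

The central question — *which* descriptor carries the generalizing signal —
is answered by randomization rather than omission, so every variant trains
on feature matrices of identical shape and sparsity:

* `rf_all`: both tables intact;
* `rf_protein`: chemical table rows permuted (one random bijection of
  descriptor rows to chemical ids);
* `rf_chemical`: enzyme table rows permuted;
* `rf_none`: both permuted, with independent sub-seeds.

Permutation preserves the multiset of vectors but destroys the object ↔
descriptor correspondence; a permuted table still lets the forest memorize
object *identity* (each id keeps one fixed vector), which is exactly the
right control — under LOOT, identity alone suffices, and the ablations
reveal that; under LPOT/LCOT the held-out objects' identities are new, so
only true descriptor signal survives. A second randomization,
residue shuffling (per-sequence permutation of residues), is used in
descriptor-space analyses: it preserves AAC/GAAC by construction and so
isolates the contribution of residue order.

Two baselines bound the problem: a random baseline scoring pairs i.i.d.
Bernoulli(training activity ratio), and an **activity model** that ranks
chemicals by training column sums and labels the top *k* active for every
enzyme (k = activity ratio × library size, rounded half-up; ties broken by
column index). The activity model is enzyme-blind: beating it under LPOT is
evidence the protein descriptors do more than recover the base-rate
structure. Under LCOT the same construction is applied to the transposed
matrix.

## Evaluation

10-fold cross-validation (sklearn `KFold`, shuffled) over pairs (LOOT),
enzymes (LPOT) or chemicals (LCOT), repeated over CV seeds (default five).
Classification metrics: AUPR (`average_precision_score`) and AUROC;
regression: R² (squared Pearson) and MAE. Folds whose validation set is
single-class are skipped and logged; a run in which more than half the
folds are skipped is an error rather than a silently unstable mean. Model
comparison uses the two-sided equal-variance two-sample t-test on per-fold
values, starred `***`/`**`/`*` at p < 0.001 / 0.01 / 0.05.

The Random Forest is sklearn's, 500 trees, unlimited depth,
`max_features="sqrt"`, seeded per (variant, CV seed). A small random-search
tuner over a fixed grid exists but the defaults are used throughout the
analyses.

## Synthetic data generator — scope

The generator exists to produce screens with *known, controllable*
structure, not to imitate real enzyme biochemistry. Latent activity is

```
A(e, c) = B[family(e), class(c)] + α·u_e + β·v_c + σ·ε
```

with a family×class block-affinity matrix B (diagonal by default,
`block_scale` on the diagonal), per-enzyme and per-chemical scalar effects
(SDs α, β), and i.i.d. Gaussian noise. The latent matrix is binarized by
taking the top-k cells (stable lexicographic tie-break) so the realized
activity ratio equals the target to within one cell. Enzyme families are
mutated copies of a random template sequence (per-site mutation probability
`mutation_rate`); chemicals are either numeric class centroids plus noise
(carried as an external descriptor table) or SMILES drawn without
replacement from a small packaged library of six scaffold groups. The
whole generator is a pure function of (config, seed).

What passing the pattern-recovery tests shows: the pipeline can detect
descriptor signal when it is present, does not hallucinate it when it is
ablated, and the split machinery leaks nothing. What it does **not** show:
that any particular real screen has such structure, nor that the measured
effect sizes transfer — the analysis-script problem sizes (a 40×20
reference screen, a six-dataset mutation-rate sweep, three CV seeds) are
deliberately small so the full pipeline reruns in minutes, and are this
package's own choices.

## Numerical choices

* Missing activity is NaN in a float matrix; all statistics are
  NaN-aware (`nansum`, pairwise deletion).
* AOIE/AOIC tie handling is exact (0.5 per tied pair), vectorized via sign
  outer products; the test suite checks it against a literal O(n²) loop.
* Pearson r uses the centered-dot-product closed form with the p-value from
  the t distribution on n−2 df, clamped to [−1, 1]; verified against scipy
  to 1e-12.
* t-SNE perplexity is auto-reduced to (n−1)/3 for small inputs; embeddings
  are seeded and deterministic.
* Random baselines derive per-fold seeds as `seed·1009 + fold`; ablation
  sub-seeds come from a child generator of the variant seed. All seeds are
  below 2³¹.

## Limitations

* Composition descriptors ignore residue order beyond adjacent pairs;
  real structure–activity signal that lives in 3-D structure is invisible
  to them.
* The balance filter thresholds (10% / 90%, count > 1) are conventions, not
  fitted; results near the cutoffs are sensitive to them.
* The activity baseline assumes one global substrate preference order; it
  is a floor, not a serious competitor, under strong class structure.
* The packaged SMILES library is a synthetic stand-in (96 molecules, six
  scaffold groups); chemical-similarity indicators computed from it span a
  narrower range than real substrate libraries would.
* Statistical comparisons treat per-fold metric values as independent
  samples; folds sharing training data violate this mildly, as is standard
  for CV t-tests.
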