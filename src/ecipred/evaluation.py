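"""Scenario splitting, metrics and the cross-validation driver.

Three splitting scenarios mirror how a trained model would be used:

* **LOOT** (leave object out) — new relationships between known enzymes and
  known chemicals: the non-missing activity pairs are split into folds.
* **LPOT** (leave protein out) — new enzymes: whole enzymes are held out.
  To avoid degenerate folds, chemicals are first filtered to those whose
  activity count lies between 10% and 90% of the number of enzymes
  (inclusive) and is larger than 1.
* **LCOT** (leave chemical out) — new chemicals: the symmetric filter and
  split on the other axis.

The driver runs 10-fold cross-validation under several fixed seeds (5 by
default), evaluates each Random-Forest ablation variant and the baselines on
identical splits, and aggregates per-fold metrics into mean, standard
deviation and the standard error of the mean. Folds whose validation labels
collapse to a single class leave the ranking metrics undefined; such folds
are skipped and logged, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import KFold

from .dataset_io import ActivityDataset, binarize_activity
from .descriptors import DescriptorSpec, build_chemical_table, build_sequence_table, concat_pair_features
from .exceptions import (
    ConfigurationError,
    DomainError,
    EciError,
    UndefinedMetricError,
    ValidationError,
)
from .models import (
    BASELINE_VARIANTS,
    RF_VARIANTS,
    activity_baseline_fit,
    apply_ablation,
    random_baseline_predict,
    train_random_forest,
)

logger = logging.getLogger(__name__)

SCENARIOS = ("LOOT", "LPOT", "LCOT")

#: Five fixed cross-validation seeds used by default for the parallel runs.
DEFAULT_SEEDS = (11, 23, 37, 53, 71)


# -- filtering and splitting ------------------------------------------------


def filter_for_scenario(
    binary_matrix: np.ndarray, scenario: str
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of enzymes and chemicals retained under a scenario's filter.

    LOOT retains everything. LPOT keeps a chemical iff its activity count c
    satisfies 0.1 * n_enzymes <= c <= 0.9 * n_enzymes (bounds inclusive) and
    c > 1; LCOT applies the symmetric rule to enzymes. The filter is applied
    once to the full binary matrix, before splitting.
    """
    m = np.asarray(binary_matrix, dtype=float)
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    n_enz, n_chem = m.shape
    e_idx = np.arange(n_enz)
    c_idx = np.arange(n_chem)
    if scenario == "LPOT":
        counts = np.nansum(m == 1.0, axis=0)
        keep = (counts >= 0.1 * n_enz) & (counts <= 0.9 * n_enz) & (counts > 1)
        c_idx = np.flatnonzero(keep)
        if c_idx.size == 0:
            raise ConfigurationError("LPOT filter removed every chemical")
    elif scenario == "LCOT":
        counts = np.nansum(m == 1.0, axis=1)
        keep = (counts >= 0.1 * n_chem) & (counts <= 0.9 * n_chem) & (counts > 1)
        e_idx = np.flatnonzero(keep)
        if e_idx.size == 0:
            raise ConfigurationError("LCOT filter removed every enzyme")
    return e_idx, c_idx


@dataclass
class SplitPlan:
    """Fold assignments for one (scenario, seed) split.

    Pairs are (enzyme_index, chemical_index) into the full dataset. The
    validation sets partition the split axis: pairs for LOOT, enzymes for
    LPOT, chemicals for LCOT.
    """

    scenario: str
    n_folds: int
    seed: int
    retained_enzymes: tuple[str, ...]
    retained_chemicals: tuple[str, ...]
    folds: list[tuple[list[tuple[int, int]], list[tuple[int, int]]]] = field(
        default_factory=list
    )


def make_splits(
    dataset: ActivityDataset, scenario: str, n_folds: int = 10, seed: int = 0
) -> SplitPlan:
    """Build the fold plan for a dataset under a scenario.

    Training pairs are all non-missing pairs among training-side objects and
    the retained objects of the other axis. Deterministic given the seed.
    """
    binary = dataset if dataset.is_binary else binarize_activity(dataset)
    e_idx, c_idx = filter_for_scenario(binary.activity, scenario)
    m = dataset.activity
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)

    def pairs_of(enzymes: Iterable[int], chemicals: Iterable[int]):
        return [
            (int(i), int(j))
            for i in enzymes
            for j in chemicals
            if not np.isnan(m[i, j])
        ]

    folds = []
    if scenario == "LOOT":
        all_pairs = pairs_of(e_idx, c_idx)
        if len(all_pairs) < n_folds:
            raise ConfigurationError(
                f"only {len(all_pairs)} pairs; reduce n_folds below {n_folds}"
            )
        pair_arr = np.array(all_pairs)
        for train_i, val_i in kf.split(pair_arr):
            folds.append(
                (
                    [tuple(p) for p in pair_arr[train_i]],
                    [tuple(p) for p in pair_arr[val_i]],
                )
            )
    elif scenario == "LPOT":
        if e_idx.size < n_folds:
            raise ConfigurationError(
                f"only {e_idx.size} enzymes; reduce n_folds below {n_folds}"
            )
        for train_i, val_i in kf.split(e_idx):
            folds.append(
                (pairs_of(e_idx[train_i], c_idx), pairs_of(e_idx[val_i], c_idx))
            )
    else:  # LCOT
        if c_idx.size < n_folds:
            raise ConfigurationError(
                f"only {c_idx.size} chemicals; reduce n_folds below {n_folds}"
            )
        for train_i, val_i in kf.split(c_idx):
            folds.append(
                (pairs_of(e_idx, c_idx[train_i]), pairs_of(e_idx, c_idx[val_i]))
            )
    return SplitPlan(
        scenario=scenario,
        n_folds=n_folds,
        seed=seed,
        retained_enzymes=tuple(dataset.enzyme_ids[i] for i in e_idx),
        retained_chemicals=tuple(dataset.chemical_ids[j] for j in c_idx),
        folds=folds,
    )


# -- metrics ----------------------------------------------------------------


def auroc(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Probability that a random positive outranks a random negative.

    Rank-based with ties counted 0.5; requires both classes.
    """
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise UndefinedMetricError("auroc needs both classes present")
    return float(roc_auc_score(y, s))


def aupr(labels: Sequence[float], scores: Sequence[float]) -> float:
    """Area under the precision-recall step curve (average precision)."""
    y = np.asarray(labels, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not np.any(y == 1.0):
        raise UndefinedMetricError("aupr needs at least one positive")
    return float(average_precision_score(y, s))


def precision_at_threshold(
    labels: Sequence[float], scores: Sequence[float], threshold: float = 0.5
) -> float:
    """Precision of the "score > threshold" decision rule (0 if no calls)."""
    y = np.asarray(labels, dtype=float)
    called = np.asarray(scores, dtype=float) > threshold
    if not called.any():
        return 0.0
    return float(np.mean(y[called] == 1.0))


def regression_metrics(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float]:
    """(R2, MAE) for a regression fold.

    R2 is the squared Pearson correlation between predicted and observed;
    MAE the mean absolute difference. With constant observed values R2 is
    undefined and returned as NaN while MAE is still computed.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size < 3:
        raise DomainError("regression metrics need at least 3 pairs")
    mae = float(np.mean(np.abs(obs - pred)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return float("nan"), mae
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r * r, mae


# -- the cross-validation driver -------------------------------------------


@dataclass
class CVResult:
    """Per-fold metric records with aggregation helpers."""

    records: list[dict] = field(default_factory=list)
    skips: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = ["scenario", "variant", "seed", "fold", "metric", "value"]
        return pd.DataFrame(self.records, columns=cols)

    def values(self, variant: str, metric: str) -> np.ndarray:
        df = self.frame()
        sel = df[(df.variant == variant) & (df.metric == metric)]
        return sel["value"].to_numpy(dtype=float)

    def aggregates(self) -> pd.DataFrame:
        """Mean, std and SEM per (variant, metric) over all folds x seeds."""
        df = self.frame()
        if df.empty:
            return pd.DataFrame(columns=["variant", "metric", "mean", "std", "sem", "n"])
        g = df.groupby(["variant", "metric"])["value"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["sem"] = out["std"] / np.sqrt(out["count"])
        return out.rename(columns={"count": "n"})[
            ["variant", "metric", "mean", "std", "sem", "n"]
        ]


def _fold_targets(matrix: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.array([matrix[i, j] for i, j in pairs], dtype=float)


def _baseline_scores(
    variant: str,
    scenario: str,
    binary_matrix: np.ndarray,
    plan: SplitPlan,
    dataset: ActivityDataset,
    train_pairs,
    val_pairs,
    seed: int,
    fold: int,
    distribution: str,
) -> np.ndarray:
    if variant == "random_baseline":
        y_train = _fold_targets(binary_matrix, train_pairs)
        ratio = float(np.mean(y_train == 1.0))
        return random_baseline_predict(
            ratio, len(val_pairs), seed=seed * 1009 + fold, distribution=distribution
        )
    # activity baseline: axis-aware top-k ranking
    if scenario == "LOOT":
        raise DomainError("activity_baseline is defined for LPOT/LCOT only")
    e_pos = {dataset.enzyme_ids.index(e) for e in plan.retained_enzymes}
    c_pos = {dataset.chemical_ids.index(c) for c in plan.retained_chemicals}
    if scenario == "LPOT":
        train_enzymes = sorted({i for i, _ in train_pairs})
        cols = sorted(c_pos)
        sub = binary_matrix[np.ix_(train_enzymes, cols)]
        model = activity_baseline_fit(sub)
        col_of = {j: p for p, j in enumerate(cols)}
        return model.scores_for([col_of[j] for _, j in val_pairs])
    # LCOT: rank enzymes by total training activity, transpose construction
    train_chems = sorted({j for _, j in train_pairs})
    rows = sorted(e_pos)
    sub = binary_matrix[np.ix_(rows, train_chems)].T
    model = activity_baseline_fit(sub)
    row_of = {i: p for p, i in enumerate(rows)}
    return model.scores_for([row_of[i] for i, _ in val_pairs])


def run_cv(
    dataset: ActivityDataset,
    enzyme_spec: DescriptorSpec,
    chemical_spec: DescriptorSpec,
    variants: Sequence[str],
    scenario: str,
    seeds: Sequence[int] | None = None,
    task: str = "classification",
    n_folds: int = 10,
    rf_params: dict | None = None,
    extra_metrics: Sequence[str] = (),
    random_baseline_distribution: str = "bernoulli",
) -> CVResult:
    """Run the full cross-validation harness for a dataset and scenario.

    For every seed: descriptor tables are built once, each RF variant's
    ablation permutation is drawn from the split seed and applied to the
    whole tables before splitting, the split plan is generated, models are
    trained on the training pairs and scored on the validation pairs, and
    per-fold metrics are recorded. Baselines are evaluated on the identical
    splits. A variant with more than half of its folds skipped aborts the
    run.
    """
    if not variants:
        raise ValidationError("at least one variant required")
    seeds = tuple(DEFAULT_SEEDS if seeds is None else seeds)
    binary = dataset if dataset.is_binary else binarize_activity(dataset)
    target_matrix = binary.activity if task == "classification" else dataset.activity

    etab = build_sequence_table(dataset.enzyme_ids, dataset.sequences, enzyme_spec)
    ctab = build_chemical_table(dataset.chemical_ids, dataset.smiles, chemical_spec)
    id_pairs = lambda pairs: [
        (dataset.enzyme_ids[i], dataset.chemical_ids[j]) for i, j in pairs
    ]

    result = CVResult()
    n_attempted: dict[str, int] = {v: 0 for v in variants}
    n_skipped: dict[str, int] = {v: 0 for v in variants}

    for seed in seeds:
        plan = make_splits(dataset, scenario, n_folds=n_folds, seed=seed)
        for variant in variants:
            if variant in RF_VARIANTS:
                etab_v, ctab_v = apply_ablation(etab, ctab, variant, seed)
            elif variant not in BASELINE_VARIANTS:
                raise ValidationError(f"unknown variant {variant!r}")
            for fold, (train_pairs, val_pairs) in enumerate(plan.folds):
                n_attempted[variant] += 1
                try:
                    y_val = _fold_targets(target_matrix, val_pairs)
                    if variant in RF_VARIANTS:
                        y_train = _fold_targets(target_matrix, train_pairs)
                        X_train = concat_pair_features(etab_v, ctab_v, id_pairs(train_pairs))
                        X_val = concat_pair_features(etab_v, ctab_v, id_pairs(val_pairs))
                        model = train_random_forest(
                            X_train, y_train, task=task,
                            hyperparameters=rf_params, seed=seed,
                        )
                        scores = model.predict(X_val)
                    else:
                        scores = _baseline_scores(
                            variant, scenario, binary.activity, plan, dataset,
                            train_pairs, val_pairs, seed, fold,
                            random_baseline_distribution,
                        )
                    metrics: dict[str, float] = {}
                    if task == "classification":
                        metrics["aupr"] = aupr(y_val, scores)
                        metrics["auroc"] = auroc(y_val, scores)
                        if "precision" in extra_metrics:
                            metrics["precision"] = precision_at_threshold(y_val, scores)
                    else:
                        r2, mae = regression_metrics(y_val, scores)
                        metrics["mae"] = mae
                        if not np.isnan(r2):
                            metrics["r2"] = r2
                    for name, value in metrics.items():
                        result.records.append(
                            {
                                "scenario": scenario,
                                "variant": variant,
                                "seed": seed,
                                "fold": fold,
                                "metric": name,
                                "value": float(value),
                            }
                        )
                except (UndefinedMetricError, EciError) as exc:
                    if not isinstance(exc, UndefinedMetricError):
                        logger.warning("fold failed: %s", exc)
                    n_skipped[variant] += 1
                    result.skips.append(
                        {
                            "scenario": scenario,
                            "variant": variant,
                            "seed": seed,
                            "fold": fold,
                            "reason": str(exc),
                        }
                    )

    for variant in variants:
        if n_attempted[variant] and n_skipped[variant] > 0.5 * n_attempted[variant]:
            raise EciError(
                f"variant {variant!r} skipped {n_skipped[variant]} of "
                f"{n_attempted[variant]} folds"
            )
    return result


# -- significance -----------------------------------------------------------


def significance_stars(p_value: float) -> str:
    """Asterisk coding: *** below 0.001, ** below 0.01, * below 0.05."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def compare_models(
    result_a,
    result_b,
    metric: str = "aupr",
    variant_a: str | None = None,
    variant_b: str | None = None,
    equal_var: bool = True,
) -> tuple[float, str]:
    """Two-sided independent two-sample t-test on per-fold metric values.

    Accepts either raw value arrays or :class:`CVResult` objects (with the
    variant named when a result holds several). The standard equal-variance
    Student form is the default; ``equal_var=False`` gives Welch's test.
    Identical samples yield t = 0, p = 1 and no stars.
    """

    def extract(result, variant):
        if isinstance(result, CVResult):
            if variant is None:
                names = result.frame()["variant"].unique()
                if len(names) != 1:
                    raise ValidationError("ambiguous CVResult; name the variant")
                variant = names[0]
            return result.values(variant, metric)
        return np.asarray(result, dtype=float)

    a = extract(result_a, variant_a)
    b = extract(result_b, variant_b)
    if a.size < 2 or b.size < 2:
        raise DomainError("need at least two values per sample")
    if np.array_equal(a, b) or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
        return 1.0, ""
    t = sps.ttest_ind(a, b, equal_var=equal_var)
    p = float(t.pvalue)
    if np.isnan(p):
        p = 1.0
    return p, significance_stars(p)
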