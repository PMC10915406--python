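"""Random-Forest ablation variants and the two non-ML baselines.

Four Random-Forest variants differ only in which descriptor tables are
corrupted by the permutation strategy before training:

================  ==========================  ==========================
variant           enzyme descriptors           chemical descriptors
================  ==========================  ==========================
``rf_all``        regular                      regular
``rf_protein``    regular                      permuted
``rf_chemical``   permuted                     regular
``rf_none``       permuted                     permuted
================  ==========================  ==========================

A permuted table still identifies training-set objects (the bijection is
fixed for the whole dataset) but carries no information transferable to new
objects, which is what makes the variants an information ablation rather
than a feature ablation.

Two baselines need no descriptors: the random model draws Bernoulli scores
with the training activity ratio as its single parameter, and the activity
model ranks chemicals by their total training activity and predicts the
top-k active for every new enzyme (k = n_chemicals x activity ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .descriptors import DescriptorTable, permute_table
from .exceptions import DegenerateTrainingError, DomainError, ValidationError

RF_VARIANTS = ("rf_all", "rf_protein", "rf_chemical", "rf_none")
BASELINE_VARIANTS = ("random_baseline", "activity_baseline")
ALL_VARIANTS = RF_VARIANTS + BASELINE_VARIANTS

#: Default Random-Forest hyperparameters (tuning is optional).
DEFAULT_RF_PARAMS = {
    "n_estimators": 500,
    "max_depth": None,
    "min_samples_leaf": 1,
    "max_features": "sqrt",
}

#: Documented random-search grid for optional hyperparameter tuning.
TUNING_GRID = {
    "n_estimators": (100, 200, 500),
    "max_depth": (None, 5, 10, 20),
    "min_samples_leaf": (1, 2, 5),
    "max_features": ("sqrt", 0.3, 0.5),
}


@dataclass(frozen=True)
class ModelVariant:
    """A named model configuration."""

    name: str
    task: str = "classification"
    permutation_seed: Optional[int] = None
    rf_hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ALL_VARIANTS:
            raise ValidationError(f"unknown variant {self.name!r}")
        if self.task not in ("classification", "regression"):
            raise ValidationError(f"unknown task {self.task!r}")
        if self.name in ("rf_protein", "rf_chemical", "rf_none") and (
            self.permutation_seed is None
        ):
            raise ValidationError(f"{self.name} requires a permutation_seed")


def apply_ablation(
    enzyme_table: DescriptorTable,
    chemical_table: DescriptorTable,
    variant: str,
    seed: int,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Apply the variant's permutation strategy to the descriptor tables.

    Permutations for the enzyme and chemical tables are independent draws
    derived from ``seed``; ``rf_all`` returns both tables unchanged.
    """
    if variant in BASELINE_VARIANTS:
        raise DomainError(f"ablation does not apply to baseline {variant!r}")
    if variant not in RF_VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2)
    etab, ctab = enzyme_table, chemical_table
    if variant in ("rf_chemical", "rf_none"):
        etab = permute_table(enzyme_table, int(child[0]))
    if variant in ("rf_protein", "rf_none"):
        ctab = permute_table(chemical_table, int(child[1]))
    return etab, ctab


@dataclass
class TrainedModel:
    """A fitted predictor plus its training bookkeeping."""

    variant: ModelVariant
    estimator: object
    training_activity_ratio: float

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Active-class probability (classification) or fitted value."""
        features = np.asarray(features, dtype=float)
        if self.variant.task == "classification":
            proba = self.estimator.predict_proba(features)
            return proba[:, list(self.estimator.classes_).index(1.0)]
        return self.estimator.predict(features)


def train_random_forest(
    features: np.ndarray,
    targets: np.ndarray,
    task: str = "classification",
    hyperparameters: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit a Random Forest on concatenated pair features.

    Classification requires both classes in ``targets`` and predicts the
    active-class probability; regression predicts the activity value.
    Deterministic given the seed.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    params = dict(DEFAULT_RF_PARAMS)
    params.update(hyperparameters or {})
    if task == "classification":
        classes = np.unique(targets)
        if classes.size < 2:
            raise DegenerateTrainingError(
                "classification training set contains a single class"
            )
        est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        ratio = float(np.mean(targets == 1.0))
    elif task == "regression":
        est = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        ratio = float("nan")
    else:
        raise ValidationError(f"unknown task {task!r}")
    est.fit(features, targets)
    return TrainedModel(
        variant=ModelVariant(name="rf_all", task=task, rf_hyperparameters=params),
        estimator=est,
        training_activity_ratio=ratio,
    )


# -- baselines --------------------------------------------------------------


def random_baseline_predict(
    training_activity_ratio: float,
    n_pairs: int,
    seed: int,
    distribution: str = "bernoulli",
) -> np.ndarray:
    """Scores from the random model.

    The training activity ratio is the model's only parameter. The default
    Bernoulli form draws score 1 with that probability and 0 otherwise, so a
    score above the 0.5 decision threshold means "predicted active". The
    ``uniform`` alternative draws U(0, 1) and returns 1[u < ratio]-style
    graded scores (u scaled so its exceedance of 0.5 has the same rate).
    """
    if not 0.0 <= training_activity_ratio <= 1.0:
        raise DomainError("activity ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if distribution == "bernoulli":
        return rng.binomial(1, training_activity_ratio, size=n_pairs).astype(float)
    if distribution == "uniform":
        # graded scores with P(score > 0.5) == ratio
        u = rng.uniform(size=n_pairs)
        return np.where(
            u < training_activity_ratio,
            0.5 + 0.5 * rng.uniform(size=n_pairs),
            0.5 * rng.uniform(size=n_pairs),
        )
    raise ValidationError(f"unknown distribution {distribution!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ActivityBaseline:
    """The activity model: rank chemicals by total training activity.

    ``chemical_scores[j]`` is chemical j's total activity over training
    enzymes (the ranking score used for AUPR/AUROC); the top-k chemicals are
    predicted active for every new enzyme, with
    k = round(n_chemicals x training activity ratio). The model is
    enzyme-independent by construction. The same construction applies to
    LCOT with the axes exchanged (rank enzymes, predict for new chemicals).
    """

    chemical_scores: np.ndarray
    k: int
    active_indices: np.ndarray

    def scores_for(self, chemical_indices: Sequence[int]) -> np.ndarray:
        return self.chemical_scores[list(chemical_indices)]

    def labels_for(self, chemical_indices: Sequence[int]) -> np.ndarray:
        active = set(self.active_indices.tolist())
        return np.array([1.0 if j in active else 0.0 for j in chemical_indices])


def activity_baseline_fit(training_matrix: np.ndarray) -> ActivityBaseline:
    """Fit the activity model on a binary training matrix (NaN = missing).

    k is rounded half-up, floored at 0 and capped at the number of
    chemicals; ties in the ranking break deterministically by column index.
    """
    m = np.asarray(training_matrix, dtype=float)
    if m.size == 0 or np.all(np.isnan(m)):
        raise DomainError("empty training matrix")
    scores = np.nansum(m == 1.0, axis=0).astype(float)
    ratio = float(np.mean(m[~np.isnan(m)] == 1.0))
    n_chem = m.shape[1]
    k = min(max(_round_half_up(n_chem * ratio), 0), n_chem)
    # stable ranking: descending score, ascending index on ties
    order = np.lexsort((np.arange(n_chem), -scores))
    return ActivityBaseline(
        chemical_scores=scores, k=k, active_indices=order[:k]
    )


# -- optional hyperparameter search -----------------------------------------


def tune_hyperparameters(
    dataset,
    variant: str,
    scenario: str,
    enzyme_spec,
    chemical_spec,
    budget: int = 10,
    seed: int = 0,
    task: str = "classification",
    n_folds: int = 5,
) -> dict:
    """Random search over :data:`TUNING_GRID`.

    The objective follows the task: mean cross-validated precision (at the
    0.5 score threshold) is maximized for classification; mean MAE is
    minimized for regression. Deterministic given the seed; ``budget`` is
    the number of sampled configurations.
    """
    from .evaluation import run_cv  # runtime import avoids a module cycle

    if budget < 1:
        raise DomainError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    best_params: dict | None = None
    best_score = -np.inf
    for _ in range(budget):
        params = {k: v[rng.integers(len(v))] for k, v in TUNING_GRID.items()}
        result = run_cv(
            dataset,
            enzyme_spec,
            chemical_spec,
            variants=[variant],
            scenario=scenario,
            seeds=[int(rng.integers(0, 2**31 - 1))],
            task=task,
            n_folds=n_folds,
            rf_params=params,
            extra_metrics=("precision",) if task == "classification" else (),
        )
        agg = result.aggregates()
        if task == "classification":
            row = agg[(agg.variant == variant) & (agg.metric == "precision")]
            score = float(row["mean"].iloc[0])
        else:
            row = agg[(agg.variant == variant) & (agg.metric == "mae")]
            score = -float(row["mean"].iloc[0])
        if score > best_score:
            best_score = score
            best_params = params
    assert best_params is not None
    return best_params
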