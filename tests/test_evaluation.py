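import numpy as np
import pytest

from ecipred import (
    DescriptorSpec,
    aupr,
    auroc,
    compare_models,
    filter_for_scenario,
    make_splits,
    regression_metrics,
    run_cv,
    significance_stars,
)
from ecipred.exceptions import (
    ConfigurationError,
    DomainError,
    UndefinedMetricError,
)
from ecipred.synthetic import SyntheticConfig, generate_dataset

from oracles import aupr_bruteforce, auroc_bruteforce


class TestScenarioFilter:
    def test_loot_keeps_everything(self, binary_matrix_10x4):
        e, c = filter_for_scenario(binary_matrix_10x4, "LOOT")
        assert e.size == 10 and c.size == 4

    def test_lpot_chemical_filter(self, binary_matrix_10x4):
        # counts (1, 10, 5, 3): 1 fails count>1, 10 fails the 90% bound
        _, c = filter_for_scenario(binary_matrix_10x4, "LPOT")
        np.testing.assert_array_equal(c, [2, 3])

    def test_lpot_bounds_inclusive(self):
        m = np.zeros((10, 2))
        m[:9, 0] = 1  # exactly 90% retained
        m[:2, 1] = 1  # exactly 2 > 1 and >= 10% retained
        _, c = filter_for_scenario(m, "LPOT")
        np.testing.assert_array_equal(c, [0, 1])

    def test_lcot_symmetric_filter(self, binary_matrix_10x4):
        e, _ = filter_for_scenario(binary_matrix_10x4.T, "LCOT")
        np.testing.assert_array_equal(e, [2, 3])

    def test_empty_after_filter(self):
        m = np.ones((10, 3))
        with pytest.raises(ConfigurationError):
            filter_for_scenario(m, "LPOT")


@pytest.fixture(scope="module")
def synthetic_dataset():
    cfg = SyntheticConfig(
        n_families=3, enzymes_per_family=7, sequence_length=60,
        mutation_rate=0.1, n_classes=3, chemicals_per_class=5,
        chemical_dim=6, noise_sd=0.8, seed=42,
    )
    return generate_dataset(cfg)


class TestSplits:
    def test_loot_partitions_pairs(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        plan = make_splits(ds, "LOOT", n_folds=10, seed=0)
        all_val = [p for _, val in plan.folds for p in val]
        assert len(all_val) == len(set(all_val)) == ds.n_enzymes * ds.n_chemicals
        sizes = [len(val) for _, val in plan.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_loot_train_val_disjoint(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        plan = make_splits(ds, "LOOT", n_folds=5, seed=1)
        for train, val in plan.folds:
            assert not set(train) & set(val)

    def test_lpot_enzymes_partitioned_no_leakage(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        plan = make_splits(ds, "LPOT", n_folds=7, seed=2)
        seen = set()
        for train, val in plan.folds:
            val_enzymes = {i for i, _ in val}
            train_enzymes = {i for i, _ in train}
            assert not val_enzymes & train_enzymes
            assert not val_enzymes & seen
            seen |= val_enzymes

    def test_lcot_chemicals_partitioned(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        plan = make_splits(ds, "LCOT", n_folds=5, seed=3)
        seen = set()
        for _, val in plan.folds:
            val_chems = {j for _, j in val}
            assert not val_chems & seen
            seen |= val_chems

    def test_deterministic_given_seed(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        p1 = make_splits(ds, "LPOT", n_folds=5, seed=4)
        p2 = make_splits(ds, "LPOT", n_folds=5, seed=4)
        assert p1.folds == p2.folds

    def test_too_many_folds_rejected(self, synthetic_dataset):
        ds, _ = synthetic_dataset
        with pytest.raises(ConfigurationError):
            make_splits(ds, "LPOT", n_folds=50, seed=0)


class TestClassificationMetrics:
    def test_perfect_separator(self):
        assert auroc([1, 0], [0.9, 0.1]) == 1.0

    def test_three_quarters_by_enumeration(self):
        assert auroc([1, 0, 1, 0], [0.8, 0.6, 0.4, 0.2]) == 0.75

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 5000)
        assert auroc(y, rng.uniform(size=10_000)) == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([1, 1], [0.3, 0.4])

    def test_aupr_perfect_ranking(self):
        assert aupr([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_aupr_single_step(self):
        assert aupr([0, 1, 0], [0.9, 0.8, 0.1]) == pytest.approx(0.5)

    def test_aupr_no_positives_undefined(self):
        with pytest.raises(UndefinedMetricError):
            aupr([0, 0], [0.2, 0.3])

    def test_aupr_random_scores_near_prevalence(self):
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=10_000) < 0.2).astype(float)
        assert aupr(y, rng.uniform(size=10_000)) == pytest.approx(0.2, abs=0.03)

    def test_auroc_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n = rng.integers(6, 51)
            y = rng.integers(0, 2, size=n).astype(float)
            if np.unique(y).size < 2:
                continue
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            assert auroc(y, s) == pytest.approx(auroc_bruteforce(y, s), abs=1e-9)

    def test_aupr_matches_stepcurve_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            n = rng.integers(4, 21)
            y = rng.integers(0, 2, size=n).astype(float)
            if not y.any():
                continue
            s = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
            assert aupr(y, s) == pytest.approx(aupr_bruteforce(y, s), abs=1e-9)


class TestRegressionMetrics:
    def test_identity(self):
        r2, mae = regression_metrics([1, 2, 3], [1, 2, 3])
        assert r2 == pytest.approx(1.0) and mae == 0.0

    def test_shift_invariance_of_r2(self):
        r2, mae = regression_metrics([1, 2, 3], [3, 4, 5])
        assert r2 == pytest.approx(1.0) and mae == pytest.approx(2.0)

    def test_hand_example(self):
        r2, mae = regression_metrics([1, 2, 3], [1, 3, 2])
        assert r2 == pytest.approx(0.25)
        assert mae == pytest.approx(2 / 3)

    def test_constant_observed_gives_nan_r2(self):
        r2, mae = regression_metrics([2, 2, 2], [1, 2, 3])
        assert np.isnan(r2) and mae == pytest.approx(2 / 3)


class TestRunCV:
    def test_record_bookkeeping_and_no_descriptor_gap(self, synthetic_dataset):
        ds, truth = synthetic_dataset
        espec = DescriptorSpec("aac")
        cspec = DescriptorSpec("external", {"table": truth.chemical_features})
        result = run_cv(
            ds, espec, cspec,
            variants=["rf_all", "random_baseline"],
            scenario="LOOT", seeds=[11, 23], n_folds=5,
            rf_params={"n_estimators": 50},
        )
        frame = result.frame()
        for variant in ("rf_all", "random_baseline"):
            n = len(frame[(frame.variant == variant) & (frame.metric == "aupr")])
            n_skip = sum(1 for s in result.skips if s["variant"] == variant)
            assert n + n_skip == 2 * 5
        agg = result.aggregates()
        assert set(agg.columns) == {"variant", "metric", "mean", "std", "sem", "n"}
        # the informed model beats the random baseline on this structured data
        rf = agg[(agg.variant == "rf_all") & (agg.metric == "aupr")]["mean"].iloc[0]
        rnd = agg[(agg.variant == "random_baseline") & (agg.metric == "aupr")]["mean"].iloc[0]
        assert rf > rnd

    def test_regression_task_records_mae(self, synthetic_dataset):
        ds, truth = synthetic_dataset
        latent = ds.with_activity(
            truth.latent_activity,
            type(ds.metadata)(name="latent", activity_scale="raw", activity_threshold=0.0),
        )
        result = run_cv(
            latent, DescriptorSpec("aac"),
            DescriptorSpec("external", {"table": truth.chemical_features}),
            variants=["rf_all"], scenario="LOOT", seeds=[11], n_folds=4,
            task="regression", rf_params={"n_estimators": 50},
        )
        metrics = set(result.frame()["metric"])
        assert "mae" in metrics and "r2" in metrics


class TestCompareModels:
    def test_identical_samples_null(self):
        p, stars = compare_models([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert p == 1.0 and stars == ""

    def test_complete_separation(self):
        p, stars = compare_models([0, 0, 0, 0], [1, 1, 1, 1])
        assert p < 0.001 and stars == "***"

    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.004, "**"), (0.04, "*"), (0.2, "")],
    )
    def test_star_thresholds(self, p, expected):
        assert significance_stars(p) == expected

    def test_insufficient_records(self):
        with pytest.raises(DomainError):
            compare_models([0.5], [0.4, 0.3])
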