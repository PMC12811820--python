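import numpy as np
import pandas as pd
import pytest

from epiage import search
from epiage.clocks import ClockConfig
from epiage.search import (
    EvaluationMetrics,
    age_bin,
    compute_metrics,
    enumerate_configs,
    evaluate_loo,
    evaluate_oob,
    rank_models,
)


class TestEnumerate:
    def test_single_point_grid(self):
        configs = enumerate_configs(
            {
                "methods": ["SVM"],
                "transforms": [False],
                "site_selections": [("ENR", "CR4+")],
                "training_samples": ["CR4+"],
                "weighted": [False],
            }
        )
        assert len(configs) == 1
        assert configs[0] == ClockConfig(
            method="SVM",
            site_selection="ENR",
            site_selection_samples="CR4+",
            training_samples="CR4+",
        )

    def test_full_product_is_336(self):
        assert len(enumerate_configs()) == 4 * 2 * 7 * 3 * 2

    def test_excluding_weighted_svm_removes_42(self):
        full = enumerate_configs()
        pruned = enumerate_configs(
            {"exclude": [{"method": "SVM", "weighted": True}]}
        )
        assert len(full) - len(pruned) == 42

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="empty grid axis"):
            enumerate_configs({"methods": []})

    def test_stable_ordering(self):
        assert enumerate_configs() == enumerate_configs()


class TestAgeBins:
    def test_bin_edges(self):
        assert list(age_bin([0, 9.9, 10, 24.9, 25, 40])) == [
            "0-9",
            "0-9",
            "10-24",
            "10-24",
            "25+",
            "25+",
        ]


class TestMetrics:
    def _table(self):
        return pd.DataFrame(
            {
                "sample_id": list("abcdefg"),
                "age_best": [5.0, 8.0, 12.0, 15.0, 20.0, 30.0, 35.0],
                "cr": [4, 5, 4, 4, 5, 4, 2],
                "predicted": [7.0, 7.0, 11.0, 18.0, 19.0, 26.0, 10.0],
                "in_training": [True] * 7,
                "evaluated": [True, True, True, True, True, True, False],
            }
        )

    def test_residual_sign_convention(self):
        metrics = compute_metrics(ClockConfig(), self._table())
        row = metrics.per_sample.set_index("sample_id")
        assert row.loc["a", "residual"] == 2.0  # predicted 7 vs Age_best 5

    def test_mae_is_median_deviance(self):
        metrics = compute_metrics(ClockConfig(), self._table())
        dev = [2.0, 1.0, 1.0, 3.0, 1.0, 4.0]
        assert metrics.mae_overall == np.median(dev)

    def test_low_cr_rows_excluded(self):
        base = compute_metrics(ClockConfig(), self._table())
        poisoned = self._table()
        poisoned.loc[poisoned["cr"] == 2, "predicted"] = 999.0
        assert (
            compute_metrics(ClockConfig(), poisoned).mae_overall
            == base.mae_overall
        )

    def test_mae_order_invariant(self):
        table = self._table()
        shuffled = table.sample(frac=1, random_state=1)
        assert (
            compute_metrics(ClockConfig(), shuffled).mae_overall
            == compute_metrics(ClockConfig(), table).mae_overall
        )

    def test_bins_partition_by_age_best(self):
        metrics = compute_metrics(ClockConfig(), self._table())
        assert set(metrics.mae_by_bin) == {"0-9", "10-24", "25+"}
        assert metrics.mae_by_bin["0-9"] == np.median([2.0, 1.0])


class TestLOO:
    def test_perfect_linear_system(self, desk_settings):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"c0": rng.uniform(-2, 2, 25)},
            index=[f"s{i}" for i in range(25)],
        )
        ages = pd.Series(10 + 5 * X["c0"], index=X.index)
        cr = pd.Series(4, index=X.index)
        metrics, _ = evaluate_loo(
            ClockConfig(method="ENR"), X, ages, cr, settings=desk_settings, seed=0
        )
        assert metrics.mae_overall < 0.2

    def test_refit_count_equals_n(self, desk_settings):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(
            rng.normal(size=(12, 3)), index=[f"s{i}" for i in range(12)]
        )
        X.columns = [str(c) for c in X.columns]
        ages = pd.Series(rng.uniform(5, 30, 12), index=X.index)
        cr = pd.Series([4, 4, 4, 4, 5, 5, 3, 3, 4, 5, 4, 4], index=X.index)
        counter = []
        metrics, _ = evaluate_loo(
            ClockConfig(method="ENR", training_samples="CR4+"),
            X,
            ages,
            cr,
            settings=desk_settings,
            seed=1,
            refit_counter=counter,
        )
        assert len(counter) == (cr >= 4).sum()

    def test_outside_samples_reported_separately(self, small_cohort, desk_settings):
        X, ages, cr = (
            small_cohort["X"],
            small_cohort["age_best"],
            small_cohort["cr"],
        )
        metrics, _ = evaluate_loo(
            ClockConfig(method="ENR", training_samples="CR4+"),
            X,
            ages,
            cr,
            settings=desk_settings,
            seed=2,
        )
        table = metrics.per_sample
        assert set(table.loc[~table["in_training"], "cr"]) <= {2, 3}
        assert not table.loc[~table["in_training"], "evaluated"].any()
        assert len(table) == len(X)

    def test_too_few_samples(self, desk_settings):
        X = pd.DataFrame({"c": [1.0, 2.0]}, index=["a", "b"])
        ages = pd.Series([4.0, 6.0], index=X.index)
        cr = pd.Series([4, 4], index=X.index)
        with pytest.raises(ValueError, match="training samples"):
            evaluate_loo(ClockConfig(), X, ages, cr, settings=desk_settings)

    def test_rfr_rejected(self, desk_settings):
        X = pd.DataFrame({"c": np.arange(5.0)})
        ages = pd.Series(np.arange(5.0))
        cr = pd.Series([4] * 5)
        with pytest.raises(ValueError, match="evaluate_oob"):
            evaluate_loo(ClockConfig(method="RFR"), X, ages, cr)


class TestOOB:
    def test_constant_target(self, desk_settings):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(
            rng.normal(size=(20, 4)), index=[f"s{i}" for i in range(20)]
        )
        X.columns = [str(c) for c in X.columns]
        ages = pd.Series(12.0, index=X.index)
        cr = pd.Series(4, index=X.index)
        metrics, _ = evaluate_oob(
            ClockConfig(method="RFR"), X, ages, cr, settings=desk_settings, seed=0
        )
        assert metrics.mae_overall == 0.0

    def test_oob_not_better_than_resubstitution(self, desk_settings):
        worse = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(30, 5)), index=[f"s{i}" for i in range(30)]
            )
            X.columns = [str(c) for c in X.columns]
            ages = pd.Series(
                10 + 3 * X["0"] + rng.normal(scale=2, size=30), index=X.index
            )
            cr = pd.Series(4, index=X.index)
            metrics, clock = evaluate_oob(
                ClockConfig(method="RFR"),
                X,
                ages,
                cr,
                settings=desk_settings,
                seed=seed,
            )
            resub = np.median(np.abs(clock.predict(X) - ages))
            worse += metrics.mae_overall >= resub
        assert worse >= 9  # OOB error is optimistic-free in ~every run

    def test_every_sample_gets_oob_votes(self, small_cohort, desk_settings):
        X, ages, cr = (
            small_cohort["X"],
            small_cohort["age_best"],
            small_cohort["cr"],
        )
        metrics, clock = evaluate_oob(
            ClockConfig(method="RFR"), X, ages, cr, settings=desk_settings, seed=3
        )
        assert not np.isnan(clock.backend.oob_prediction_).any()


class TestRanking:
    def _metrics(self, mae, corr):
        return EvaluationMetrics(
            config=ClockConfig(),
            per_sample=pd.DataFrame(),
            mae_overall=mae,
            mae_by_bin={},
            mean_residual_by_bin={},
            mean_residual_overall=0.0,
            correlation=corr,
            n_eval=10,
        )

    def test_single_model(self):
        table = rank_models([self._metrics(2.0, 0.9)])
        assert list(table["rank"]) == [1]

    def test_sorted_by_mae(self):
        table = rank_models(
            [self._metrics(m, 0.8) for m in (2.0, 1.7, 3.1)]
        )
        assert list(table["mae_overall"]) == [1.7, 2.0, 3.1]

    def test_tie_broken_by_correlation(self):
        table = rank_models(
            [self._metrics(2.0, 0.8), self._metrics(2.0, 0.9)]
        )
        assert list(table["correlation"]) == [0.9, 0.8]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestRunSearch:
    def test_small_grid_end_to_end(self, small_cohort, desk_settings):
        X, ages, cr = (
            small_cohort["X"],
            small_cohort["age_best"],
            small_cohort["cr"],
        )
        grid = {
            "methods": ["ENR", "RFR"],
            "transforms": [False],
            "site_selections": [("ENR", "All")],
            "training_samples": ["All"],
            "weighted": [False],
        }
        table, results = search.run_search(
            X, ages, cr, grid_spec=grid, settings=desk_settings, seed=0,
            selection_reps=10,
        )
        assert len(table) == 2
        assert table["mae_overall"].is_monotonic_increasing
        assert {"method", "correlation", "mae_0-9"} <= set(table.columns)
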