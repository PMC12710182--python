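"""Metrics, group-aware cross-validation, model selection, and the
Friedman comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.dummy import DummyRegressor

from nanpqsar import (
    IFNB,
    NANPDataset,
    PredictionSet,
    descriptor_table,
    external_evaluate,
    friedman_compare,
    make_rf_factory,
    r_squared,
    repeated_group_cv,
    rmse,
    select_best,
)
from nanpqsar.data import Shape, log10_transform_targets
from nanpqsar.evaluation import (
    CVSummary,
    FoldResult,
    IncompleteDataError,
    IncompleteMatrixError,
    LeakageError,
    UndefinedR2Error,
)
from nanpqsar.models import RF_DESCRIPTORS, TrainedModel
from nanpqsar.simulate import GeneratorParams, ResponseCoefficients, generate_library

from conftest import make_record


class TestMetrics:
    def test_r2_hand_example(self):
        p = PredictionSet([0, 1, 2], [0, 1, 1])
        assert r_squared(p) == pytest.approx(0.5, abs=1e-12)

    def test_r2_perfect_and_mean(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert r_squared(PredictionSet(obs, obs)) == 1.0
        assert r_squared(
            PredictionSet(obs, np.full(3, obs.mean()))
        ) == pytest.approx(0.0, abs=1e-12)

    def test_r2_undefined_for_constant_obs(self):
        with pytest.raises(UndefinedR2Error):
            r_squared(PredictionSet([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_rmse_hand_example(self):
        p = PredictionSet([0.0, 0.0], [3.0, 4.0])
        assert rmse(p) == pytest.approx(np.sqrt(25 / 2), abs=1e-12)

    def test_rmse_zero_and_homogeneity(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert rmse(PredictionSet(obs, obs)) == 0.0
        err = np.array([0.5, -1.0, 2.0])
        base = rmse(PredictionSet(obs, obs + err))
        assert rmse(PredictionSet(obs, obs + 3 * err)) == pytest.approx(3 * base)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=2, max_value=40), st.integers(0, 2**31 - 1))
    def test_agree_with_two_pass_reference(self, n, seed):
        """Closed-form metrics match naive reference implementations."""
        rng = np.random.default_rng(seed)
        obs = rng.normal(size=n)
        pred = obs + rng.normal(size=n)
        if np.allclose(obs, obs[0]):
            return
        p = PredictionSet(obs, pred)
        ref_rmse = np.sqrt(sum((a - b) ** 2 for a, b in zip(pred, obs)) / n)
        mean = sum(obs) / n
        ref_r2 = 1 - sum((a - b) ** 2 for a, b in zip(pred, obs)) / sum(
            (o - mean) ** 2 for o in obs
        )
        assert rmse(p) == pytest.approx(ref_rmse, abs=1e-12)
        assert r_squared(p) == pytest.approx(ref_r2, abs=1e-12)


def _mean_factory(train_dataset, endpoint, seed):
    """Trivial comparator: always predicts the training mean."""
    y = np.array([r.endpoints[endpoint] for r in train_dataset])
    X = descriptor_table(train_dataset).to_numpy()
    est = DummyRegressor(strategy="mean").fit(X, y)
    return TrainedModel(
        kind=RF_DESCRIPTORS, endpoint=endpoint, params={"estimator": est},
        vocab=None, config=None,
        train_ids=frozenset(train_dataset.ids()),
    )


class TestRepeatedGroupCV:
    def test_fold_count_5x10(self, small_library):
        summary = repeated_group_cv(
            small_library, _mean_factory, IFNB, k=5, repeats=10, seed=0
        )
        assert len(summary.fold_results) == 50

    def test_each_record_validated_once_per_repeat(self):
        records = [
            make_record(f"N{i}", endpoints={IFNB: float(i + 1)}) for i in range(4)
        ]
        ds = log10_transform_targets(NANPDataset(records))
        seen = []
        def spy_factory(train_dataset, endpoint, seed):
            seen.append(set(train_dataset.ids()))
            return _mean_factory(train_dataset, endpoint, seed)
        repeated_group_cv(ds, spy_factory, IFNB, k=2, repeats=1, seed=1)
        validated = [set(ds.ids()) - train_ids for train_ids in seen]
        assert sorted(x for fold in validated for x in fold) == sorted(ds.ids())

    def test_summary_recomputable_from_folds(self, small_library):
        summary = repeated_group_cv(
            small_library, _mean_factory, IFNB, k=3, repeats=2, seed=2
        )
        r2s = np.array([f.r2 for f in summary.fold_results])
        rmses = np.array([f.rmse for f in summary.fold_results])
        assert summary.mean_r2 == pytest.approx(r2s.mean(), abs=1e-12)
        assert summary.sd_r2 == pytest.approx(r2s.std(ddof=1), abs=1e-12)
        assert summary.mean_rmse == pytest.approx(rmses.mean(), abs=1e-12)

    def test_missing_endpoint_raises(self, small_library):
        broken = NANPDataset(
            [make_record("X1"), make_record("X2")], metadata={}
        )
        with pytest.raises(IncompleteDataError):
            repeated_group_cv(broken, _mean_factory, IFNB, k=2, repeats=1, seed=0)

    def test_signal_recovery_vs_shuffled_control(self):
        """With a well-specified descriptor model the protocol reports
        high held-out R^2; with shuffled labels it collapses."""
        params = GeneratorParams(
            n_per_shape={Shape.TRIANGLE: 15, Shape.SQUARE: 15,
                         Shape.PENTAGON: 15, Shape.CUBE: 15},
            response={
                IFNB: ResponseCoefficients(1.55, 1.10, 0.0, 0.0),
                "IL6": ResponseCoefficients(2.25, 0.95, 0.0, 0.0),
            },
            enforce_panel_ranges=False,
            seed=4,
        )
        lib = log10_transform_targets(generate_library(params))
        factory = make_rf_factory(n_estimators=150)
        summary = repeated_group_cv(lib, factory, IFNB, k=5, repeats=1, seed=3)
        assert summary.mean_r2 > 0.9

        rng = np.random.default_rng(0)
        order = rng.permutation(len(lib))
        import dataclasses
        shuffled = NANPDataset(
            [
                dataclasses.replace(rec, endpoints=lib.records[j].endpoints)
                for rec, j in zip(lib.records, order)
            ]
        )
        null = repeated_group_cv(shuffled, factory, IFNB, k=5, repeats=1, seed=3)
        assert null.mean_r2 <= 0.1


class TestSelectBest:
    def _fold(self, repeat, fold, r2, rm, tag):
        return FoldResult(repeat, fold, r2, rm, model_ref=tag)

    def test_tie_break_rules(self):
        folds = [
            self._fold(0, 0, 0.8, 0.2, "a"),
            self._fold(0, 1, 0.9, 0.2, "b"),  # same RMSE, higher R2 wins
            self._fold(1, 0, 0.7, 0.3, "c"),
        ]
        assert select_best(CVSummary(folds)) == "b"

    def test_identical_metrics_first_fold_wins(self):
        folds = [self._fold(r, f, 0.5, 0.1, f"m{r}{f}")
                 for r in range(2) for f in range(2)]
        assert select_best(CVSummary(folds)) == "m00"

    def test_strict_dominance(self):
        folds = [
            self._fold(0, 0, 0.6, 0.3, "a"),
            self._fold(0, 1, 0.95, 0.05, "winner"),
        ]
        assert select_best(CVSummary(folds)) == "winner"


class TestExternalEvaluate:
    def test_leakage_guard(self, small_library):
        factory = make_rf_factory(n_estimators=50)
        model = factory(small_library, IFNB, seed=0)
        with pytest.raises(LeakageError):
            external_evaluate(model, small_library, IFNB)

    def test_perfect_oracle_scores_one(self):
        """A model matching the noiseless generating surface exactly."""
        coef = ResponseCoefficients(1.55, 1.10, 0.0, 0.0)
        params = GeneratorParams(
            n_per_shape={Shape.PENTAGON: 20}, noise_sd_log10=0.0,
            response={IFNB: coef, "IL6": coef}, motif_prevalence=0.0,
            enforce_panel_ranges=False, seed=6,
        )
        lib = log10_transform_targets(generate_library(params))

        class OracleEstimator:
            def predict(self, X):
                # descriptor column 0 is the RNA-base ratio
                return coef.intercept_log10 + coef.beta_rna_ratio * X[:, 0]

        model = TrainedModel(
            kind=RF_DESCRIPTORS, endpoint=IFNB,
            params={"estimator": OracleEstimator()}, vocab=None, config=None,
            train_ids=frozenset(),
        )
        r2, err, _ = external_evaluate(model, lib, IFNB)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert err == pytest.approx(0.0, abs=1e-9)


class TestFriedman:
    def test_tied_matrix_statistic_zero(self):
        matrix = np.ones((3, 10))
        comp = friedman_compare(matrix)
        assert comp.friedman_statistic == pytest.approx(0.0)
        assert 0.0 <= comp.p_value <= 1.0

    def test_consistent_ordering_closed_form(self):
        """Three models strictly ordered in all 10 cells: chi2 = 2n = 20."""
        base = np.arange(10, dtype=float)
        matrix = np.vstack([base, base + 1, base + 2])
        comp = friedman_compare(matrix)
        assert comp.friedman_statistic == pytest.approx(20.0)

    def test_matches_bruteforce_rank_oracle(self):
        rng = np.random.default_rng(5)
        matrix = rng.normal(size=(3, 4))
        m, n = matrix.shape
        # naive oracle: rank by sorting within each cell, then the formula
        ranks = np.empty_like(matrix)
        for j in range(n):
            col = matrix[:, j]
            ranks[:, j] = [1 + sum(other < v for other in col) for v in col]
        rbar = ranks.mean(axis=1)
        oracle = 12 * n / (m * (m + 1)) * ((rbar - (m + 1) / 2) ** 2).sum()
        assert friedman_compare(matrix).friedman_statistic == pytest.approx(oracle)

    def test_matches_scipy_when_tie_free(self):
        rng = np.random.default_rng(8)
        matrix = rng.normal(size=(4, 12))
        stat, p = stats.friedmanchisquare(*matrix)
        comp = friedman_compare(matrix)
        assert comp.friedman_statistic == pytest.approx(stat)
        assert comp.p_value == pytest.approx(p)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(11)
        matrix = rng.normal(size=(3, 8))
        a = friedman_compare(matrix).friedman_statistic
        b = friedman_compare(np.exp(matrix)).friedman_statistic
        assert a == pytest.approx(b)

    def test_incomplete_matrix_rejected(self):
        bad = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(IncompleteMatrixError):
            friedman_compare(bad)
        with pytest.raises(IncompleteMatrixError):
            friedman_compare(np.ones((1, 5)))
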