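"""Metrics, repeated group-aware cross-validation, and model comparison.

R^2 and RMSE are computed on the log10 scale.  Cross-validation folds
partition parent NANP records, never augmented variants: permutation
augmentation is applied to the training side of each fold only, so no
variant of a validation record can leak into training (group integrity).
Model families are compared with the Friedman non-parametric test over
the repeat x fold metric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import NANPDataset, NanpError
from .models import ModelFactory, TrainedModel, predict_record


class UndefinedR2Error(NanpError):
    """Zero total sum of squares: R^2 is undefined."""


class IncompleteDataError(NanpError):
    """A record lacks the endpoint being modeled."""


class LeakageError(NanpError):
    """Overlap between training records and an 'external' test set."""


class IncompleteMatrixError(NanpError):
    """Missing cells in a model-comparison metric matrix."""


@dataclass
class PredictionSet:
    """Paired observed/predicted log10 values."""

    y_obs: np.ndarray
    y_pred: np.ndarray
    nanp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.y_obs = np.asarray(self.y_obs, dtype=float)
        self.y_pred = np.asarray(self.y_pred, dtype=float)
        if self.y_obs.shape != self.y_pred.shape:
            raise ValueError("y_obs and y_pred must have equal length")

    @property
    def n(self) -> int:
        return len(self.y_obs)

    @property
    def y_mean(self) -> float:
        return float(self.y_obs.mean())


def r_squared(p: PredictionSet) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    Negative for predictors worse than the observed mean.
    """
    if p.n < 2:
        raise ValueError("R^2 needs at least 2 observations")
    ss_tot = float(((p.y_obs - p.y_mean) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedR2Error("observed values are all identical")
    ss_res = float(((p.y_pred - p.y_obs) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def rmse(p: PredictionSet) -> float:
    """Root mean squared prediction error."""
    if p.n < 1:
        raise ValueError("RMSE needs at least 1 observation")
    return float(np.sqrt(((p.y_pred - p.y_obs) ** 2).mean()))


@dataclass
class FoldResult:
    repeat_index: int
    fold_index: int
    r2: float
    rmse: float
    model_ref: TrainedModel | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass
class CVSummary:
    fold_results: list[FoldResult]
    mean_r2: float = field(init=False)
    sd_r2: float = field(init=False)
    mean_rmse: float = field(init=False)
    sd_rmse: float = field(init=False)

    def __post_init__(self) -> None:
        r2s = np.array([f.r2 for f in self.fold_results])
        rmses = np.array([f.rmse for f in self.fold_results])
        self.mean_r2 = float(r2s.mean())
        self.sd_r2 = float(r2s.std(ddof=1)) if len(r2s) > 1 else 0.0
        self.mean_rmse = float(rmses.mean())
        self.sd_rmse = float(rmses.std(ddof=1)) if len(rmses) > 1 else 0.0

    @property
    def best(self) -> FoldResult:
        return _best_fold(self.fold_results)

    def to_frame(self, model_kind: str = "", endpoint: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [f.repeat_index for f in self.fold_results],
                "fold": [f.fold_index for f in self.fold_results],
                "model_kind": model_kind,
                "endpoint": endpoint,
                "r2": [f.r2 for f in self.fold_results],
                "rmse": [f.rmse for f in self.fold_results],
            }
        )


def _best_fold(folds: Sequence[FoldResult]) -> FoldResult:
    # minimal RMSE; ties -> higher R^2; then lowest (repeat, fold)
    return min(
        folds, key=lambda f: (f.rmse, -f.r2, f.repeat_index, f.fold_index)
    )


def select_best(summary: CVSummary) -> TrainedModel:
    """The fold model minimizing validation RMSE (deterministic ties)."""
    if not summary.fold_results:
        raise ValueError("empty CV summary")
    return _best_fold(summary.fold_results).model_ref


def repeated_group_cv(
    dataset: NANPDataset,
    model_factory: ModelFactory,
    endpoint: str,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    n_permutations_eval: int = 1,
) -> CVSummary:
    """k-fold cross-validation over parent records, repeated with
    reshuffled folds.

    The factory receives only that fold's training records (and applies
    its own augmentation), so every permutation variant of a record
    stays inside the record's fold.  Validation records are scored via
    :func:`predict_record` (identity order by default).
    """
    for rec in dataset:
        if rec.endpoints is None or endpoint not in rec.endpoints:
            raise IncompleteDataError(
                f"{rec.nanp_id}: missing endpoint {endpoint}"
            )
    n = len(dataset)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    ids = dataset.ids()
    results: list[FoldResult] = []
    for repeat in range(repeats):
        rng = np.random.default_rng(seed * 10_000 + repeat)
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        for fold_i, val_idx in enumerate(folds):
            val_ids = {ids[i] for i in val_idx}
            train_set = dataset.subset([i for i in ids if i not in val_ids])
            val_set = dataset.subset([i for i in ids if i in val_ids])
            assert not (set(train_set.ids()) & val_ids), "fold group leakage"
            model = model_factory(
                train_set, endpoint, seed * 10_000 + repeat * 100 + fold_i
            )
            obs, pred = [], []
            for rec in val_set:
                mean, _ = predict_record(
                    model, rec, n_permutations=n_permutations_eval, seed=seed
                )
                obs.append(rec.endpoints[endpoint])
                pred.append(mean)
            pset = PredictionSet(np.array(obs), np.array(pred),
                                 tuple(val_set.ids()))
            results.append(
                FoldResult(repeat, fold_i, r_squared(pset), rmse(pset), model)
            )
    return CVSummary(results)


def external_evaluate(
    model: TrainedModel,
    test: NANPDataset,
    endpoint: str,
    n_permutations: int = 1,
    seed: int = 0,
) -> tuple[float, float, PredictionSet]:
    """Score a trained model on a disjoint external test set.

    Raises :class:`LeakageError` if any test record was seen in training
    (checked against the fingerprinted training ids in the model).
    """
    overlap = model.train_ids & set(test.ids())
    if overlap:
        raise LeakageError(
            f"test records overlap training set: {sorted(overlap)[:5]}..."
        )
    obs, pred = [], []
    for rec in test:
        if rec.endpoints is None or endpoint not in rec.endpoints:
            raise IncompleteDataError(f"{rec.nanp_id}: missing endpoint {endpoint}")
        mean, _ = predict_record(model, rec, n_permutations=n_permutations, seed=seed)
        obs.append(rec.endpoints[endpoint])
        pred.append(mean)
    pset = PredictionSet(np.array(obs), np.array(pred), tuple(test.ids()))
    return r_squared(pset), rmse(pset), pset


@dataclass
class ModelComparison:
    model_names: tuple[str, ...]
    metric_matrix: np.ndarray  # models x cells
    friedman_statistic: float
    p_value: float
    mean_ranks: np.ndarray
    df: int


def friedman_compare(
    matrix: np.ndarray | Mapping[str, Sequence[float]],
) -> ModelComparison:
    """Friedman rank test of m models over n fold cells.

    Within each cell the models are ranked (average ranks on ties);
    chi2_F = 12 n / (m (m+1)) * sum_j (Rbar_j - (m+1)/2)^2, with the
    asymptotic chi-square p-value on m - 1 degrees of freedom.
    """
    if isinstance(matrix, Mapping):
        names = tuple(matrix.keys())
        mat = np.array([np.asarray(matrix[name], dtype=float) for name in names])
    else:
        mat = np.asarray(matrix, dtype=float)
        names = tuple(f"model_{i}" for i in range(mat.shape[0]))
    if mat.ndim != 2:
        raise IncompleteMatrixError("metric matrix must be 2-D (models x cells)")
    m, n = mat.shape
    if m < 2 or n < 2:
        raise IncompleteMatrixError("need >= 2 models and >= 2 cells")
    if not np.isfinite(mat).all():
        raise IncompleteMatrixError("metric matrix contains missing cells")
    # rank models within each cell (columns), average ranks for ties
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)
    mean_ranks = ranks.mean(axis=1)
    statistic = 12.0 * n / (m * (m + 1)) * float(
        ((mean_ranks - (m + 1) / 2.0) ** 2).sum()
    )
    p_value = float(stats.chi2.sf(statistic, df=m - 1))
    return ModelComparison(
        model_names=names,
        metric_matrix=mat,
        friedman_statistic=statistic,
        p_value=p_value,
        mean_ranks=mean_ranks,
        df=m - 1,
    )
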