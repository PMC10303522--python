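"""Joint-angle regression: cuckoo-search-tuned random forests.

The regression maps per-window time-domain sEMG features (24 columns for
six muscles) to window-averaged joint angles.  Gait cycles are the
splitting unit — whole cycles go to either the training or the test set
(default ratio 4:1) so that within-cycle correlation cannot leak across
the split.  Cuckoo search tunes the forest's ``n_estimators`` and
``max_features`` against a held-out-cycle RMSE fitness; the best
parameters are refit on the full training set.  Predictions are smoothed
with the five-point cubic (Savitzky–Golay window 5, order 3) filter and
scored with RMSE, MAE and R² — both the standard residual-based R² and a
variant that replaces residuals with the predictions' deviations from
their own mean, reported for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.ensemble import RandomForestRegressor

from .cuckoo import CSConfig, CSResult, SearchSpace, cs_optimize

__all__ = [
    "RFParams",
    "SplitPlan",
    "EvalReport",
    "split_by_cycle",
    "fitness",
    "make_rf",
    "cs_rf_fit",
    "smooth_five_point",
    "evaluate",
    "default_search_space",
]


@dataclass(frozen=True)
class RFParams:
    """The two tuned random-forest hyperparameters."""

    n_estimators: int
    max_features: int

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.max_features < 1:
            raise ValueError("max_features must be >= 1")


@dataclass
class SplitPlan:
    """Whole-cycle train/test assignment."""

    train_cycle_ids: np.ndarray
    test_cycle_ids: np.ndarray
    ratio: tuple

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_cycle_ids, self.test_cycle_ids).size:
            raise ValueError("train and test cycles overlap")

    def mask(self, cycle_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ids = np.asarray(cycle_ids)
        train = np.isin(ids, self.train_cycle_ids)
        test = np.isin(ids, self.test_cycle_ids)
        return train, test


@dataclass
class EvalReport:
    rmse: float
    mae: float
    r2: float
    r2_variant: float
    degenerate: bool = False  # constant actuals: R² undefined

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "r2": self.r2,
                "r2_variant": self.r2_variant}


def split_by_cycle(cycle_ids, ratio: tuple = (4, 1), seed: int = 0) -> SplitPlan:
    """Randomly assign whole gait cycles to train/test in the given ratio.

    The remainder after the exact ratio goes to the training set; 200
    cycles at 4:1 give 160 train / 40 test.
    """
    unique = np.unique(np.asarray(cycle_ids))
    a, b = ratio
    if unique.size < a + b:
        raise ValueError("fewer cycles than the ratio denominator")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n_test = unique.size * b // (a + b)
    return SplitPlan(train_cycle_ids=np.sort(perm[n_test:]),
                     test_cycle_ids=np.sort(perm[:n_test]),
                     ratio=(a, b))


def make_rf(params: RFParams, seed: int = 0) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=params.n_estimators,
        max_features=params.max_features,
        random_state=seed,
        n_jobs=1,
    )


def fitness(params: RFParams, X_train: np.ndarray, y_train: np.ndarray,
            X_val: np.ndarray, y_val: np.ndarray, seed: int = 0) -> float:
    """Validation RMSE of a forest with the given hyperparameters."""
    if params.max_features > X_train.shape[1]:
        raise ValueError("max_features exceeds the feature count")
    rf = make_rf(params, seed=seed)
    rf.fit(X_train, y_train)
    pred = rf.predict(X_val)
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


def default_search_space(n_features: int) -> SearchSpace:
    return SearchSpace(bounds=((10, 300), (1, n_features)),
                       types=("integer", "integer"))


def cs_rf_fit(X: np.ndarray, y: np.ndarray, cycle_ids: np.ndarray | None = None,
              cs_cfg: CSConfig | None = None, space: SearchSpace | None = None,
              *, val_fraction: float = 0.2, max_fitness_rows: int | None = None,
              seed: int = 0):
    """Tune and fit a random forest with cuckoo search.

    The fitness of a parameter vector is the RMSE on a fixed, seeded
    hold-out: 20% of the training cycles (or of the rows when no cycle ids
    are given).  ``max_fitness_rows`` optionally subsamples the fitness
    split's rows — a surrogate-fitness speed-up for large window counts;
    the final model is always refit on all rows with the best parameters.

    Returns
    -------
    (fitted RandomForestRegressor, RFParams, CSResult)
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and targets are not row-aligned")
    if cs_cfg is None:
        cs_cfg = CSConfig(seed=seed)
    if space is None:
        space = default_search_space(X.shape[1])

    rng = np.random.default_rng(seed)
    if cycle_ids is not None:
        inner = split_by_cycle(cycle_ids, ratio=(4, 1), seed=seed)
        tr_mask, va_mask = inner.mask(cycle_ids)
    else:
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = max(1, int(round(val_fraction * n)))
        va_mask = np.zeros(n, dtype=bool)
        va_mask[perm[:n_val]] = True
        tr_mask = ~va_mask
    tr_idx = np.flatnonzero(tr_mask)
    va_idx = np.flatnonzero(va_mask)
    if max_fitness_rows is not None:
        if tr_idx.size > max_fitness_rows:
            tr_idx = rng.choice(tr_idx, size=max_fitness_rows, replace=False)
        n_val_keep = max(1, max_fitness_rows // 4)
        if va_idx.size > n_val_keep:
            va_idx = rng.choice(va_idx, size=n_val_keep, replace=False)
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = X[va_idx], y[va_idx]

    def objective(x: np.ndarray) -> float:
        params = RFParams(n_estimators=int(x[0]), max_features=int(x[1]))
        return fitness(params, Xtr, ytr, Xva, yva, seed=seed)

    result = cs_optimize(objective, space, cs_cfg)
    best = RFParams(n_estimators=int(result.best_params[0]),
                    max_features=int(result.best_params[1]))
    final = make_rf(best, seed=seed)
    final.fit(X, y)
    return final, best, result


# five-point cubic interior weights (-3, 12, 17, 12, -3)/35; ends use the
# asymmetric five-point cubic fits, which savgol's "interp" mode provides
def smooth_five_point(series: np.ndarray) -> np.ndarray:
    """Five-point cubic smoothing; length-preserving; exact on polynomials
    up to degree 3.  Series shorter than 5 are returned unchanged with a
    warning."""
    x = np.asarray(series, dtype=np.float64)
    if x.size < 5:
        warnings.warn("series shorter than 5 samples: smoothing skipped")
        return x.copy()
    return savgol_filter(x, window_length=5, polyorder=3, mode="interp")


def evaluate(pred: np.ndarray, actual: np.ndarray) -> EvalReport:
    """RMSE, MAE and both R² readings for a prediction series.

    ``r2`` is the standard coefficient of determination
    1 - Σ(pred-actual)²/Σ(actual-mean)²; ``r2_variant`` replaces the
    residual sum with the predictions' deviations from their own mean,
    1 - Σ(pred-mean_pred)²/Σ(actual-mean_actual)².  Constant actuals make
    both undefined; they are reported as NaN with ``degenerate=True``.
    """
    p = np.asarray(pred, dtype=np.float64)
    a = np.asarray(actual, dtype=np.float64)
    if p.size != a.size:
        raise ValueError("series lengths differ")
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    rmse = float(np.sqrt(np.mean((p - a) ** 2)))
    mae = float(np.mean(np.abs(p - a)))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant actual series: R² undefined")
        return EvalReport(rmse=rmse, mae=mae, r2=np.nan, r2_variant=np.nan,
                          degenerate=True)
    r2 = 1.0 - float(np.sum((p - a) ** 2)) / ss_tot
    r2_variant = 1.0 - float(np.sum((p - p.mean()) ** 2)) / ss_tot
    return EvalReport(rmse=rmse, mae=mae, r2=r2, r2_variant=r2_variant)
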