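"""Random-forest modelling of the WA secretion score.

Includes the Kennard-Stone maximin train/test split, the
:class:`EfficiencyRegressor` estimator (a random forest with the screen's
hyperparameters and a backend-independent tree accessor for the explainer),
MSE evaluation, seeded k-fold grid search and JSON model serialization.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error
from sklearn.model_selection import GridSearchCV, KFold

from .trees import TreeStructure

#: Hyperparameters selected by the screen's 5-fold grid search.  The
#: min-samples parameters are fractions of the training set (sklearn resolves
#: them as ceil(fraction * n)).  ``max_features=None`` means all features,
#: which is what an explicit count equal to the feature-set size selects.
DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 75,
    "max_depth": 25,
    "max_features": None,
    "min_samples_leaf": 0.0001,
    "min_samples_split": 0.001,
}


def _as_array(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return arr


def kennard_stone_split(
    X, n_train: int, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic maximin selection of ``n_train`` training rows.

    Seeds with the most distant pair, then greedily adds the point whose
    minimal distance to the selected set is maximal (ties: lowest row index).
    Distances are Euclidean on z-scored features by default.  Returns
    (train_indices, test_indices) partitioning ``range(n)``.
    """
    arr = _as_array(X)
    n = arr.shape[0]
    if not 2 <= n_train <= n:
        raise ValueError(f"n_train must be in [2, {n}], got {n_train}")
    if standardize:
        sd = arr.std(axis=0)
        sd[sd == 0] = 1.0
        arr = (arr - arr.mean(axis=0)) / sd
    sq = (arr**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * arr @ arr.T
    np.maximum(d2, 0, out=d2)
    # seed pair: maximal distance, ties by lowest flat index
    i, j = np.unravel_index(int(d2.argmax()), d2.shape)
    selected = [min(i, j), max(i, j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_d2 = np.minimum(d2[selected[0]], d2[selected[1]])
    while len(selected) < n_train:
        min_d2[in_set] = -np.inf
        nxt = int(min_d2.argmax())  # argmax returns the lowest tied index
        selected.append(nxt)
        in_set[nxt] = True
        np.minimum(min_d2, d2[nxt], out=min_d2)
    train = np.array(selected, dtype=int)
    test = np.flatnonzero(~in_set)
    return train, test


class EfficiencyRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regressor of WA on the selected feature set.

    Wraps scikit-learn's RandomForestRegressor with the screen's defaults and
    exposes the fitted ensemble as backend-independent ``trees_`` structures
    consumed by the Shapley explainer and the JSON serializer.
    """

    def __init__(
        self,
        n_estimators: int = 75,
        max_depth: int | None = 25,
        max_features: int | float | str | None = None,
        min_samples_leaf: float | int = 0.0001,
        min_samples_split: float | int = 0.001,
        random_state: int | None = None,
        wa_bounds: tuple[float, float] | None = (1.0, 10.0),
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.min_samples_split = min_samples_split
        self.random_state = random_state
        self.wa_bounds = wa_bounds

    def fit(self, X, y) -> "EfficiencyRegressor":
        arr = _as_array(X)
        y = np.asarray(y, dtype=float)
        if arr.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if np.isnan(arr).any() or np.isnan(y).any():
            raise ValueError("NaN values in X or y")
        if self.wa_bounds is not None:
            lo, hi = self.wa_bounds
            if y.min() < lo or y.max() > hi:
                raise ValueError(f"y values outside the WA range [{lo}, {hi}]")
        self.feature_names_in_ = (
            list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(arr.shape[1])]
        )
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            random_state=self.random_state,
            bootstrap=True,
        )
        self.model_.fit(arr, y)
        self.trees_ = [TreeStructure.from_sklearn(t) for t in self.model_.estimators_]
        self.expected_value_ = float(np.mean([t.expected_value() for t in self.trees_]))
        return self

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise KeyError(f"missing features: {missing}")
            X = X[self.feature_names_in_]
        arr = _as_array(X)
        if arr.shape[1] != len(self.feature_names_in_):
            raise ValueError("feature count mismatch")
        return arr

    def predict(self, X) -> np.ndarray:
        arr = self._align(X)
        if hasattr(self, "model_") and self.model_ is not None:
            return self.model_.predict(arr)
        preds = np.array([[t.predict_one(x) for t in self.trees_] for x in arr])
        return preds.mean(axis=1)

    # -- persistence --------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names_in_,
            "expected_value": self.expected_value_,
            "params": self.get_params(),
            "trees": [t.to_dict() for t in self.trees_],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "EfficiencyRegressor":
        payload = json.loads(Path(path).read_text())
        params = payload.get("params", {})
        params.pop("wa_bounds", None)
        est = cls(**{k: v for k, v in params.items() if k in cls().get_params()})
        est.feature_names_in_ = payload["feature_names"]
        est.expected_value_ = payload["expected_value"]
        est.trees_ = [TreeStructure.from_dict(d) for d in payload["trees"]]
        est.model_ = None
        return est


def train_forest(X, y, random_state: int | None = None, **hyperparameters) -> EfficiencyRegressor:
    params = {**DEFAULT_HYPERPARAMETERS, **hyperparameters}
    return EfficiencyRegressor(random_state=random_state, **params).fit(X, y)


def evaluate_mse(predictions: Sequence[float], truth: Sequence[float]) -> float:
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    return float(mean_squared_error(truth, predictions))


def grid_search_cv(
    X,
    y,
    param_grid: dict[str, list],
    k: int = 5,
    seed: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Seeded k-fold grid search minimizing validation MSE.

    Ties resolve to the first grid point in iteration order.  Returns the
    best parameter dict and the full CV table.
    """
    arr = _as_array(X)
    if arr.shape[0] < k:
        raise ValueError(f"need at least {k} samples for {k}-fold CV")
    if not param_grid:
        raise ValueError("empty parameter grid")
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        EfficiencyRegressor(random_state=seed, wa_bounds=None),
        param_grid,
        scoring="neg_mean_squared_error",
        cv=cv,
    )
    search.fit(arr, np.asarray(y, dtype=float))
    table = pd.DataFrame(search.cv_results_)
    table["mean_validation_mse"] = -table["mean_test_score"]
    return dict(search.best_params_), table
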