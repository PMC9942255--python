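"""Shapley explanation of the WA forest.

``TreeExplainer`` computes path-dependent Shapley attributions (and pairwise
interaction values) from the backend-independent tree structures of a fitted
:class:`~spscreen.model.EfficiencyRegressor`.  Local accuracy holds exactly:
base value + sum of attributions = model prediction.  Positive attributions
push the prediction toward a higher WA, i.e. worse secretion.

A brute-force subset-enumeration implementation ships as the oracle for
small models (it is exponential in the feature count and gated accordingly).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd

from ._treeshap import COND_ABSENT, COND_NONE, COND_PRESENT, _tree_shap_kernel
from .model import EfficiencyRegressor
from .trees import TreeStructure


@dataclass
class Attribution:
    """Per-SP decomposition of the predicted WA."""

    sp_id: str
    base_value: float
    phi: dict[str, float]
    phi2: pd.DataFrame | None = None

    @property
    def prediction(self) -> float:
        return self.base_value + sum(self.phi.values())


class TreeExplainer:
    """Path-dependent Shapley attributions for a tree ensemble.

    The background weighting comes from the training-sample coverage stored
    in the tree nodes, so the base value equals the mean training prediction
    of the ensemble.
    """

    def __init__(
        self,
        model: EfficiencyRegressor | Sequence[TreeStructure],
        feature_names: Sequence[str] | None = None,
    ):
        if isinstance(model, EfficiencyRegressor):
            self.trees = list(model.trees_)
            self.feature_names = list(model.feature_names_in_)
        else:
            self.trees = list(model)
            if feature_names is None:
                used = max((int(t.feature.max()) for t in self.trees), default=-1)
                feature_names = [f"x{i}" for i in range(used + 1)]
            self.feature_names = list(feature_names)
        self.n_features = len(self.feature_names)
        self.base_value_ = float(np.mean([t.expected_value() for t in self.trees]))
        self._depths = [max(t.max_depth, 1) for t in self.trees]

    # -- core ---------------------------------------------------------------
    def _phi_one(self, x: np.ndarray, condition: int = COND_NONE, cond_feature: int = -1):
        phi = np.zeros(self.n_features, dtype=np.float64)
        for tree, depth in zip(self.trees, self._depths):
            _tree_shap_kernel(
                tree.children_left,
                tree.children_right,
                tree.feature,
                tree.threshold,
                tree.value,
                tree.cover,
                x,
                phi,
                condition,
                cond_feature,
                depth,
            )
        return phi / len(self.trees)

    def shap_values(self, X) -> np.ndarray:
        """(n_samples, n_features) attribution matrix."""
        arr = self._align(X)
        return np.vstack([self._phi_one(x) for x in arr])

    def _align(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"missing features: {missing}")
            X = X[self.feature_names]
        arr = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if arr.shape[1] != self.n_features:
            raise ValueError("feature count mismatch")
        return arr

    def attribute(self, x, sp_id: str = "") -> Attribution:
        arr = self._align(x)[0]
        phi = self._phi_one(arr)
        return Attribution(
            sp_id=sp_id,
            base_value=self.base_value_,
            phi=dict(zip(self.feature_names, phi.tolist())),
        )

    # -- interactions -------------------------------------------------------
    def interaction_values(self, x) -> pd.DataFrame:
        """Symmetric pairwise interaction matrix; rows sum to the attributions."""
        arr = self._align(x)[0]
        phi = self._phi_one(arr)
        used = sorted({int(f) for t in self.trees for f in t.feature if f >= 0})
        M = self.n_features
        phi2 = np.zeros((M, M))
        for i in used:
            present = self._phi_one(arr, COND_PRESENT, i)
            absent = self._phi_one(arr, COND_ABSENT, i)
            delta = 0.5 * (present - absent)
            delta[i] = 0.0
            phi2[i, :] = delta
        phi2 = 0.5 * (phi2 + phi2.T)  # symmetric up to float error by theory
        np.fill_diagonal(phi2, 0.0)
        np.fill_diagonal(phi2, phi - phi2.sum(axis=1))
        return pd.DataFrame(phi2, index=self.feature_names, columns=self.feature_names)

    def attribute_interactions(self, x, sp_id: str = "") -> Attribution:
        out = self.attribute(x, sp_id=sp_id)
        out.phi2 = self.interaction_values(x)
        return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def rank_features(
    attributions: Sequence[Attribution] | np.ndarray,
    feature_names: Sequence[str] | None = None,
    top_k: int | None = None,
) -> pd.Series:
    """Features ordered by descending mean |attribution| (ties: alphabetical)."""
    if len(attributions) == 0:
        raise ValueError("no attributions to rank")
    if isinstance(attributions, np.ndarray):
        if feature_names is None:
            raise ValueError("feature_names required with a raw attribution matrix")
        mean_abs = pd.Series(np.abs(attributions).mean(axis=0), index=list(feature_names))
    else:
        frame = pd.DataFrame([a.phi for a in attributions])
        mean_abs = frame.abs().mean(axis=0)
    order = sorted(mean_abs.index, key=lambda name: (-mean_abs[name], name))
    ranked = mean_abs.loc[order]
    ranked.name = "mean_abs_shap"
    return ranked.head(top_k) if top_k is not None else ranked


def force_decomposition(attribution: Attribution, top_n: int = 10) -> dict:
    """Largest signed contributions plus an aggregated remainder.

    Segments and base value reconstruct the prediction exactly.
    """
    items = sorted(attribution.phi.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    head = items[:top_n]
    remainder = sum(v for _, v in items[top_n:])
    return {
        "sp_id": attribution.sp_id,
        "base_value": attribution.base_value,
        "segments": head,
        "remainder": remainder,
        "prediction": attribution.base_value + sum(v for _, v in head) + remainder,
    }


def attributions_to_frame(
    attributions: Sequence[Attribution],
) -> pd.DataFrame:
    """Rows = SPs, columns = features plus a base_value column (TSV-ready)."""
    frame = pd.DataFrame([a.phi for a in attributions], index=[a.sp_id for a in attributions])
    frame.insert(0, "base_value", [a.base_value for a in attributions])
    frame.index.name = "id"
    return frame


# ---------------------------------------------------------------------------
# Brute-force oracle (exponential; small models only)
# ---------------------------------------------------------------------------

_BRUTE_MAX_FEATURES = 14


def _conditional_expectation(tree: TreeStructure, x: np.ndarray, mask: int) -> float:
    def rec(node: int) -> float:
        if tree.is_leaf(node):
            return float(tree.value[node])
        f = int(tree.feature[node])
        left, right = int(tree.children_left[node]), int(tree.children_right[node])
        if (mask >> f) & 1:
            nxt = left if x[f] <= tree.threshold[node] else right
            return rec(nxt)
        wl = tree.cover[left] / tree.cover[node]
        return wl * rec(left) + (1 - wl) * rec(right)

    return rec(0)


def _value_table(trees: Sequence[TreeStructure], x: np.ndarray, M: int) -> np.ndarray:
    if M > _BRUTE_MAX_FEATURES:
        raise ValueError(f"brute-force oracle is gated to <= {_BRUTE_MAX_FEATURES} features")
    v = np.zeros(1 << M)
    for mask in range(1 << M):
        v[mask] = np.mean([_conditional_expectation(t, x, mask) for t in trees])
    return v


def brute_force_shapley(
    trees: Sequence[TreeStructure], x, n_features: int
) -> np.ndarray:
    """Exact Shapley values by enumerating all feature coalitions."""
    x = np.asarray(x, dtype=float)
    M = n_features
    v = _value_table(trees, x, M)
    weights = [factorial(s) * factorial(M - s - 1) / factorial(M) for s in range(M)]
    phi = np.zeros(M)
    others = list(range(M))
    for i in range(M):
        rest = [f for f in others if f != i]
        for size in range(M):
            for subset in combinations(rest, size):
                mask = 0
                for f in subset:
                    mask |= 1 << f
                phi[i] += weights[size] * (v[mask | (1 << i)] - v[mask])
    return phi


def brute_force_interactions(
    trees: Sequence[TreeStructure], x, n_features: int
) -> np.ndarray:
    """Exact Shapley interaction index by coalition enumeration."""
    x = np.asarray(x, dtype=float)
    M = n_features
    v = _value_table(trees, x, M)
    phi = brute_force_shapley(trees, x, M)
    phi2 = np.zeros((M, M))
    if M >= 2:
        weights = [
            factorial(s) * factorial(M - s - 2) / (2 * factorial(M - 1)) for s in range(M - 1)
        ]
        for i, j in combinations(range(M), 2):
            rest = [f for f in range(M) if f not in (i, j)]
            bi, bj = 1 << i, 1 << j
            total = 0.0
            for size in range(M - 1):
                for subset in combinations(rest, size):
                    mask = 0
                    for f in subset:
                        mask |= 1 << f
                    delta = v[mask | bi | bj] - v[mask | bi] - v[mask | bj] + v[mask]
                    total += weights[size] * delta
            phi2[i, j] = phi2[j, i] = total
    np.fill_diagonal(phi2, phi - phi2.sum(axis=1))
    return phi2
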