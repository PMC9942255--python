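"""Feature-set reduction for the screen's feature matrix.

Pipeline: (1) drop zero-variance columns; (2) partition the remainder at a
pairwise correlation threshold (default |r| > 0.7); (3) cluster the redundant
block with affinity propagation (features as points, similarity = negative
squared Euclidean distance between standardized columns); (4) keep one
representative per cluster (the exemplar, with explicit overrides for manual
exceptions); (5) append the 40 cleavage-site dummies untouched.

Affinity propagation is implemented deterministically (no tie-breaking
noise): responsibility/availability message passing with damping, preference
defaulting to the median similarity, and exemplar-stability convergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DUMMY_PREFIXES = ("-3_", "-1_")


@dataclass(frozen=True)
class Cluster:
    members: tuple[str, ...]
    exemplar: str


@dataclass
class SelectionReport:
    dropped_invariant: list[str] = field(default_factory=list)
    retained_low_corr: list[str] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)
    dummies: list[str] = field(default_factory=list)
    final_set: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped_invariant": self.dropped_invariant,
            "retained_low_corr": self.retained_low_corr,
            "clusters": [
                {"members": list(c.members), "exemplar": c.exemplar} for c in self.clusters
            ],
            "representatives": self.representatives,
            "dummies": self.dummies,
            "final_set": self.final_set,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def representative_of(self, feature: str) -> str | None:
        """The feature standing in for ``feature`` in the final set.

        Returns the feature itself when retained, the representative of its
        cluster when it was absorbed by clustering, None when dropped.
        """
        if feature in self.final_set:
            return feature
        for cluster in self.clusters:
            if feature in cluster.members:
                kept = [m for m in cluster.members if m in self.representatives]
                return kept[0] if kept else None
        return None


def drop_invariant_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove columns showing no variation."""
    if matrix.empty:
        raise ValueError("empty feature matrix")
    values = matrix.to_numpy()
    invariant = matrix.columns[(values.max(axis=0) - values.min(axis=0)) == 0]
    return matrix.drop(columns=invariant), list(invariant)


def correlation_partition(
    matrix: pd.DataFrame, threshold: float = 0.7, method: str = "pearson"
) -> tuple[list[str], list[str]]:
    """Split features into an independent and a redundant (|r|>thr) block."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to compute correlations")
    corr = matrix.corr(method=method).abs()
    if corr.isna().to_numpy().any():
        raise ValueError(
            "undefined correlation (constant column?): run drop_invariant_features first"
        )
    mask = corr.to_numpy() > threshold
    np.fill_diagonal(mask, False)
    redundant = mask.any(axis=0)
    return list(matrix.columns[~redundant]), list(matrix.columns[redundant])


def _similarity_matrix(matrix: pd.DataFrame) -> np.ndarray:
    cols = matrix.to_numpy(dtype=float)
    mu, sd = cols.mean(axis=0), cols.std(axis=0)
    sd[sd == 0] = 1.0
    pts = ((cols - mu) / sd).T  # one point per feature
    sq = (pts**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * pts @ pts.T
    np.maximum(d2, 0, out=d2)
    return -d2


class AffinityPropagationError(RuntimeError):
    def __init__(self, message: str, partial_exemplars: list[str]):
        super().__init__(message)
        self.partial_exemplars = partial_exemplars


def affinity_propagation_cluster(
    matrix: pd.DataFrame,
    damping: float = 0.5,
    preference: float | None = None,
    max_iter: int = 500,
    convergence_iter: int = 15,
) -> list[Cluster]:
    """Cluster feature columns by affinity propagation; infers cluster count."""
    names = list(matrix.columns)
    n = len(names)
    if n == 0:
        raise ValueError("no features to cluster")
    if n == 1:
        return [Cluster(members=(names[0],), exemplar=names[0])]
    S = _similarity_matrix(matrix)
    off_diag = S[~np.eye(n, dtype=bool)]
    if off_diag.max() - off_diag.min() < 1e-12:
        # all pairwise distances equal (e.g. duplicated columns): message
        # passing has no structure to resolve, so the whole block is one
        # cluster with the first column as exemplar
        return [Cluster(members=tuple(names), exemplar=names[0])]
    pref = float(np.median(S)) if preference is None else float(preference)
    np.fill_diagonal(S, pref)

    A = np.zeros((n, n))
    R = np.zeros((n, n))
    idx = np.arange(n)
    last_exemplars: np.ndarray | None = None
    stable = 0
    for _ in range(max_iter):
        # responsibilities
        AS = A + S
        first = AS.argmax(axis=1)
        y1 = AS[idx, first]
        AS[idx, first] = -np.inf
        y2 = AS.max(axis=1)
        R_new = S - y1[:, None]
        R_new[idx, first] = S[idx, first] - y2
        R = (1 - damping) * R_new + damping * R
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        A_new = Rp.sum(axis=0)[None, :] - Rp
        dA = A_new[idx, idx].copy()
        A_new = np.minimum(A_new, 0)
        A_new[idx, idx] = dA
        A = (1 - damping) * A_new + damping * A

        exemplars = np.flatnonzero((A[idx, idx] + R[idx, idx]) > 0)
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
            if stable >= convergence_iter and exemplars.size > 0:
                break
        else:
            stable = 0
        last_exemplars = exemplars
    else:
        raise AffinityPropagationError(
            f"affinity propagation did not converge within {max_iter} iterations",
            [names[i] for i in (last_exemplars if last_exemplars is not None else [])],
        )

    I = exemplars
    labels = S[:, I].argmax(axis=1)
    labels[I] = np.arange(I.size)
    # refine exemplars: within-cluster similarity maximizer
    for k in range(I.size):
        members = np.flatnonzero(labels == k)
        I[k] = members[S[np.ix_(members, members)].sum(axis=0).argmax()]
    labels = S[:, I].argmax(axis=1)
    labels[I] = np.arange(I.size)
    clusters = []
    for k, ex in enumerate(I):
        members = tuple(names[i] for i in np.flatnonzero(labels == k))
        clusters.append(Cluster(members=members, exemplar=names[ex]))
    return clusters


def select_cluster_representatives(
    clusters: Sequence[Cluster],
    overrides: Mapping[str, str | Sequence[str]] | None = None,
) -> list[str]:
    """One representative (the exemplar) per cluster, plus explicit overrides.

    ``overrides`` is keyed by exemplar name; the value is either ``"all"``
    (keep the whole cluster) or a list of extra member names to keep.
    """
    overrides = dict(overrides or {})
    known = {m for c in clusters for m in c.members}
    for key, value in overrides.items():
        bad = {key} - known
        if value != "all":
            bad |= set(value) - known
        if bad:
            raise KeyError(f"override references unknown features: {sorted(bad)}")
    names: list[str] = []
    for cluster in clusters:
        spec = overrides.get(cluster.exemplar)
        if spec == "all":
            names.extend(cluster.members)
        elif spec is not None:
            names.append(cluster.exemplar)
            names.extend(m for m in spec if m != cluster.exemplar)
        else:
            names.append(cluster.exemplar)
    return names


def build_final_feature_set(
    matrix: pd.DataFrame,
    dummies: pd.DataFrame | Sequence[str] | None = None,
    corr_threshold: float = 0.7,
    method: str = "pearson",
    damping: float = 0.5,
    preference: float | None = None,
    overrides: Mapping[str, str | Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Run the full reduction and append the dummy block."""
    dummy_df = None
    if isinstance(dummies, pd.DataFrame):
        dummy_df = dummies
        dummy_names = list(dummies.columns)
    else:
        dummy_names = list(dummies or [])
    overlap = set(dummy_names) & set(matrix.columns)
    if overlap:
        raise ValueError(f"dummies overlap computed features: {sorted(overlap)}")

    varying, dropped = drop_invariant_features(matrix)
    independent, redundant = correlation_partition(varying, corr_threshold, method)
    clusters: list[Cluster] = []
    representatives: list[str] = []
    if redundant:
        clusters = affinity_propagation_cluster(
            varying[redundant], damping=damping, preference=preference
        )
        representatives = select_cluster_representatives(clusters, overrides)
    final = independent + representatives + dummy_names
    report = SelectionReport(
        dropped_invariant=dropped,
        retained_low_corr=independent,
        clusters=clusters,
        representatives=representatives,
        dummies=dummy_names,
        final_set=final,
    )
    reduced = varying[independent + representatives]
    if dummy_df is not None:
        reduced = pd.concat([reduced, dummy_df], axis=1)
    return reduced, report


class CorrelationAPSelector:
    """sklearn-style transformer running the full feature reduction.

    Columns whose names start with a dummy prefix (default ``-3_``/``-1_``)
    bypass the variance/correlation machinery and are appended unchanged.
    """

    def __init__(
        self,
        corr_threshold: float = 0.7,
        method: str = "pearson",
        damping: float = 0.5,
        preference: float | None = None,
        overrides: Mapping[str, str | Sequence[str]] | None = None,
        dummy_prefixes: tuple[str, ...] = DUMMY_PREFIXES,
    ):
        self.corr_threshold = corr_threshold
        self.method = method
        self.damping = damping
        self.preference = preference
        self.overrides = overrides
        self.dummy_prefixes = dummy_prefixes

    def get_params(self, deep: bool = True) -> dict:
        return {
            "corr_threshold": self.corr_threshold,
            "method": self.method,
            "damping": self.damping,
            "preference": self.preference,
            "overrides": self.overrides,
            "dummy_prefixes": self.dummy_prefixes,
        }

    def set_params(self, **params) -> "CorrelationAPSelector":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def _split(self, X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        is_dummy = X.columns.str.startswith(self.dummy_prefixes)
        return X.loc[:, ~is_dummy], X.loc[:, is_dummy]

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationAPSelector":
        computed, dummy = self._split(X)
        _, self.report_ = build_final_feature_set(
            computed,
            dummies=dummy,
            corr_threshold=self.corr_threshold,
            method=self.method,
            damping=self.damping,
            preference=self.preference,
            overrides=self.overrides,
        )
        self.selected_features_ = list(self.report_.final_set)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.selected_features_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
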