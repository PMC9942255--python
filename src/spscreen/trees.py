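"""Backend-independent regression-tree structures.

Trees extracted from the fitted forest carry everything the explainer and
the JSON serializer need: split feature/threshold, children, leaf values and
training-sample coverage per node.  Serialization uses nested node objects so
saved models can be explained without the training backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TreeStructure:
    children_left: np.ndarray  # int, -1 for leaves
    children_right: np.ndarray
    feature: np.ndarray  # int split feature, -2 for leaves
    threshold: np.ndarray  # float
    value: np.ndarray  # float leaf/internal mean response
    cover: np.ndarray  # float weighted training samples per node

    LEAF = -1

    def __post_init__(self):
        self.children_left = np.asarray(self.children_left, dtype=np.int64)
        self.children_right = np.asarray(self.children_right, dtype=np.int64)
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.cover = np.asarray(self.cover, dtype=np.float64)

    @property
    def n_nodes(self) -> int:
        return self.children_left.size

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] == self.LEAF

    @property
    def max_depth(self) -> int:
        depth = np.zeros(self.n_nodes, dtype=int)
        out = 0
        for node in range(self.n_nodes):  # parents precede children in sklearn order
            if not self.is_leaf(node):
                for child in (self.children_left[node], self.children_right[node]):
                    depth[child] = depth[node] + 1
                    out = max(out, depth[child])
        return out

    @classmethod
    def from_sklearn(cls, tree) -> "TreeStructure":
        t = tree.tree_
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=t.value[:, 0, 0].copy(),
            cover=t.weighted_n_node_samples.copy(),
        )

    def predict_one(self, x: np.ndarray) -> float:
        node = 0
        while not self.is_leaf(node):
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.children_left[node]
            else:
                node = self.children_right[node]
        return float(self.value[node])

    def expected_value(self) -> float:
        """Cover-weighted mean over leaves (model output with no features known)."""
        leaves = self.children_left == self.LEAF
        return float(self.value[leaves] @ self.cover[leaves] / self.cover[0])

    # -- nested-node JSON ---------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(i: int) -> dict:
            if self.is_leaf(i):
                return {"value": float(self.value[i]), "cover": float(self.cover[i])}
            return {
                "feature": int(self.feature[i]),
                "threshold": float(self.threshold[i]),
                "value": float(self.value[i]),
                "cover": float(self.cover[i]),
                "left": node_dict(int(self.children_left[i])),
                "right": node_dict(int(self.children_right[i])),
            }

        return node_dict(0)

    @classmethod
    def from_dict(cls, root: dict) -> "TreeStructure":
        cl, cr, feat, thr, val, cov = [], [], [], [], [], []

        def add(node: dict) -> int:
            i = len(cl)
            for arr in (cl, cr, feat, thr, val, cov):
                arr.append(0)
            feat[i] = node.get("feature", -2)
            thr[i] = node.get("threshold", 0.0)
            val[i] = node["value"]
            cov[i] = node["cover"]
            if "left" in node:
                cl[i] = add(node["left"])
                cr[i] = add(node["right"])
            else:
                cl[i] = cr[i] = cls.LEAF
            return i

        add(root)
        return cls(cl, cr, feat, thr, val, cov)
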