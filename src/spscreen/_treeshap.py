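"""Polynomial-time path-dependent Shapley attribution for regression trees.

The kernel walks every root-to-leaf path while maintaining the path of
unique split features together with the fraction of "zero" (feature absent:
cover-weighted both-branch flow) and "one" (feature present: follow x) paths
that reach the current node, extending/unwinding the permutation-weight
recurrence at each step.  Node training coverage provides the background
weighting, so the no-feature baseline is the cover-weighted leaf mean.

The same kernel, run with a feature conditioned "present" or "absent",
yields the conditional attributions that pairwise interaction values are
assembled from.

Written to compile under numba; falls back to pure Python when numba is
unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

COND_NONE = 0
COND_PRESENT = 1
COND_ABSENT = 2
_SKIP = -10


@njit(cache=True)
def _tree_shap_kernel(  # pragma: no cover - exercised via TreeExplainer
    children_left,
    children_right,
    feature,
    threshold,
    value,
    cover,
    x,
    phi,
    condition,
    cond_feature,
    max_depth,
):
    stride = max_depth + 2
    nlev = max_depth + 2
    pdx = np.empty(nlev * stride, dtype=np.int64)
    pzb = np.empty(nlev * stride, dtype=np.float64)
    pob = np.empty(nlev * stride, dtype=np.float64)
    pwb = np.empty(nlev * stride, dtype=np.float64)

    cap = 4 * (max_depth + 2) + 4
    st_node = np.empty(cap, dtype=np.int64)
    st_depth = np.empty(cap, dtype=np.int64)
    st_plen = np.empty(cap, dtype=np.int64)
    st_pf = np.empty(cap, dtype=np.int64)
    st_pz = np.empty(cap, dtype=np.float64)
    st_po = np.empty(cap, dtype=np.float64)
    st_q = np.empty(cap, dtype=np.float64)

    top = 0
    st_node[top] = 0
    st_depth[top] = 0
    st_plen[top] = 0
    st_pf[top] = -1  # dummy path element at the root
    st_pz[top] = 1.0
    st_po[top] = 1.0
    st_q[top] = 1.0
    top += 1

    while top > 0:
        top -= 1
        node = st_node[top]
        depth = st_depth[top]
        plen = st_plen[top]
        pf = st_pf[top]
        pz = st_pz[top]
        po = st_po[top]
        q = st_q[top]

        base = depth * stride
        if depth > 0:
            pbase = (depth - 1) * stride
            for t in range(plen):
                pdx[base + t] = pdx[pbase + t]
                pzb[base + t] = pzb[pbase + t]
                pob[base + t] = pob[pbase + t]
                pwb[base + t] = pwb[pbase + t]

        if pf != _SKIP:
            # EXTEND the path with the pending (feature, fractions)
            l = plen
            pdx[base + l] = pf
            pzb[base + l] = pz
            pob[base + l] = po
            pwb[base + l] = 1.0 if l == 0 else 0.0
            for i in range(l - 1, -1, -1):
                pwb[base + i + 1] += po * pwb[base + i] * (i + 1.0) / (l + 1.0)
                pwb[base + i] = pz * pwb[base + i] * (l - i) / (l + 1.0)
            plen = l + 1

        if children_left[node] < 0:
            # leaf: credit every real path element
            leaf_value = value[node]
            for i in range(1, plen):
                one = pob[base + i]
                zero = pzb[base + i]
                total = 0.0
                n_ = pwb[base + plen - 1]
                for jj in range(plen - 2, -1, -1):
                    if one != 0.0:
                        t_ = n_ * plen / ((jj + 1.0) * one)
                        total += t_
                        n_ = pwb[base + jj] - t_ * zero * (plen - 1.0 - jj) / plen
                    else:
                        total += pwb[base + jj] * plen / (zero * (plen - 1.0 - jj))
                phi[pdx[base + i]] += total * (one - zero) * leaf_value * q
            continue

        d = feature[node]
        if x[d] <= threshold[node]:
            hot, cold = children_left[node], children_right[node]
        else:
            hot, cold = children_right[node], children_left[node]
        rj = cover[node]

        if condition != COND_NONE and d == cond_feature:
            if condition == COND_PRESENT:
                st_node[top] = hot
                st_depth[top] = depth + 1
                st_plen[top] = plen
                st_pf[top] = _SKIP
                st_q[top] = q
                top += 1
            else:
                st_node[top] = cold
                st_depth[top] = depth + 1
                st_plen[top] = plen
                st_pf[top] = _SKIP
                st_q[top] = q * cover[cold] / rj
                top += 1
                st_node[top] = hot
                st_depth[top] = depth + 1
                st_plen[top] = plen
                st_pf[top] = _SKIP
                st_q[top] = q * cover[hot] / rj
                top += 1
            continue

        iz = 1.0
        io = 1.0
        k = -1
        for t in range(1, plen):
            if pdx[base + t] == d:
                k = t
                break
        if k >= 0:
            # feature already on the path: UNWIND its element first
            iz = pzb[base + k]
            io = pob[base + k]
            n_ = pwb[base + plen - 1]
            for jj in range(plen - 2, -1, -1):
                if io != 0.0:
                    t_ = pwb[base + jj]
                    pwb[base + jj] = n_ * plen / ((jj + 1.0) * io)
                    n_ = t_ - pwb[base + jj] * iz * (plen - 1.0 - jj) / plen
                else:
                    pwb[base + jj] = pwb[base + jj] * plen / (iz * (plen - 1.0 - jj))
            for jj in range(k, plen - 1):
                pdx[base + jj] = pdx[base + jj + 1]
                pzb[base + jj] = pzb[base + jj + 1]
                pob[base + jj] = pob[base + jj + 1]
            plen -= 1

        st_node[top] = cold
        st_depth[top] = depth + 1
        st_plen[top] = plen
        st_pf[top] = d
        st_pz[top] = iz * cover[cold] / rj
        st_po[top] = 0.0
        st_q[top] = q
        top += 1
        st_node[top] = hot
        st_depth[top] = depth + 1
        st_plen[top] = plen
        st_pf[top] = d
        st_pz[top] = iz * cover[hot] / rj
        st_po[top] = io
        st_q[top] = q
        top += 1


def tree_shap(
    tree,
    x: np.ndarray,
    n_features: int,
    condition: int = COND_NONE,
    cond_feature: int = -1,
) -> np.ndarray:
    """Attributions of one tree's prediction for input ``x``."""
    phi = np.zeros(n_features, dtype=np.float64)
    _tree_shap_kernel(
        tree.children_left,
        tree.children_right,
        tree.feature,
        tree.threshold,
        tree.value,
        tree.cover,
        np.asarray(x, dtype=np.float64),
        phi,
        condition,
        cond_feature,
        max(tree.max_depth, 1),
    )
    return phi
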