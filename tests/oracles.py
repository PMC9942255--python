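"""Independent brute-force oracles used only by the tests.

Each implementation deliberately avoids the package's algorithms: folding by
exhaustive enumeration of nested pairings, KS by evaluating both ECDFs on the
pooled support, Kennard-Stone by direct max-min recomputation, pI by grid
search on the closed-form charge equation, affinity propagation by exemplar-
subset enumeration of the net-similarity objective.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def nussinov_enumerate(seq: str, min_loop: int = 3) -> int:
    """Maximum nested base pairs by exhaustive recursion (tiny inputs)."""
    seq = seq.upper().replace("T", "U")

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        out = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                out = max(out, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return out

    return best(0, len(seq) - 1)


def ks_statistic_enumerate(a, b) -> float:
    """sup |ECDF_a - ECDF_b| evaluated at every pooled sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    points = np.unique(np.concatenate([a, b]))
    d = 0.0
    for t in points:
        d = max(d, abs((a <= t).mean() - (b <= t).mean()))
    return d


def kennard_stone_bruteforce(X: np.ndarray, n_train: int) -> list[int]:
    """Greedy max-min selection recomputed from scratch at every step.

    Distances on z-scored columns; seed pair = maximal distance with lowest
    flat (i, j) tie-break; growth step ties resolve to the lowest index.
    """
    X = np.asarray(X, float)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    n = len(Z)

    def dist(i, j):
        return float(np.linalg.norm(Z[i] - Z[j]))

    best_pair, best_d = None, -1.0
    for i in range(n):
        for j in range(i + 1, n):
            if dist(i, j) > best_d:
                best_pair, best_d = (i, j), dist(i, j)
    selected = list(best_pair)
    while len(selected) < n_train:
        best_idx, best_min = None, -1.0
        for cand in range(n):
            if cand in selected:
                continue
            m = min(dist(cand, s) for s in selected)
            if m > best_min:
                best_idx, best_min = cand, m
        selected.append(best_idx)
    return selected


def pi_grid_search(seq: str, pka: dict[str, float], step: float = 1e-4) -> float:
    """pH minimizing |net charge| on a dense grid (closed-form charge)."""
    grid = np.arange(0.0, 14.0 + step, step)
    pos = 1.0 / (1.0 + 10 ** (grid - pka["Nterm"]))
    neg = -1.0 / (1.0 + 10 ** (pka["Cterm"] - grid))
    charge = pos + neg
    for aa in "KRH":
        if aa in pka:
            charge = charge + seq.count(aa) / (1.0 + 10 ** (grid - pka[aa]))
    for aa in "DECY":
        if aa in pka:
            charge = charge - seq.count(aa) / (1.0 + 10 ** (pka[aa] - grid))
    return float(grid[np.abs(charge).argmin()])


def affinity_propagation_bruteforce(S: np.ndarray) -> tuple[int, ...]:
    """Exemplar subset maximizing net similarity (preference on diagonal)."""
    n = S.shape[0]
    best_set, best_score = None, -np.inf
    for k in range(1, n + 1):
        for subset in combinations(range(n), k):
            score = sum(S[i, i] for i in subset)
            score += sum(
                max(S[i, j] for j in subset) for i in range(n) if i not in subset
            )
            if score > best_score:
                best_set, best_score = subset, score
    return best_set
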