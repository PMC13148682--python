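"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: shortest paths are found
by exhaustive simple-path enumeration, clustering by explicit neighbour
counting, and the ICC by literal sums-of-squares loops.  They are only
feasible on tiny inputs, which is the point.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def enumerate_simple_paths(adj: np.ndarray, s: int, t: int):
    """All simple paths from s to t on a boolean adjacency matrix."""
    n = adj.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[last, nxt] and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_distances_and_counts(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hop distances and shortest-path counts via path enumeration."""
    n = adj.shape[0]
    D = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = enumerate_simple_paths(adj, s, t)
            if not paths:
                continue
            lengths = [len(p) - 1 for p in paths]
            d = min(lengths)
            D[s, t] = d
            sigma[s, t] = sum(1 for ln in lengths if ln == d)
    return D, sigma


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Normalised betweenness by counting shortest paths through each node."""
    n = adj.shape[0]
    B = np.zeros(n)
    if n < 3:
        return B
    for v in range(n):
        total = 0.0
        for s, t in itertools.combinations(range(n), 2):
            if v in (s, t):
                continue
            paths = enumerate_simple_paths(adj, s, t)
            if not paths:
                continue
            d = min(len(p) - 1 for p in paths)
            shortest = [p for p in paths if len(p) - 1 == d]
            through = sum(1 for p in shortest if v in p[1:-1])
            total += through / len(shortest)
        B[v] = total / (math.comb(n - 1, 2))
    return B


def brute_clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = [u for u in range(n) if adj[v, u]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out[v] = links / math.comb(k, 2)
    return out


def brute_global_efficiency(adj: np.ndarray) -> float:
    D, _ = brute_distances_and_counts(adj)
    n = adj.shape[0]
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        vals.append(0.0 if math.isinf(D[i, j]) else 1.0 / D[i, j])
    return float(np.mean(vals))


def brute_mean_shortest_path(adj: np.ndarray) -> tuple[float, int]:
    D, _ = brute_distances_and_counts(adj)
    n = adj.shape[0]
    finite, excluded = [], 0
    for i, j in itertools.combinations(range(n), 2):
        if math.isinf(D[i, j]):
            excluded += 1
        else:
            finite.append(D[i, j])
    return (float(np.mean(finite)) if finite else 0.0), excluded


def anova_icc31(X: np.ndarray) -> tuple[float, float, float, float]:
    """ICC(3,1) by literal two-way sums of squares.

    Returns (icc_raw, MSp, MS_sessions, MSe).
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    grand = X.mean()
    ss_subj = 0.0
    for i in range(n):
        ss_subj += d * (X[i].mean() - grand) ** 2
    ss_sess = 0.0
    for j in range(d):
        ss_sess += n * (X[:, j].mean() - grand) ** 2
    ss_total = float(((X - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_sess
    msp = ss_subj / (n - 1)
    mss = ss_sess / (d - 1)
    mse = ss_err / ((n - 1) * (d - 1))
    denom = msp + (d - 1) * mse
    icc_raw = 0.0 if denom == 0 else (msp - mse) / denom
    return icc_raw, msp, mss, mse


def bh_stepup(p: list[float]) -> list[float]:
    """Hand Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q
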