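"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimised code paths: partitions are
enumerated exhaustively, statistics are recomputed from first principles.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def set_partitions(n: int):
    """Yield every partition of range(n) as a restricted-growth string."""
    a = [0] * n
    b = [0] * n
    while True:
        yield list(a)
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[j - 1]


def modularity_from_edges(edges, degrees, L, assign):
    """M = Σ_s [l_s/L − (d_s/2L)²] computed directly from an edge list."""
    n_mod = max(assign) + 1
    l = [0] * n_mod
    d = [0.0] * n_mod
    for u, v in edges:
        if assign[u] == assign[v]:
            l[assign[u]] += 1
    for u, k in enumerate(degrees):
        d[assign[u]] += k
    return sum(l[s] / L - (d[s] / (2.0 * L)) ** 2 for s in range(n_mod))


def exhaustive_best_partition(incidence: np.ndarray) -> tuple[float, list[int]]:
    """Maximum modularity over ALL joint partitions (species + OTU nodes)."""
    S, O = incidence.shape
    n = S + O
    edges = [(r, S + c) for r, c in zip(*np.nonzero(incidence))]
    L = len(edges)
    degrees = list(np.concatenate([incidence.sum(1), incidence.sum(0)]))
    best, best_p = -np.inf, None
    for p in set_partitions(n):
        m = modularity_from_edges(edges, degrees, L, p)
        if m > best:
            best, best_p = m, list(p)
    return best, best_p


def random_pruned_incidence(rng, max_nodes: int = 10, p: float = 0.45) -> np.ndarray:
    """Random bipartite incidence with no isolated nodes, ≤ max_nodes total."""
    while True:
        S = int(rng.integers(2, 5))
        O = int(rng.integers(2, max(3, max_nodes - S + 1)))
        if S + O > max_nodes:
            continue
        inc = (rng.random((S, O)) < p).astype(np.int8)
        inc = inc[inc.sum(axis=1) > 0][:, inc.sum(axis=0) > 0]
        if inc.shape[0] >= 2 and inc.shape[1] >= 2:
            return inc


def brute_force_indval(counts: np.ndarray, labels: list[str], target: set[str]):
    """Per-OTU (A, B) for one habitat union, from the formula definition.

    ``counts`` are site × OTU abundances already on the intended basis.
    """
    habitats = sorted(set(labels))
    out = []
    for j in range(counts.shape[1]):
        x = counts[:, j]
        means = {
            h: np.mean([x[i] for i, g in enumerate(labels) if g == h]) for h in habitats
        }
        target_sites = [i for i, g in enumerate(labels) if g in target]
        mean_t = np.mean(x[target_sites])
        denom = mean_t + sum(means[h] for h in habitats if h not in target)
        A = mean_t / denom if denom > 0 else np.nan
        B = np.mean(x[target_sites] > 0)
        out.append((A, B))
    return out


def all_unions(habitats, max_order):
    return [
        frozenset(c)
        for r in range(1, max_order + 1)
        for c in combinations(sorted(habitats), r)
    ]
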