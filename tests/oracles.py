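"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (literal loops, no vectorization,
no shared code with the package) so that agreement with the package is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from cernapipe.datatypes import ExpressionDataset, InteractionDB, RNAClass


# ---------------------------------------------------------------------------
# brute-force primary-network enumeration
# ---------------------------------------------------------------------------

def brute_force_primary_edges(
    dataset: ExpressionDataset,
    db: InteractionDB,
    corr_threshold: float = 0.4,
    p_threshold: float = 0.05,
) -> dict[tuple[str, str], set[str]]:
    """Enumerate every (sponge pair, miRNA) combination and apply the
    triplet rules literally.  Returns edge -> supporting miRNA set."""
    genes = dataset.genes
    x = {g: dataset.values.loc[g].to_numpy(dtype=float) for g in genes}
    usable = [g for g in genes if np.ptp(x[g]) > 0]
    cls = dataset.classes

    def ok_neg(a, b):
        r, p = stats.pearsonr(x[a], x[b])
        return r < -corr_threshold and p < p_threshold

    def ok_pos(a, b):
        r, p = stats.pearsonr(x[a], x[b])
        return r > corr_threshold and p < p_threshold

    mirnas = [g for g in usable if cls[g] == RNAClass.MIRNA]
    sponges = [g for g in usable if cls[g] != RNAClass.MIRNA]
    edges: dict[tuple[str, str], set[str]] = {}
    for i, u in enumerate(sponges):
        for v in sponges[i + 1:]:
            cu, cv = cls[u], cls[v]
            pair = tuple(sorted((u, v)))
            circ_involved = RNAClass.CIRCRNA in (cu, cv)
            for t in mirnas:
                if circ_involved:
                    route_ok = True                      # correlation-only route
                else:
                    route_ok = (t, u) in db.pairs and (t, v) in db.pairs
                if route_ok and ok_neg(t, u) and ok_neg(t, v) and ok_pos(u, v):
                    edges.setdefault(pair, set()).add(t)
    return edges


# ---------------------------------------------------------------------------
# reference MCL (independent coding of the canonical algorithm)
# ---------------------------------------------------------------------------

def reference_mcl_partition(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> set[frozenset[int]]:
    """Canonical MCL on a symmetric weighted adjacency with max-weight
    self-loops; clusters read as groups of columns sharing attractor rows."""
    a = np.array(adjacency, dtype=float)
    n = a.shape[0]
    for i in range(n):
        col_max = max(a[:, i].max(), 0.0)
        a[i, i] = col_max if col_max > 0 else 1.0
    m = np.empty_like(a)
    for j in range(n):
        m[:, j] = a[:, j] / a[:, j].sum()
    for _ in range(max_iter):
        prev = m.copy()
        # expansion: repeated matrix product
        e = m.copy()
        for _ in range(expansion - 1):
            e = e @ m
        m = e ** inflation
        m[m < prune] = 0.0
        for j in range(n):
            s = m[:, j].sum()
            if s > 0:
                m[:, j] /= s
        if np.max(np.abs(m - prev)) < tol:
            break
    # cluster readout: columns i, j belong together when some attractor row
    # gives mass to both
    attractors = [i for i in range(n) if m[i, i] > prune]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in attractors:
        members = [j for j in range(n) if m[i, j] > prune]
        for j in members:
            union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# naive BH and exact hypergeometric tail
# ---------------------------------------------------------------------------

def naive_bh(pvalues) -> list[float]:
    """O(m^2) Benjamini-Hochberg step-up straight from the definition."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = min(running_min, 1.0)
    return adj


def exact_hypergeom_upper_tail(k: int, big_n: int, big_k: int, n: int) -> float:
    """P[X >= k] by direct combinatorial enumeration of overlap outcomes."""
    denom = math.comb(big_n, n)
    total = 0
    for kk in range(k, min(n, big_k) + 1):
        if n - kk > big_n - big_k:
            continue
        total += math.comb(big_k, kk) * math.comb(big_n - big_k, n - kk)
    return total / denom
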