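"""Gene-set over-representation for modules: hypergeometric upper tail + BH."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneSetCollection


@dataclass
class EnrichmentResult:
    module_id: str
    set_name: str
    k: int          # overlap
    n: int          # module size (within universe)
    K: int          # set size (within universe)
    N: int          # universe size
    p: float
    fdr: float = np.nan


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_enrich(
    modules: dict[str, list[str]],
    sets: GeneSetCollection,
    universe: list[str],
) -> list[EnrichmentResult]:
    """Over-representation of each (module, gene set) pair.

    p = P[X >= k] for X ~ Hypergeometric(N, K, n); gene sets are intersected
    with the universe before testing; BH correction spans all

    (module, set) tests; results are sorted by FDR then by ids.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    for mid, genes in modules.items():
        off = sorted(set(genes) - uni)
        if off:
            raise ValueError(f"module {mid!r} not contained in universe: {off}")
    results: list[EnrichmentResult] = []
    big_n = len(uni)
    for mid in sorted(modules):
        mod = set(modules[mid])
        for name in sorted(sets.sets):
            members = set(sets.sets[name][1]) & uni
            if not members:
                continue
            k = len(mod & members)
            p = float(stats.hypergeom.sf(k - 1, big_n, len(members), len(mod)))
            results.append(EnrichmentResult(
                module_id=mid, set_name=name, k=k, n=len(mod), K=len(members),
                N=big_n, p=min(p, 1.0)))
    if results:
        fdrs = bh_adjust([r.p for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return sorted(results, key=lambda r: (r.fdr, r.module_id, r.set_name))


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.module_id, r.set_name, r.k, r.n, r.K, r.N, r.p, r.fdr) for r in results],
        columns=["module", "gene_set", "overlap", "module_size", "set_size",
                 "universe_size", "p", "fdr"])
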