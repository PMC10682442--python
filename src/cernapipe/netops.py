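"""Common/specific network algebra, Markov clustering, module filtering.

The *common* network is the node and edge intersection across all
subtypes' primary networks; each subtype's *specific* network is its
primary network minus the common edges.  Specific networks are clustered
with the Markov cluster algorithm (MCL) and only modules containing at
least one lncRNA or circRNA are retained for downstream biomarker work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .datatypes import RNAClass
from .network import CeRNANetwork

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# set algebra on networks
# ---------------------------------------------------------------------------

def common_network(primaries: dict[str, CeRNANetwork]) -> CeRNANetwork:
    """Intersection network: shared nodes, shared edges (weight = mean of the
    per-subtype weights; supporting miRNAs = union).  May contain isolated
    nodes - a node common to every subtype whose edges are not."""
    if len(primaries) < 2:
        raise ValueError("common network needs >= 2 primary networks")
    nets = list(primaries.values())
    nodes = reduce(set.__and__, (n.node_set() for n in nets))
    edges = reduce(set.__and__, (n.edge_set() for n in nets))
    out = CeRNANetwork(tag="common")
    ref = nets[0]
    for n in sorted(nodes):
        out.add_node(n, ref.node_class(n))
    for a, b in sorted(edges):
        weights = [net.graph.edges[a, b]["weight"] for net in nets]
        mirnas: set[str] = set()
        for net in nets:
            mirnas.update(net.graph.edges[a, b]["supporting_mirnas"])
        out.add_edge(a, b, ref.node_class(a), ref.node_class(b),
                     float(np.mean(weights)), tuple(sorted(mirnas)),
                     ref.graph.edges[a, b]["evidence"])
    return out


def specific_network(primary: CeRNANetwork, common: CeRNANetwork) -> CeRNANetwork:
    """Primary minus common (edge difference); nodes are the endpoints of the
    surviving edges.  The naive node-set difference |N^C - N^common| is kept
    as graph attribute ``node_difference_count`` for reporting."""
    out = CeRNANetwork(tag=primary.tag)
    common_edges = common.edge_set()
    for a, b in sorted(primary.edge_set() - common_edges):
        d = primary.graph.edges[a, b]
        out.add_edge(a, b, primary.node_class(a), primary.node_class(b),
                     d["weight"], d["supporting_mirnas"], d["evidence"])
    out.graph.graph["node_difference_count"] = len(primary.node_set() - common.node_set())
    return out


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

@dataclass
class MCLConfig:
    inflation: float = 2.0
    expansion: int = 2
    self_loop: str = "max-weight"     # max-weight | unit
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-8

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.self_loop not in ("max-weight", "unit"):
            raise ValueError(f"unknown self_loop mode {self.self_loop!r}")


@dataclass
class ModuleSet:
    """Disjoint modules of one specific network, flagged by contained classes."""

    tag: str
    modules: list[tuple[str, ...]]
    source: CeRNANetwork
    converged: bool = True

    def __post_init__(self) -> None:
        seen: set[str] = set()
        nodes = self.source.node_set()
        for mod in self.modules:
            if seen & set(mod):
                raise ValueError("modules must be disjoint")
            if not set(mod) <= nodes:
                raise ValueError("module node outside the source network")
            seen.update(mod)

    def flags(self, module: tuple[str, ...]) -> dict[str, bool]:
        classes = {self.source.node_class(g) for g in module}
        return {"contains_lncRNA": RNAClass.LNCRNA in classes,
                "contains_circRNA": RNAClass.CIRCRNA in classes}

    def __len__(self) -> int:
        return len(self.modules)

    def all_genes(self) -> set[str]:
        return {g for mod in self.modules for g in mod}

    def genes_of_class(self, rna_class: RNAClass) -> set[str]:
        return {g for g in self.all_genes() if self.source.node_class(g) == rna_class}


def mcl_matrix(m: np.ndarray, config: MCLConfig) -> tuple[np.ndarray, bool]:
    """Run MCL iterations on a column-stochastic matrix; returns the limit
    matrix and a convergence flag."""
    for _ in range(config.max_iterations):
        prev = m
        m = np.linalg.matrix_power(m, config.expansion)
        m = m ** config.inflation
        m[m < config.prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m = m / colsum
        if np.abs(m - prev).max() < config.convergence_tol:
            return m, True
    return m, False


def mcl_cluster(network: CeRNANetwork, config: MCLConfig | None = None) -> ModuleSet:
    """Cluster a network with MCL.

    The weighted adjacency (plus self-loops) is column-normalized and
    iterated through expansion (matrix power) and inflation (entry-wise
    power + renormalization) with pruning until the matrix is stable.
    Clusters are read from the attractor structure; every node joins
    exactly one module (highest attraction wins, ties go to the
    lexicographically first attractor).  Nodes are processed in sorted
    order, so the result is invariant to input node order.
    """
    config = config or MCLConfig()
    config.validate()
    nodes = sorted(network.node_set())
    if not nodes:
        raise ValueError("cannot cluster an empty network")
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in network.edge_set():
        w = float(network.graph.edges[u, v]["weight"])
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    if config.self_loop == "max-weight":
        diag = np.where(a.max(axis=0) > 0, a.max(axis=0), 1.0)
    else:
        diag = np.ones(n)
    a[np.diag_indices(n)] = diag
    m = a / a.sum(axis=0, keepdims=True)
    m, converged = mcl_matrix(m, config)
    if not converged:
        log.warning("MCL did not converge within %d iterations", config.max_iterations)

    eps = config.prune_threshold
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:  # pragma: no cover - degenerate fallback
        attractors = list(range(n))
    # attractor systems: attractors mutually reachable in the limit matrix
    parent = list(range(len(attractors)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai, i in enumerate(attractors):
        for aj, j in enumerate(attractors[ai + 1:], start=ai + 1):
            if m[i, j] > eps or m[j, i] > eps:
                ri, rj = find(ai), find(aj)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    att_rows = m[np.array(attractors), :]
    assign = np.argmax(att_rows, axis=0)       # first (lexicographic) max wins
    groups: dict[int, list[str]] = {}
    for col, arow in enumerate(assign):
        groups.setdefault(find(int(arow)), []).append(nodes[col])
    modules = sorted(tuple(sorted(g)) for g in groups.values())
    return ModuleSet(tag=network.tag, modules=modules, source=network, converged=converged)


def filter_lc_modules(modules: ModuleSet) -> ModuleSet:
    """Keep modules containing at least one lncRNA or circRNA member."""
    kept = [mod for mod in modules.modules
            if any(modules.source.node_class(g) in (RNAClass.LNCRNA, RNAClass.CIRCRNA)
                   for g in mod)]
    return ModuleSet(tag=modules.tag, modules=kept, source=modules.source,
                     converged=modules.converged)
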