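"""The ceRNA network container.

Nodes are mRNA/lncRNA/circRNA genes; an undirected edge records the
positive co-expression of two sponges together with the miRNAs whose
anti-correlation supports the competing-endogenous-RNA interpretation.
miRNAs themselves are never nodes - they are edge evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .datatypes import RNAClass

#: evidence levels an edge can carry
DB_VALIDATED = "db-validated"
CORRELATION_ONLY = "correlation-only"


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class CeRNANetwork:
    """A typed, weighted, undirected ceRNA network.

    ``tag`` is the subtype label for primary/specific networks or
    ``"common"`` for the cross-subtype intersection.  The underlying
    ``networkx.Graph`` stores node attribute ``rna_class`` and edge
    attributes ``weight`` (Pearson r of the two sponges),
    ``supporting_mirnas`` (sorted tuple) and ``evidence``.
    """

    tag: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, gene: str, rna_class: RNAClass) -> None:
        if rna_class == RNAClass.MIRNA:
            raise ValueError("miRNAs cannot be network nodes")
        self.graph.add_node(gene, rna_class=RNAClass(rna_class))

    def add_edge(
        self,
        a: str,
        b: str,
        class_a: RNAClass,
        class_b: RNAClass,
        weight: float,
        supporting_mirnas: tuple[str, ...],
        evidence: str,
    ) -> None:
        if not supporting_mirnas:
            raise ValueError(f"edge {a!r}-{b!r} has no supporting miRNAs")
        if evidence not in (DB_VALIDATED, CORRELATION_ONLY):
            raise ValueError(f"unknown evidence level {evidence!r}")
        self.add_node(a, class_a)
        self.add_node(b, class_b)
        self.graph.add_edge(
            a, b,
            weight=float(weight),
            supporting_mirnas=tuple(sorted(supporting_mirnas)),
            evidence=evidence,
        )

    # -- views -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str]]:
        return {edge_key(a, b) for a, b in self.graph.edges}

    def node_class(self, gene: str) -> RNAClass:
        return RNAClass(self.graph.nodes[gene]["rna_class"])

    def remove_isolated_nodes(self) -> list[str]:
        isolated = [n for n in self.graph.nodes if self.graph.degree(n) == 0]
        self.graph.remove_nodes_from(isolated)
        return isolated

    def edge_records(self) -> list[dict]:
        """Edge table rows, deterministically ordered."""
        rows = []
        for a, b in sorted(self.edge_set()):
            d = self.graph.edges[a, b]
            rows.append({
                "node_a": a,
                "node_b": b,
                "class_a": str(self.node_class(a)),
                "class_b": str(self.node_class(b)),
                "weight": d["weight"],
                "evidence": d["evidence"],
                "supporting_mirnas": ",".join(d["supporting_mirnas"]),
            })
        return rows
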