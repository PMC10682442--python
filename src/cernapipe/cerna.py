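"""Primary ceRNA network inference from one subtype's expression matrix.

An edge between two sponge RNAs (mRNA/lncRNA/circRNA) is called when the
pair is positively correlated and at least one miRNA is negatively
correlated with both — the competing-endogenous-RNA signature.  Two
routes exist:

* **db route** (mRNA/lncRNA pairs): the mediating miRNA must also have
  an experimentally supported interaction with *both* endpoints.
* **correlation-only route** (pairs involving a circRNA): no database
  evidence exists for circRNAs, so any miRNA satisfying the correlation
  pattern may mediate.

All correlation thresholds are strict: |r| must exceed ``corr_threshold``
and the two-sided p-value must be below ``p_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ExpressionDataset, InteractionDB, RNAClass, SPONGE_CLASSES
from .network import CORRELATION_ONLY, DB_VALIDATED, CeRNANetwork

log = logging.getLogger(__name__)


@dataclass
class InferenceConfig:
    corr_threshold: float = 0.4
    p_threshold: float = 0.05

    def validate(self) -> None:
        if not (0 < self.corr_threshold < 1):
            raise ValueError("corr_threshold must be in (0, 1)")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float
    p: float
    n: int


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with the two-sided Student-t p-value.

    ``t = r * sqrt((n-2) / (1-r^2))`` against t(n-2); |r| = 1 gives p = 0.
    Constant input is a degenerate-input error (the caller excludes such
    genes from inference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def correlation_matrices(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p over rows of *values*.

    Rows must be non-constant (the caller filters).  Vectorized version of
    :func:`pearson_with_p`; identical formulas.
    """
    n = values.shape[1]
    xc = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc ** 2).sum(axis=1))
    r = (xc @ xc.T) / np.outer(norms, norms)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    return r, np.minimum(p, 1.0)


def _usable_rows(dataset: ExpressionDataset) -> tuple[list[str], np.ndarray]:
    """Gene list excluding within-subtype constant genes (logged), plus values."""
    arr = dataset.values.to_numpy()
    constant = np.ptp(arr, axis=1) == 0
    if constant.any():
        dropped = [g for g, c in zip(dataset.genes, constant) if c]
        log.warning("%s: excluding %d constant gene(s) from inference: %s",
                    dataset.subtype, len(dropped), dropped[:5])
    genes = [g for g, c in zip(dataset.genes, constant) if not c]
    return genes, arr[~constant]


class _Screen:
    """Shared correlation screen over one subtype's usable genes."""

    def __init__(self, dataset: ExpressionDataset, config: InferenceConfig):
        config.validate()
        if len(dataset.samples) < 3:
            raise ValueError("need at least 3 samples for correlation inference")
        self.genes, values = _usable_rows(dataset)
        self.pos = {g: i for i, g in enumerate(self.genes)}
        self.classes = dataset.classes
        self.r, self.p = correlation_matrices(values)
        self.neg_ok = (self.r < -config.corr_threshold) & (self.p < config.p_threshold)
        self.pos_ok = (self.r > config.corr_threshold) & (self.p < config.p_threshold)
        self.mirnas = [g for g in self.genes if self.classes[g] == RNAClass.MIRNA]

    def of_class(self, *rna_classes: RNAClass) -> list[str]:
        return [g for g in self.genes if self.classes[g] in rna_classes]


def infer_db_edges(
    dataset: ExpressionDataset, db: InteractionDB, config: InferenceConfig | None = None,
    screen: _Screen | None = None,
) -> list[tuple]:
    """Edges among mRNA/lncRNA pairs sharing a database-supported miRNA.

    Returns tuples ``(a, b, weight, supporting_mirnas, evidence)``.
    """
    config = config or InferenceConfig()
    s = screen or _Screen(dataset, config)
    if not db.pairs:
        log.warning("empty interaction database: no db-validated edges possible")
        return []
    eligible = set(s.of_class(RNAClass.MRNA, RNAClass.LNCRNA))
    support: dict[tuple[str, str], list[str]] = {}
    for mirna, targets in sorted((m, ts) for m, ts in db.by_mirna().items()):
        if mirna not in s.pos:
            continue
        mi = s.pos[mirna]
        hits = sorted(t for t in targets if t in eligible and s.neg_ok[mi, s.pos[t]])
        for i, u in enumerate(hits):
            for v in hits[i + 1:]:
                if s.pos_ok[s.pos[u], s.pos[v]]:
                    support.setdefault((u, v) if u <= v else (v, u), []).append(mirna)
    return [(a, b, float(s.r[s.pos[a], s.pos[b]]), tuple(sorted(set(ms))), DB_VALIDATED)
            for (a, b), ms in sorted(support.items())]


def infer_corr_only_edges(
    dataset: ExpressionDataset, config: InferenceConfig | None = None,
    screen: _Screen | None = None,
) -> list[tuple]:
    """Edges for pairs involving a circRNA, mediated by any anti-correlated miRNA."""
    config = config or InferenceConfig()
    s = screen or _Screen(dataset, config)
    circ = s.of_class(RNAClass.CIRCRNA)
    others = s.of_class(RNAClass.MRNA, RNAClass.LNCRNA)
    if not circ or not s.mirnas:
        return []
    mir_idx = np.array([s.pos[m] for m in s.mirnas])
    edges = []
    pairs = [(u, v) for i, u in enumerate(circ) for v in circ[i + 1:]]
    pairs += [(u, v) for u in circ for v in others]
    for u, v in pairs:
        iu, iv = s.pos[u], s.pos[v]
        if not s.pos_ok[iu, iv]:
            continue
        mediators = s.neg_ok[mir_idx, iu] & s.neg_ok[mir_idx, iv]
        if mediators.any():
            supporting = tuple(sorted(s.mirnas[k] for k in np.flatnonzero(mediators)))
            a, b = (u, v) if u <= v else (v, u)
            edges.append((a, b, float(s.r[iu, iv]), supporting, CORRELATION_ONLY))
    return sorted(edges)


def build_primary_network(
    dataset: ExpressionDataset, db: InteractionDB, config: InferenceConfig | None = None,
) -> CeRNANetwork:
    """Per-subtype primary network: both inference routes, isolated nodes removed."""
    config = config or InferenceConfig()
    screen = _Screen(dataset, config)
    net = CeRNANetwork(tag=dataset.subtype)
    for g in screen.genes:
        if screen.classes[g] in SPONGE_CLASSES:
            net.add_node(g, screen.classes[g])
    for a, b, w, mirnas, evidence in (
            infer_db_edges(dataset, db, config, screen=screen)
            + infer_corr_only_edges(dataset, config, screen=screen)):
        net.add_edge(a, b, screen.classes[a], screen.classes[b], w, mirnas, evidence)
    net.remove_isolated_nodes()
    return net
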