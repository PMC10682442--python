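"""Cohort preprocessing: abundance filter, variance filter, outlier removal.

Gene filters pool samples across all subtypes (the cohort shares one gene
space, so a gene is kept or dropped everywhere at once).  Outliers are
detected per subtype by agglomerative clustering of samples; the tree is
cut at a robust height threshold, median + k * 1.4826*MAD of the merge
heights, and everything outside the largest cluster is discarded.  The
robust location/scale is deliberate: outlier samples join the tree at
extreme heights, which would inflate a mean/sd-based threshold and mask
exactly the merges the rule is meant to catch, while for homogeneous
cohorts the maximum of ~n merge heights routinely exceeds mean + 2*sd,
producing spurious removals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    mean_threshold: float = 0.5
    variance_threshold: float = 1e-8
    linkage_method: str = "average"            # average | complete | ward
    distance: str = "one-minus-pearson"        # one-minus-pearson | euclidean-on-log
    cut_k: float = 5.0             # h* = median(heights) + k * 1.4826*MAD(heights)

    def validate(self) -> None:
        if self.mean_threshold < 0 or self.variance_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.linkage_method not in ("average", "complete", "ward"):
            raise ValueError(f"unknown linkage {self.linkage_method!r}")
        if self.distance not in ("one-minus-pearson", "euclidean-on-log"):
            raise ValueError(f"unknown distance {self.distance!r}")


@dataclass
class PreprocessReport:
    genes_removed_mean: list[str] = field(default_factory=list)
    genes_removed_variance: list[str] = field(default_factory=list)
    samples_removed: dict[str, list[str]] = field(default_factory=dict)
    retained_genes: int = 0
    retained_samples: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("gene_removed_mean", "", g) for g in self.genes_removed_mean]
        rows += [("gene_removed_variance", "", g) for g in self.genes_removed_variance]
        for label, sams in self.samples_removed.items():
            rows += [("sample_removed", label, s) for s in sams]
        rows.append(("retained_genes", "", str(self.retained_genes)))
        for label, n in self.retained_samples.items():
            rows.append(("retained_samples", label, str(n)))
        return pd.DataFrame(rows, columns=["record", "subtype", "value"])


def _check_shared_genes(datasets: dict[str, ExpressionDataset]) -> list[str]:
    its = iter(datasets.values())
    genes = next(its).genes
    for ds in its:
        if ds.genes != genes:
            raise ValueError("subtype datasets do not share the same gene list")
    return genes


def _pooled(datasets: dict[str, ExpressionDataset]) -> np.ndarray:
    return np.concatenate([ds.values.to_numpy() for ds in datasets.values()], axis=1)


def filter_low_mean(
    datasets: dict[str, ExpressionDataset], threshold: float = 0.5
) -> tuple[dict[str, ExpressionDataset], list[str]]:
    """Drop genes whose mean over the pooled samples of all subtypes is < threshold."""
    genes = _check_shared_genes(datasets)
    means = _pooled(datasets).mean(axis=1)
    removed = [g for g, m in zip(genes, means) if m < threshold]
    keep = [g for g in genes if g not in set(removed)]
    return {lbl: ds.subset_genes(keep) for lbl, ds in datasets.items()}, removed


def filter_low_variance(
    datasets: dict[str, ExpressionDataset], threshold: float = 1e-8
) -> tuple[dict[str, ExpressionDataset], list[str]]:
    """Drop genes with pooled-sample (population) variance < threshold, plus
    exactly-constant genes at any threshold."""
    genes = _check_shared_genes(datasets)
    pooled = _pooled(datasets)
    var = pooled.var(axis=1)
    constant = (pooled == pooled[:, :1]).all(axis=1)
    removed = [g for g, v, c in zip(genes, var, constant) if v < threshold or c]
    keep = [g for g in genes if g not in set(removed)]
    return {lbl: ds.subset_genes(keep) for lbl, ds in datasets.items()}, removed


def _sample_distance(dataset: ExpressionDataset, distance: str) -> np.ndarray:
    logx = np.log1p(dataset.values.to_numpy())
    if distance == "one-minus-pearson":
        sd = logx.std(axis=0)
        if (sd == 0).any():
            bad = [dataset.samples[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance sample(s) under Pearson distance: {bad}")
        d = 1.0 - np.corrcoef(logx.T)
        np.fill_diagonal(d, 0.0)
        return np.clip((d + d.T) / 2.0, 0.0, None)
    # euclidean on log1p
    diff = logx.T[:, None, :] - logx.T[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


def merge_tree_newick(z: np.ndarray, labels: list[str]) -> str:
    """Nested-string (Newick) rendering of a scipy linkage matrix for audit."""
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, h, _) in enumerate(z):
        la, ha = nodes[int(a)]
        lb, hb = nodes[int(b)]
        nodes[n + i] = (f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})", h)
    return nodes[n + len(z) - 1][0] + ";"


def detect_outliers(
    dataset: ExpressionDataset, config: PreprocessConfig | None = None
) -> tuple[ExpressionDataset, list[str], np.ndarray]:
    """Remove samples outside the largest cluster after cutting the sample
    dendrogram at median + k*1.4826*MAD of the merge heights.

    Returns the retained dataset, the removed sample ids, and the scipy
    linkage matrix (the dendrogram merge tree).
    """
    config = config or PreprocessConfig()
    config.validate()
    n = len(dataset.samples)
    if n < 3:
        raise ValueError(f"outlier detection needs >= 3 samples, got {n}")
    dist = _sample_distance(dataset, config.distance)
    z = linkage(squareform(dist, checks=False), method=config.linkage_method)
    heights = z[:, 2]
    med = np.median(heights)
    mad = 1.4826 * np.median(np.abs(heights - med))
    h_star = med + config.cut_k * mad
    labels = fcluster(z, t=h_star, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    biggest = sizes.max()
    # deterministic tie-break: among largest clusters keep the one containing
    # the earliest sample
    candidates = set(sizes.index[sizes == biggest])
    keep_label = next(lab for lab in labels if lab in candidates)
    removed = [s for s, lab in zip(dataset.samples, labels) if lab != keep_label]
    kept = [s for s in dataset.samples if s not in set(removed)]
    if removed:
        log.info("%s: removed %d/%d samples as outliers", dataset.subtype, len(removed), n)
    return dataset.subset_samples(kept), removed, z


def preprocess(
    datasets: dict[str, ExpressionDataset], config: PreprocessConfig | None = None
) -> tuple[dict[str, ExpressionDataset], PreprocessReport, dict[str, np.ndarray]]:
    """Run all three stages in order; returns datasets, report and dendrograms."""
    config = config or PreprocessConfig()
    config.validate()
    report = PreprocessReport()
    datasets, report.genes_removed_mean = filter_low_mean(datasets, config.mean_threshold)
    datasets, report.genes_removed_variance = filter_low_variance(
        datasets, config.variance_threshold)
    trees: dict[str, np.ndarray] = {}
    out: dict[str, ExpressionDataset] = {}
    for label, ds in datasets.items():
        kept, removed, z = detect_outliers(ds, config)
        out[label] = kept
        report.samples_removed[label] = removed
        report.retained_samples[label] = len(kept.samples)
        trees[label] = z
    report.retained_genes = len(next(iter(out.values())).genes) if out else 0
    return out, report, trees
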