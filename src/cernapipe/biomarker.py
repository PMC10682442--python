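"""Between-subtype differential expression and biomarker validation.

Differential expression follows the classic count-based recipe: TMM
(trimmed mean of M-values) composition normalization, then a conditional
negative-binomial exact test per gene at a common dispersion.  A gene is
a biomarker of subtype C when it passes FDR < 0.05 and |log2FC| > 0.5
(strict) against *every* other subtype; the final set is validated with
an RBF-kernel SVM under stratified five-fold cross-validation (one
subtype versus the rest), reporting per-fold ROC/AUC.

The conditional exact test: per-sample counts are NB(mu, phi); at equal
effective library sizes a group total over n samples is NB with size
n/phi, and conditional on the two-group total the group-A total follows
a negative hypergeometric law that does not depend on mu.  With phi = 0
this reduces to the binomial conditional (exact Poisson) test.  The
two-sided p doubles the smaller tail (observed point included), capped
at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatypes import ExpressionDataset
from .enrich import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class DEThresholds:
    fdr: float = 0.05
    log2fc: float = 0.5
    dispersion: float | None = None   # None: pooled method-of-moments estimate
    prior_count: float = 0.5


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.3,
                abundance_trim: float = 0.05) -> pd.Series:
    """TMM normalization factors (geometric mean 1) for a genes x samples
    count matrix.

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile.  For each sample, gene-wise log ratios (M) and
    average abundances (A) versus the reference are doubly trimmed (30% of
    M each side, 5% of A) and combined with inverse-variance weights.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = [counts.columns[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"all-zero sample(s): {bad}")
    uq = np.array([np.quantile(mat[:, j][mat[:, j] > 0], 0.75) / lib[j]
                   if (mat[:, j] > 0).any() else 0.0 for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        y, r = mat[:, j], mat[:, ref]
        keep = (y > 0) & (r > 0)
        if not keep.any():
            continue
        py, pr = y[keep] / lib[j], r[keep] / lib[ref]
        m = np.log2(py / pr)
        a = 0.5 * np.log2(py * pr)
        w = (lib[j] - y[keep]) / (lib[j] * y[keep]) + (lib[ref] - r[keep]) / (lib[ref] * r[keep])
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [abundance_trim, 1 - abundance_trim])
        sel = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not sel.any() or w[sel].sum() == 0:
            continue
        factors[j] = 2.0 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_counts(counts_a: pd.DataFrame, counts_b: pd.DataFrame) -> pd.Series:
    """Effective library-size factors for the two groups' samples jointly."""
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices must share the same gene list")
    return tmm_factors(pd.concat([counts_a, counts_b], axis=1))


# ---------------------------------------------------------------------------
# conditional NB exact test
# ---------------------------------------------------------------------------

def _conditional_two_sided_p(y_a: int, total: int, n_a: int, n_b: int,
                             dispersion: float) -> float:
    """P-value of the group-A total conditional on the combined total.

    The conditional pmf is proportional to
    ``C(y + r_a - 1, y) * C(t - y + r_b - 1, t - y)`` with ``r = n/phi``,
    which is exactly the beta-binomial law BetaBin(t, r_a, r_b); with
    ``phi = 0`` it degenerates to Binomial(t, n_a/(n_a + n_b)).
    """
    if total == 0:
        return 1.0
    if dispersion == 0:
        d = stats.binom(total, n_a / (n_a + n_b))
    else:
        d = stats.betabinom(total, n_a / dispersion, n_b / dispersion)
    lower, upper = d.cdf(y_a), d.sf(y_a - 1)
    lower, upper = max(float(lower), 0.0), max(float(upper), 0.0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def estimate_common_dispersion(norm_a: pd.DataFrame, norm_b: pd.DataFrame) -> float:
    """Pooled method-of-moments NB dispersion over both groups.

    Per gene and group, ``var = mu + phi * mu^2`` gives
    ``phi = (s^2 - mu) / mu^2``; the median across all gene/group estimates
    (clipped at 0) is robust to differentially expressed genes.
    """
    phis = []
    for block in (norm_a, norm_b):
        if block.shape[1] < 2:
            continue
        mu = block.mean(axis=1).to_numpy()
        s2 = block.var(axis=1, ddof=1).to_numpy()
        ok = mu > 0
        phis.append((s2[ok] - mu[ok]) / mu[ok] ** 2)
    if not phis:
        return 0.0
    pooled = np.concatenate(phis)
    return float(max(np.median(pooled), 0.0)) if pooled.size else 0.0


def nb_exact_test(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                  dispersion: float | None = None,
                  prior_count: float = 0.5,
                  genes: list[str] | None = None) -> pd.DataFrame:
    """Per-gene log2 fold change (A vs B) and exact conditional NB p-value.

    Counts are scaled to equal effective library sizes (TMM); log2FC uses a
    prior count to avoid division by zero.  ``dispersion=None`` plugs in the
    pooled method-of-moments estimate, which absorbs biological variation
    beyond shot noise.  Genes all-zero in both groups get p = 1, log2FC = 0.

    ``genes`` restricts the *reported* table to a subset while library-size
    factors and the dispersion estimate still come from the full matrices
    (normalizing on a small subset would let a few strongly shifted genes
    masquerade as a library-size difference).
    """
    if dispersion is not None and dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    factors = normalize_counts(counts_a, counts_b)
    lib = pd.concat([counts_a, counts_b], axis=1).sum(axis=0)
    eff = lib * factors
    scale = eff.mean() / eff
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    norm_a = counts_a * scale[counts_a.columns]
    norm_b = counts_b * scale[counts_b.columns]
    if dispersion is None:
        dispersion = estimate_common_dispersion(norm_a, norm_b)
    if genes is not None:
        counts_a, counts_b = counts_a.loc[genes], counts_b.loc[genes]
        norm_a, norm_b = norm_a.loc[genes], norm_b.loc[genes]
    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    log2fc = np.log2((mean_a + prior_count) / (mean_b + prior_count))
    pvals = np.ones(len(counts_a.index))
    tot_a = norm_a.sum(axis=1).round().astype(int).to_numpy()
    tot_b = norm_b.sum(axis=1).round().astype(int).to_numpy()
    for i in range(len(pvals)):
        t = tot_a[i] + tot_b[i]
        if t == 0:
            continue
        pvals[i] = _conditional_two_sided_p(int(tot_a[i]), int(t), n_a, n_b, dispersion)
    out = pd.DataFrame({"log2fc": log2fc, "p": pvals}, index=counts_a.index)
    out.loc[(counts_a.sum(axis=1) == 0) & (counts_b.sum(axis=1) == 0),
            ["log2fc", "p"]] = [0.0, 1.0]
    return out


# ---------------------------------------------------------------------------
# pairwise DE and the biomarker intersection
# ---------------------------------------------------------------------------

@dataclass
class DEResultSet:
    subtype: str
    other: str
    table: pd.DataFrame       # index gene; columns log2fc, p, fdr, passed
    thresholds: DEThresholds


def pairwise_deg(
    counts: dict[str, pd.DataFrame],
    subtype: str,
    genes: list[str],
    thresholds: DEThresholds | None = None,
) -> dict[tuple[str, str], DEResultSet]:
    """BSDEG sets: subtype C against every other subtype over gene list G.

    ``counts`` holds the *full* per-subtype count matrices; normalization and
    dispersion use all genes, the test reports only G.  BH correction is
    applied within each comparison; a gene passes iff fdr < thresholds.fdr
    AND |log2fc| > thresholds.log2fc (both strict).
    """
    thresholds = thresholds or DEThresholds()
    out: dict[tuple[str, str], DEResultSet] = {}
    genes = sorted(genes)
    for other in counts:
        if other == subtype:
            continue
        if genes:
            res = nb_exact_test(counts[subtype], counts[other],
                                dispersion=thresholds.dispersion,
                                prior_count=thresholds.prior_count,
                                genes=genes)
            res["fdr"] = bh_adjust(res["p"].to_numpy())
            res["passed"] = (res["fdr"] < thresholds.fdr) & \
                            (res["log2fc"].abs() > thresholds.log2fc)
        else:
            res = pd.DataFrame(columns=["log2fc", "p", "fdr", "passed"])
        out[(subtype, other)] = DEResultSet(subtype=subtype, other=other,
                                            table=res, thresholds=thresholds)
    return out


@dataclass
class BiomarkerSet:
    subtype: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene, avg_abs_log2fc, std_abs_log2fc, avg_fdr, std_fdr

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist() if len(self.table) else []


def intersect_biomarkers(deg_sets: dict[tuple[str, str], DEResultSet]) -> BiomarkerSet:
    """Bio_DEG: genes passing thresholds in every pairwise comparison, with
    mean/sd summaries of |log2FC| and FDR across the comparisons."""
    if not deg_sets:
        raise ValueError("no DE result sets given")
    subtypes = {k[0] for k in deg_sets}
    if len(subtypes) != 1:
        raise ValueError("DE result sets must all concern the same subtype")
    subtype = subtypes.pop()
    passing = [set(r.table.index[r.table["passed"]]) for r in deg_sets.values()]
    genes = sorted(set.intersection(*passing)) if passing else []
    rows = []
    for g in genes:
        lfc = np.array([r.table.loc[g, "log2fc"] for r in deg_sets.values()], dtype=float)
        fdr = np.array([r.table.loc[g, "fdr"] for r in deg_sets.values()], dtype=float)
        rows.append((g, np.abs(lfc).mean(), np.abs(lfc).std(ddof=1) if lfc.size > 1 else 0.0,
                     fdr.mean(), fdr.std(ddof=1) if fdr.size > 1 else 0.0))
    table = pd.DataFrame(rows, columns=["gene", "avg_abs_log2fc", "std_abs_log2fc",
                                        "avg_fdr", "std_fdr"])
    return BiomarkerSet(subtype=subtype, table=table)


# ---------------------------------------------------------------------------
# SVM cross-validated validation
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    subtype: str
    fold_aucs: list[float]
    mean_auc: float
    roc_points: pd.DataFrame   # columns fold, fpr, tpr


def svm_cv_evaluate(
    datasets: dict[str, ExpressionDataset],
    biomarkers: BiomarkerSet,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    cost: float = 1.0,
) -> CVReport:
    """One-vs-rest SVM validation of a biomarker set.

    Features are the biomarker genes' expression across all subtypes'
    samples, z-scored with training-fold statistics only; stratified
    k-fold with a fixed seed; per-fold ROC from decision scores with
    trapezoidal AUC.
    """
    genes = biomarkers.genes
    if not genes:
        raise ValueError(f"empty biomarker set for {biomarkers.subtype!r}")
    blocks, labels = [], []
    for label in sorted(datasets):
        ds = datasets[label]
        blocks.append(ds.values.loc[genes].to_numpy(dtype=float).T)
        labels += [1 if label == biomarkers.subtype else 0] * len(ds.samples)
    x = np.vstack(blocks)
    y = np.asarray(labels)
    n_pos, n_neg = int(y.sum()), int((y == 0).sum())
    if min(n_pos, n_neg) < folds:
        raise ValueError(f"need >= {folds} samples per class, got {n_pos} vs {n_neg}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    roc_rows = []
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        mu = x[tr].mean(axis=0)
        sd = x[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(kernel=kernel, C=cost)
        clf.fit((x[tr] - mu) / sd, y[tr])
        scores = clf.decision_function((x[te] - mu) / sd)
        fpr, tpr, _ = roc_curve(y[te], scores)
        fold_aucs.append(float(auc(fpr, tpr)))
        roc_rows += [(fold, float(f), float(t)) for f, t in zip(fpr, tpr)]
    return CVReport(subtype=biomarkers.subtype, fold_aucs=fold_aucs,
                    mean_auc=float(np.mean(fold_aucs)),
                    roc_points=pd.DataFrame(roc_rows, columns=["fold", "fpr", "tpr"]))
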