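"""Synthetic multi-subtype cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: five subtypes with unequal sample counts, four RNA classes with
class-specific abundance (circRNAs lowest), planted miRNA-sponge
triplets (negative miRNA<->sponge, positive sponge<->sponge expression
correlation, subtype-scoped), planted subtype-restricted differential
biomarkers, one expression-linked survival gene per subtype, and
scale-and-shuffle outlier samples.

Correlation planting
--------------------
Each triplet draws a latent per-sample miRNA activity ``m ~ N(0, 1)``.
A member gene's log-expression deviates from its baseline by
``tau * (s*m + sigma*eps) / sqrt(1 + sigma^2)`` with sign ``s = -1`` for
the miRNA and ``+1`` for both sponges, so the deviation sd is exactly
``tau`` (the same marginal the gene has in subtypes where it is not
planted).  Because the downstream screen computes Pearson correlation on
the *expression* scale, the noise is solved from the exact lognormal
correlation identity: for bivariate normal logs with common variance
``v = tau^2`` and correlation ``rho_n``,

    corr(exp scale) = (exp(rho_n * v) - 1) / (exp(v) - 1)

so ``rho_n = log(1 + rho * (exp(v) - 1)) / v`` hits the requested
sponge-sponge expression correlation ``rho`` and ``sigma^2 = 1/rho_n - 1``.
The miRNA arms attenuate asymmetrically (about -0.62 at rho = 0.7),
still clearing the 0.4 screen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import (
    DEFAULT_SUBTYPES,
    ClinicalTable,
    ExpressionDataset,
    GeneSetCollection,
    InteractionDB,
    RNAClass,
)

log = logging.getLogger(__name__)

#: sponge class pairs a planted triplet can take; `db` marks whether the
#: (miRNA, sponge) pairs are deposited in the interaction database
#: (mRNA/lncRNA sponges have experimentally supported pairs, circRNAs never do).
TRIPLET_ROUTES: tuple[tuple[RNAClass, RNAClass, bool], ...] = (
    (RNAClass.MRNA, RNAClass.LNCRNA, True),
    (RNAClass.CIRCRNA, RNAClass.MRNA, False),
    (RNAClass.CIRCRNA, RNAClass.CIRCRNA, False),
    (RNAClass.CIRCRNA, RNAClass.LNCRNA, False),
)

COMMON_SCOPE = "common"


@dataclass
class GeneratorConfig:
    """Stated world of the synthetic cohort; defaults mirror the real study's
    post-filter cohort sizes (88/100/76/252/42)."""

    seed: int = 0
    subtypes: tuple[tuple[str, int], ...] = tuple(zip(DEFAULT_SUBTYPES, (88, 100, 76, 252, 42)))
    n_genes: dict = field(default_factory=lambda: {
        RNAClass.MRNA: 200, RNAClass.LNCRNA: 60,
        RNAClass.CIRCRNA: 60, RNAClass.MIRNA: 60,
    })
    n_common_triplets: int = 3
    n_specific_triplets: int = 4          # per subtype
    triplet_strength: float = 0.7         # target sponge-sponge expression |PCC|
    n_planted_biomarkers: int = 2         # per subtype
    biomarker_log2fc: float = 2.0
    nb_dispersion: float = 0.2
    survival_effect: float = 0.8          # log-hazard per expression z-score unit
    baseline_hazard: float = 0.01
    censor_rate: float = 0.3
    n_outliers: int = 3                   # per subtype
    outlier_scale: float = 5.0
    # log-normal baselines: per-class mean of gene baselines, spread of gene
    # baselines, and per-sample noise sd (log scale)
    baseline_log_mean: dict = field(default_factory=lambda: {
        RNAClass.MRNA: 4.0, RNAClass.LNCRNA: 2.5,
        RNAClass.CIRCRNA: 1.5, RNAClass.MIRNA: 3.0,
    })
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.5
    planted_log_sd: float = 0.4
    n_decoy_interactions: int = 150

    def validate(self) -> None:
        if not (0 < self.triplet_strength < 1):
            raise ValueError("triplet_strength must be in (0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0, 1)")
        for name in ("n_common_triplets", "n_specific_triplets", "n_planted_biomarkers",
                     "n_outliers", "n_decoy_interactions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        labels = [s for s, _ in self.subtypes]
        if len(set(labels)) != len(labels) or any(not s for s in labels):
            raise ValueError("subtype labels must be unique and non-empty")


@dataclass
class PlantedTriplet:
    mirna: str
    sponge_a: str
    sponge_b: str
    scope: str  # COMMON_SCOPE or a subtype label


@dataclass
class GroundTruth:
    planted_triplets: list[PlantedTriplet] = field(default_factory=list)
    planted_biomarkers: dict[str, list[str]] = field(default_factory=dict)
    survival_genes: dict[str, str] = field(default_factory=dict)
    outlier_samples: dict[str, list[str]] = field(default_factory=dict)

    def triplets_for(self, subtype: str) -> list[PlantedTriplet]:
        return [t for t in self.planted_triplets if t.scope in (COMMON_SCOPE, subtype)]

    def specific_edges(self, subtype: str) -> set[tuple[str, str]]:
        return {tuple(sorted((t.sponge_a, t.sponge_b)))
                for t in self.planted_triplets if t.scope == subtype}

    def common_edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((t.sponge_a, t.sponge_b)))
                for t in self.planted_triplets if t.scope == COMMON_SCOPE}

    def expected_edges(self, subtype: str) -> set[tuple[str, str]]:
        return self.specific_edges(subtype) | self.common_edges()


@dataclass
class SyntheticCohort:
    expression: dict[str, ExpressionDataset]
    counts: dict[str, pd.DataFrame]
    interactions: InteractionDB
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    truth: GroundTruth
    config: GeneratorConfig


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in label).strip("-")


def planted_noise_sd(strength: float, log_sd: float) -> float:
    """Latent-factor noise sd solving the expression-scale correlation target."""
    v = log_sd ** 2
    rho_n = math.log1p(strength * math.expm1(v)) / v
    return math.sqrt(1.0 / rho_n - 1.0)


def _solve_censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Horizon H of Uniform(0, H) censoring giving the requested expected
    censored fraction under per-sample exponential event rates."""
    def frac(h: float) -> float:
        x = rates * h
        return float(np.mean(-np.expm1(-x) / x)) - censor_rate

    return brentq(frac, 1e-12, 1e12, xtol=1e-10, rtol=1e-12)


def generate(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full cohort; bit-reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    prefixes = {RNAClass.MRNA: "mRNA", RNAClass.LNCRNA: "lnc",
                RNAClass.CIRCRNA: "circ", RNAClass.MIRNA: "mir"}
    gene_ids = {cls: [f"{prefixes[cls]}_{i:04d}" for i in range(config.n_genes[cls])]
                for cls in RNAClass}
    classes = pd.Series({g: cls for cls in RNAClass for g in gene_ids[cls]})
    all_genes = classes.index.tolist()

    # ---- allocate planted triplets (genes never reused across triplets)
    cursor = {cls: 0 for cls in RNAClass}

    def take(cls: RNAClass) -> str:
        i = cursor[cls]
        if i >= config.n_genes[cls]:
            raise ValueError(f"not enough {cls.value} genes to plant the requested triplets")
        cursor[cls] += 1
        return gene_ids[cls][i]

    truth = GroundTruth()
    scopes = [COMMON_SCOPE] * config.n_common_triplets
    for label, _ in config.subtypes:
        scopes += [label] * config.n_specific_triplets
    route_at = {}  # scope -> next route index, cycled per scope
    for scope in scopes:
        r = route_at.get(scope, 0)
        cls_a, cls_b, _ = TRIPLET_ROUTES[r % len(TRIPLET_ROUTES)]
        route_at[scope] = r + 1
        truth.planted_triplets.append(PlantedTriplet(
            mirna=take(RNAClass.MIRNA), sponge_a=take(cls_a), sponge_b=take(cls_b),
            scope=scope))

    # ---- interaction database: planted db-route pairs + background decoys
    pairs: set[tuple[str, str]] = set()
    for t in truth.planted_triplets:
        if classes[t.sponge_a] != RNAClass.CIRCRNA and classes[t.sponge_b] != RNAClass.CIRCRNA:
            pairs.add((t.mirna, t.sponge_a))
            pairs.add((t.mirna, t.sponge_b))
    planted_gene_set = {g for t in truth.planted_triplets
                       for g in (t.mirna, t.sponge_a, t.sponge_b)}
    bg_targets = [g for g in gene_ids[RNAClass.MRNA] + gene_ids[RNAClass.LNCRNA]
                  if g not in planted_gene_set]
    bg_mirnas = [g for g in gene_ids[RNAClass.MIRNA] if g not in planted_gene_set]
    for _ in range(config.n_decoy_interactions):
        if not bg_mirnas or not bg_targets:
            break
        pairs.add((bg_mirnas[rng.integers(len(bg_mirnas))],
                   bg_targets[rng.integers(len(bg_targets))]))
    interactions = InteractionDB(pairs=pairs, source="synthetic")

    # ---- gene baselines (shared across subtypes so unplanted genes are null DE)
    base_mu = pd.Series(
        {g: config.baseline_log_mean[classes[g]] + config.baseline_log_sd * rng.standard_normal()
         for g in all_genes})
    # planted genes must survive the mean-expression filter
    planted_sorted = sorted(planted_gene_set)
    base_mu[planted_sorted] = base_mu[planted_sorted].clip(lower=1.0)

    # ---- biomarkers and survival genes, chosen among specific-triplet sponges
    for label, _ in config.subtypes:
        sponges: list[str] = []
        for t in truth.planted_triplets:
            if t.scope == label:
                sponges += [t.sponge_a, t.sponge_b]
        non_mrna = [g for g in sponges if classes[g] != RNAClass.MRNA]
        mrna = [g for g in sponges if classes[g] == RNAClass.MRNA]
        picks = (non_mrna + mrna)[: config.n_planted_biomarkers]
        if len(picks) < config.n_planted_biomarkers:
            raise ValueError("not enough specific-triplet sponges to host the requested "
                             f"biomarkers for {label!r}")
        truth.planted_biomarkers[label] = picks
        if mrna:
            truth.survival_genes[label] = mrna[0]

    sigma = planted_noise_sd(config.triplet_strength, config.planted_log_sd)
    norm = math.sqrt(1.0 + sigma ** 2)

    expression: dict[str, ExpressionDataset] = {}
    counts: dict[str, pd.DataFrame] = {}
    clin_frames: list[pd.DataFrame] = []

    for label, n_samples in config.subtypes:
        samples = [f"{_slug(label)}_s{i:03d}" for i in range(n_samples)]
        active = {t.mirna: t for t in truth.planted_triplets if t.scope in (COMMON_SCOPE, label)}

        logx = (base_mu.to_numpy()[:, None]
                + config.noise_log_sd * rng.standard_normal((len(all_genes), n_samples)))
        gene_pos = {g: i for i, g in enumerate(all_genes)}
        # planted genes: replace the per-sample deviation (same sd everywhere,
        # correlated only within this subtype's scoped triplets)
        scoped_members: set[str] = set()
        for t in active.values():
            m = rng.standard_normal(n_samples)
            for gene, sign in ((t.mirna, -1.0), (t.sponge_a, +1.0), (t.sponge_b, +1.0)):
                eps = rng.standard_normal(n_samples)
                dev = config.planted_log_sd * (sign * m + sigma * eps) / norm
                logx[gene_pos[gene]] = base_mu[gene] + dev
                scoped_members.add(gene)
        # sorted: set iteration order is hash-randomized and would desync the RNG
        for gene in sorted(planted_gene_set - scoped_members):
            dev = config.planted_log_sd * rng.standard_normal(n_samples)
            logx[gene_pos[gene]] = base_mu[gene] + dev

        x = np.exp(logx)

        # subtype-restricted biomarker fold change (constant factor: leaves PCC intact)
        for gene in truth.planted_biomarkers.get(label, []):
            x[gene_pos[gene]] *= 2.0 ** config.biomarker_log2fc

        # survival from the designated mRNA's (pre-outlier) expression
        surv_gene = truth.survival_genes.get(label)
        if surv_gene is not None:
            expr = x[gene_pos[surv_gene]]
            z = (expr - expr.mean()) / expr.std()
            rates = config.baseline_hazard * np.exp(config.survival_effect * z)
        else:  # pragma: no cover - defensive: no mRNA sponge planted
            rates = np.full(n_samples, config.baseline_hazard)
        event_t = rng.exponential(1.0 / rates)
        if config.censor_rate > 0:
            horizon = _solve_censor_horizon(rates, config.censor_rate)
            censor_t = rng.uniform(0.0, horizon, n_samples)
            time = np.minimum(event_t, censor_t)
            event = (event_t <= censor_t).astype(int)
        else:
            time, event = event_t, np.ones(n_samples, dtype=int)
        clin_frames.append(pd.DataFrame({
            "sample": samples, "time": time, "event": event, "subtype": label}))

        # outliers: scaled, gene-shuffled copies of their own profile
        if config.n_outliers > 0:
            if config.n_outliers >= n_samples:
                raise ValueError(f"n_outliers >= sample count for {label!r}")
            out_idx = rng.choice(n_samples, size=config.n_outliers, replace=False)
            for j in sorted(out_idx):
                x[:, j] = config.outlier_scale * rng.permutation(x[:, j])
            truth.outlier_samples[label] = [samples[j] for j in sorted(out_idx)]
        else:
            truth.outlier_samples[label] = []

        values = pd.DataFrame(x, index=all_genes, columns=samples)
        expression[label] = ExpressionDataset(subtype=label, values=values,
                                              classes=classes.copy())

        # sequencing-like counts: expression values as NB means (gamma-Poisson)
        if config.nb_dispersion > 0:
            lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * x)
        else:
            lam = x
        counts[label] = pd.DataFrame(rng.poisson(lam), index=all_genes, columns=samples)

    clinical = ClinicalTable(records=pd.concat(clin_frames, ignore_index=True))
    gene_sets = _make_gene_sets(config, truth, classes, all_genes, rng)
    return SyntheticCohort(expression=expression, counts=counts, interactions=interactions,
                           clinical=clinical, gene_sets=gene_sets, truth=truth,
                           config=config)


def _make_gene_sets(config: GeneratorConfig, truth: GroundTruth, classes: pd.Series,
                    all_genes: list[str], rng: np.random.Generator) -> GeneSetCollection:
    """One set per subtype holding its specific-triplet sponges (padded with
    random genes) plus random null sets, so over-representation of recovered
    modules is checkable."""
    sets: dict[str, tuple[str, list[str]]] = {}
    non_mirna = [g for g in all_genes if classes[g] != RNAClass.MIRNA]
    for label, _ in config.subtypes:
        members = sorted({g for t in truth.planted_triplets if t.scope == label
                          for g in (t.sponge_a, t.sponge_b)})
        if not members:
            continue
        pad = [g for g in non_mirna if g not in members]
        extra = [pad[i] for i in rng.choice(len(pad), size=min(6, len(pad)), replace=False)]
        sets[f"pathway_{_slug(label)}"] = (f"planted sponge program of {label}",
                                           members + sorted(extra))
    for k in range(10):
        members = [non_mirna[i]
                   for i in rng.choice(len(non_mirna), size=10, replace=False)]
        sets[f"random_set_{k:02d}"] = ("random null set", sorted(members))
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# ground-truth serialization (tagged TSV)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path: Path | str) -> None:
    rows: list[tuple[str, ...]] = []
    for t in truth.planted_triplets:
        rows.append(("triplet", t.scope, t.mirna, t.sponge_a, t.sponge_b))
    for label, genes in truth.planted_biomarkers.items():
        for g in genes:
            rows.append(("biomarker", label, g))
    for label, g in truth.survival_genes.items():
        rows.append(("survival_gene", label, g))
    for label, sams in truth.outlier_samples.items():
        for s in sams:
            rows.append(("outlier", label, s))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_ground_truth(path: Path | str) -> GroundTruth:
    truth = GroundTruth()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            tag = parts[0]
            if tag == "triplet":
                truth.planted_triplets.append(PlantedTriplet(
                    scope=parts[1], mirna=parts[2], sponge_a=parts[3], sponge_b=parts[4]))
            elif tag == "biomarker":
                truth.planted_biomarkers.setdefault(parts[1], []).append(parts[2])
            elif tag == "survival_gene":
                truth.survival_genes[parts[1]] = parts[2]
            elif tag == "outlier":
                truth.outlier_samples.setdefault(parts[1], []).append(parts[2])
            else:
                raise ValueError(f"unknown ground-truth tag {tag!r}")
    return truth
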