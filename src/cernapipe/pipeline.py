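"""Staged pipeline orchestration over plain-text artifacts.

Every stage reads its inputs from, and writes its outputs to, a fixed
layout under ``config.outdir``, so a monolithic :func:`run_pipeline` and
stage-by-stage invocation of :func:`run_stage` produce byte-identical
artifacts and either can resume a partial run.  All randomness flows
from ``config.seed``; artifacts carry a provenance line with the config
hash and seed.

Stage order: generate (or ingest) -> preprocess -> infer-network ->
network-algebra -> cluster -> enrich -> survival -> biomarkers ->
evaluate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .biomarker import (BiomarkerSet, DEThresholds, intersect_biomarkers,
                        pairwise_deg, svm_cv_evaluate)
from .cerna import InferenceConfig, build_primary_network
from .datatypes import RNAClass
from .enrich import enrichment_frame, hypergeom_enrich
from .netops import MCLConfig, ModuleSet, common_network, filter_lc_modules, \
    mcl_cluster, specific_network
from .preprocess import PreprocessConfig, preprocess, merge_tree_newick
from .simulate import GeneratorConfig, generate, write_ground_truth
from .survival import screen_frame, screen_module_mrnas

log = logging.getLogger(__name__)

STAGES = ("generate", "preprocess", "infer-network", "network-algebra",
          "cluster", "enrich", "survival", "biomarkers", "evaluate")


def _slug(label: str) -> str:
    return "".join(c if c.isalnum() else "-" for c in label).strip("-")


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    input_paths: dict | None = None   # expression: {label: path}, classes, interactions,
    #                                   clinical, and optionally gene_sets (GMT), counts
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    mcl: MCLConfig = field(default_factory=MCLConfig)
    de: DEThresholds = field(default_factory=DEThresholds)
    survival_alpha: float = 0.05
    enrich_fdr: float = 0.05
    cv_folds: int = 5

    def validate(self) -> None:
        if (self.generator is None) == (self.input_paths is None):
            raise ValueError("exactly one of generator config or input paths "
                             "must be supplied")

    def subtype_labels(self) -> list[str]:
        if self.generator is not None:
            return [s for s, _ in self.generator.subtypes]
        return sorted(self.input_paths["expression"])

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, RNAClass):
                return str(obj)
            return obj

        return enc(self)

    @property
    def config_hash(self) -> str:
        # outdir excluded: the hash identifies the scientific configuration,
        # not where its artifacts happen to live
        payload = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:12]

    @property
    def provenance(self) -> str:
        return f"cernapipe config={self.config_hash} seed={self.seed}"


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: pd.DataFrame   # columns: stage, subtype, metric, value


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the {producer!r} stage first")
    return path


def _read_datasets(cfg: PipelineConfig, stage_dir: str, producer: str):
    base = Path(cfg.outdir)
    class_map = cio.read_class_map(_require(base / "cohort" / "class_map.tsv", "generate"))
    out = {}
    for label in cfg.subtype_labels():
        path = _require(base / stage_dir / f"expression_{_slug(label)}.tsv", producer)
        out[label] = cio.read_expression(path, class_map, subtype=label)
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_generate(cfg: PipelineConfig) -> None:
    """Generate the synthetic cohort (or ingest external inputs) into cohort/."""
    base = Path(cfg.outdir) / "cohort"
    base.mkdir(parents=True, exist_ok=True)
    if cfg.generator is not None:
        cohort = generate(cfg.generator)
        classes = next(iter(cohort.expression.values())).classes
        cio.write_class_map(classes, base / "class_map.tsv")
        for label, ds in cohort.expression.items():
            cio.write_expression(ds, base / f"expression_{_slug(label)}.tsv",
                                 provenance=cfg.provenance)
            counts = cohort.counts[label].copy()
            counts.index.name = "gene"
            cio._write_tsv(counts, base / f"counts_{_slug(label)}.tsv",
                           cfg.provenance, index=True)
        cio.write_interactions(cohort.interactions, base / "interactions.tsv")
        cio.write_clinical(cohort.clinical, base / "clinical.tsv",
                           provenance=cfg.provenance)
        cio.write_gmt(cohort.gene_sets, base / "gene_sets.gmt")
        write_ground_truth(cohort.truth, base / "ground_truth.tsv")
    else:
        paths = cfg.input_paths
        class_map = cio.read_class_map(paths["classes"])
        cio.write_class_map(class_map, base / "class_map.tsv")
        for label, path in paths["expression"].items():
            ds = cio.read_expression(path, class_map, subtype=label)
            cio.write_expression(ds, base / f"expression_{_slug(label)}.tsv",
                                 provenance=cfg.provenance)
            if "counts" in paths and label in paths["counts"]:
                counts = pd.read_csv(paths["counts"][label], sep="\t", comment="#",
                                     index_col=0)
            else:  # fall back: rounded expression as count surrogate
                counts = ds.values.round().astype(int)
            counts.index.name = "gene"
            cio._write_tsv(counts, base / f"counts_{_slug(label)}.tsv",
                           cfg.provenance, index=True)
        cio.write_interactions(cio.read_interactions(paths["interactions"]),
                               base / "interactions.tsv")
        cio.write_clinical(cio.read_clinical(paths["clinical"]), base / "clinical.tsv",
                           provenance=cfg.provenance)
        if "gene_sets" in paths:
            cio.write_gmt(cio.read_gmt(paths["gene_sets"]), base / "gene_sets.gmt")


def stage_preprocess(cfg: PipelineConfig) -> None:
    datasets = _read_datasets(cfg, "cohort", "generate")
    out = Path(cfg.outdir) / "preprocess"
    filtered, report, trees = preprocess(datasets, cfg.preprocess)
    for label, ds in filtered.items():
        cio.write_expression(ds, out / f"expression_{_slug(label)}.tsv",
                             provenance=cfg.provenance)
        nwk = merge_tree_newick(trees[label], datasets[label].samples)
        (out / f"dendrogram_{_slug(label)}.nwk").write_text(nwk + "\n")
    cio._write_tsv(report.to_frame(), out / "report.tsv", cfg.provenance, index=False)


def stage_infer_network(cfg: PipelineConfig) -> None:
    datasets = _read_datasets(cfg, "preprocess", "preprocess")
    db = cio.read_interactions(
        _require(Path(cfg.outdir) / "cohort" / "interactions.tsv", "generate"))
    out = Path(cfg.outdir) / "networks"
    for label, ds in datasets.items():
        net = build_primary_network(ds, db, cfg.inference)
        net.graph.graph["provenance"] = cfg.provenance
        cio.write_network(net, out / f"primary_{_slug(label)}.graphml")
        cio.write_edge_table(net, out / f"primary_{_slug(label)}.edges.tsv",
                             provenance=cfg.provenance)


def stage_network_algebra(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    primaries = {
        label: cio.read_network(
            _require(base / "networks" / f"primary_{_slug(label)}.graphml",
                     "infer-network"))
        for label in cfg.subtype_labels()}
    out = base / "algebra"
    common = common_network(primaries)
    common.graph.graph["provenance"] = cfg.provenance
    cio.write_network(common, out / "common.graphml")
    cio.write_edge_table(common, out / "common.edges.tsv", provenance=cfg.provenance)
    for label, net in primaries.items():
        spec = specific_network(net, common)
        spec.graph.graph["provenance"] = cfg.provenance
        cio.write_network(spec, out / f"specific_{_slug(label)}.graphml")
        cio.write_edge_table(spec, out / f"specific_{_slug(label)}.edges.tsv",
                             provenance=cfg.provenance)


def _load_modules(cfg: PipelineConfig, label: str) -> ModuleSet:
    base = Path(cfg.outdir)
    net = cio.read_network(_require(
        base / "algebra" / f"specific_{_slug(label)}.graphml", "network-algebra"))
    path = _require(base / "modules" / f"modules_{_slug(label)}.tsv", "cluster")
    df = pd.read_csv(path, sep="\t", comment="#")
    mods = [tuple(sorted(grp["gene"])) for _, grp in df.groupby("module", sort=True)] \
        if len(df) else []
    return ModuleSet(tag=label, modules=mods, source=net)


def stage_cluster(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    out = base / "modules"
    for label in cfg.subtype_labels():
        net = cio.read_network(_require(
            base / "algebra" / f"specific_{_slug(label)}.graphml", "network-algebra"))
        rows = []
        if net.n_nodes:
            lc = filter_lc_modules(mcl_cluster(net, cfg.mcl))
            for i, mod in enumerate(lc.modules):
                flags = lc.flags(mod)
                for g in mod:
                    rows.append((f"M{i:03d}", g, str(net.node_class(g)),
                                 flags["contains_lncRNA"], flags["contains_circRNA"]))
        df = pd.DataFrame(rows, columns=["module", "gene", "rna_class",
                                         "contains_lncRNA", "contains_circRNA"])
        cio._write_tsv(df, out / f"modules_{_slug(label)}.tsv", cfg.provenance,
                       index=False)


def stage_enrich(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    gmt_path = base / "cohort" / "gene_sets.gmt"
    out = base / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    if not gmt_path.exists():
        log.info("no gene sets supplied; enrichment stage writes nothing")
        return
    sets = cio.read_gmt(gmt_path)
    datasets = _read_datasets(cfg, "preprocess", "preprocess")
    for label in cfg.subtype_labels():
        ds = datasets[label]
        universe = [g for g in ds.genes if ds.classes[g] != RNAClass.MIRNA]
        modules = _load_modules(cfg, label)
        named = {f"M{i:03d}": list(mod) for i, mod in enumerate(modules.modules)}
        results = hypergeom_enrich(named, sets, universe) if named else []
        df = enrichment_frame(results)
        df["significant"] = df["fdr"] < cfg.enrich_fdr if len(df) else []
        cio._write_tsv(df, out / f"enrichment_{_slug(label)}.tsv", cfg.provenance,
                       index=False)


def stage_survival(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    clinical = cio.read_clinical(_require(base / "cohort" / "clinical.tsv", "generate"))
    datasets = _read_datasets(cfg, "preprocess", "preprocess")
    out = base / "survival"
    for label in cfg.subtype_labels():
        modules = _load_modules(cfg, label)
        results = screen_module_mrnas(modules, datasets[label], clinical,
                                      alpha=cfg.survival_alpha) if len(modules) else []
        cio._write_tsv(screen_frame(results), out / f"screen_{_slug(label)}.tsv",
                       cfg.provenance, index=False)
        km_rows = []
        for r in results:
            if not r.significant:
                continue
            for group, curve in (("high", r.km_high), ("low", r.km_low)):
                for _, row in curve.iterrows():
                    km_rows.append((r.gene, group, row["time"], int(row["at_risk"]),
                                    int(row["events"]), row["survival"]))
        km = pd.DataFrame(km_rows, columns=["gene", "group", "time", "at_risk",
                                            "events", "survival"])
        cio._write_tsv(km, out / f"km_{_slug(label)}.tsv", cfg.provenance, index=False)


def stage_biomarkers(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    counts = {}
    for label in cfg.subtype_labels():
        path = _require(base / "cohort" / f"counts_{_slug(label)}.tsv", "generate")
        counts[label] = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    retained = _read_datasets(cfg, "preprocess", "preprocess")
    out = base / "de"
    for label in cfg.subtype_labels():
        modules = _load_modules(cfg, label)
        genes = sorted(modules.all_genes())
        # restrict counts to samples surviving preprocessing
        sub_counts = {lbl: counts[lbl][retained[lbl].samples] for lbl in counts}
        deg = pairwise_deg(sub_counts, label, genes, cfg.de)
        for (c, other), res in deg.items():
            tbl = res.table.copy()
            tbl.index.name = "gene"
            cio._write_tsv(tbl, out / f"de_{_slug(c)}_vs_{_slug(other)}.tsv",
                           cfg.provenance, index=True)
        bio = intersect_biomarkers(deg) if deg else BiomarkerSet(subtype=label)
        cio._write_tsv(bio.table, out / f"biomarkers_{_slug(label)}.tsv",
                       cfg.provenance, index=False)


def stage_evaluate(cfg: PipelineConfig) -> None:
    base = Path(cfg.outdir)
    retained = _read_datasets(cfg, "preprocess", "preprocess")
    out = base / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    for label in cfg.subtype_labels():
        path = _require(base / "de" / f"biomarkers_{_slug(label)}.tsv", "biomarkers")
        table = pd.read_csv(path, sep="\t", comment="#")
        if table.empty:
            log.warning("%s: empty biomarker set, skipping SVM validation", label)
            continue
        bio = BiomarkerSet(subtype=label, table=table)
        report = svm_cv_evaluate(retained, bio, folds=cfg.cv_folds, seed=cfg.seed)
        cv = pd.DataFrame({"fold": list(range(len(report.fold_aucs))) + ["mean"],
                           "auc": report.fold_aucs + [report.mean_auc]})
        cio._write_tsv(cv, out / f"cv_{_slug(label)}.tsv", cfg.provenance, index=False)
        cio._write_tsv(report.roc_points, out / f"roc_{_slug(label)}.tsv",
                       cfg.provenance, index=False)


_STAGE_FUNCS = {
    "generate": stage_generate,
    "preprocess": stage_preprocess,
    "infer-network": stage_infer_network,
    "network-algebra": stage_network_algebra,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "survival": stage_survival,
    "biomarkers": stage_biomarkers,
    "evaluate": stage_evaluate,
}


def run_stage(cfg: PipelineConfig, stage: str) -> None:
    cfg.validate()
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    t0 = time.perf_counter()
    try:
        _STAGE_FUNCS[stage](cfg)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)


def build_report(cfg: PipelineConfig) -> RunReport:
    """Collect per-stage counts from the artifacts on disk."""
    base = Path(cfg.outdir)
    rows: list[tuple[str, str, str, object]] = []
    for label in cfg.subtype_labels():
        s = _slug(label)
        raw = pd.read_csv(base / "cohort" / f"expression_{s}.tsv", sep="\t",
                          comment="#", index_col=0)
        rows.append(("generate", label, "genes", raw.shape[0]))
        rows.append(("generate", label, "samples", raw.shape[1]))
        filt = pd.read_csv(base / "preprocess" / f"expression_{s}.tsv", sep="\t",
                           comment="#", index_col=0)
        rows.append(("preprocess", label, "genes", filt.shape[0]))
        rows.append(("preprocess", label, "samples", filt.shape[1]))
        for stage_dir, name, prefix in (("networks", "infer-network", "primary"),
                                        ("algebra", "network-algebra", "specific")):
            edges = pd.read_csv(base / stage_dir / f"{prefix}_{s}.edges.tsv",
                                sep="\t", comment="#")
            nodes = set(edges["node_a"]) | set(edges["node_b"]) if len(edges) else set()
            rows.append((name, label, f"{prefix}_edges", len(edges)))
            rows.append((name, label, f"{prefix}_nodes", len(nodes)))
        mods = pd.read_csv(base / "modules" / f"modules_{s}.tsv", sep="\t", comment="#")
        rows.append(("cluster", label, "lc_modules",
                     mods["module"].nunique() if len(mods) else 0))
        bio = pd.read_csv(base / "de" / f"biomarkers_{s}.tsv", sep="\t", comment="#")
        rows.append(("biomarkers", label, "biomarkers", len(bio)))
    common = pd.read_csv(base / "algebra" / "common.edges.tsv", sep="\t", comment="#")
    rows.append(("network-algebra", "common", "common_edges", len(common)))
    counts = pd.DataFrame(rows, columns=["stage", "subtype", "metric", "value"])
    return RunReport(config_hash=cfg.config_hash, seed=cfg.seed, counts=counts)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages in order and write the run report."""
    cfg.validate()
    base = Path(cfg.outdir)
    base.mkdir(parents=True, exist_ok=True)
    (base / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
    for stage in STAGES:
        run_stage(cfg, stage)
    report = build_report(cfg)
    cio._write_tsv(report.counts, base / "run_report.tsv", cfg.provenance, index=False)
    return report
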