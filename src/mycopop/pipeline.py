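"""End-to-end orchestration: config, stage ordering, manifest, and report.

A run either reads real inputs (VCF + annotation + GO map + groups +
phenotypes) or simulates them from a :class:`~mycopop.simulate.SimulationConfig`
block — exactly one of the two.  Stages execute in the fixed order
simulate/read -> filter -> thin -> diversity -> structure -> F_ST/scan ->
candidate assignment -> enrichment -> phenotypes, every output lands in the
output directory, and a manifest records each file's SHA-256 so a rerun with
the same config and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from . import diversity, divergence, enrichment, phenotype, phylo, simulate, variant_io
from .core import GenotypeMatrix, GroupAssignment

logger = logging.getLogger("mycopop")

__all__ = ["PipelineConfig", "PipelineError", "ConfigError", "run_pipeline",
           "write_report", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run.

    Thresholds default to the study's values: QUAL >= 30, mean depth >= 5,
    MAF >= 0.05, 1,000-bp thinning, 5-kb windows, top 5% windows, q < 0.05.
    """

    outdir: str = "mycopop_run"
    seed: int = 0
    # input paths (exclusive with `simulation`)
    vcf: str | None = None
    annotation: str | None = None
    go_map: str | None = None
    phenotypes: str | None = None
    groups: str | None = None
    simulation: simulate.SimulationConfig | None = None
    # thresholds
    min_qual: float = 30.0
    min_mean_depth: float = 5.0
    min_maf: float = 0.05
    thin_bp: int = 1000
    window_size: int = 5000
    top_fraction: float = 0.05
    q_threshold: float = 0.05
    prior_odds: float = 10.0
    mcmc: divergence.McmcSettings = field(default_factory=divergence.McmcSettings)
    bootstrap_replicates: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        has_paths = self.vcf is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigError(
                "exactly one of a VCF input path or a simulation block is required"
            )
        if has_paths and self.groups is None:
            raise ConfigError("a groups table is required with VCF input")
        for name, value, lo, hi in (
            ("min_maf", self.min_maf, 0.0, 0.5),
            ("top_fraction", self.top_fraction, 0.0, 1.0),
            ("q_threshold", self.q_threshold, 0.0, 1.0),
        ):
            if not lo <= value <= hi:
                raise ConfigError(f"{name}={value} outside [{lo}, {hi}]")
        if self.min_qual < 0 or self.min_mean_depth < 0 or self.thin_bp < 0:
            raise ConfigError("thresholds must be non-negative")
        if self.window_size < 1:
            raise ConfigError("window_size must be positive")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Read a YAML config; a `simulation:` mapping becomes a SimulationConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    mcmc = raw.pop("mcmc", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    if sim is not None:
        for key in ("strains_per_population", "baseline_divergence", "inbreeding",
                    "hybrid_parents"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if "scaffold_layout" in sim:
            sim["scaffold_layout"] = tuple(tuple(x) for x in sim["scaffold_layout"])
        cfg.simulation = simulate.SimulationConfig(**sim)
    if mcmc is not None:
        cfg.mcmc = divergence.McmcSettings(**mcmc)
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """Mutable state threaded through the stages."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outputs: dict[str, str] = {}
        self.stage_seconds: dict[str, float] = {}
        self.matrix: GenotypeMatrix | None = None
        self.thinned: GenotypeMatrix | None = None
        self.assignment: GroupAssignment | None = None
        self.annotation: pd.DataFrame | None = None
        self.go_map: pd.DataFrame | None = None
        self.phenotypes: pd.DataFrame | None = None
        self.summary: dict = {}

    def emit(self, name: str, filename: str, writer) -> None:
        path = os.path.join(self.config.outdir, filename)
        writer(path)
        self.outputs[name] = path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Any stage failure raises :class:`PipelineError` naming the stage; outputs
    already written are retained for inspection.
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    os.makedirs(config.outdir, exist_ok=True)
    run = _Run(config)
    stages = [
        ("acquire", _stage_acquire),
        ("filter", _stage_filter),
        ("thin", _stage_thin),
        ("diversity", _stage_diversity),
        ("structure", _stage_structure),
        ("divergence", _stage_divergence),
        ("enrichment", _stage_enrichment),
        ("phenotypes", _stage_phenotypes),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            fn(run)
        except Exception as exc:  # abort with stage name; keep partial outputs
            raise PipelineError(name, exc) from exc
        run.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, run.stage_seconds[name])

    manifest = {
        "seed": config.seed,
        "outdir": config.outdir,
        "stage_seconds": run.stage_seconds,
        "summary": run.summary,
        "outputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in sorted(run.outputs.items())
        },
    }
    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_acquire(run: _Run) -> None:
    cfg = run.config
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        matrix, truth = simulate.simulate_genotypes(sim)
        run.annotation, run.go_map = simulate.simulate_annotation(sim, truth)
        run.phenotypes = simulate.simulate_phenotypes(sim, truth)
        run.assignment = truth.assignment()
        vcf_path = os.path.join(cfg.outdir, "simulated.vcf")
        simulate.write_vcf(matrix, vcf_path)
        run.outputs["vcf"] = vcf_path
        written = simulate.write_tables(
            cfg.outdir,
            annotation=run.annotation,
            go_map=run.go_map,
            phenotypes=run.phenotypes,
            assignment=run.assignment,
            truth=truth,
        )
        run.outputs.update(written)
        samples, records = variant_io.read_vcf(vcf_path)
        run._samples, run._records = samples, records
    else:
        samples, records = variant_io.read_vcf(cfg.vcf)
        run._samples, run._records = samples, records
        run.assignment = variant_io.read_group_table(cfg.groups)
        if cfg.annotation:
            run.annotation = pd.read_csv(cfg.annotation, sep="\t")
        if cfg.go_map:
            run.go_map = pd.read_csv(cfg.go_map, sep="\t")
        if cfg.phenotypes:
            run.phenotypes = pd.read_csv(cfg.phenotypes, index_col=0)
    run.assignment.validate(run._samples)


def _stage_filter(run: _Run) -> None:
    cfg = run.config
    run.matrix = variant_io.filter_variants(
        run._samples,
        run._records,
        min_qual=cfg.min_qual,
        min_mean_depth=cfg.min_mean_depth,
        min_maf=cfg.min_maf,
    )
    run.summary["n_snps"] = run.matrix.n_loci
    run.summary["n_strains"] = run.matrix.n_strains
    counts = {
        g: variant_io.group_snp_count(run.matrix, run.assignment, g)
        for g in run.assignment.groups()
    }
    run.summary["group_snp_counts"] = counts


def _stage_thin(run: _Run) -> None:
    run.thinned = variant_io.thin_by_distance(run.matrix, run.config.thin_bp)
    run.summary["n_snps_thinned"] = run.thinned.n_loci
    run.emit(
        "thinned_loci",
        "thinned_loci.tsv",
        lambda p: run.thinned.loci.to_csv(p, sep="\t", index=False),
    )


def _stage_diversity(run: _Run) -> None:
    cfg = run.config
    win = diversity.window_tajima_d(run.matrix, cfg.window_size)
    run.emit("window_stats", "window_stats.tsv",
             lambda p: win.to_csv(p, sep="\t", index=False))
    present = win[win["n_sites"] > 0]
    run.summary["pi_mean"] = float(present["pi"].mean())
    run.summary["tajima_d_mean"] = float(present["tajima_d"].dropna().mean())

    het_frames = []
    for g in run.assignment.groups(include_outliers=True):
        members = run.assignment.members(g)
        sub = run.matrix.take_strains(members)
        het = diversity.strain_het(sub)
        het.insert(1, "group", g)
        het_frames.append(het)
    het_all = pd.concat(het_frames, ignore_index=True)
    run.emit("strain_het", "strain_het.tsv",
             lambda p: het_all.to_csv(p, sep="\t", index=False))
    run.summary["mean_F_by_group"] = {
        g: float(het_all.loc[het_all["group"] == g, "F"].mean())
        for g in het_all["group"].unique()
    }

    if run.annotation is not None:
        ratios = diversity.snp_class_ratios(run.matrix, run.annotation, run.assignment)
        run.emit("snp_class_ratios", "snp_class_ratios.tsv",
                 lambda p: ratios.to_csv(p, sep="\t", index=False))

    # AMOVA on the thinned set, following the study's choice of marker set
    table = diversity.amova(run.thinned, run.assignment)
    run.emit("amova", "amova.tsv",
             lambda p: table.table.round(2).to_csv(p, sep="\t", index=False))
    run.summary["amova_percent"] = [round(x, 2) for x in table.percents()]


def _stage_structure(run: _Run) -> None:
    cfg = run.config
    dist = phylo.genotype_distance(run.matrix)
    run.emit(
        "distance_matrix",
        "distance_matrix.tsv",
        lambda p: pd.DataFrame(
            dist.data, index=list(dist.ids), columns=list(dist.ids)
        ).to_csv(p, sep="\t"),
    )
    tree = phylo.neighbor_joining(dist)
    run._tree = tree
    run.emit("nj_tree", "nj_tree.nwk", lambda p: tree.write(p))
    if cfg.bootstrap_replicates:
        support = phylo.bootstrap_support(
            run.matrix, tree, cfg.bootstrap_replicates, seed=cfg.seed
        )
        rows = [
            {"clade": ";".join(sorted(s)), "support": v} for s, v in support.items()
        ]
        run.emit(
            "bootstrap_support",
            "bootstrap_support.tsv",
            lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False),
        )


def _stage_divergence(run: _Run) -> None:
    cfg = run.config
    groups = run.assignment.groups()
    sites_all = divergence.wc_fst_sites(run.matrix, run.assignment, groups)
    run.summary["fst_multipop"] = round(divergence.multipop_fst(sites_all), 4)

    top_by_pair: dict[tuple[str, str], pd.DataFrame] = {}
    pair_means = {}
    for a, b in combinations(groups, 2):
        sites = divergence.wc_fst_sites(run.matrix, run.assignment, [a, b])
        win = divergence.wc_fst_windows(sites, cfg.window_size)
        top = divergence.top_fraction_windows(win, cfg.top_fraction)
        top_by_pair[(a, b)] = top
        pair_means[f"{a}-{b}"] = round(float(win["fst"].dropna().mean()), 4)
    run.summary["fst_window_means"] = pair_means

    alt, tot, scan_groups = divergence.allele_counts_by_population(
        run.matrix, run.assignment, groups
    )
    scan = divergence.bayesian_outlier_scan(
        alt,
        tot,
        prior_odds=cfg.prior_odds,
        settings=cfg.mcmc,
        seed=cfg.seed,
        groups=scan_groups,
        loci=run.matrix.loci,
    )
    run.emit("outlier_scan", "outlier_scan.tsv",
             lambda p: scan.loci.to_csv(p, sep="\t", index=False))
    outliers = divergence.call_outliers(scan, cfg.q_threshold)
    run.summary["n_outliers"] = len(outliers)

    assigned = divergence.assign_candidate_divergence_snps(
        outliers, top_by_pair, cfg.window_size
    )
    run.emit("candidate_snps", "candidate_snps.tsv",
             lambda p: assigned.to_csv(p, sep="\t", index=False))
    run.summary["candidates_per_group"] = {
        g: int(sum(g in str(x).split(",") for x in assigned["groups"]))
        for g in groups
    }
    run._assigned = assigned
    if run.annotation is not None:
        gene_lists, report = divergence.candidate_genes(assigned, run.annotation)
        run.emit("candidate_genes", "candidate_genes.tsv",
                 lambda p: report.to_csv(p, sep="\t", index=False))
        run.summary["candidate_genes_per_group"] = {
            g: len(v) for g, v in gene_lists.items()
        }
        run.summary["candidate_genes_shared_all"] = int(
            (report["n_groups"] == len(groups)).sum()
        ) if len(report) else 0


def _stage_enrichment(run: _Run) -> None:
    if run.annotation is None or run.go_map is None:
        logger.info("enrichment skipped: no annotation/GO inputs")
        return
    specific = enrichment.group_specific_snps(run.matrix, run.assignment)
    run.summary["group_specific_snps"] = {
        g: int(m.sum()) for g, m in specific.items()
    }
    sets = enrichment.missense_gene_sets(specific, run.matrix, run.annotation)
    background = enrichment.snp_background_genes(run.matrix, run.annotation)
    frames = []
    for g, gs in sets.items():
        if not gs.genes:
            continue
        table = enrichment.fisher_enrichment(gs, run.go_map, background)
        table.insert(0, "group", g)
        frames.append(table)
    result = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["group", "term_id", "k", "n", "K", "N",
                                   "p_value", "log2_odds", "stars"])
    )
    run.emit("enrichment", "enrichment.tsv",
             lambda p: result.to_csv(p, sep="\t", index=False))


def _stage_phenotypes(run: _Run) -> None:
    if run.phenotypes is None:
        logger.info("phenotype stage skipped: no phenotype table")
        return
    norm = phenotype.normalize(run.phenotypes)
    run.emit("phenotypes_normalized", "phenotypes_normalized.csv",
             lambda p: norm.to_csv(p))
    strain_link, trait_link, ordered, _ = phenotype.cluster(norm)
    run.emit("phenotype_ordered", "phenotype_ordered.tsv",
             lambda p: ordered.to_csv(p, sep="\t"))
    run.emit(
        "phenotype_dendrograms",
        "phenotype_dendrograms.nwk",
        lambda p: open(p, "w").write(
            phenotype.linkage_to_newick(strain_link, list(norm.index))
            + "\n"
            + phenotype.linkage_to_newick(trait_link, list(norm.columns))
            + "\n"
        ),
    )
    summary = phenotype.group_summary(run.phenotypes, run.assignment)
    run.emit("phenotype_group_summary", "phenotype_group_summary.tsv",
             lambda p: summary.to_csv(p, sep="\t", index=False))


def write_report(manifest: dict, path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Flatten the manifest's summary into a two-column key/value TSV."""
    rows = []

    def _walk(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                _walk(f"{prefix}.{k}" if prefix else str(k), v)
        elif isinstance(obj, (list, tuple)):
            rows.append({"key": prefix, "value": ";".join(str(x) for x in obj)})
        else:
            rows.append({"key": prefix, "value": obj})

    _walk("", manifest.get("summary", {}))
    report = pd.DataFrame(rows, columns=["key", "value"])
    if path is not None:
        report.to_csv(path, sep="\t", index=False)
    return report
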