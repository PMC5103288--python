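"""Multi-population synthetic genotype, annotation, and phenotype generator.

Genotypes follow the Balding-Nichols model: each locus has an ancestral
frequency p drawn uniformly, and each population draws its own frequency from
Beta(p(1-c)/c, (1-p)(1-c)/c), where c is that locus/population's divergence
parameter -- the quantity Weir-Cockerham F_ST estimates downstream.  A small
fraction of loci can be "planted" at an elevated c to emulate selection
outliers, individuals carry within-population inbreeding F, and admixed hybrid
strains draw one allele from each of two parental populations, which produces
the excess heterozygosity (negative F) seen in hybrid dikaryons.

The model is deliberately locus-independent: no linkage disequilibrium beyond
positional thinning, no demographic history. It exists so every downstream
estimator can be tested against known truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, GroupAssignment, OUTLIER_LABEL

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_genotypes",
    "simulate_annotation",
    "simulate_phenotypes",
    "write_vcf",
    "write_tables",
    "default_group_assignment",
]

#: The 13 agronomic traits measured on shiitake strains: days to primordium
#: (FP) and first harvest (FB), pileus diameter/thickness/weight, stipe
#: length/diameter/weight, number and unit weight of fruiting bodies, yield
#: per bag, and mycelial growth rates on MYG agar and sawdust.
TRAIT_NAMES = (
    "FP", "FB", "PD", "PT", "PW", "SL", "SD", "SW", "NF", "WF", "Y",
    "DGR-myg", "DGR-sd",
)

_GROUP_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

# Default per-group trait shifts (in units of the trait noise SD, sigma=1):
# clear group separation for most traits, none for NF and SL, mirroring a
# design in which nearly all traits are stratified by population structure.
def _default_phenotype_effects(n_populations: int) -> dict[str, dict[str, float]]:
    effects: dict[str, dict[str, float]] = {}
    for k in range(n_populations):
        label = _GROUP_LABELS[k]
        effects[label] = {
            t: (0.0 if t in ("NF", "SL") else 3.0 * (k - (n_populations - 1) / 2))
            for t in TRAIT_NAMES
        }
    return effects


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the structure of the Chinese shiitake resequencing
    cohort this toolkit was built around: three populations of 26/6/26
    dikaryotic strains plus two admixed hybrids (60 strains total), baseline
    pairwise divergence in the 0.23-0.33 F_ST range, strong within-population
    inbreeding in the two cultivar-influenced groups, and ~6 SNPs/kb density.
    """

    n_populations: int = 3
    strains_per_population: tuple[int, ...] = (26, 6, 26)
    n_loci: int = 20_000
    scaffold_layout: tuple[tuple[str, int], ...] = tuple(
        (f"scaffold_{i + 1}", 400_000) for i in range(8)
    )
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    # Per-population Balding-Nichols c chosen so the three pairwise
    # Weir-Cockerham F_ST values land near 0.33 / 0.31 / 0.23.
    baseline_divergence: tuple[float, ...] = (0.40, 0.25, 0.22)
    outlier_fraction: float = 0.0
    outlier_divergence: float = 0.6
    inbreeding: tuple[float, ...] = (0.39, 0.45, 0.20)
    n_hybrids: int = 2
    hybrid_parents: tuple[int, int] = (0, 2)
    maf_floor: float = 0.05
    n_genes: int = 800
    gene_length: int = 1_500
    missense_rate: float = 0.3
    n_go_terms: int = 50
    n_enriched_terms: int = 2
    phenotype_effects: dict[str, dict[str, float]] | None = None
    phenotype_noise_sd: float = 1.0
    phenotype_missing_rate: float = 0.02
    seed: int = 0

    max_redraws: int = 100

    def __post_init__(self) -> None:
        self.strains_per_population = tuple(self.strains_per_population)
        self.baseline_divergence = tuple(self.baseline_divergence)
        self.inbreeding = tuple(self.inbreeding)
        self.scaffold_layout = tuple((str(s), int(l)) for s, l in self.scaffold_layout)
        if len(self.strains_per_population) != self.n_populations:
            raise ValueError("strains_per_population length != n_populations")
        if len(self.baseline_divergence) != self.n_populations:
            raise ValueError("baseline_divergence length != n_populations")
        if len(self.inbreeding) != self.n_populations:
            raise ValueError("inbreeding length != n_populations")
        for c in (*self.baseline_divergence, self.outlier_divergence):
            if not 0.0 < c < 1.0:
                raise ValueError(f"divergence parameter c={c} outside (0, 1)")
        if self.outlier_fraction and self.outlier_divergence <= max(
            self.baseline_divergence
        ):
            raise ValueError("outlier_divergence must exceed every baseline c")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction outside [0, 1)")
        for f in self.inbreeding:
            if not -1.0 < f < 1.0:
                raise ValueError(f"inbreeding F={f} outside (-1, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("ancestral_freq_range must be within [0, 1]")
        if self.n_hybrids and (
            max(self.hybrid_parents) >= self.n_populations
            or self.hybrid_parents[0] == self.hybrid_parents[1]
        ):
            raise ValueError("hybrid_parents must name two distinct populations")
        total_length = sum(l for _, l in self.scaffold_layout)
        if self.n_loci > total_length:
            raise ValueError("more loci than base pairs in scaffold_layout")

    @property
    def n_strains(self) -> int:
        return sum(self.strains_per_population) + self.n_hybrids

    @property
    def group_labels(self) -> tuple[str, ...]:
        return _GROUP_LABELS[: self.n_populations]

    def rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the global seed."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=(sum(ord(ch) for ch in stage), len(stage))
        )
        return np.random.default_rng(ss)


@dataclass
class TruthTable:
    """Ground truth recorded during simulation, for parameter-recovery tests."""

    loci: pd.DataFrame  # scaffold, pos, p_anc, p_<group>..., is_outlier
    strains: pd.DataFrame  # strain, population, is_hybrid
    genes: pd.DataFrame | None = None  # gene_id, scaffold, start, end, go terms
    enriched_terms: tuple[str, ...] = ()

    def assignment(self) -> GroupAssignment:
        labels = {
            row.strain: (OUTLIER_LABEL if row.is_hybrid else row.population)
            for row in self.strains.itertuples()
        }
        return GroupAssignment(labels=labels)


def default_group_assignment(config: SimulationConfig) -> GroupAssignment:
    labels: dict[str, str] = {}
    i = 0
    for k, size in enumerate(config.strains_per_population):
        for _ in range(size):
            labels[f"S{i:03d}"] = config.group_labels[k]
            i += 1
    for _ in range(config.n_hybrids):
        labels[f"S{i:03d}"] = OUTLIER_LABEL
        i += 1
    return GroupAssignment(labels=labels)


def _place_loci(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distribute loci over scaffolds proportionally to length, sorted by pos."""
    names = [s for s, _ in config.scaffold_layout]
    lengths = np.array([l for _, l in config.scaffold_layout], dtype=float)
    counts = np.floor(config.n_loci * lengths / lengths.sum()).astype(int)
    # hand out the remainder to the longest scaffolds first
    for i in np.argsort(-lengths)[: config.n_loci - counts.sum()]:
        counts[i] += 1
    frames = []
    for name, length, count in zip(names, lengths.astype(int), counts):
        pos = np.sort(rng.choice(length, size=count, replace=False)) + 1
        frames.append(pd.DataFrame({"scaffold": name, "pos": pos}))
    return pd.concat(frames, ignore_index=True)


def _genotype_probs(p: np.ndarray, f: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inbreeding-adjusted Hardy-Weinberg genotype probabilities for alt freq p."""
    het = 2.0 * p * (1.0 - p) * (1.0 - f)
    hom_alt = p * p + f * p * (1.0 - p)
    hom_ref = (1.0 - p) ** 2 + f * p * (1.0 - p)
    return hom_ref, het, hom_alt


def _draw_panel(
    p_anc: np.ndarray,
    c_loci: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-population frequencies and all genotypes for a block of loci.

    Returns (pop_freqs with shape (n_pops, n_loci), dosages (n_strains, n_loci)).
    """
    n_loci = p_anc.size
    n_pops = config.n_populations
    pop_freq = np.empty((n_pops, n_loci))
    for j in range(n_pops):
        c = np.where(
            c_loci > 0, c_loci, config.baseline_divergence[j]
        )  # c_loci>0 marks planted outlier c
        with np.errstate(divide="ignore"):
            alpha = p_anc * (1.0 - c) / c
            beta = (1.0 - p_anc) * (1.0 - c) / c
        pop_freq[j] = rng.beta(np.maximum(alpha, 1e-12), np.maximum(beta, 1e-12))
    dosages = np.empty((config.n_strains, n_loci), dtype=np.int8)
    row = 0
    for j, size in enumerate(config.strains_per_population):
        hom_ref, het, _ = _genotype_probs(pop_freq[j], config.inbreeding[j])
        u = rng.random((size, n_loci))
        dosages[row : row + size] = (u >= hom_ref).astype(np.int8) + (
            u >= hom_ref + het
        ).astype(np.int8)
        row += size
    pa, pb = config.hybrid_parents
    for _ in range(config.n_hybrids):
        allele_a = rng.random(n_loci) < pop_freq[pa]
        allele_b = rng.random(n_loci) < pop_freq[pb]
        dosages[row] = allele_a.astype(np.int8) + allele_b.astype(np.int8)
        row += 1
    return pop_freq, dosages


def simulate_genotypes(config: SimulationConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Draw the full genotype panel plus its ground-truth table.

    Loci whose cohort-wide minor allele frequency falls below
    ``config.maf_floor`` are redrawn in place (same position, new frequencies
    and genotypes), up to ``config.max_redraws`` attempts; exhaustion raises
    with the offending locus index rather than silently dropping the locus.
    """
    rng = config.rng("genotypes")
    loci = _place_loci(config, rng)
    n_loci = len(loci)
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    n_outliers = int(round(config.outlier_fraction * n_loci))
    is_outlier = np.zeros(n_loci, dtype=bool)
    if n_outliers:
        is_outlier[rng.choice(n_loci, size=n_outliers, replace=False)] = True
    c_loci = np.where(is_outlier, config.outlier_divergence, 0.0)

    pop_freq, dosages = _draw_panel(p_anc, c_loci, config, rng)
    # redraw loci failing the cohort-wide MAF floor
    for attempt in range(config.max_redraws):
        alt = dosages.sum(axis=0) / (2 * config.n_strains)
        bad = np.minimum(alt, 1 - alt) < config.maf_floor
        if not bad.any():
            break
        p_anc[bad] = rng.uniform(lo, hi, size=bad.sum())
        new_freq, new_dos = _draw_panel(p_anc[bad], c_loci[bad], config, rng)
        pop_freq[:, bad] = new_freq
        dosages[:, bad] = new_dos
    else:
        alt = dosages.sum(axis=0) / (2 * config.n_strains)
        bad = np.flatnonzero(np.minimum(alt, 1 - alt) < config.maf_floor)
        raise RuntimeError(
            f"MAF floor unmet after {config.max_redraws} redraws at loci {bad[:10]}"
        )

    assignment = default_group_assignment(config)
    strains = list(assignment.labels)
    ref, alt_allele = _draw_alleles(rng, n_loci)
    loci = loci.assign(ref=ref, alt=alt_allele)
    matrix = GenotypeMatrix(strains=strains, loci=loci, dosages=dosages)

    truth_loci = loci[["scaffold", "pos"]].copy()
    truth_loci["p_anc"] = p_anc
    for j, lab in enumerate(config.group_labels):
        truth_loci[f"p_{lab}"] = pop_freq[j]
    truth_loci["is_outlier"] = is_outlier
    truth_strains = pd.DataFrame(
        {
            "strain": strains,
            "population": [assignment.labels[s] for s in strains],
            "is_hybrid": [assignment.labels[s] == OUTLIER_LABEL for s in strains],
        }
    )
    return matrix, TruthTable(loci=truth_loci, strains=truth_strains)


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return bases[ref_idx], bases[alt_idx]


def simulate_annotation(
    config: SimulationConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay non-overlapping gene intervals and classify each SNP by effect.

    Returns ``(annotation, go_map)``: the annotation table has one row per
    locus (scaffold, pos, gene_id, effect in {synonymous_variant,
    missense_variant, intergenic}); the GO map has one (gene_id, term_id) row
    per assignment.  A configurable handful of "enriched" terms is attached
    preferentially to genes carrying missense SNPs private to one population,
    so that downstream over-representation tests have planted signal.

    Side effect: ``truth.genes`` and ``truth.enriched_terms`` are filled in.
    """
    rng = config.rng("annotation")
    layout = dict(config.scaffold_layout)
    lengths = np.array([l for _, l in config.scaffold_layout], dtype=float)
    capacity = (lengths // (2 * config.gene_length)).astype(int)
    if config.n_genes > capacity.sum():
        raise ValueError(
            f"{config.n_genes} genes do not fit on the scaffolds "
            f"(capacity {capacity.sum()} at gene_length={config.gene_length})"
        )
    counts = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    counts = np.minimum(counts, capacity)
    for i in np.argsort(-(capacity - counts))[: config.n_genes - counts.sum()]:
        counts[i] += 1

    gene_rows = []
    gid = 0
    for (name, length), count in zip(config.scaffold_layout, counts):
        if count == 0:
            continue
        # evenly spaced non-overlapping intervals with jitter
        slot = length // count
        for k in range(count):
            start = k * slot + 1 + int(rng.integers(0, max(slot - config.gene_length, 1)))
            end = min(start + config.gene_length - 1, length)
            gene_rows.append((f"gene_{gid:05d}", name, start, end))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "scaffold", "start", "end"])

    ann = truth.loci[["scaffold", "pos"]].copy()
    ann["gene_id"] = ""
    ann["effect"] = "intergenic"
    for scaf, sub in genes.groupby("scaffold"):
        mask = ann["scaffold"] == scaf
        pos = ann.loc[mask, "pos"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        gene_ids = sub["gene_id"].to_numpy()
        hit = np.where(inside, gene_ids[np.clip(idx, 0, len(gene_ids) - 1)], "")
        ann.loc[mask, "gene_id"] = hit
    genic = ann["gene_id"] != ""
    is_missense = genic & (rng.random(len(ann)) < config.missense_rate)
    ann.loc[genic, "effect"] = "synonymous_variant"
    ann.loc[is_missense, "effect"] = "missense_variant"

    # GO assignment: 1-5 terms per gene; enriched terms preferentially attach
    # to genes with group-private missense SNPs (judged from truth frequencies).
    terms = [f"GO:{i:07d}" for i in range(config.n_go_terms)]
    enriched = tuple(terms[: config.n_enriched_terms]) if config.n_go_terms > 1 else ()
    freq_cols = [f"p_{lab}" for lab in config.group_labels]
    freqs = truth.loci[freq_cols].to_numpy().T  # pops x loci
    # "private-ish": minor allele convincingly present in exactly one population
    present = (freqs > 0.1) & (freqs < 0.9)
    private = present.sum(axis=0) == 1
    target_genes = set(ann.loc[is_missense.to_numpy() & private, "gene_id"])

    go_rows = []
    background = terms[config.n_enriched_terms :] or terms
    for gene in genes["gene_id"]:
        k = int(rng.integers(1, 6))
        chosen = list(rng.choice(background, size=min(k, len(background)), replace=False))
        if enriched and gene in target_genes and rng.random() < 0.8:
            chosen[0] = str(rng.choice(enriched))
        elif enriched and rng.random() < 0.05:
            chosen[0] = str(rng.choice(enriched))
        for t in dict.fromkeys(chosen):
            go_rows.append((gene, t))
    go_map = pd.DataFrame(go_rows, columns=["gene_id", "term_id"])

    term_sets = go_map.groupby("gene_id")["term_id"].agg(lambda s: ";".join(sorted(s)))
    genes = genes.assign(go_terms=genes["gene_id"].map(term_sets).fillna(""))
    truth.genes = genes
    truth.enriched_terms = enriched
    return ann, go_map


def simulate_phenotypes(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Group-structured trait table: global mean + group shift + Gaussian noise.

    Hybrid strains receive the mean of their two parental groups' shifts.
    Values are masked missing-at-random at ``phenotype_missing_rate``.
    """
    rng = config.rng("phenotypes")
    effects = config.phenotype_effects or _default_phenotype_effects(config.n_populations)
    base = {t: 10.0 for t in TRAIT_NAMES}
    rows = []
    pa, pb = config.hybrid_parents
    hybrid_shift = {
        t: 0.5
        * (
            effects[config.group_labels[pa]][t]
            + effects[config.group_labels[pb]][t]
        )
        for t in TRAIT_NAMES
    }
    for rec in truth.strains.itertuples():
        shifts = hybrid_shift if rec.is_hybrid else effects[rec.population]
        noise = rng.normal(0.0, config.phenotype_noise_sd, size=len(TRAIT_NAMES))
        rows.append(
            [rec.strain]
            + [base[t] + shifts[t] + e for t, e in zip(TRAIT_NAMES, noise)]
        )
    table = pd.DataFrame(rows, columns=["strain"] + list(TRAIT_NAMES)).set_index(
        "strain"
    )
    if config.phenotype_missing_rate > 0:
        mask = rng.random(table.shape) < config.phenotype_missing_rate
        table = table.mask(mask)
    return table


# ---------------------------------------------------------------------------
# plain-text writers


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Emit a VCFv4.2 file with GT:DP per sample and QUAL populated.

    Depth is a fixed nominal 50 (the cohort's mean resequencing depth scale);
    the writer exists for round-tripping through the pipeline's reader, not
    for emulating sequencing noise.
    """
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mycopop-simulate\n")
        for scaf in matrix.loci["scaffold"].unique():
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.strains)
            + "\n"
        )
        dosages = matrix.dosages
        for i, rec in enumerate(matrix.loci.itertuples()):
            fields = [
                str(rec.scaffold),
                str(rec.pos),
                ".",
                str(rec.ref),
                str(rec.alt),
                "999",
                "PASS",
                ".",
                "GT:DP",
            ]
            fields += [f"{gt_strings[int(d)]}:50" for d in dosages[:, i]]
            fh.write("\t".join(fields) + "\n")


def write_tables(
    outdir: str | os.PathLike,
    *,
    annotation: pd.DataFrame | None = None,
    go_map: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    assignment: GroupAssignment | None = None,
    truth: TruthTable | None = None,
) -> dict[str, str]:
    """Write the tabular fixtures as TSV/CSV; returns {name: path}."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written: dict[str, str] = {}
    if annotation is not None:
        p = os.path.join(outdir, "annotation.tsv")
        annotation.to_csv(p, sep="\t", index=False)
        written["annotation"] = p
    if go_map is not None:
        p = os.path.join(outdir, "go_map.tsv")
        go_map.to_csv(p, sep="\t", index=False)
        written["go_map"] = p
    if phenotypes is not None:
        p = os.path.join(outdir, "phenotypes.csv")
        phenotypes.to_csv(p)
        written["phenotypes"] = p
    if assignment is not None:
        p = os.path.join(outdir, "groups.tsv")
        assignment.to_table().to_csv(p, sep="\t", index=False)
        written["groups"] = p
    if truth is not None:
        p = os.path.join(outdir, "truth_loci.tsv")
        truth.loci.to_csv(p, sep="\t", index=False)
        written["truth_loci"] = p
        p = os.path.join(outdir, "truth_strains.tsv")
        truth.strains.to_csv(p, sep="\t", index=False)
        written["truth_strains"] = p
    return written
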