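"""VCF input and the site-filtering / thinning front end of the pipeline.

Filtering follows the resequencing study's rules: drop sites with QUAL < 30
or mean depth < 5, then keep only biallelic SNPs with MAF >= 0.05 and no
missing genotype across the cohort.  LD reduction is positional: keep loci at
least 1,000 bp apart within each scaffold (greedy from the leftmost).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import MISSING, GenotypeMatrix, GroupAssignment

__all__ = [
    "VariantRecord",
    "read_vcf",
    "read_group_table",
    "filter_variants",
    "thin_by_distance",
    "subset_by_group",
    "group_snp_count",
]


@dataclass
class VariantRecord:
    """One VCF site: coordinates, alleles, QUAL, and per-sample GT dosage/DP."""

    scaffold: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    qual: float | None
    dosages: np.ndarray  # alt-allele count per sample; MISSING for no-call
    depths: np.ndarray  # per-sample DP; MISSING when absent

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position {self.pos} is not 1-based")
        if not self.alt:
            raise ValueError("alt allele list is empty")

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alt) == 1
            and len(self.ref) == 1
            and len(self.alt[0]) == 1
            and self.alt[0] in "ACGT"
            and self.ref in "ACGT"
        )


def read_vcf(path: str | os.PathLike) -> tuple[list[str], list[VariantRecord]]:
    """Read a VCFv4.x file into (sample names, records in file order).

    Missing genotypes are preserved as MISSING (-1); multiallelic records are
    kept (they are removed later by :func:`filter_variants`).  Mixed-ploidy
    (non-diploid) genotype entries are an error.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for line_no, v in enumerate(vcf, start=1):
        ploidy = v.ploidy
        if samples and ploidy != 2:
            raise ValueError(
                f"record {line_no} ({v.CHROM}:{v.POS}): ploidy {ploidy} is not diploid"
            )
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=np.int16)
        dosages = np.where(gt == 3, MISSING, gt).astype(np.int8)
        try:
            dp = v.format("DP")
        except Exception:
            dp = None
        if dp is None:
            depths = np.full(len(samples), MISSING, dtype=np.int32)
        else:
            depths = np.asarray(dp, dtype=np.int32).reshape(-1)
            depths = np.where(depths < 0, MISSING, depths)
        records.append(
            VariantRecord(
                scaffold=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=tuple(v.ALT),
                qual=v.QUAL,
                dosages=dosages,
                depths=depths,
            )
        )
    return samples, records


def read_group_table(path: str | os.PathLike) -> GroupAssignment:
    df = pd.read_csv(path, sep="\t")
    if not {"strain", "label"} <= set(df.columns):
        raise ValueError("group table needs columns: strain, label")
    return GroupAssignment.from_table(df)


def filter_variants(
    samples: list[str],
    records: list[VariantRecord],
    *,
    min_qual: float = 30.0,
    min_mean_depth: float = 5.0,
    min_maf: float = 0.05,
    require_complete: bool = True,
    biallelic_only: bool = True,
) -> GenotypeMatrix:
    """Apply all site filters and assemble the analysis-ready matrix.

    A record is retained iff it passes every enabled check: biallelic SNP,
    QUAL >= min_qual, mean DP over non-missing samples >= min_mean_depth, no
    missing genotype (when require_complete), and allele-count MAF >= min_maf
    (computed over 2N called alleles; the >= is inclusive).
    """
    if not samples:
        raise ValueError("no samples")
    kept_rows = []
    kept_dosages = []
    for rec in records:
        if biallelic_only and not rec.is_biallelic_snp:
            continue
        if rec.qual is not None and rec.qual < min_qual:
            continue
        called_dp = rec.depths[rec.depths != MISSING]
        if min_mean_depth > 0 and called_dp.size:
            if called_dp.mean() < min_mean_depth:
                continue
        called = rec.dosages != MISSING
        if require_complete and not called.all():
            continue
        n_alleles = 2 * int(called.sum())
        if n_alleles == 0:
            continue
        p = rec.dosages[called].sum() / n_alleles
        if min(p, 1.0 - p) < min_maf:
            continue
        kept_rows.append((rec.scaffold, rec.pos, rec.ref, rec.alt[0]))
        kept_dosages.append(rec.dosages)
    if not kept_rows:
        warnings.warn("no variants survived filtering; returning empty matrix")
        loci = pd.DataFrame(columns=["scaffold", "pos", "ref", "alt"])
        return GenotypeMatrix(
            strains=list(samples),
            loci=loci,
            dosages=np.empty((len(samples), 0), dtype=np.int8),
        )
    loci = pd.DataFrame(kept_rows, columns=["scaffold", "pos", "ref", "alt"])
    dosages = np.stack(kept_dosages, axis=1)
    return GenotypeMatrix(strains=list(samples), loci=loci, dosages=dosages)


def thin_by_distance(matrix: GenotypeMatrix, min_bp: int = 1000) -> GenotypeMatrix:
    """Greedy per-scaffold positional thinning.

    Keep the first (leftmost) locus of each scaffold; keep each subsequent
    locus iff its position is >= min_bp beyond the last kept position.
    Input must be sorted by (scaffold, pos).
    """
    scaf = matrix.loci["scaffold"].to_numpy()
    pos = matrix.loci["pos"].to_numpy()
    for i in range(1, len(pos)):
        if scaf[i] == scaf[i - 1] and pos[i] < pos[i - 1]:
            raise ValueError(
                f"loci not sorted by position within scaffold {scaf[i]} at index {i}"
            )
    keep = []
    last_scaf = None
    last_pos = None
    for i in range(len(pos)):
        if scaf[i] != last_scaf or pos[i] - last_pos >= min_bp:
            keep.append(i)
            last_scaf = scaf[i]
            last_pos = pos[i]
    return matrix.take_loci(np.array(keep, dtype=int))


def _group_segregating(
    matrix: GenotypeMatrix, assignment: GroupAssignment, group: str, rule: str
) -> np.ndarray:
    """Boolean mask of loci "detected" in the group under the membership rule.

    rule="polymorphic": both alleles observed among the group's strains.
    rule="alt_present": at least one alternate allele observed.
    """
    members = assignment.members(group)
    if not members:
        raise ValueError(f"group {group!r} has no strains")
    idx = [matrix.strains.index(s) for s in members]
    sub = matrix.dosages[idx, :]
    called = sub != MISSING
    alt = np.where(called, sub, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    if rule == "polymorphic":
        return (alt > 0) & (alt < total)
    if rule == "alt_present":
        return alt > 0
    raise ValueError(f"unknown membership rule {rule!r}")


def subset_by_group(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    group: str,
    rule: str = "polymorphic",
) -> GenotypeMatrix:
    """Matrix of the group's strains at loci detected within that group."""
    mask = _group_segregating(matrix, assignment, group, rule)
    members = assignment.members(group)
    return matrix.take_strains(members).take_loci(np.flatnonzero(mask))


def group_snp_count(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    group: str,
    rule: str = "polymorphic",
) -> int:
    """Number of loci detected in the group (see membership rules above)."""
    return int(_group_segregating(matrix, assignment, group, rule).sum())
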