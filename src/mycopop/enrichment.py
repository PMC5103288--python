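"""Group-specific SNPs, missense gene sets, and GO over-representation.

A "group-specific" SNP is one detected (segregating, by the pipeline's
membership rule) in exactly one of the non-outlier groups.  Missense SNPs
among them define per-group gene sets, which are tested for GO-term
over-representation with a one-sided Fisher (hypergeometric tail) test
against the background of all genes carrying at least one analyzed SNP.
The accompanying effect size is log2 of the in-set versus background term
frequency ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import GenotypeMatrix, GroupAssignment
from .variant_io import _group_segregating

__all__ = [
    "group_specific_snps",
    "GeneSet",
    "missense_gene_sets",
    "fisher_enrichment",
    "log_odds",
    "snp_background_genes",
]


def group_specific_snps(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    rule: str = "polymorphic",
) -> dict[str, np.ndarray]:
    """Per-group boolean masks of loci detected in that group only.

    The masks are pairwise disjoint by construction: a locus detected in two
    or more groups belongs to none of the specific sets.
    """
    groups = assignment.groups()
    detected = np.stack(
        [_group_segregating(matrix, assignment, g, rule) for g in groups]
    )
    n_detected = detected.sum(axis=0)
    return {g: detected[k] & (n_detected == 1) for k, g in enumerate(groups)}


@dataclass
class GeneSet:
    """Genes hit by a group's specific missense SNPs."""

    group: str
    genes: tuple[str, ...]
    n_snps: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("genes within a set must be unique")


def missense_gene_sets(
    specific: dict[str, np.ndarray],
    matrix: GenotypeMatrix,
    annotation: pd.DataFrame,
) -> dict[str, GeneSet]:
    """Filter each specific set to missense SNPs and collect their genes."""
    ann = matrix.loci[["scaffold", "pos"]].merge(
        annotation, on=["scaffold", "pos"], how="left"
    )
    missense = (ann["effect"] == "missense_variant").to_numpy()
    gene_ids = ann["gene_id"].fillna("").to_numpy()
    out: dict[str, GeneSet] = {}
    for g, mask in specific.items():
        hit = mask & missense & (gene_ids != "")
        genes = tuple(dict.fromkeys(gene_ids[hit]))  # dedupe, keep order
        out[g] = GeneSet(group=g, genes=genes, n_snps=int(hit.sum()))
    return out


def snp_background_genes(matrix: GenotypeMatrix, annotation: pd.DataFrame) -> list[str]:
    """All genes carrying >= 1 analyzed SNP (the enrichment background)."""
    ann = matrix.loci[["scaffold", "pos"]].merge(
        annotation, on=["scaffold", "pos"], how="left"
    )
    genes = ann["gene_id"].fillna("")
    return sorted(set(genes[genes != ""]))


def log_odds(k: int, n: int, K: int, N: int) -> float:
    """log2((k/n) / (K/N)); NaN (flagged undefined) when k = 0 or K = 0."""
    if k == 0 or K == 0 or n == 0 or N == 0:
        return float("nan")
    return float(np.log2((k / n) / (K / N)))


def fisher_enrichment(
    gene_set: GeneSet,
    go_map: pd.DataFrame,
    background: list[str],
    bh_column: bool = True,
) -> pd.DataFrame:
    """One-sided over-representation test per GO term.

    For a term annotating K of the N background genes and k of the n set
    genes, p = P[X >= k] with X ~ Hypergeom(N, K, n).  Rows are sorted by p
    and starred at 0.05 / 0.01.  A Benjamini-Hochberg ``bh_fdr`` column is
    appended as an optional extra (not part of the star calls).
    """
    bg = set(background)
    missing = [g for g in gene_set.genes if g not in bg]
    if missing:
        raise ValueError(f"set genes absent from background: {missing[:5]}")
    N = len(bg)
    n = len(gene_set.genes)
    set_genes = set(gene_set.genes)
    term_genes = (
        go_map[go_map["gene_id"].isin(bg)].groupby("term_id")["gene_id"].agg(set)
    )
    rows = []
    for term, genes in term_genes.items():
        K = len(genes)
        k = len(genes & set_genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": min(p, 1.0),
                "log2_odds": log_odds(k, n, K, N),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "n", "K", "N", "p_value", "log2_odds"]
    ).sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    out["stars"] = np.select(
        [out["p_value"] < 0.01, out["p_value"] < 0.05], ["**", "*"], default=""
    )
    if bh_column and len(out):
        m = len(out)
        ranked = out["p_value"].to_numpy() * m / np.arange(1, m + 1)
        out["bh_fdr"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    return out
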