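"""Core in-memory containers shared across the pipeline.

The central object is :class:`GenotypeMatrix`: strains x biallelic loci with
alternate-allele dosage coding (0, 1, 2; -1 for missing before filtering).
Dikaryotic strains are represented as diploid genotype calls, matching how
resequencing VCFs code them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Locus table columns required by GenotypeMatrix
LOCUS_COLUMNS = ("scaffold", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Strains x loci dosage matrix with locus coordinates.

    Parameters
    ----------
    strains
        Sample names, one per matrix row.
    loci
        DataFrame with columns ``scaffold, pos, ref, alt`` (1-based inclusive
        positions, VCF convention), one row per matrix column.
    dosages
        ``(n_strains, n_loci)`` integer array of alternate-allele counts
        in {0, 1, 2}; ``-1`` marks a missing call.
    """

    strains: list[str]
    loci: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.strains), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.strains)} strains x {len(self.loci)} loci"
            )
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise ValueError(f"loci table lacks columns: {sorted(missing_cols)}")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def alt_freq(self) -> np.ndarray:
        """Per-locus alternate-allele frequency over called alleles (2 per strain)."""
        called = self.dosages != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, self.dosages, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the loci at positional ``index`` (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            strains=list(self.strains),
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def take_strains(self, names: list[str]) -> "GenotypeMatrix":
        order = [self.strains.index(n) for n in names]
        return GenotypeMatrix(
            strains=list(names),
            loci=self.loci.copy(),
            dosages=self.dosages[order, :],
        )

    def locus_keys(self) -> pd.Index:
        """(scaffold, pos) MultiIndex identifying each locus."""
        return pd.MultiIndex.from_frame(self.loci[["scaffold", "pos"]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and self.loci[list(LOCUS_COLUMNS)].equals(other.loci[list(LOCUS_COLUMNS)])
            and np.array_equal(self.dosages, other.dosages)
        )


OUTLIER_LABEL = "outlier"


@dataclass
class GroupAssignment:
    """Strain -> population label (e.g. "I", "II", "III", or "outlier").

    The "outlier" label marks admixed/hybrid strains that are excluded from
    all between-group analyses.
    """

    labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GroupAssignment":
        return cls(labels=dict(zip(df["strain"].astype(str), df["label"].astype(str))))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain": list(self.labels), "label": list(self.labels.values())}
        )

    def groups(self, include_outliers: bool = False) -> list[str]:
        """Distinct non-outlier group labels in first-appearance order."""
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen and (include_outliers or lab != OUTLIER_LABEL):
                seen.append(lab)
        return seen

    def members(self, group: str) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == group]

    def validate(self, strains: list[str]) -> None:
        missing = [s for s in strains if s not in self.labels]
        if missing:
            raise ValueError(f"strains without a group label: {missing[:5]}")
        if len(self.groups()) < 2:
            raise ValueError("need >= 2 non-outlier groups for divergence analyses")
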