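"""Windowed diversity statistics, per-strain heterozygosity, and AMOVA.

Conventions:

* Site diversity uses the unbiased pairwise estimator over the 2N called
  alleles, pi_site = 2*p*(1-p) * 2N/(2N-1).
* Window pi is the sum of site pi divided by the window length in bp
  (per-bp diversity, the VCFtools ``--window-pi`` convention), on 5-kb
  non-overlapping windows tiled from position 1.
* Tajima's D uses the standard 1989 normalizing constants with n = 2N
  sampled alleles; it is undefined (NaN) when a window has no segregating
  site.
* The inbreeding coefficient is the observed-vs-expected homozygosity form
  F = (O_hom - E_hom)/(L - E_hom) with the expectation taken from the
  pooled allele frequencies of the cohort the matrix contains.
* AMOVA treats each diploid strain as two allele-observations and partitions
  the total sum of squares (summed over loci) into among-population,
  among-strain-within-population, and within-strain levels, solving the
  standard hierarchical moment equations for the variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, GroupAssignment, OUTLIER_LABEL

__all__ = [
    "site_pi",
    "window_pi",
    "window_tajima_d",
    "tajima_d",
    "strain_het",
    "snp_class_ratios",
    "AmovaTable",
    "amova",
    "amova_components_from_ss",
    "window_bounds",
]

WINDOW_SIZE = 5000


def site_pi(dosages: np.ndarray) -> float:
    """Per-site pairwise diversity over the called alleles at one locus.

    Equal to (# differing pairs)/(# pairs) among the 2N alleles, i.e.
    2*p*(1-p)*2N/(2N-1).
    """
    d = np.asarray(dosages)
    called = d != MISSING
    n = 2 * int(called.sum())
    if n < 2:
        return 0.0
    alt = int(d[called].sum())
    p = alt / n
    return 2.0 * p * (1.0 - p) * n / (n - 1.0)


def _site_pi_vector(matrix: GenotypeMatrix) -> np.ndarray:
    called = matrix.dosages != MISSING
    n = 2 * called.sum(axis=0)
    alt = np.where(called, matrix.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        pi = np.where(n >= 2, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0), 0.0)
    return pi


def window_bounds(pos: np.ndarray, window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Window index per position and the number of windows covering max(pos)."""
    idx = (np.asarray(pos) - 1) // window_size
    n_windows = int(idx.max()) + 1 if len(idx) else 0
    return idx.astype(int), n_windows


def _tile_windows(
    matrix: GenotypeMatrix, window_size: int, per_site: np.ndarray, seg: np.ndarray
) -> pd.DataFrame:
    """Aggregate per-site values into tiled windows (one row per window)."""
    rows = []
    loci = matrix.loci
    for scaf, sub in loci.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        sub_idx = sub.index.to_numpy()
        widx, n_windows = window_bounds(pos, window_size)
        for w in range(n_windows):
            in_w = sub_idx[widx == w]
            rows.append(
                {
                    "scaffold": scaf,
                    "start": w * window_size + 1,
                    "end": (w + 1) * window_size,
                    "n_sites": len(in_w),
                    "pi_sum": float(per_site[in_w].sum()),
                    "n_seg": int(seg[in_w].sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "n_sites", "pi_sum", "n_seg"]
    )


def window_pi(matrix: GenotypeMatrix, window_size: int = WINDOW_SIZE) -> pd.DataFrame:
    """Per-bp nucleotide diversity in non-overlapping windows.

    Returns a DataFrame (scaffold, start, end, n_sites, pi); windows with no
    site report pi = 0.
    """
    per_site = _site_pi_vector(matrix)
    seg = per_site > 0
    win = _tile_windows(matrix, window_size, per_site, seg)
    win["pi"] = win["pi_sum"] / window_size
    return win[["scaffold", "start", "end", "n_sites", "pi"]]


def _tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled alleles."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajima_d(pi_sum: float, n_seg: int, n_alleles: int) -> float:
    """Tajima's D for one window from its summed pairwise diversity and S.

    NaN when S = 0 (undefined).  Refuses n_alleles < 4, where the variance
    constants degenerate.
    """
    if n_alleles < 4:
        raise ValueError(f"Tajima's D needs >= 4 sampled alleles, got {n_alleles}")
    if n_seg == 0:
        return float("nan")
    k = _tajima_constants(n_alleles)
    var = k["e1"] * n_seg + k["e2"] * n_seg * (n_seg - 1.0)
    return (pi_sum - n_seg / k["a1"]) / np.sqrt(var)


def window_tajima_d(
    matrix: GenotypeMatrix, window_size: int = WINDOW_SIZE
) -> pd.DataFrame:
    """Windowed Tajima's D (and pi) with n = 2N alleles per window.

    Returns (scaffold, start, end, n_sites, pi, tajima_d); D is NaN where a
    window has no segregating site.
    """
    n_alleles = 2 * matrix.n_strains
    per_site = _site_pi_vector(matrix)
    seg = per_site > 0
    win = _tile_windows(matrix, window_size, per_site, seg)
    win["pi"] = win["pi_sum"] / window_size
    win["tajima_d"] = [
        tajima_d(row.pi_sum, row.n_seg, n_alleles) for row in win.itertuples()
    ]
    return win[["scaffold", "start", "end", "n_sites", "pi", "tajima_d"]]


def strain_het(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-strain heterozygous/homozygous locus counts and inbreeding F.

    F = (O_hom - E_hom)/(L - E_hom), with E_hom summed over loci from the
    pooled allele frequencies of the strains in ``matrix`` (pass a subset
    matrix to estimate F within a group).
    """
    d = matrix.dosages
    called = d != MISSING
    het = (d == 1).sum(axis=1)
    hom = ((d == 0) | (d == 2)).sum(axis=1)
    n = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        exp_het_site = np.where(
            n >= 2, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1.0), 0.0
        )
    e_hom = float((1.0 - exp_het_site).sum())
    L = matrix.n_loci
    rows = []
    for i, strain in enumerate(matrix.strains):
        denom = L - e_hom
        f = (hom[i] - e_hom) / denom if denom != 0 else float("nan")
        rows.append({"strain": strain, "n_het": int(het[i]), "n_hom": int(hom[i]),
                     "expected_hom": e_hom, "F": f})
    return pd.DataFrame(rows)


def snp_class_ratios(
    matrix: GenotypeMatrix,
    annotation: pd.DataFrame,
    assignment: GroupAssignment | None = None,
    rule: str = "polymorphic",
) -> pd.DataFrame:
    """SNP effect-class counts and ratios, overall and (optionally) per group.

    Reports intragenic/total and missense/synonymous as decimal ratios
    rounded to 3 places; a zero synonymous count yields NaN with a warning.
    """
    from .variant_io import _group_segregating

    ann = matrix.loci[["scaffold", "pos"]].merge(
        annotation, on=["scaffold", "pos"], how="left"
    )
    effect = ann["effect"].fillna("intergenic").to_numpy()
    intragenic = effect != "intergenic"
    missense = effect == "missense_variant"
    synonymous = effect == "synonymous_variant"

    scopes: list[tuple[str, np.ndarray]] = [
        ("all", np.ones(matrix.n_loci, dtype=bool))
    ]
    if assignment is not None:
        for g in assignment.groups():
            scopes.append((g, _group_segregating(matrix, assignment, g, rule)))

    rows = []
    for name, mask in scopes:
        total = int(mask.sum())
        n_intra = int((mask & intragenic).sum())
        n_mis = int((mask & missense).sum())
        n_syn = int((mask & synonymous).sum())
        if n_syn == 0:
            warnings.warn(f"scope {name!r}: zero synonymous SNPs; ratio undefined")
        rows.append(
            {
                "scope": name,
                "n_snps": total,
                "n_intragenic": n_intra,
                "n_missense": n_mis,
                "n_synonymous": n_syn,
                "intragenic_ratio": round(n_intra / total, 3) if total else float("nan"),
                "missense_synonymous_ratio": (
                    round(n_mis / n_syn, 3) if n_syn else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AmovaTable:
    """Three-level AMOVA with the conventional rows plus a total line."""

    table: pd.DataFrame  # source, df, SS, MS, variance, percent

    SOURCES = (
        "Among populations",
        "Among strains within populations",
        "Within individual strains",
    )

    @classmethod
    def from_components(
        cls, ss: tuple[float, float, float], df: tuple[int, int, int],
        vc: tuple[float, float, float],
    ) -> "AmovaTable":
        ms = tuple(s / d for s, d in zip(ss, df))
        total_vc = sum(vc)
        rows = []
        for src, d, s, m, v in zip(cls.SOURCES, df, ss, ms, vc):
            pct = 100.0 * v / total_vc if total_vc != 0 else float("nan")
            rows.append({"source": src, "df": d, "SS": s, "MS": m,
                         "variance": v, "percent": pct})
        rows.append(
            {
                "source": "Total",
                "df": sum(df),
                "SS": sum(ss),
                "MS": sum(ss) / sum(df),
                "variance": total_vc,
                "percent": 100.0 if total_vc != 0 else float("nan"),
            }
        )
        if any(v < 0 for v in vc):
            warnings.warn("negative AMOVA variance component (reported as-is)")
        return cls(table=pd.DataFrame(rows))

    def variance_components(self) -> tuple[float, float, float]:
        return tuple(self.table["variance"].iloc[:3])

    def percents(self) -> tuple[float, float, float]:
        return tuple(self.table["percent"].iloc[:3])


def amova_components_from_ss(
    ss: tuple[float, float, float],
    df: tuple[int, int, int],
    population_sizes: tuple[int, ...],
    observations_per_strain: int = 2,
) -> AmovaTable:
    """Solve the hierarchical moment equations from printed SS/df.

    ``ss``/``df`` are ordered (among populations, among strains within
    populations, within strains); population sizes are in strains, each
    contributing ``observations_per_strain`` allele-observations.  The
    expected mean squares are::

        E[MS_within] = s2_w
        E[MS_strain] = s2_w + 2 s2_s
        E[MS_pop]    = s2_w + 2 s2_s + n0 s2_p,
        n0 = (A - sum(A_k^2)/A) / (P - 1)

    over allele-observation counts A_k = 2 * n_k.
    """
    ms = tuple(s / d for s, d in zip(ss, df))
    ms_pop, ms_strain, ms_within = ms
    a_k = np.array(population_sizes, dtype=float) * observations_per_strain
    A = a_k.sum()
    P = len(a_k)
    n0 = (A - (a_k**2).sum() / A) / (P - 1)
    s2_w = ms_within
    s2_s = (ms_strain - ms_within) / observations_per_strain
    s2_p = (ms_pop - ms_strain) / n0
    return AmovaTable.from_components(ss, df, (s2_p, s2_s, s2_w))


def amova(matrix: GenotypeMatrix, assignment: GroupAssignment) -> AmovaTable:
    """Allele-based hierarchical AMOVA over all loci.

    Each strain contributes two allele-observations per locus (alt-allele
    indicators; a heterozygote is one 0 and one 1).  Sums of squares are
    accumulated over loci at the three levels, and components follow from
    :func:`amova_components_from_ss`.  Strains labeled "outlier" are
    excluded; every population must be non-empty.
    """
    groups = assignment.groups()
    members = {g: assignment.members(g) for g in groups}
    for g, m in members.items():
        if len(m) == 0:
            raise ValueError(f"population {g!r} has no strains")
    keep = [s for g in groups for s in members[g]]
    sub = matrix.take_strains(keep)
    labels = np.array([assignment.labels[s] for s in keep])
    d = sub.dosages.astype(float)
    if (d == MISSING).any():
        raise ValueError("AMOVA requires a complete (no-missing) matrix")

    N = len(keep)
    P = len(groups)
    strain_mean = d / 2.0  # per strain x locus
    grand_mean = d.mean(axis=0) / 2.0
    # within-strain SS: heterozygote contributes (0-.5)^2+(1-.5)^2 = 0.5
    ss_within = 0.5 * float((d == 1).sum())
    ss_strain = 0.0
    ss_pop = 0.0
    sizes = []
    for g in groups:
        mask = labels == g
        sizes.append(int(mask.sum()))
        pop_mean = strain_mean[mask].mean(axis=0)
        ss_strain += float(2.0 * ((strain_mean[mask] - pop_mean) ** 2).sum())
        ss_pop += float(2.0 * mask.sum() * ((pop_mean - grand_mean) ** 2).sum())
    df = (P - 1, N - P, N)
    return amova_components_from_ss(
        (ss_pop, ss_strain, ss_within), df, tuple(sizes)
    )
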