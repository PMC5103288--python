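"""Phenotype normalization, group summaries, and trait/strain clustering.

Each trait is min-max normalized over its non-missing values,
value' = (P - min)/(max - min), so every trait lives on [0, 1].  Strains and
traits are then clustered by complete linkage on Euclidean distances (the
standard two-way heatmap layout for agronomic trait panels); missing values
are imputed with the trait mean for clustering only, and imputed cells are
flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import complete, leaves_list
from scipy.spatial.distance import pdist

__all__ = ["normalize", "cluster", "group_summary", "linkage_to_newick"]


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each trait column to [0, 1] over non-missing values.

    Missing entries stay missing.  A constant trait (max == min) maps to all
    zeros with a warning.
    """
    out = table.copy().astype(float)
    for col in out.columns:
        vals = out[col]
        if vals.notna().sum() == 0:
            raise ValueError(f"trait {col!r} has no non-missing value")
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn(f"trait {col!r} is constant; normalized to 0")
            out[col] = vals.where(vals.isna(), 0.0)
        else:
            out[col] = (vals - lo) / (hi - lo)
    return out


def _ordered_linkage(data: np.ndarray, labels: list[str]):
    """Complete-linkage on Euclidean distances with label-order tie stability."""
    dist = pdist(data, metric="euclidean")
    return complete(dist)


def cluster(
    table_normalized: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Two-way complete-linkage clustering of a normalized trait table.

    Missing entries are imputed with the trait mean (clustering only); the
    returned ``imputed`` frame flags those cells.  Returns
    ``(strain_linkage, trait_linkage, ordered_table, imputed_flags)`` where
    the linkages are scipy linkage matrices and ``ordered_table`` is the
    input reordered by both dendrograms' leaf orders.
    """
    values = table_normalized.to_numpy(dtype=float)
    imputed = table_normalized.isna()
    if imputed.any().any():
        col_means = np.nanmean(values, axis=0)
        fill = np.where(np.isnan(values), col_means[None, :], values)
    else:
        fill = values
    strains = list(table_normalized.index)
    traits = list(table_normalized.columns)
    strain_linkage = _ordered_linkage(fill, strains)
    trait_linkage = _ordered_linkage(fill.T, traits)
    row_order = leaves_list(strain_linkage)
    col_order = leaves_list(trait_linkage)
    ordered = table_normalized.iloc[row_order, col_order]
    return strain_linkage, trait_linkage, ordered, imputed


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with heights."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node = n + k
        newick[node] = f"({newick[a]}:{la:g},{newick[b]}:{lb:g})"
        heights[node] = h
    return newick[n + len(linkage) - 1] + ";"


def group_summary(table: pd.DataFrame, assignment) -> pd.DataFrame:
    """Mean/SD/count per (group, trait) over non-missing values.

    SD is NaN (flagged) for single-observation cells.
    """
    labels = pd.Series(
        {s: assignment.labels.get(s, "unassigned") for s in table.index}
    )
    rows = []
    for group in dict.fromkeys(labels):
        sub = table.loc[labels[table.index] == group]
        for trait in table.columns:
            vals = sub[trait].dropna()
            rows.append(
                {
                    "group": group,
                    "trait": trait,
                    "n": len(vals),
                    "mean": vals.mean() if len(vals) else float("nan"),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
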