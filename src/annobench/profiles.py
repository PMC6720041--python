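"""Cluster-average expression profiles and expression thresholding.

The test-side input to every scoring method is the cluster profile matrix:
for each gene x and cell cluster y, the arithmetic mean of raw counts over
all cells assigned to y.  No normalisation, log transform or library-size
scaling is applied — averaging raw counts is the whole contract.

Over-representation analysis additionally needs a discrete "expressed genes"
list per cluster; :func:`top_fraction_genes` produces it by keeping, per
column, the top fraction of genes by value (default 5%), with a deterministic
tie rule at the cutoff.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["average_profiles", "top_fraction_genes", "top_k_column"]


def average_profiles(cells: pd.DataFrame, assign: Mapping[str, str]) -> pd.DataFrame:
    """Build the cluster-average matrix from cell-level counts.

    Parameters
    ----------
    cells
        Genes x cells raw count matrix.
    assign
        Mapping cell-id -> cluster-id.  Every assigned cell must be a column
        of ``cells``; cells present in the matrix but absent from the mapping
        are dropped (a count is logged).

    Returns
    -------
    Genes x clusters matrix of per-cluster arithmetic means of raw counts,
    cluster columns in first-seen assignment order.
    """
    missing = [c for c in assign if c not in cells.columns]
    if missing:
        raise ValueError(f"{len(missing)} assigned cells absent from the matrix (first: {missing[0]!r})")
    unassigned = [c for c in cells.columns if c not in assign]
    if unassigned:
        logger.info("dropping %d cells without a cluster assignment", len(unassigned))

    clusters: dict[str, list[str]] = {}
    for cell, cluster in assign.items():
        clusters.setdefault(cluster, []).append(cell)
    for cluster, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {cluster!r} has no cells")
    out = pd.DataFrame(
        {cluster: cells[members].to_numpy().mean(axis=1) for cluster, members in clusters.items()},
        index=cells.index,
    )
    return out


def top_k_column(values: pd.Series, k: int) -> list[str]:
    """Ids of the ``k`` largest entries; ties broken by value desc, id asc."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return order[:k]


def top_fraction_genes(profile: pd.DataFrame, fraction: float = 0.05) -> dict[str, list[str]]:
    """Per column, the top ``ceil(fraction * n_genes)`` genes by value.

    Ties at the cutoff are broken by descending value then ascending gene id,
    so the output is deterministic.  The ceiling guarantees a non-empty list
    for any positive fraction.  An all-zero column has no expressed genes and
    is an error.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * profile.shape[0])
    lists: dict[str, list[str]] = {}
    for col in profile.columns:
        values = profile[col]
        if not np.any(values.to_numpy() > 0):
            raise ValueError(f"column {col!r} is all zero: no expressed genes")
        lists[col] = top_k_column(values, k)
    return lists
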