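"""Cell-type signatures in three interchangeable forms.

A signature characterises one cell type by its marker genes.  It can be

* a **gene set** — a named list of marker gene ids (:class:`~annobench.io.GeneSetDB`);
* a **continuous profile** — a genes x cell-types matrix of expression values
  (LM22 is the canonical example: 547 genes x 22 leukocyte types);
* a **binary matrix** — genes x cell-types with 1 marking each type's
  top-expressed genes.

Binarisation keeps, per type column, the top 5% of genes by expression value
(ceiling of the fractional count, deterministic tie-break).  Gene sets and
binary matrices convert losslessly into each other: the binary row space is
the union of all set genes, and a gene present in other sets but absent from
set m gets a 0 in column m.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import GeneSetDB
from .profiles import top_k_column

__all__ = ["binarize_profile", "binary_to_gene_sets", "gene_sets_to_binary"]


def binarize_profile(sig: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Threshold a continuous profile signature to 0/1.

    Per type column, the ``ceil(fraction * n_genes)`` genes with highest
    expression get 1, all others 0.  Ties at the cutoff break by descending
    value then ascending gene id.  A constant column carries no ranking
    information and is rejected.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * sig.shape[0])
    binary = pd.DataFrame(0, index=sig.index, columns=sig.columns, dtype=int)
    for col in sig.columns:
        values = sig[col]
        if fraction < 1 and values.nunique() == 1:
            raise ValueError(f"column {col!r} is constant: cannot threshold")
        binary.loc[top_k_column(values, k), col] = 1
    return binary


def binary_to_gene_sets(binary: pd.DataFrame) -> GeneSetDB:
    """Each type's gene set = the genes marked 1 in its column (row order kept)."""
    arr = binary.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary signature entries must be 0 or 1")
    sets = {}
    for col in binary.columns:
        genes = list(binary.index[binary[col].to_numpy() == 1])
        if not genes:
            raise ValueError(f"column {col!r} has no genes marked 1")
        sets[str(col)] = genes
    return GeneSetDB(sets=sets)


def gene_sets_to_binary(db: GeneSetDB) -> pd.DataFrame:
    """Organise gene sets as a genes x cell-types 0/1 matrix.

    Rows are the union of all set genes in first-seen order; entry (g, m) is
    1 iff g belongs to set m.  Genes outside every set are not represented.
    """
    genes = db.all_genes()
    binary = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=db.labels, dtype=int)
    for label, members in db.sets.items():
        binary.loc[members, label] = 1
    return binary
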