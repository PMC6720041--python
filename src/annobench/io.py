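"""Readers and writers for the on-disk formats used throughout the package.

Three external representations are supported:

* **GMT** gene-set files (tab-separated ``name<TAB>description<TAB>gene...``),
  the de-facto exchange format for named gene sets.
* **TSV expression tables** (genes in rows, first header row of column ids),
  carrying cell-level count matrices, cluster-average matrices and continuous
  profile signatures such as LM22.
* **Two-column TSV maps** for cell->cluster assignments and for gold-standard
  cluster->cell-type annotations.

All readers validate and reject malformed input rather than repairing it;
error messages carry the offending location.  Gene identifiers are matched by
exact, case-sensitive string comparison everywhere in the package; callers who
need to reconcile mouse/human symbol casing can pre-fold with
:func:`uppercase_genes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetDB",
    "GoldStandard",
    "FormatError",
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "read_gold_standard",
    "write_gold_standard",
    "read_cluster_assignment",
    "validate_expression_table",
    "uppercase_genes",
]


class FormatError(ValueError):
    """A file violated its format contract (location reported in the message)."""


@dataclass
class GeneSetDB:
    """Named cell-type gene sets: label -> ordered list of unique gene ids.

    Invariants (checked on construction): labels unique and tab-free, every
    set non-empty, gene ids unique within a set.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("GeneSetDB must contain at least one gene set")
        for name, genes in self.sets.items():
            if "\t" in name or "\n" in name:
                raise ValueError(f"gene-set label {name!r} contains a tab/newline")
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate gene ids")
            for g in genes:
                if "\t" in g or "\n" in g:
                    raise ValueError(f"gene id {g!r} in set {name!r} contains a tab/newline")

    @property
    def labels(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        """Union of all set genes, in first-seen order."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, label: str) -> list[str]:
        return self.sets[label]


# A gold standard is a plain mapping cluster-id -> cell-type label; clusters
# missing from the mapping are simply excluded from evaluation downstream.
GoldStandard = dict


def read_gmt(path) -> GeneSetDB:
    """Parse a GMT file into a :class:`GeneSetDB`.

    Duplicate genes within one line are collapsed keeping the first
    occurrence; a duplicate set name or a line with fewer than three fields
    raises :class:`FormatError` naming the line.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            genes: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    genes.setdefault(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = list(genes)
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetDB(sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path) -> None:
    """Write a :class:`GeneSetDB` as GMT; empty descriptions become ``"na"``."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in db.sets.items():
            desc = db.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *genes]) + "\n")


def validate_expression_table(df: pd.DataFrame, *, context: str = "expression table") -> pd.DataFrame:
    """Check expression-table invariants: unique ids, numeric, finite, non-negative."""
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{context}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{context}: duplicate column id {dup!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{context}: non-numeric values present")
    if not np.isfinite(values).all():
        raise FormatError(f"{context}: non-finite (NA/inf) values present")
    if (values < 0).any():
        raise FormatError(f"{context}: negative expression values present")
    return df


def read_expression_table(path, *, transpose: bool = False) -> pd.DataFrame:
    """Read a genes x columns TSV matrix (header row of column ids).

    ``transpose=True`` accepts a columns x genes layout and flips it.  Ragged
    rows, non-numeric cells and duplicate ids raise :class:`FormatError`; there
    is no silent aggregation of duplicated gene rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_filter=False)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if transpose:
        df = df.T
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_expression_table(df.astype(float), context=str(path))


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def _read_two_column_tsv(path, what: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
            key, value = fields
            if key in mapping:
                raise FormatError(f"{path}:{lineno}: duplicate {what} id {key!r}")
            mapping[key] = value
    if not mapping:
        raise FormatError(f"{path}: empty {what} table")
    return mapping


def read_gold_standard(path) -> GoldStandard:
    """Read a 2-column TSV of ``cluster-id<TAB>cell-type``.

    Duplicate cluster ids are an error.  Clusters absent from the file are
    permitted elsewhere in the pipeline and excluded from evaluation.
    """
    return GoldStandard(_read_two_column_tsv(path, "cluster"))


def write_gold_standard(gold: Mapping[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cluster, label in gold.items():
            fh.write(f"{cluster}\t{label}\n")


def read_cluster_assignment(path) -> dict[str, str]:
    """Read a 2-column TSV of ``cell-id<TAB>cluster-id``."""
    return _read_two_column_tsv(path, "cell")


def uppercase_genes(obj):
    """Optional case-folding helper for cross-species gene-symbol matching.

    Accepts a :class:`GeneSetDB` or an expression table and returns a copy
    with all gene ids upper-cased.  Folding that introduces duplicates raises.
    """
    if isinstance(obj, GeneSetDB):
        sets = {}
        for name, genes in obj.sets.items():
            folded = [g.upper() for g in genes]
            if len(set(folded)) != len(folded):
                raise ValueError(f"case-folding created duplicate gene ids in set {name!r}")
            sets[name] = folded
        return GeneSetDB(sets=sets, descriptions=dict(obj.descriptions))
    df = obj.copy()
    df.index = df.index.str.upper()
    if df.index.has_duplicates:
        raise ValueError("case-folding created duplicate gene ids")
    return df
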