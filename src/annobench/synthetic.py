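"""Synthetic scRNA-seq fixtures with planted cell-type marker structure.

The generator emulates the inputs of the benchmarking workflow without any
download: a gene x cell raw count matrix grouped into one cluster per cell
type, each type's marker genes expressed at an elevated mean in its own
cluster, matched signatures in all three representations (gene sets,
continuous profile, binary via :mod:`annobench.signatures`), and a gold
standard mapping cluster i -> type i.

Counts follow a negative-binomial model with gene-specific baseline
expression (lognormal around the background mean, as real transcriptomes
never express all genes at one level), multiplicative marker effects and
Bernoulli dropout — the minimal structure that makes averaging, rank
statistics and deconvolution all non-trivial.  Batch effects, doublets and
realistic library-size variation are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetDB

__all__ = ["SyntheticConfig", "generate_dataset", "derive_profile_signature"]


@dataclass
class SyntheticConfig:
    """Knobs of the planted-marker count model.

    ``effect`` multiplies the negative-binomial mean of a type's markers in
    its own cluster (must exceed 1); ``dispersion`` is the NB overdispersion
    (variance = mu + dispersion * mu^2; 0 degenerates to Poisson);
    ``overlap`` is the fraction of each type's markers shared with the next
    type's block; ``dropout`` zeroes each count independently.
    """

    n_genes: int = 2000
    n_types: int = 8
    markers_per_type: int = 25
    cells_per_cluster: int = 50
    effect: float = 8.0
    background_mean: float = 1.0
    dispersion: float = 0.5
    overlap: float = 0.0
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect <= 1:
            raise ValueError("effect must be > 1")
        if not (0 <= self.overlap <= 1 and 0 <= self.dropout <= 1):
            raise ValueError("overlap and dropout must lie in [0, 1]")
        if self.dispersion < 0 or self.background_mean <= 0:
            raise ValueError("dispersion must be >= 0 and background_mean > 0")
        if min(self.n_genes, self.n_types, self.markers_per_type, self.cells_per_cluster) < 1:
            raise ValueError("dimensions must be >= 1")
        shared = int(round(self.overlap * self.markers_per_type))
        span = (self.n_types - 1) * (self.markers_per_type - shared) + self.markers_per_type
        if span > self.n_genes:
            raise ValueError("marker blocks do not fit: markers_per_type * n_types exceeds n_genes")

    # deterministic identifier vocabularies -------------------------------
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def type_labels(self) -> list[str]:
        return [f"type_{i:02d}" for i in range(1, self.n_types + 1)]

    def cluster_ids(self) -> list[str]:
        return [f"cluster_{i:02d}" for i in range(1, self.n_types + 1)]

    def baselines(self) -> np.ndarray:
        """Per-gene baseline means: lognormal, median = background_mean.

        sigma = 0.25 keeps baselines within ~2x of the background mean, so
        markers (effect > 1 required, 8 by default) stay clearly above every
        background gene.  Drawn from a dedicated substream so counts and
        baselines are independently reproducible.
        """
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(1,)))
        return self.background_mean * rng.lognormal(mean=0.0, sigma=0.25, size=self.n_genes)


def _marker_blocks(cfg: SyntheticConfig) -> dict[str, list[int]]:
    """Marker gene indices per type: consecutive blocks, optionally overlapping."""
    k = cfg.markers_per_type
    shared = int(round(cfg.overlap * k))
    step = k - shared if k > shared else 1
    blocks = {}
    for t, label in enumerate(cfg.type_labels()):
        start = t * step
        blocks[label] = list(range(start, start + k))
    return blocks


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, dict[str, str], GeneSetDB, pd.DataFrame, dict[str, str]]:
    """Draw one synthetic dataset.

    Returns ``(cells, assignment, gene_sets, profile_signature, gold)``:
    the gene x cell count matrix, the cell -> cluster map, the planted marker
    gene sets, the noiseless expected-mean profile signature, and the gold
    standard ``cluster_i -> type_i``.  Same config (incl. seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    genes = cfg.gene_ids()
    types = cfg.type_labels()
    clusters = cfg.cluster_ids()
    blocks = _marker_blocks(cfg)

    n_cells = cfg.n_types * cfg.cells_per_cluster
    mu = np.tile(cfg.baselines()[:, None], (1, n_cells))
    assignment: dict[str, str] = {}
    cell_ids = []
    for t, (cluster, label) in enumerate(zip(clusters, types)):
        lo = t * cfg.cells_per_cluster
        hi = lo + cfg.cells_per_cluster
        mu[blocks[label], lo:hi] *= cfg.effect
        for j in range(lo, hi):
            cid = f"cell_{j + 1:05d}"
            cell_ids.append(cid)
            assignment[cid] = cluster

    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    if cfg.dropout > 0:
        counts = counts * (rng.random(counts.shape) >= cfg.dropout)

    cells = pd.DataFrame(counts.astype(float), index=genes, columns=cell_ids)
    db = GeneSetDB(sets={label: [genes[i] for i in blocks[label]] for label in types})
    profile = derive_profile_signature(db, cfg)
    gold = dict(zip(clusters, types))
    return cells, assignment, db, profile, gold


def derive_profile_signature(db: GeneSetDB, cfg: SyntheticConfig) -> pd.DataFrame:
    """Noiseless expected-mean profile over the full gene vocabulary.

    Each type's column holds the gene baselines, with the type's markers
    multiplied by the effect size — the mean of the count model without
    noise or dropout, mirroring how reference profiles such as LM22 are
    averages of purified measurements.
    """
    genes = cfg.gene_ids()
    base = cfg.baselines()
    profile = pd.DataFrame(
        {label: base.copy() for label in db.labels},
        index=pd.Index(genes, name="gene"),
    )
    for label, members in db.sets.items():
        profile.loc[members, label] *= cfg.effect
    return profile
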