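"""Gene-set based cell-type scoring of cluster profiles: ORA, GSEA, GSVA.

Each scorer consumes the cluster-average expression matrix (genes x clusters)
plus named cell-type gene sets and returns a cell-types x clusters matrix of
prediction scores in which higher means stronger support for "this cluster is
that cell type".

* **ORA** (over-representation analysis): one-sided Fisher exact test of the
  overlap between a cluster's expressed-gene list and each marker set, over a
  gene universe restricted to the intersection of signature genes and matrix
  genes.  Scores are -log10 p-values.
* **GSEA preranked**: weighted Kolmogorov–Smirnov-like running sum over the
  cluster's expression-ranked gene list; significance by gene-label
  permutation, one-sided for enrichment.  Scores are -log10 empirical
  p-values, floored at 1/(nperm+1) so they stay finite.
* **GSVA-style**: per-gene cross-cluster kernel CDF estimation, symmetric
  rank statistic, and a weighted random walk per cluster; the enrichment
  score itself is the prediction score (no p-value).

A cell type whose gene set shares no genes with the matrix cannot be scored;
its entries are emitted as NaN ("missing") and excluded from evaluation
downstream, never imputed as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetDB

logger = logging.getLogger(__name__)

__all__ = [
    "OraParams",
    "GseaParams",
    "GsvaParams",
    "neglog10_transform",
    "ora_scores",
    "gsea_enrichment_score",
    "gsea_scores",
    "gsva_scores",
]


def neglog10_transform(p: float, floor: float) -> float:
    """Map a p-value to ``-log10(max(p, floor))`` (monotone decreasing in p).

    The floor keeps permutation p-values of 0 finite; with the add-one
    permutation estimator the natural floor is ``1/(nperm+1)``.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if not 0 < floor <= 1:
        raise ValueError(f"floor outside (0, 1]: {floor}")
    return -math.log10(max(p, floor))


# --------------------------------------------------------------------------- ORA

@dataclass
class OraParams:
    """Parameters of the over-representation scorer.

    ``fraction`` is the expressed-gene threshold used when a cluster profile
    matrix (rather than precomputed gene lists) is supplied: per cluster the
    top fraction of genes by average expression count as "expressed".  The
    universe is always the intersection of signature genes and matrix genes.
    """

    fraction: float = 0.05
    p_floor: float = 1e-300  # numerical guard only; exact-test p-values are > 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")


def ora_scores(
    gene_lists: Mapping[str, Sequence[str]],
    db: GeneSetDB,
    params: OraParams | None = None,
    *,
    matrix_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score (cell type, cluster) pairs by one-sided Fisher exact enrichment.

    Parameters
    ----------
    gene_lists
        Cluster-id -> expressed gene list (e.g. from
        :func:`annobench.profiles.top_fraction_genes`).
    db
        Cell-type marker gene sets.
    matrix_genes
        The gene ids of the cluster profile matrix.  The test universe is
        ``union(db genes) & matrix_genes``; if omitted, the union of all
        cluster lists stands in for the matrix gene space.

    Returns
    -------
    Cell-types x clusters matrix of ``-log10`` one-sided enrichment p-values.
    """
    params = params or OraParams()
    if matrix_genes is None:
        matrix_genes = {g for genes in gene_lists.values() for g in genes}
    universe = set(db.all_genes()) & set(matrix_genes)
    if not universe:
        raise ValueError("empty gene universe: signature and matrix share no genes")
    N = len(universe)

    scores = pd.DataFrame(np.nan, index=db.labels, columns=list(gene_lists))
    for label in db.labels:
        gene_set = set(db[label]) & universe
        K = len(gene_set)
        if K == 0:
            logger.info("cell type %r shares no universe genes; scores flagged missing", label)
            continue
        for cluster, expressed in gene_lists.items():
            drawn = set(expressed) & universe
            n = len(drawn)
            k = len(drawn & gene_set)
            # One-sided enrichment tail of the 2x2 table, identical to
            # fisher.test(alternative="greater"): P(X >= k), X ~ Hypergeom(N, K, n).
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            scores.loc[label, cluster] = neglog10_transform(min(p, 1.0), params.p_floor)
    return scores


# -------------------------------------------------------------------------- GSEA

@dataclass
class GseaParams:
    """Parameters of the preranked GSEA scorer.

    ``nperm`` gene-label permutations give the empirical p-value (add-one
    estimator, one-sided for positive enrichment); ``weight_exponent`` is the
    running-sum exponent p (1 = weighted, 0 = classic).  ``ranking`` selects
    the per-cluster gene ordering: ``"expression"`` ranks by descending
    average expression within the cluster; ``"zscore"`` ranks by the gene's
    expression z-score against the other clusters.
    """

    nperm: int = 1000
    weight_exponent: float = 1.0
    ranking: str = "expression"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nperm < 1:
            raise ValueError("nperm must be >= 1")
        if self.ranking not in ("expression", "zscore"):
            raise ValueError(f"unknown ranking metric {self.ranking!r}")


def gsea_enrichment_score(
    genes: Sequence[str],
    weights: Sequence[float],
    gene_set: Sequence[str],
    p_exp: float = 1.0,
) -> float:
    """Signed enrichment score of ``gene_set`` on a ranked gene list.

    Walking down the ranked list, genes in the set add
    ``|w_i|^p / sum_hits |w|^p`` and genes outside subtract ``1/(N - N_hits)``;
    the ES is the deviation from zero of largest magnitude (signed).  When the
    set covers all genes the miss step is defined as 0.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("ranked gene list is empty")
    if len(genes) != len(weights):
        raise ValueError("genes and weights differ in length")
    members = set(gene_set)
    hit = np.array([g in members for g in genes])
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    walk = _running_walk(np.asarray(weights, dtype=float), hit, p_exp)
    return float(walk[np.argmax(np.abs(walk))])


def _running_walk(weights: np.ndarray, hit: np.ndarray, p_exp: float) -> np.ndarray:
    """Cumulative hit-minus-miss walk over an already-ordered gene list."""
    n = len(weights)
    n_hits = int(hit.sum())
    wp = np.abs(weights) ** p_exp
    hit_mass = np.where(hit, wp, 0.0)
    total = hit_mass.sum()
    if total == 0:  # all hit weights zero: fall back to uniform hit mass
        hit_mass = hit.astype(float)
        total = float(n_hits)
    miss_step = 0.0 if n == n_hits else 1.0 / (n - n_hits)
    steps = hit_mass / total - np.where(hit, 0.0, miss_step)
    return np.cumsum(steps)


def _positive_es_from_hits(
    sorted_hit_pos: np.ndarray, wp: np.ndarray, n: int, n_hits: int
) -> np.ndarray:
    """Max positive walk deviation for each row of hit positions.

    The walk only rises at hits, so its positive extremum is attained just
    after some hit: after the i-th hit (0-based) at rank s_i the walk equals
    ``cumhit_i / W - (s_i - i) * miss``.  Vectorised over permutations.
    """
    miss = 0.0 if n == n_hits else 1.0 / (n - n_hits)
    hit_w = wp[sorted_hit_pos]                      # (R, k)
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        hit_w[zero] = 1.0
        totals = hit_w.sum(axis=1, keepdims=True)
    cum = np.cumsum(hit_w, axis=1) / totals
    i = np.arange(sorted_hit_pos.shape[1])
    walk_at_hits = cum - (sorted_hit_pos - i) * miss
    return np.maximum(walk_at_hits.max(axis=1), 0.0)


def _rank_columns(exy: pd.DataFrame, ranking: str) -> dict[str, pd.Series]:
    """Per-cluster descending ranking metric (ties broken by gene id)."""
    metrics: dict[str, pd.Series] = {}
    for col in exy.columns:
        if ranking == "expression":
            metric = exy[col]
        else:  # z-score versus the other clusters
            rest = exy.drop(columns=col)
            sd = rest.std(axis=1, ddof=1).replace(0.0, 1.0)
            metric = (exy[col] - rest.mean(axis=1)) / sd
        order = sorted(metric.index, key=lambda g: (-metric[g], g))
        metrics[col] = metric.loc[order]
    return metrics


def gsea_scores(
    exy: pd.DataFrame, db: GeneSetDB, params: GseaParams | None = None
) -> pd.DataFrame:
    """Preranked GSEA scores for every (cell type, cluster) pair.

    Per pair, genes are ranked within the cluster, the observed positive-side
    enrichment score is compared with ``nperm`` gene-label permutations, and
    the score is ``-log10`` of the add-one empirical p-value
    ``(1 + #{ES_perm >= ES_obs}) / (nperm + 1)``.  Runs are reproducible for
    a fixed seed.  Sets with no genes in the matrix yield NaN.
    """
    params = params or GseaParams()
    floor = 1.0 / (params.nperm + 1)
    ranked = _rank_columns(exy, params.ranking)
    scores = pd.DataFrame(np.nan, index=db.labels, columns=exy.columns)
    rng = np.random.default_rng(params.seed)
    n = exy.shape[0]
    for cluster in exy.columns:
        metric = ranked[cluster]
        wp = np.abs(metric.to_numpy()) ** params.weight_exponent
        pos = {g: i for i, g in enumerate(metric.index)}
        for label in db.labels:
            hits = np.array(sorted(pos[g] for g in db[label] if g in pos))
            if hits.size == 0:
                continue
            k = hits.size
            obs = _positive_es_from_hits(hits[None, :], wp, n, k)[0]
            # permute gene labels: k uniform random hit positions per replicate
            perm_pos = np.sort(
                rng.permuted(np.tile(np.arange(n), (params.nperm, 1)), axis=1)[:, :k], axis=1
            )
            perm_es = _positive_es_from_hits(perm_pos, wp, n, k)
            p = (1 + int((perm_es >= obs - 1e-12).sum())) / (params.nperm + 1)
            scores.loc[label, cluster] = neglog10_transform(p, floor)
    return scores


# -------------------------------------------------------------------------- GSVA

@dataclass
class GsvaParams:
    """Parameters of the GSVA-style scorer.

    ``kernel`` selects the per-gene cross-cluster CDF estimator: ``"gaussian"``
    (bandwidth = per-gene sd / 4) or ``"poisson"`` (rate = value + 0.5,
    appropriate for counts).  ``tau`` is the rank-weight exponent of the
    random walk; ``es_mode`` is ``"diff"`` (largest positive deviation minus
    magnitude of largest negative deviation) or ``"max"`` (signed extremum).
    """

    kernel: str = "gaussian"
    tau: float = 1.0
    es_mode: str = "diff"

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "poisson"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.es_mode not in ("diff", "max"):
            raise ValueError(f"unknown es_mode {self.es_mode!r}")


def _kernel_cdf(exy: pd.DataFrame, kernel: str) -> np.ndarray:
    """Per-gene cross-cluster kernel CDF estimate z[i, y] (constant genes -> 0.5)."""
    E = exy.to_numpy(dtype=float)
    if kernel == "gaussian":
        sd = E.std(axis=1, ddof=1)
        const = sd == 0
        h = np.where(const, 1.0, sd / 4.0)
        # z_iy = mean_j Phi((e_iy - e_ij) / h_i)
        diff = (E[:, :, None] - E[:, None, :]) / h[:, None, None]
        z = stats.norm.cdf(diff).mean(axis=2)
        z[const] = 0.5
    else:
        lam = E + 0.5
        z = stats.poisson.cdf(E[:, :, None], lam[:, None, :]).mean(axis=2)
        const = (E == E[:, :1]).all(axis=1)
        z[const] = 0.5
    return z


def gsva_scores(
    exy: pd.DataFrame, db: GeneSetDB, params: GsvaParams | None = None
) -> pd.DataFrame:
    """GSVA-style sample-wise enrichment scores, used directly as predictions.

    Stages: (1) per-gene cross-cluster kernel CDF estimate; (2) per cluster,
    genes ordered by decreasing CDF value with the symmetric rank statistic
    ``r = |G/2 - rank|``; (3) weighted KS-like walk over that ordering with
    hit mass proportional to ``r^tau`` and miss step ``1/(G - |set|)``;
    (4) ES per ``es_mode``.  ES lies in [-1, 1].  Requires >= 3 clusters
    (cross-column CDF estimation degenerates below that).
    """
    params = params or GsvaParams()
    if exy.shape[1] < 3:
        raise ValueError("GSVA scoring needs at least 3 clusters")
    z = _kernel_cdf(exy, params.kernel)
    G = exy.shape[0]
    genes = list(exy.index)
    scores = pd.DataFrame(np.nan, index=db.labels, columns=exy.columns)
    matrix_genes = set(genes)
    for c_idx, cluster in enumerate(exy.columns):
        zc = pd.Series(z[:, c_idx], index=genes)
        order = sorted(genes, key=lambda g: (-zc[g], g))
        rank = np.arange(1, G + 1)
        r = np.abs(G / 2.0 - rank) ** params.tau
        ordered = pd.Index(order)
        for label in db.labels:
            members = set(db[label]) & matrix_genes
            if not members:
                continue
            hit = np.asarray(ordered.isin(list(members)))
            k = int(hit.sum())
            hit_mass = np.where(hit, r, 0.0)
            total = hit_mass.sum()
            if total == 0:
                hit_mass = hit.astype(float)
                total = float(k)
            miss = 0.0 if G == k else 1.0 / (G - k)
            walk = np.cumsum(hit_mass / total - np.where(hit, 0.0, miss))
            if params.es_mode == "diff":
                es = max(walk.max(), 0.0) + min(walk.min(), 0.0)
            else:
                es = walk[np.argmax(np.abs(walk))]
            scores.loc[label, cluster] = es
    return scores
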