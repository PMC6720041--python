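"""Profile-signature based scoring: nu-SVR deconvolution and neighbor voting.

Both methods consume the cluster-average matrix together with a cell-type
signature given as a genes x cell-types matrix — either continuous expression
values (e.g. LM22) or a thresholded binary matrix — and emit a cell-types x
clusters score matrix.

* **Deconvolution** treats each cluster's average profile as a mixture and
  regresses it on the signature columns with linear nu-support-vector
  regression over a small nu grid, CIBERSORT-style; the estimated cell-type
  fraction is the prediction score.
* **Neighbor voting** builds a rank-normalised Spearman-correlation network
  over the concatenated cluster and signature columns and lets each signature
  column vote for clusters through it; the prediction score is the one-sided
  AUROC of a cluster's vote among all clusters.  The voting is directional —
  signatures train, clusters test — with no train/test averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import NuSVR

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionParams",
    "VotingParams",
    "svr_deconvolve",
    "cibersort_scores",
    "build_voting_network",
    "metaneighbor_scores",
]


@dataclass
class DeconvolutionParams:
    """nu-SVR deconvolution settings.

    The nu grid {0.25, 0.5, 0.75} controls the support-vector fraction; the
    fit with the lowest root-mean-square reconstruction error wins.
    ``standardize`` z-scores the mixture and globally standardises the
    signature matrix over the shared genes before fitting.
    """

    nus: tuple[float, ...] = (0.25, 0.5, 0.75)
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < nu < 1 for nu in self.nus):
            raise ValueError("nu values must lie in (0, 1)")


@dataclass
class VotingParams:
    """Neighbor-voting settings (rank correlation, signatures as training)."""

    correlation: str = "spearman"

    def __post_init__(self) -> None:
        if self.correlation != "spearman":
            raise ValueError("only rank (spearman) correlation is supported")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def svr_deconvolve(
    mixture: pd.Series,
    sig: pd.DataFrame,
    params: DeconvolutionParams | None = None,
) -> pd.Series:
    """Estimate cell-type fractions in one mixture profile.

    Genes are intersected between mixture and signature (signature row order);
    the mixture is z-scored and the signature matrix is standardised globally
    (one mean and sd for the whole matrix, which preserves mixing proportions
    up to a common scale); a linear nu-SVR is fitted for each nu in the grid
    and the lowest-RMSE fit's coefficients, clipped at zero and normalised to
    sum 1, are the fractions.  An all-zero coefficient vector falls back to a
    uniform vector (logged).
    """
    params = params or DeconvolutionParams()
    shared = sig.index.intersection(mixture.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared genes between mixture and signature")
    if sig.shape[1] < 2:
        raise ValueError("signature must contain at least 2 cell types")
    y = mixture.loc[shared].to_numpy(dtype=float)
    X = sig.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("mixture is constant over the shared genes")
    if params.standardize:
        y = _zscore(y)
        X = (X - X.mean()) / X.std()

    best_coef, best_rmse = None, np.inf
    for nu in params.nus:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(X, y)
        rmse = float(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        if rmse < best_rmse:
            best_rmse, best_coef = rmse, model.coef_.ravel().copy()
    frac = np.clip(best_coef, 0.0, None)
    total = frac.sum()
    if total == 0:
        logger.warning("all deconvolution coefficients non-positive; returning uniform fractions")
        frac = np.full(sig.shape[1], 1.0 / sig.shape[1])
    else:
        frac = frac / total
    return pd.Series(frac, index=sig.columns)


def cibersort_scores(
    exy: pd.DataFrame,
    sig: pd.DataFrame,
    params: DeconvolutionParams | None = None,
) -> pd.DataFrame:
    """Deconvolve every cluster column; score(m, y) = fraction of type m in y.

    Accepts continuous and binary signatures through the same entry point.
    Deterministic: the nu-SVR fit has no random component.
    """
    params = params or DeconvolutionParams()
    cols = {
        cluster: svr_deconvolve(exy[cluster], sig, params) for cluster in exy.columns
    }
    return pd.DataFrame(cols, columns=exy.columns)


def build_voting_network(exy: pd.DataFrame, sig: pd.DataFrame) -> pd.DataFrame:
    """Rank-normalised rank-correlation network over clusters + cell types.

    Cluster columns and signature columns are concatenated over their shared
    genes; the Spearman correlation of every column pair is computed; then
    every entry of the correlation matrix (diagonal included) is replaced by
    its average-tie rank over the whole flattened matrix, scaled into (0, 1].
    """
    if exy.shape[1] < 2 or sig.shape[1] < 2:
        raise ValueError("need at least 2 clusters and 2 cell types")
    clash = set(exy.columns) & set(sig.columns)
    if clash:
        raise ValueError(f"cluster and cell-type labels overlap: {sorted(clash)[:3]}")
    shared = exy.index.intersection(sig.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")
    joint = pd.concat([exy.loc[shared], sig.loc[shared]], axis=1)
    corr = stats.spearmanr(joint.to_numpy()).statistic
    corr = np.atleast_2d(corr)
    ranks = stats.rankdata(corr.ravel(), method="average").reshape(corr.shape)
    network = ranks / ranks.size
    return pd.DataFrame(network, index=joint.columns, columns=joint.columns)


def metaneighbor_scores(
    exy: pd.DataFrame,
    sig: pd.DataFrame,
    params: VotingParams | None = None,
) -> pd.DataFrame:
    """Directional neighbor-voting scores of cell types for clusters.

    Each cell-type signature column t casts degree-normalised votes through
    the network: ``vote(y) = A[y, t] / sum_y' A[y', t]``, i.e. every training
    column distributes one unit of vote mass over the test clusters in
    proportion to its affinities.  The score of cluster y for type t is the
    one-sided AUROC of y's vote among all cluster votes — with a single
    positive this is ``(rank_y - 1)/(n_clusters - 1)``, average ranks on
    ties.  No train/test averaging is applied, so votes flow only from
    signatures to clusters.
    """
    params = params or VotingParams()
    if exy.shape[1] < 2:
        raise ValueError("need at least 2 clusters to rank votes")
    network = build_voting_network(exy, sig)
    clusters = list(exy.columns)
    A = network.loc[clusters, list(sig.columns)]
    degree = A.sum(axis=0).to_numpy()
    scores = pd.DataFrame(np.nan, index=sig.columns, columns=clusters)
    n = len(clusters)
    for j, t in enumerate(sig.columns):
        votes = A[t].to_numpy() / degree[j]
        ranks = stats.rankdata(votes, method="average")
        scores.loc[t] = (ranks - 1.0) / (n - 1.0)
    return scores
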