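"""Signature-subsampling robustness simulations.

How sensitive is each scoring method to incomplete marker knowledge?  The
simulation degrades the cell-type signatures at increasing severities,
re-scores and re-evaluates, and reports the ROC/PR AUC distribution over
replicates at each severity — the data behind the usual violin plots.

Two degradation protocols match the two signature kinds:

* **gene sets** — randomly remove a fixed fraction of genes from every set
  (10% to 99% in 10% increments, keeping at least one gene); binary-matrix
  methods receive the subsampled sets re-organised as a 0/1 matrix;
* **continuous profiles** — identify each type's top-5% highest-expressed
  genes, then overwrite a random fraction of them (10% to 100%) with the
  column minimum, leaving matrix dimensions untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import methods as _methods
from .evaluation import concatenate_with_truth, pr_curve, roc_curve
from .io import GeneSetDB
from .signatures import binarize_profile

__all__ = [
    "SubsampleSpec",
    "subsample_gene_sets",
    "subsample_profile",
    "robustness_experiment",
    "DEFAULT_REMOVAL_GRID",
]

# 10%..90% in 10% steps, capped at 99% so every set keeps >= 1 gene by rounding
DEFAULT_REMOVAL_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)


@dataclass
class SubsampleSpec:
    """Grid, replicate count and seed of a robustness run.

    The default grid serves the gene-set protocol; for profile methods the
    fractions are interpreted as the share of top-5% genes masked (1.0 =
    mask all of them).
    """

    fractions: tuple[float, ...] = DEFAULT_REMOVAL_GRID
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5))


def subsample_gene_sets(db: GeneSetDB, removal: float, rng: np.random.Generator) -> GeneSetDB:
    """Remove a random ``removal`` fraction of genes from every set.

    A set of size n keeps ``max(1, round((1 - removal) * n))`` genes
    (round half away from zero), drawn uniformly without replacement;
    the surviving genes keep their original order.
    """
    if not 0 <= removal < 1:
        raise ValueError(f"removal must be in [0, 1), got {removal}")
    sets = {}
    for name, genes in db.sets.items():
        keep = max(1, _round_half_away((1.0 - removal) * len(genes)))
        if keep >= len(genes):
            sets[name] = list(genes)
        else:
            idx = np.sort(rng.choice(len(genes), size=keep, replace=False))
            sets[name] = [genes[i] for i in idx]
    return GeneSetDB(sets=sets, descriptions=dict(db.descriptions))


def subsample_profile(
    sig: pd.DataFrame, fraction: float, rng: np.random.Generator, top_fraction: float = 0.05
) -> pd.DataFrame:
    """Mask a random fraction of each type's top-expressed genes.

    Per column: the top ``top_fraction`` genes (same thresholding rule as
    binarisation) are identified and ``ceil(fraction * k)`` of them, chosen
    uniformly, have their value overwritten by the column minimum.  Output
    dimensions are identical to the input.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    binary = binarize_profile(sig, top_fraction)
    out = sig.copy()
    for col in sig.columns:
        top = list(binary.index[binary[col].to_numpy() == 1])
        n_mask = int(np.ceil(fraction * len(top)))
        idx = rng.choice(len(top), size=n_mask, replace=False)
        out.loc[[top[i] for i in idx], col] = sig[col].min()
    return out


def robustness_experiment(
    exy: pd.DataFrame,
    gold: Mapping[str, str],
    spec: SubsampleSpec,
    *,
    methods: Sequence[str],
    gene_sets: GeneSetDB | None = None,
    profile: pd.DataFrame | None = None,
    method_params: Mapping[str, Mapping[str, Any]] | None = None,
) -> pd.DataFrame:
    """Subsample -> score -> evaluate over the full grid for each method.

    Returns the violin-ready long table with one row per (method, fraction,
    replicate) holding both ROC AUC and PR AUC.  Each cell of the grid uses
    an independent, deterministic random substream derived from the spec
    seed, so results are bit-reproducible and insensitive to method order.
    """
    method_params = method_params or {}
    for name in methods:
        if name in _methods.GENE_SET_METHODS and gene_sets is None:
            raise ValueError(f"method {name!r} requires gene-set signatures")
        if name in _methods.PROFILE_METHODS and profile is None:
            raise ValueError(f"method {name!r} requires a continuous profile signature")
        if name not in _methods.ALL_METHODS:
            raise ValueError(f"unknown method {name!r}")

    rows = []
    for name in methods:
        mi = _methods.ALL_METHODS.index(name)
        for fi, frac in enumerate(spec.fractions):
            for rep in range(spec.replicates):
                ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(mi, fi, rep))
                rng = np.random.default_rng(ss)
                score_seed = int(rng.integers(2**31))
                if name in _methods.GENE_SET_METHODS:
                    sub_db = subsample_gene_sets(gene_sets, min(frac, 0.99), rng)
                    scores = _methods.score_method(
                        name, exy, gene_sets=sub_db,
                        params=method_params.get(name), seed=score_seed,
                    )
                else:
                    sub_sig = subsample_profile(profile, frac, rng)
                    scores = _methods.score_method(
                        name, exy, profile=sub_sig,
                        params=method_params.get(name), seed=score_seed,
                    )
                ls = concatenate_with_truth(scores, gold)
                rows.append({
                    "method": name, "fraction": frac, "replicate": rep,
                    "roc_auc": roc_curve(ls).auc, "pr_auc": pr_curve(ls).auc,
                })
    return pd.DataFrame(rows, columns=["method", "fraction", "replicate", "roc_auc", "pr_auc"])
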