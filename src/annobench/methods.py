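"""Uniform dispatch over the five cell-type scoring methods.

Method names accepted throughout the package and CLI:

==========================  =========================  =========================
name                        signature input            scorer
==========================  =========================  =========================
``ora``                     gene sets                  Fisher exact enrichment
``gsea``                    gene sets                  preranked GSEA
``gsva``                    gene sets                  GSVA-style enrichment
``cibersort_binary``        gene sets (as 0/1 matrix)  nu-SVR deconvolution
``cibersort_continuous``    continuous profile         nu-SVR deconvolution
``metaneighbor_binary``     gene sets (as 0/1 matrix)  directional neighbor voting
``metaneighbor_continuous`` continuous profile         directional neighbor voting
==========================  =========================  =========================
"""

from __future__ import annotations

from typing import Any, Mapping

import pandas as pd

from .gene_set_scoring import GseaParams, GsvaParams, OraParams, gsea_scores, gsva_scores, ora_scores
from .io import GeneSetDB
from .profile_scoring import (
    DeconvolutionParams,
    VotingParams,
    cibersort_scores,
    metaneighbor_scores,
)
from .profiles import top_fraction_genes
from .signatures import gene_sets_to_binary

GENE_SET_METHODS = ("ora", "gsea", "gsva", "cibersort_binary", "metaneighbor_binary")
PROFILE_METHODS = ("cibersort_continuous", "metaneighbor_continuous")
ALL_METHODS = GENE_SET_METHODS + PROFILE_METHODS


def score_method(
    name: str,
    exy: pd.DataFrame,
    *,
    gene_sets: GeneSetDB | None = None,
    profile: pd.DataFrame | None = None,
    params: Mapping[str, Any] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run one scoring method and return its cell-types x clusters matrix.

    ``params`` are keyword overrides for the method's parameter dataclass
    (e.g. ``{"nperm": 200}`` for GSEA).  ``seed`` feeds the permutation
    scorers; the other methods are deterministic.
    """
    params = dict(params or {})
    if name in GENE_SET_METHODS:
        if gene_sets is None:
            raise ValueError(f"method {name!r} needs gene-set signatures")
    elif name in PROFILE_METHODS:
        if profile is None:
            raise ValueError(f"method {name!r} needs a continuous profile signature")
    else:
        raise ValueError(f"unknown method {name!r}; choose from {ALL_METHODS}")

    if name == "ora":
        fraction = params.pop("fraction", 0.05)
        p = OraParams(fraction=fraction, **params)
        lists = top_fraction_genes(exy, p.fraction)
        return ora_scores(lists, gene_sets, p, matrix_genes=exy.index)
    if name == "gsea":
        params.setdefault("seed", seed)
        return gsea_scores(exy, gene_sets, GseaParams(**params))
    if name == "gsva":
        return gsva_scores(exy, gene_sets, GsvaParams(**params))
    if name == "cibersort_binary":
        sig = gene_sets_to_binary(gene_sets).astype(float)
        return cibersort_scores(exy, sig, DeconvolutionParams(**params))
    if name == "cibersort_continuous":
        return cibersort_scores(exy, profile, DeconvolutionParams(**params))
    if name == "metaneighbor_binary":
        sig = gene_sets_to_binary(gene_sets).astype(float)
        return metaneighbor_scores(exy, sig, VotingParams(**params))
    # metaneighbor_continuous
    return metaneighbor_scores(exy, profile, VotingParams(**params))
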