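"""ICM-specific gene inference from split-blastocyst samples.

The blastocyst cannot be dissected into a pure inner cell mass (ICM), but it
can be split into a pure trophectoderm half (TE) and a half containing the
ICM plus some TE (ICMTE).  Genes expressed specifically in the ICM then show
up as significantly higher in ICMTE than in TE: the caller applies the plain
subtraction test (q < alpha, fold change > min_fc, blastocyst RPKM > min_rpkm
in the ICMTE sample), with no explicit mixture deconvolution.

Morula co-expression lists intersect the morula expressed-gene list
(RPKM > threshold) with the ICM-specific list and with the TE expressed list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExpressionMatrix, GeneAnnotation, ValidationError
from .diffexpr import de_table
from .quantify import NormalizationFactors, log_transform, rpkm

log = logging.getLogger("embryostage")


@dataclass(frozen=True)
class LineageCallSet:
    icm_specific: frozenset[str]
    te_enriched: frozenset[str]
    te_expressed: frozenset[str]
    morula_icm_coexpressed: frozenset[str]
    morula_te_coexpressed: frozenset[str]

    def __post_init__(self) -> None:
        if not self.morula_icm_coexpressed <= self.icm_specific:
            raise ValidationError("morula/ICM co-expressed genes must be ICM-specific")
        if not self.morula_te_coexpressed <= self.te_expressed:
            raise ValidationError("morula/TE co-expressed genes must be TE-expressed")


def infer_icm_specific(
    cm: CountMatrix,
    ann: GeneAnnotation,
    nf: NormalizationFactors | None,
    icmte_samples: Sequence[str],
    te_samples: Sequence[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
    min_rpkm: float = 3.0,
    side: str = "icm",
    rpkm_in: str = "icmte",
) -> tuple[frozenset[str], pd.DataFrame]:
    """ICM-specific (or, with side="te", TE-enriched) genes plus the DE table.

    A gene is ICM-specific iff the ICMTE-vs-TE test calls it significantly up
    in ICMTE and its blastocyst RPKM exceeds `min_rpkm`.  `rpkm_in` selects
    which blastocyst sample must exceed the floor: "icmte" (default, the
    sample the gene is called specific in), "te", or "both".
    """
    icmte_samples, te_samples = list(icmte_samples), list(te_samples)
    if not icmte_samples or not te_samples:
        raise ValidationError("both ICMTE and TE sample groups are required")
    if side not in ("icm", "te"):
        raise ValidationError("side must be 'icm' or 'te'")
    if rpkm_in not in ("icmte", "te", "both"):
        raise ValidationError("rpkm_in must be 'icmte', 'te' or 'both'")

    de = de_table(cm, nf, icmte_samples, te_samples, alpha=alpha, min_fc=min_fc)
    em = rpkm(cm, ann, nf)
    icmte_rpkm = em.mean_for_samples(icmte_samples)
    te_rpkm = em.mean_for_samples(te_samples)

    if side == "icm":
        called = de.index[de["significant"] & (de["direction"] == "up")]
        floor_sample = {"icmte": icmte_rpkm, "te": te_rpkm}.get(rpkm_in)
    else:
        called = de.index[de["significant"] & (de["direction"] == "down")]
        floor_sample = {"icmte": te_rpkm, "te": icmte_rpkm}.get(rpkm_in)
    if rpkm_in == "both":
        above = set(icmte_rpkm.index[(icmte_rpkm > min_rpkm) & (te_rpkm > min_rpkm)])
    else:
        above = set(floor_sample.index[floor_sample > min_rpkm])
    return frozenset(set(called) & above), de


def coexpression_lists(
    em: ExpressionMatrix,
    morula_samples: Sequence[str],
    icm_specific: frozenset[str] | set[str],
    te_samples: Sequence[str],
    expressed_threshold: float = 3.0,
) -> tuple[frozenset[str], frozenset[str]]:
    """Morula/ICM and morula/TE co-expression lists.

    A gene co-expresses when it appears on both lists: the morula expressed
    list (mean RPKM > threshold, strict) and either the ICM-specific list or
    the TE expressed list (mean TE RPKM > threshold).
    """
    morula_samples = list(morula_samples)
    if not morula_samples:
        raise ValidationError("no morula samples given")
    morula_mean = em.mean_for_samples(morula_samples)
    morula_expressed = set(morula_mean.index[morula_mean > expressed_threshold])
    te_mean = em.mean_for_samples(list(te_samples))
    te_expressed = set(te_mean.index[te_mean > expressed_threshold])
    return (
        frozenset(morula_expressed & set(icm_specific)),
        frozenset(morula_expressed & te_expressed),
    )


def lineage_call_set(
    cm: CountMatrix,
    ann: GeneAnnotation,
    nf: NormalizationFactors | None,
    icmte_samples: Sequence[str],
    te_samples: Sequence[str],
    morula_samples: Sequence[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
    min_rpkm: float = 3.0,
    expressed_threshold: float = 3.0,
) -> LineageCallSet:
    """Full lineage workflow: subtraction test plus morula co-expression lists."""
    icm, _ = infer_icm_specific(
        cm, ann, nf, icmte_samples, te_samples, alpha, min_fc, min_rpkm, side="icm"
    )
    te_enriched, _ = infer_icm_specific(
        cm, ann, nf, icmte_samples, te_samples, alpha, min_fc, min_rpkm, side="te"
    )
    em = rpkm(cm, ann, nf)
    te_mean = em.mean_for_samples(list(te_samples))
    te_expressed = frozenset(te_mean.index[te_mean > expressed_threshold])
    morula_icm, morula_te = coexpression_lists(
        em, morula_samples, icm, te_samples, expressed_threshold
    )
    return LineageCallSet(
        icm_specific=icm,
        te_enriched=te_enriched,
        te_expressed=te_expressed,
        morula_icm_coexpressed=morula_icm,
        morula_te_coexpressed=morula_te,
    )


def marker_profile_matrix(
    em: ExpressionMatrix,
    markers: Sequence[str],
    stages: Sequence[str] | None = None,
    log_base: int = 10,
    pseudocount: float = 1.0,
    zscore: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Stage x marker mean log expression table for heat-map export.

    Markers absent from the expression matrix are omitted and returned in the
    report list (not fatal).  With ``zscore=True`` each marker row is scaled
    to zero mean / unit variance across stages (constant rows map to zeros).
    """
    present = [m for m in markers if m in em.values.index]
    missing = [m for m in markers if m not in em.values.index]
    if missing:
        log.warning("marker profile: %d markers absent from data: %s", len(missing), missing)
    logged = log_transform(em, base=log_base, pseudocount=pseudocount)
    profile = logged.stage_means(stages).loc[present]  # markers x stages
    if zscore:
        arr = profile.to_numpy()
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        profile = pd.DataFrame((arr - mu) / sd, index=profile.index, columns=profile.columns)
    return profile.T, missing
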