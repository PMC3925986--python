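"""Maternal/zygotic transcript classification and ZGA-stage detection.

Maternal deposit genes are defined by mean oocyte RPKM > 3 (strict).  Zygotic
activated genes are formalized as: not maternally deposited (mean oocyte
RPKM <= threshold), significantly up-regulated at some stage transition up to
and including the zygotic-genome-activation (ZGA) transition, and expressed
(RPKM > threshold) at the downstream stage of that transition.  The ZGA stage
is the downstream stage of the transition with the largest total number of
regulated genes (up + down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .datamodel import CLEAVAGE_STAGES, CountMatrix, ExpressionMatrix, ValidationError
from .diffexpr import de_table, significant_down, significant_up
from .quantify import NormalizationFactors

log = logging.getLogger("embryostage")

Transition = tuple[str, str]


@dataclass(frozen=True)
class StageCallSet:
    """Per-gene maternal/zygotic classification plus per-transition counts."""

    maternal_genes: frozenset[str]
    zygotic_genes: frozenset[str]
    regulated: pd.DataFrame  # index (stage_from, stage_to); columns n_up, n_down, n_total
    zga_stage: str

    def __post_init__(self) -> None:
        if self.maternal_genes & self.zygotic_genes:
            raise ValidationError("maternal and zygotic sets must be disjoint")


def call_maternal(
    em: ExpressionMatrix, oocyte_samples: Sequence[str], threshold: float = 3.0
) -> frozenset[str]:
    """Genes with mean oocyte RPKM strictly above `threshold`."""
    oocyte_samples = list(oocyte_samples)
    if not oocyte_samples:
        raise ValidationError("no oocyte samples given")
    if threshold <= 0:
        raise ValidationError("maternal threshold must be positive")
    means = em.mean_for_samples(oocyte_samples)
    return frozenset(means.index[means > threshold])


def regulated_counts(
    cm: CountMatrix,
    nf: NormalizationFactors | None,
    stage_order: Sequence[str] | None = None,
    condition: str | None = None,
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> tuple[pd.DataFrame, dict[Transition, pd.DataFrame]]:
    """Significant up/down gene counts for every consecutive stage transition.

    Returns the count table (index = (from, to)) and the per-transition DE
    tables, keyed by transition, for reuse by :func:`call_zygotic`.
    """
    stages = list(stage_order) if stage_order is not None else [
        s for s in cm.samples.stages_present() if s in CLEAVAGE_STAGES
    ]
    if len(stages) < 2:
        raise ValidationError("need at least two stages for transition counts")
    groups = {}
    for st in stages:
        ids = cm.samples.samples_for_stage(st, condition)
        if not ids:
            raise ValidationError(f"stage {st!r} has no samples")
        groups[st] = ids

    rows = []
    de_by_transition: dict[Transition, pd.DataFrame] = {}
    for a, b in zip(stages[:-1], stages[1:]):
        # direction "up" means higher at the downstream stage b
        de = de_table(cm, nf, groups[b], groups[a], alpha=alpha, min_fc=min_fc)
        de_by_transition[(a, b)] = de
        n_up = len(significant_up(de))
        n_down = len(significant_down(de))
        rows.append((a, b, n_up, n_down, n_up + n_down))
    table = pd.DataFrame(
        rows, columns=["stage_from", "stage_to", "n_up", "n_down", "n_total"]
    ).set_index(["stage_from", "stage_to"])
    return table, de_by_transition


def detect_zga(regulated: pd.DataFrame, up_only: bool = False) -> str:
    """Downstream stage of the transition with the most regulated genes.

    Ties break toward the earlier transition (logged).  Raises when no
    transition has any regulated gene.
    """
    col = "n_up" if up_only else "n_total"
    totals = regulated[col]
    if (totals <= 0).all():
        raise ValidationError("no transcriptional burst detected (all transitions zero)")
    best = int(totals.to_numpy().argmax())  # argmax returns the first maximum
    if (totals.to_numpy() == totals.iloc[best]).sum() > 1:
        log.warning("ZGA detection: tie on %s; keeping earliest transition", col)
    return regulated.index[best][1]


def call_zygotic(
    em: ExpressionMatrix,
    de_by_transition: Mapping[Transition, pd.DataFrame],
    oocyte_samples: Sequence[str],
    oocyte_threshold: float = 3.0,
    expressed_threshold: float = 3.0,
    zga_stage: str | None = None,
    regulated: pd.DataFrame | None = None,
) -> frozenset[str]:
    """Zygotic-activated genes from the transition-wise DE results.

    A gene qualifies iff its mean oocyte RPKM <= `oocyte_threshold`, it is
    significantly up-regulated at some transition up to and including the ZGA
    transition, and its mean RPKM at that transition's downstream stage
    exceeds `expressed_threshold`.  When `zga_stage` is None it is detected
    from `regulated` (or recomputed from the DE tables).
    """
    transitions = list(de_by_transition.keys())
    if regulated is None:
        rows = [
            (a, b, len(significant_up(de)), len(significant_down(de)))
            for (a, b), de in de_by_transition.items()
        ]
        regulated = pd.DataFrame(
            rows, columns=["stage_from", "stage_to", "n_up", "n_down"]
        ).set_index(["stage_from", "stage_to"])
        regulated["n_total"] = regulated["n_up"] + regulated["n_down"]
    if zga_stage is None:
        zga_stage = detect_zga(regulated)

    oocyte_mean = em.mean_for_samples(list(oocyte_samples))
    stage_means = em.stage_means()
    zygotic: set[str] = set()
    for (a, b), de in de_by_transition.items():
        up = significant_up(de)
        expressed = stage_means.index[stage_means[b] > expressed_threshold]
        zygotic.update(set(up) & set(expressed))
        if b == zga_stage:
            break
    low_in_oocyte = set(oocyte_mean.index[oocyte_mean <= oocyte_threshold])
    return frozenset(zygotic & low_in_oocyte)


def stage_call_set(
    cm: CountMatrix,
    em: ExpressionMatrix,
    nf: NormalizationFactors | None,
    stage_order: Sequence[str] | None = None,
    condition: str | None = None,
    alpha: float = 0.05,
    min_fc: float = 2.0,
    maternal_threshold: float = 3.0,
    expressed_threshold: float = 3.0,
) -> StageCallSet:
    """Full maternal/zygotic/ZGA workflow for one condition's stage series."""
    oocyte_samples = cm.samples.samples_for_stage("oocyte", condition)
    maternal = call_maternal(em, oocyte_samples, maternal_threshold)
    regulated, de_by_transition = regulated_counts(
        cm, nf, stage_order, condition, alpha=alpha, min_fc=min_fc
    )
    zga = detect_zga(regulated)
    zygotic = call_zygotic(
        em,
        de_by_transition,
        oocyte_samples,
        oocyte_threshold=maternal_threshold,
        expressed_threshold=expressed_threshold,
        zga_stage=zga,
        regulated=regulated,
    )
    return StageCallSet(
        maternal_genes=frozenset(maternal),
        zygotic_genes=frozenset(zygotic - maternal),
        regulated=regulated,
        zga_stage=zga,
    )
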