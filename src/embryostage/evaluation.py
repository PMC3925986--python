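"""Self-contained recovery benchmarks on the synthetic study.

Each function regenerates its inputs from a seed, runs the relevant pipeline
stage and measures recovery against the planted truth.  These power both the
acceptance checks and ad-hoc method evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cross_species import overlap_stats
from .datamodel import CountMatrix, SampleSheet
from .diffexpr import bh_adjust, conditional_binomial_pvalues, de_table
from .lineage import infer_icm_specific
from .network import MarkerPanel, build_network
from .pipeline import ortholog_space
from .quantify import rpkm, tmm_factors
from .stage_dynamics import detect_zga, regulated_counts, stage_call_set
from .synthetic import (
    ConditionSpec,
    GeneratorConfig,
    generate,
    profiles_to_expression,
    simulate_marker_network,
    simulate_two_group,
    truth_eval,
)


def _two_sample_matrix(k1: np.ndarray, k2: np.ndarray) -> CountMatrix:
    genes = [f"g{i:05d}" for i in range(k1.size)]
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["A", "B"],
                "stage": ["oocyte", "oocyte"],
                "condition": "sim",
                "species": "sim",
                "replicate": [1, 2],
            }
        )
    )
    return CountMatrix(pd.DataFrame({"A": k1, "B": k2}, index=genes), sheet)


def null_type_one_rate(
    seed: int, n_genes: int = 10_000, depth: float = 1e6, dispersion: float = 0.1
) -> dict:
    """Fraction of null genes with p < 0.05 under equal proportions."""
    k1, k2, _, n1, n2 = simulate_two_group(
        n_genes=n_genes, n_de=0, depth=depth, dispersion=dispersion, seed=seed
    )
    p = conditional_binomial_pvalues(k1, k2, n1, n2)
    return {"rate": float((p < 0.05).mean()), "n": n_genes}


def de_recovery(
    seed: int,
    n_genes: int = 5000,
    n_de: int = 200,
    fold: float = 8.0,
    depth: float = 1e6,
    dispersion: float = 0.1,
) -> dict:
    """Recall and empirical FDR for planted fold changes at pipeline defaults."""
    k1, k2, is_de, _, _ = simulate_two_group(
        n_genes, n_de, fold, depth, dispersion, seed=seed
    )
    cm = _two_sample_matrix(k1, k2)
    de = de_table(cm, tmm_factors(cm), ["A"], ["B"])
    sig = de["significant"].to_numpy()
    return {
        "recall": float((sig & is_de).sum() / max(is_de.sum(), 1)),
        "fdr": float((sig & ~is_de).sum() / max(sig.sum(), 1)),
        "n": n_genes,
    }


def zga_detection_rates(
    seed: int, n_runs: int = 100, n_genes: int = 2000
) -> dict[str, dict]:
    """Fraction of seeded series whose detected ZGA stage matches the plant.

    Mirrors the three study conditions: a burst at the 2-cell stage
    (mouse-like), 4-cell (normal pig) and 8-cell (pig SCNT)."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for stage in ("2cell", "4cell", "8cell"):
        hits = 0
        for _ in range(n_runs):
            cfg = GeneratorConfig(
                n_genes=n_genes,
                seed=int(rng.integers(0, 2**31 - 1)),
                conditions=(ConditionSpec("sim", "pig", stage),),
            )
            study = generate(cfg)
            cm = study.counts["sim"]
            reg, _ = regulated_counts(cm, tmm_factors(cm))
            if detect_zga(reg) == stage:
                hits += 1
        out[stage] = {"rate": hits / n_runs, "n": n_runs}
    return out


def classification_recovery(seed: int, n_genes: int = 3000) -> dict:
    """Maternal/zygotic recovery: exact on noiseless data, Jaccard on noisy."""
    cond = (ConditionSpec("sim", "pig", "4cell"),)
    out: dict = {"n": n_genes}
    for label, dispersion in (("noiseless", 0.0), ("noisy", 0.1)):
        study = generate(
            GeneratorConfig(
                n_genes=n_genes, dispersion=dispersion, seed=seed, conditions=cond
            )
        )
        cm = study.counts["sim"]
        nf = tmm_factors(cm)
        em = rpkm(cm, study.annotations["pig"], nf)
        calls = stage_call_set(cm, em, nf)
        universe = set(cm.gene_ids)
        mat = truth_eval(calls.maternal_genes, study.truth.maternal["sim"], universe)
        zyg = truth_eval(calls.zygotic_genes, study.truth.zygotic["sim"], universe)
        out[label] = {
            "maternal_jaccard": mat["jaccard"],
            "zygotic_jaccard": zyg["jaccard"],
            "maternal_exact": calls.maternal_genes == study.truth.maternal["sim"],
            "zygotic_exact": calls.zygotic_genes == study.truth.zygotic["sim"],
        }
    return out


def icm_recovery(seed: int, n_genes: int = 5000, mixing_fraction: float = 0.5) -> dict:
    """Sensitivity/specificity of the ICMTE-vs-TE subtraction test."""
    study = generate(
        GeneratorConfig(
            n_genes=n_genes,
            mixing_fraction=mixing_fraction,
            seed=seed,
            conditions=(ConditionSpec("sim", "pig", "4cell"),),
        )
    )
    cm = study.counts["sim"]
    nf = tmm_factors(cm)
    icm, _ = infer_icm_specific(
        cm,
        study.annotations["pig"],
        nf,
        cm.samples.samples_for_stage("ICMTE"),
        cm.samples.samples_for_stage("TE"),
    )
    m = truth_eval(icm, study.truth.icm_specific["sim"], set(cm.gene_ids))
    return {
        "sensitivity": m["sensitivity"],
        "specificity": m["specificity"],
        "n": n_genes,
        "n_planted": len(study.truth.icm_specific["sim"]),
    }


def maternal_overlap_recovery(
    seed: int, n_genes: int = 10_000, share: float = 0.8
) -> dict:
    """Cross-species maternal overlap percentage at a planted sharing level."""
    conds = (
        ConditionSpec("pig", "pig", "4cell"),
        ConditionSpec("mouse", "mouse", "2cell", maternal_share=share, zygotic_share=share),
    )
    study = generate(GeneratorConfig(n_genes=n_genes, conditions=conds, seed=seed))
    sets = {}
    for name, cm in study.counts.items():
        ann = study.annotations[cm.samples.table["species"].iloc[0]]
        nf = tmm_factors(cm)
        em = rpkm(cm, ann, nf)
        from .stage_dynamics import call_maternal

        mat = call_maternal(em, cm.samples.samples_for_stage("oocyte"))
        sets[name] = ortholog_space(mat, study.orthologs)
    rep = overlap_stats(sets)
    return {"overlap_pct": rep.shared_pct["pig"], "n": n_genes}


def network_recovery(seed: int, n_targets: int = 20, n_noise: int = 200) -> dict:
    """Edge-recovery F1 on the planted marker-module simulation."""
    panel = MarkerPanel.default()
    profiles, truth = simulate_marker_network(
        panel.all_markers, n_targets=n_targets, n_noise=n_noise, seed=seed
    )
    em = profiles_to_expression(profiles)
    net = build_network(em, panel, threshold=0.9)
    markers = set(panel.all_markers)
    called = {(u, v) if u in markers else (v, u) for u, v in net.graph.edges()}
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    return {"f1": f1, "n": len(truth)}
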