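"""End-to-end orchestration: quantify -> stage dynamics -> lineage ->
cross-species -> network, with every artifact written to a report directory
and a deterministic JSON summary."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as esio
from .config import PipelineConfig
from .cross_species import hierarchical_cluster, overlap_stats, similarity
from .datamodel import CountMatrix, GeneAnnotation, OrthologTable, ValidationError
from .lineage import lineage_call_set
from .network import MarkerPanel, build_network, export_network, remove_singletons
from .quantify import NormalizationFactors, log_transform, rpkm, tmm_factors
from .stage_dynamics import stage_call_set

log = logging.getLogger("embryostage")


def ortholog_space(genes, ot: OrthologTable) -> set[str]:
    """Project a gene set into the ortholog table's first-species id space,
    keeping only one-to-one mapped genes."""
    a2b = ot.a_to_b()
    b2a = ot.b_to_a()
    out: set[str] = set()
    for g in genes:
        if g in a2b:
            out.add(g)
        elif g in b2a:
            out.add(b2a[g])
    return out


def analyze_condition(
    cm: CountMatrix,
    ann: GeneAnnotation,
    cfg: PipelineConfig,
    condition: str | None = None,
    panel: MarkerPanel | None = None,
) -> dict:
    """Run the full single-condition analysis; returns in-memory artifacts."""
    nf = tmm_factors(cm, cfg.trim_m, cfg.trim_a) if cfg.use_tmm else None
    em = rpkm(cm, ann, nf)
    out: dict = {"nf": nf, "em": em}

    stages = cm.samples.stages_present()
    if "oocyte" in stages and len(stages) >= 2:
        calls = stage_call_set(
            cm,
            em,
            nf,
            condition=condition,
            alpha=cfg.alpha,
            min_fc=cfg.min_fc,
            maternal_threshold=cfg.maternal_rpkm,
            expressed_threshold=cfg.expressed_rpkm,
        )
        out["stage_calls"] = calls
        log.info(
            "stage dynamics%s: ZGA at %s; %d maternal, %d zygotic genes",
            f" [{condition}]" if condition else "",
            calls.zga_stage,
            len(calls.maternal_genes),
            len(calls.zygotic_genes),
        )

    needed = {"ICMTE", "TE", "morula"}
    if needed <= set(stages):
        lin = lineage_call_set(
            cm,
            ann,
            nf,
            cm.samples.samples_for_stage("ICMTE", condition),
            cm.samples.samples_for_stage("TE", condition),
            cm.samples.samples_for_stage("morula", condition),
            alpha=cfg.alpha,
            min_fc=cfg.min_fc,
            min_rpkm=cfg.icm_min_rpkm,
            expressed_threshold=cfg.expressed_rpkm,
        )
        out["lineage_calls"] = lin
        log.info(
            "lineage%s: %d ICM-specific, %d TE-enriched genes",
            f" [{condition}]" if condition else "",
            len(lin.icm_specific),
            len(lin.te_enriched),
        )

    panel = panel or MarkerPanel.default()
    if any(m in em.values.index for m in panel.all_markers) and len(stages) >= 4:
        net = build_network(
            em,
            panel,
            threshold=cfg.correlation_threshold,
            expression_floor=cfg.network_expression_floor,
            log_base=cfg.log_base,
            pseudocount=cfg.pseudocount,
        )
        out["network"] = remove_singletons(
            net, cfg.singleton_min_shared, cfg.singleton_denominator
        )
    return out


def run_all(
    conditions: dict[str, tuple[CountMatrix, GeneAnnotation]],
    cfg: PipelineConfig,
    out_dir: str | Path,
    orthologs: OrthologTable | None = None,
    panel: MarkerPanel | None = None,
) -> dict:
    """Analyze every condition, compare them, write artifacts + summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"conditions": {}}
    results: dict[str, dict] = {}

    for name, (cm, ann) in conditions.items():
        res = analyze_condition(cm, ann, cfg, panel=panel)
        results[name] = res
        cdir = out_dir / name
        cdir.mkdir(exist_ok=True)
        esio.write_expression(res["em"], cdir / "rpkm.tsv")
        entry: dict = {
            "n_genes": cm.n_genes,
            "n_samples": cm.n_samples,
        }
        if "stage_calls" in res:
            calls = res["stage_calls"]
            esio.write_gene_list(calls.maternal_genes, cdir / "maternal_genes.txt")
            esio.write_gene_list(calls.zygotic_genes, cdir / "zygotic_genes.txt")
            calls.regulated.to_csv(cdir / "zga_report.tsv", sep="\t")
            entry.update(
                zga_stage=calls.zga_stage,
                n_maternal=len(calls.maternal_genes),
                n_zygotic=len(calls.zygotic_genes),
            )
        if "lineage_calls" in res:
            lin = res["lineage_calls"]
            esio.write_gene_list(lin.icm_specific, cdir / "icm_specific_genes.txt")
            esio.write_gene_list(lin.te_enriched, cdir / "te_enriched_genes.txt")
            entry.update(
                n_icm_specific=len(lin.icm_specific),
                n_te_enriched=len(lin.te_enriched),
                n_morula_icm_coexpressed=len(lin.morula_icm_coexpressed),
                n_morula_te_coexpressed=len(lin.morula_te_coexpressed),
            )
        if "network" in res:
            export_network(res["network"], cdir / "network_edges.tsv")
            entry["n_network_edges"] = res["network"].graph.number_of_edges()
        # within-condition similarity + clustering
        sim = similarity(
            res["em"], log_base=cfg.log_base, pseudocount=cfg.pseudocount
        )
        for coef, mat in sim.items():
            mat.to_csv(cdir / f"similarity_{coef}.tsv", sep="\t", float_format="%.10g")
        logged = log_transform(res["em"], cfg.log_base, cfg.pseudocount)
        dend = hierarchical_cluster(logged.values.T)
        (cdir / "dendrogram.newick").write_text(dend.to_newick() + "\n")
        summary["conditions"][name] = entry

    if orthologs is not None and len(results) >= 2:
        overlaps: dict = {}
        for kind in ("maternal_genes", "zygotic_genes"):
            sets = {}
            for name, res in results.items():
                calls = res.get("stage_calls")
                if calls is not None:
                    sets[name] = ortholog_space(getattr(calls, kind), orthologs)
            if len(sets) >= 2:
                report = overlap_stats(dict(list(sets.items())[:3]))
                overlaps[kind] = report.as_dict()
        summary["overlaps"] = overlaps

    text = json.dumps(summary, indent=2, sort_keys=True)
    (out_dir / "summary.json").write_text(text + "\n")
    return summary
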