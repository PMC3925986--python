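"""Marker-hub co-expression network over the developmental stage series.

Each lineage marker (ICM segregation, primitive endoderm differentiation, TE
commitment) becomes a hub; a candidate gene is linked to a marker when the
absolute Pearson correlation of their stage-mean expression profiles, taken
over all points of the series, exceeds the threshold (strictly; default 0.9).
Marker-centred sub-networks that share fewer than 5% of their targets with
every other marker's sub-network are "singletons" and are removed together
with their exclusive targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, ValidationError
from .quantify import log_transform

log = logging.getLogger("embryostage")

# Marker genes for the three lineage layers, after restricting to genes with
# one-to-one pig/mouse orthologs (Klf2, Rex1, Gata4, Mixl1, Sox7 and Pace4
# have no such ortholog and are excluded from the default panel).
ICM_MARKERS_FULL = (
    "Pou5f1", "Sox2", "Klf2", "Nanog", "Rex1", "Utf1", "Zfx", "Esrrb",
    "Tbx3", "Tcl1", "Klf4",
)
PE_MARKERS_FULL = (
    "Gata6", "Gata4", "Gdf1", "Gdf3", "Hnf4a", "Mixl1", "Sall4", "Sox7", "Sox17",
)
TE_MARKERS_FULL = (
    "Cdx2", "Eomes", "Hand1", "Fgfr2", "Ets2", "Tcfap2", "Elf5", "Etv4",
    "Furin", "Ccdc3", "Pace4", "Casq1", "Wnt7a", "Fgf5", "Pax6", "Tead4",
)
NON_ORTHOLOGOUS = ("Klf2", "Rex1", "Gata4", "Mixl1", "Sox7", "Pace4")


@dataclass(frozen=True)
class MarkerPanel:
    """Three disjoint marker groups keyed by lineage layer."""

    icm: tuple[str, ...]
    primitive_endoderm: tuple[str, ...]
    te: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [set(self.icm), set(self.primitive_endoderm), set(self.te)]
        if len(set.union(*groups)) != sum(len(g) for g in groups):
            raise ValidationError("marker groups must be disjoint")

    @classmethod
    def default(cls) -> "MarkerPanel":
        drop = set(NON_ORTHOLOGOUS)
        return cls(
            icm=tuple(m for m in ICM_MARKERS_FULL if m not in drop),
            primitive_endoderm=tuple(m for m in PE_MARKERS_FULL if m not in drop),
            te=tuple(m for m in TE_MARKERS_FULL if m not in drop),
        )

    @property
    def all_markers(self) -> tuple[str, ...]:
        return self.icm + self.primitive_endoderm + self.te

    def group_of(self, marker: str) -> str:
        if marker in self.icm:
            return "ICM"
        if marker in self.primitive_endoderm:
            return "PE"
        if marker in self.te:
            return "TE"
        raise KeyError(marker)


@dataclass
class CoexpressionNetwork:
    """Undirected marker-target graph; every edge touches >= 1 marker."""

    graph: nx.Graph
    markers: tuple[str, ...]

    def target_sets(self) -> dict[str, set[str]]:
        """Non-marker neighbours per marker present in the graph."""
        marker_set = set(self.markers)
        return {
            m: {n for n in self.graph.neighbors(m) if n not in marker_set}
            for m in self.markers
            if m in self.graph
        }

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "weight"])

    def component_membership(self) -> dict[str, int]:
        return {
            node: i
            for i, comp in enumerate(
                sorted(nx.connected_components(self.graph), key=lambda c: sorted(c)[0])
            )
            for node in comp
        }


def build_network(
    em: ExpressionMatrix,
    panel: MarkerPanel | None = None,
    threshold: float = 0.9,
    expression_floor: float = 3.0,
    stages: Sequence[str] | None = None,
    log_base: int = 10,
    pseudocount: float = 1.0,
) -> CoexpressionNetwork:
    """Correlate every marker with every expressed candidate gene.

    Profiles are stage means of log expression over the whole series (>= 4
    stages required).  Candidates are non-marker genes whose RPKM exceeds
    `expression_floor` at at least one stage.  An edge is added when
    |Pearson r| > `threshold` (strict), weighted by |r|.
    """
    panel = panel or MarkerPanel.default()
    raw_means = em.stage_means(stages)  # genes x stages, RPKM units
    if raw_means.shape[1] < 4:
        raise ValidationError("need >= 4 stages for profile correlation")
    logged = log_transform(em, base=log_base, pseudocount=pseudocount)
    profiles = logged.stage_means(stages)

    markers = [m for m in panel.all_markers if m in profiles.index]
    absent = [m for m in panel.all_markers if m not in profiles.index]
    if absent:
        log.warning("network: markers absent from expression data: %s", absent)

    marker_set = set(markers)
    expressed = raw_means.max(axis=1) > expression_floor
    candidates = [g for g in profiles.index[expressed] if g not in set(panel.all_markers)]

    graph = nx.Graph()
    for m in markers:
        graph.add_node(m, group=panel.group_of(m), hub=True)

    if markers and candidates:
        mk = profiles.loc[markers].to_numpy(dtype=float)
        cd = profiles.loc[candidates].to_numpy(dtype=float)

        def standardize(x: np.ndarray) -> np.ndarray:
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            out = np.zeros_like(x)
            np.divide(x - mu, sd, out=out, where=sd > 0)
            return out

        r = standardize(mk) @ standardize(cd).T / mk.shape[1]  # markers x candidates
        hits = np.argwhere(np.abs(r) > threshold)
        for i, j in hits:
            g = candidates[j]
            if g not in graph:
                graph.add_node(g, group="target", hub=False)
            graph.add_edge(markers[i], g, weight=float(abs(r[i, j])))
    return CoexpressionNetwork(graph=graph, markers=tuple(markers))


def shared_target_fraction(
    targets_a: set[str], targets_b: set[str], denominator: str = "min"
) -> float:
    """Fraction of targets two markers share, per the chosen convention."""
    inter = len(targets_a & targets_b)
    if denominator == "min":
        denom = min(len(targets_a), len(targets_b))
    elif denominator == "union":
        denom = len(targets_a | targets_b)
    else:
        raise ValidationError("denominator must be 'min' or 'union'")
    return inter / denom if denom else 0.0


def remove_singletons(
    net: CoexpressionNetwork,
    min_shared_fraction: float = 0.05,
    denominator: str = "min",
) -> CoexpressionNetwork:
    """Drop marker sub-networks isolated from every other marker.

    A marker m is a singleton when, for every other marker m', the shared
    target fraction |T(m) & T(m')| / min(|T(m)|, |T(m')|) stays below
    `min_shared_fraction`.  Singleton markers are removed together with their
    exclusive targets (targets with no surviving marker neighbour) and all
    incident edges.  Idempotent.
    """
    targets = net.target_sets()
    markers = [m for m in net.markers if m in net.graph]
    if len(markers) <= 1:
        if markers:
            log.warning("singleton removal on a single-marker network removes everything")
        return CoexpressionNetwork(graph=nx.Graph(), markers=net.markers)

    doomed = []
    for m in markers:
        best = max(
            shared_target_fraction(targets[m], targets[o], denominator)
            for o in markers
            if o != m
        )
        if best < min_shared_fraction:
            doomed.append(m)

    graph = net.graph.copy()
    survivors = set(markers) - set(doomed)
    for m in doomed:
        exclusive = {
            t for t in targets[m] if not any(t in targets[s] for s in survivors)
        }
        graph.remove_nodes_from(exclusive & set(graph.nodes))
        if m in graph:
            graph.remove_node(m)
    return CoexpressionNetwork(graph=graph, markers=net.markers)


def export_network(
    net: CoexpressionNetwork, path: str | Path, fmt: str = "edgelist"
) -> Path:
    """Write the network as a 3-column edge-list TSV or GraphML."""
    path = Path(path)
    if fmt == "edgelist":
        net.edges_table().to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValidationError("format must be 'edgelist' or 'graphml'")
    return path


def read_network(path: str | Path, markers: Iterable[str], fmt: str = "edgelist") -> CoexpressionNetwork:
    """Round-trip reader for :func:`export_network` output."""
    path = Path(path)
    markers = tuple(markers)
    if fmt == "edgelist":
        table = pd.read_csv(path, sep="\t")
        graph = nx.Graph()
        for _, row in table.iterrows():
            graph.add_edge(str(row["source"]), str(row["target"]), weight=float(row["weight"]))
    elif fmt == "graphml":
        graph = nx.read_graphml(path)
    else:
        raise ValidationError("format must be 'edgelist' or 'graphml'")
    return CoexpressionNetwork(graph=graph, markers=markers)
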