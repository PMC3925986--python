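"""Cross-species comparison: ortholog mapping, overlap (Venn) statistics,
transcriptome similarity by three correlation coefficients, and average-linkage
hierarchical clustering of samples with Newick export.

Which three coefficients the original similarity analysis used is not
documented anywhere; this module computes the most common triple — Pearson,
Spearman (average-rank ties) and Kendall tau-b — and labels outputs
explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ExpressionMatrix, OrthologTable, ValidationError

log = logging.getLogger("embryostage")

COEFFICIENTS = ("pearson", "spearman", "kendall")


def map_orthologs(
    genes_a: Sequence[str] | set[str],
    genes_b: Sequence[str] | set[str],
    ot: OrthologTable,
) -> list[tuple[str, str]]:
    """Aligned (gene_a, gene_b) pairs where both partners are present."""
    set_a, set_b = set(genes_a), set(genes_b)
    pairs = ot.pairs
    keep = pairs["gene_a"].isin(set_a) & pairs["gene_b"].isin(set_b)
    return list(map(tuple, pairs.loc[keep, ["gene_a", "gene_b"]].itertuples(index=False)))


@dataclass(frozen=True)
class OverlapReport:
    """Exact intersection arithmetic over 2 or 3 named gene sets."""

    set_sizes: dict[str, int]
    intersections: dict[tuple[str, ...], int]
    shared_pct: dict[str, float]  # % of each set inside the common intersection
    jaccard: dict[tuple[str, ...], float]
    undefined: tuple[str, ...] = ()  # sets whose percentage is undefined (empty)

    def as_dict(self) -> dict:
        return {
            "set_sizes": dict(self.set_sizes),
            "intersections": {"&".join(k): v for k, v in self.intersections.items()},
            "shared_pct": dict(self.shared_pct),
            "jaccard": {"&".join(k): v for k, v in self.jaccard.items()},
            "undefined": list(self.undefined),
        }


def overlap_stats(sets: Mapping[str, set[str] | frozenset[str]]) -> OverlapReport:
    """Pairwise and (for three sets) three-way overlap statistics.

    ``shared_pct[X]`` is |intersection of all sets| / |X| * 100; empty sets
    are flagged as undefined rather than reported as 0.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValidationError("overlap_stats takes 2 or 3 named sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    sizes = {k: len(v) for k, v in as_sets.items()}

    inter: dict[tuple[str, ...], int] = {}
    jac: dict[tuple[str, ...], float] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            cap = as_sets[a] & as_sets[b]
            cup = as_sets[a] | as_sets[b]
            inter[(a, b)] = len(cap)
            jac[(a, b)] = len(cap) / len(cup) if cup else float("nan")
    common = set.intersection(*as_sets.values())
    if len(names) == 3:
        inter[tuple(names)] = len(common)

    shared = {}
    undefined = []
    for k in names:
        if sizes[k] == 0:
            shared[k] = float("nan")
            undefined.append(k)
        else:
            shared[k] = 100.0 * len(common) / sizes[k]
    return OverlapReport(sizes, inter, shared, jac, tuple(undefined))


def _corr_matrix(values: np.ndarray, method: str) -> np.ndarray:
    """Pairwise column correlations; constant columns yield NaN entries."""
    n = values.shape[1]
    out = np.full((n, n), np.nan)
    const = values.max(axis=0) == values.min(axis=0)
    if method == "pearson":
        ok = ~const
        if ok.sum() >= 1:
            sub = np.corrcoef(values[:, ok], rowvar=False)
            sub = np.atleast_2d(sub)
            idx = np.flatnonzero(ok)
            out[np.ix_(idx, idx)] = sub
    elif method == "spearman":
        ranks = np.apply_along_axis(stats.rankdata, 0, values)
        return _corr_matrix(ranks, "pearson")
    elif method == "kendall":
        for i in range(n):
            for j in range(i, n):
                if const[i] or const[j]:
                    continue
                tau = stats.kendalltau(values[:, i], values[:, j], variant="b").statistic
                out[i, j] = out[j, i] = tau
    else:
        raise ValidationError(f"unknown coefficient {method!r}")
    np.fill_diagonal(out, np.where(const, np.nan, 1.0))
    return out


def similarity(
    em_a: ExpressionMatrix,
    em_b: ExpressionMatrix | None = None,
    ot: OrthologTable | None = None,
    coefficients: Sequence[str] = COEFFICIENTS,
    log_base: int = 10,
    pseudocount: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Sample-by-sample similarity matrices over log-transformed RPKM.

    With two matrices, genes are aligned through the one-to-one ortholog
    table before pooling samples.  Each requested coefficient yields a
    symmetric matrix with unit diagonal; samples with constant log profiles
    produce NaN (undefined) entries.
    """
    if em_b is not None:
        if ot is None:
            raise ValidationError("ortholog table required to compare two matrices")
        pairs = map_orthologs(em_a.gene_ids, em_b.gene_ids, ot)
        if len(pairs) < 3:
            raise ValidationError("fewer than 3 shared (ortholog-mapped) genes")
        ids_a = [a for a, _ in pairs]
        ids_b = [b for _, b in pairs]
        left = em_a.values.loc[ids_a].to_numpy(dtype=float)
        right = em_b.values.loc[ids_b].to_numpy(dtype=float)
        values = np.hstack([left, right])
        columns = list(em_a.values.columns) + list(em_b.values.columns)
    else:
        if em_a.values.shape[0] < 3:
            raise ValidationError("fewer than 3 shared genes")
        values = em_a.values.to_numpy(dtype=float)
        columns = list(em_a.values.columns)

    logged = np.log(values + pseudocount) / np.log(log_base)
    out = {}
    for method in coefficients:
        mat = _corr_matrix(logged, method)
        out[method] = pd.DataFrame(mat, index=columns, columns=columns)
    return out


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over samples (heights in Euclidean units)."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: tuple[str, ...]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string; branch lengths are parent-child height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """UPGMA-style average-linkage clustering of samples.

    Parameters
    ----------
    profiles
        Samples as rows, features (genes) as columns.  Rows are sorted
        lexicographically by sample id before clustering so tie-breaking is
        deterministic.
    """
    if profiles.shape[0] < 2:
        raise ValidationError("need at least two samples to cluster")
    arr = profiles.to_numpy(dtype=float)
    if np.isnan(arr).any():
        g, s = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"NaN in clustering input at sample {profiles.index[g]!r}, "
            f"feature {profiles.columns[s]!r}"
        )
    order = np.argsort(profiles.index.astype(str), kind="stable")
    profiles = profiles.iloc[order]
    z = hierarchy.linkage(pdist(profiles.to_numpy(dtype=float)), method="average")
    return Dendrogram(linkage=z, labels=tuple(map(str, profiles.index)))
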