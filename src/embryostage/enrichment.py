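"""Category (GO-style) over-representation with an optional gene-length-aware
resampling null.

RNA-seq gene lists are biased toward long genes (more reads, more power), so
a plain hypergeometric test over-states enrichment of categories rich in long
genes.  The length-aware test replaces the uniform null by Monte-Carlo
resampling of same-size gene lists where each gene's selection weight comes
from a monotone (isotonic) fit of list membership on log length — a direct
resampling analogue of length-bias-adjusted enrichment.  The resampling
p-value carries an add-one correction so it is never 0.

Category annotations are a plain table (gene_id, category_id[, category_name]);
no ontology topology is used.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .datamodel import GeneAnnotation, ValidationError
from .diffexpr import bh_adjust

log = logging.getLogger("embryostage")

RESULT_COLUMNS = ("category_id", "k", "n", "K", "N", "p", "q")


def _category_table(categories: pd.DataFrame, universe: set[str]) -> dict[str, set[str]]:
    cats: dict[str, set[str]] = {}
    tab = categories.iloc[:, :2]
    tab.columns = ["gene_id", "category_id"]
    for cat, sub in tab.groupby("category_id"):
        members = set(sub["gene_id"].astype(str)) & universe
        if members:
            cats[str(cat)] = members
        else:
            log.warning("enrichment: category %s absent from universe; skipped", cat)
    return cats


def hypergeom_enrich(
    gene_list: set[str] | frozenset[str],
    categories: pd.DataFrame,
    universe: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per category.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with universe size N, category
    size K and list size n; BH adjustment across categories.
    """
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list <= universe:
        raise ValidationError("gene list must be a subset of the universe")
    cats = _category_table(categories, universe)
    n, big_n = len(gene_list), len(universe)
    rows = []
    for cat in sorted(cats):
        members = cats[cat]
        k, big_k = len(gene_list & members), len(members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append((cat, k, n, big_k, big_n, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["category_id", "k", "n", "K", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("q", kind="stable").reset_index(drop=True)


def _length_weights(
    universe_genes: list[str], in_list: np.ndarray, lengths: pd.Series
) -> np.ndarray:
    """Selection weights from a monotone fit of membership on log length."""
    x = np.log(lengths.loc[universe_genes].to_numpy(dtype=float))
    if np.allclose(x, x[0]):
        log.info("enrichment: degenerate (equal) lengths; uniform weights")
        return np.full(len(universe_genes), 1.0 / len(universe_genes))
    iso = IsotonicRegression(increasing="auto", out_of_bounds="clip")
    fitted = iso.fit_transform(x, in_list.astype(float))
    w = np.clip(fitted, 1e-8, None)
    return w / w.sum()


def length_aware_enrich(
    gene_list: set[str] | frozenset[str],
    categories: pd.DataFrame,
    universe: set[str] | frozenset[str],
    ann: GeneAnnotation,
    n_resample: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Monte-Carlo length-bias-aware over-representation test.

    Resamples ``len(gene_list)`` genes (without replacement) from the
    universe with length-derived weights and compares each category's
    observed hit count k against the resampled null:
    p = (1 + #{k* >= k}) / (1 + n_resample).
    """
    if n_resample < 1:
        raise ValidationError("n_resample must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = set(universe)
    gene_list = set(gene_list)
    if not gene_list <= universe:
        raise ValidationError("gene list must be a subset of the universe")
    universe_genes = sorted(universe)
    lengths = ann.lengths_for(universe_genes)
    in_list = np.fromiter((g in gene_list for g in universe_genes), dtype=bool)
    weights = _length_weights(universe_genes, in_list, lengths)

    cats = _category_table(categories, universe)
    cat_names = sorted(cats)
    membership = np.zeros((len(cat_names), len(universe_genes)), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(universe_genes)}
    for ci, cat in enumerate(cat_names):
        membership[ci, [gene_pos[g] for g in cats[cat]]] = True
    observed = membership[:, in_list].sum(axis=1)

    n = len(gene_list)
    exceed = np.zeros(len(cat_names), dtype=np.int64)
    idx = np.arange(len(universe_genes))
    for _ in range(n_resample):
        draw = rng.choice(idx, size=n, replace=False, p=weights)
        kstar = membership[:, draw].sum(axis=1)
        exceed += kstar >= observed
    p = (1.0 + exceed) / (1.0 + n_resample)

    rows = []
    for ci, cat in enumerate(cat_names):
        rows.append((cat, int(observed[ci]), n, len(cats[cat]), len(universe), p[ci]))
    out = pd.DataFrame(rows, columns=["category_id", "k", "n", "K", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("q", kind="stable").reset_index(drop=True)
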