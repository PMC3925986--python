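"""Replicate-free differential expression between two pooled libraries.

The study design pools 4-10 embryos per sample with no biological replicates
per comparison group, so dispersion cannot be estimated per gene.  Under a
random-sampling model, conditional on the total t = k1 + k2 of a gene's counts
in the two (pooled) libraries, k1 ~ Binomial(t, n1 / (n1 + n2)) when the gene
is expressed at the same proportion in both — an exact conditional test that
needs no replicates.  The two-sided p-value doubles the smaller tail
(inclusive of the observed count) and is capped at 1.  Totals above
``EXACT_MAX_TOTAL`` use a normal approximation with continuity correction.

Significance follows the joint rule: Benjamini-Hochberg adjusted p < alpha
and fold change > min_fc (or < 1/min_fc), both strict.  Fold changes are
ratios of normalized count proportions with a pseudocount of 0.5 added to
both pooled counts.

The classic alternative for this design is an MA-plot z-test — a normal
approximation to the same sampling model; ``ma_ztest_pvalues`` provides it
for comparison.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, ValidationError
from .quantify import NormalizationFactors

EXACT_MAX_TOTAL = 10_000
FC_PSEUDOCOUNT = 0.5


def conditional_binomial_pvalues(
    k1, k2, n1, n2, exact_max_total: int = EXACT_MAX_TOTAL
) -> np.ndarray:
    """Vectorized two-sided conditional binomial p-values.

    Parameters
    ----------
    k1, k2
        Counts in the two libraries (arrays or scalars).
    n1, n2
        Effective library sizes (> 0).
    """
    k1 = np.atleast_1d(np.asarray(k1, dtype=np.int64))
    k2 = np.atleast_1d(np.asarray(k2, dtype=np.int64))
    n1 = float(n1)
    n2 = float(n2)
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    t = k1 + k2
    pi = n1 / (n1 + n2)
    p = np.ones(t.shape, dtype=float)

    exact = (t > 0) & (t <= exact_max_total)
    if exact.any():
        te, ke = t[exact], k1[exact]
        lower = stats.binom.cdf(ke, te, pi)
        upper = stats.binom.sf(ke - 1, te, pi)
        p[exact] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

    approx = t > exact_max_total
    if approx.any():
        ta, ka = t[approx].astype(float), k1[approx].astype(float)
        mu = ta * pi
        sd = np.sqrt(ta * pi * (1.0 - pi))
        lower = stats.norm.cdf((ka + 0.5 - mu) / sd)
        upper = stats.norm.sf((ka - 0.5 - mu) / sd)
        p[approx] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return p


def conditional_binomial_test(k1: int, k2: int, n1: float, n2: float) -> float:
    """Scalar convenience wrapper around :func:`conditional_binomial_pvalues`."""
    return float(conditional_binomial_pvalues([k1], [k2], n1, n2)[0])


def ma_ztest_pvalues(k1, k2, n1, n2) -> np.ndarray:
    """MA-plot normal z-test on log2 ratios, for comparison.

    Under the random-sampling model, M = log2(k1) - log2(k2) given t has an
    approximately normal distribution; the test standardizes M against its
    estimated null mean and variance.
    """
    k1 = np.atleast_1d(np.asarray(k1, dtype=float))
    k2 = np.atleast_1d(np.asarray(k2, dtype=float))
    t = k1 + k2
    pi = float(n1) / (float(n1) + float(n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2(k1) - np.log2(k2)
        mu0 = np.log2(pi / (1 - pi))
        # delta-method variance of M given t under H0
        var = (1.0 / (t * pi) + 1.0 / (t * (1 - pi))) / (np.log(2.0) ** 2)
        z = (m - mu0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~np.isfinite(p)] = 1.0
    return np.minimum(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def de_table(
    cm: CountMatrix,
    nf: NormalizationFactors | None,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
    method: str = "binomial",
) -> pd.DataFrame:
    """Per-gene differential expression between two pooled sample groups.

    Counts within each group are summed (pooled-embryo design) and effective
    library sizes are pooled accordingly.  Returns a DataFrame indexed by
    gene id with columns ``count_a, count_b, fc, log2fc, p, q, direction,
    significant``; ``fc`` is the group-A/group-B ratio of pooled proportions
    (pseudocount 0.5 on both pooled counts).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValidationError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    if method not in ("binomial", "ma_ztest"):
        raise ValidationError(f"unknown test method {method!r}")

    if nf is None:
        nf = NormalizationFactors.unit(cm.counts.columns)
    eff = nf.effective_library_sizes(cm)
    k1 = cm.counts[group_a].sum(axis=1).to_numpy()
    k2 = cm.counts[group_b].sum(axis=1).to_numpy()
    n1 = float(eff[group_a].sum())
    n2 = float(eff[group_b].sum())

    if method == "binomial":
        p = conditional_binomial_pvalues(k1, k2, n1, n2)
    else:
        p = ma_ztest_pvalues(k1, k2, n1, n2)
    q = bh_adjust(p)

    fc = ((k1 + FC_PSEUDOCOUNT) / n1) / ((k2 + FC_PSEUDOCOUNT) / n2)
    log2fc = np.log2(fc)
    significant = (q < alpha) & ((fc > min_fc) | (fc < 1.0 / min_fc))
    direction = np.where(fc > 1.0, "up", np.where(fc < 1.0, "down", "none"))

    return pd.DataFrame(
        {
            "count_a": k1,
            "count_b": k2,
            "fc": fc,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
            "significant": significant,
        },
        index=cm.counts.index,
    )


def significant_up(de: pd.DataFrame) -> pd.Index:
    return de.index[de["significant"] & (de["direction"] == "up")]


def significant_down(de: pd.DataFrame) -> pd.Index:
    return de.index[de["significant"] & (de["direction"] == "down")]
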