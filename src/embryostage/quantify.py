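"""Library-size normalization and RPKM quantification.

Per-sample scaling factors use the trimmed mean of M-values (TMM): pick the
library whose upper-quartile count-per-million is closest to the mean
upper-quartile as the reference, compute per-gene log2 proportion ratios (M)
and mean log2 abundances (A) against it over genes observed in both libraries,
discard the extreme 30% of M and 5% of A, and average the surviving M values
with delta-method precision weights.  Factors are rescaled to geometric mean
one, so the product of library size and factor (the *effective* library size)
preserves total scale.

RPKM (reads per kilobase of coding sequence per million mapped reads) is

    rpkm(g, s) = 1e9 * count(g, s) / (effective_library_size(s) * length_bp(g))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExpressionMatrix, GeneAnnotation, ValidationError

log = logging.getLogger("embryostage")

#: fewer surviving genes than this triggers the factor-1 fallback
MIN_GENES_AFTER_TRIM = 10


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean one)."""

    factors: pd.Series
    reference_sample_id: str

    def __post_init__(self) -> None:
        f = self.factors.astype(float)
        if (f <= 0).any() or not np.isfinite(f).all():
            raise ValidationError("normalization factors must be positive and finite")
        gm = float(np.exp(np.mean(np.log(f))))
        if abs(gm - 1.0) > 1e-9:
            raise ValidationError(f"factors must have geometric mean 1, got {gm}")
        object.__setattr__(self, "factors", f)

    def effective_library_sizes(self, cm: CountMatrix) -> pd.Series:
        lib = cm.library_sizes.astype(float)
        return lib * self.factors.reindex(lib.index)

    @classmethod
    def unit(cls, sample_ids) -> "NormalizationFactors":
        """All-ones factors (plain library-size normalization)."""
        ids = list(sample_ids)
        return cls(pd.Series(1.0, index=ids), reference_sample_id=ids[0])


def _trim_keep_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Keep mask after symmetric trimming of `trim` fraction from each end.

    Ties are broken by original position (stable), so an independently coded
    sort-and-slice implementation gives identical gene sets.
    """
    n = values.size
    k = int(np.floor(n * trim))
    order = np.lexsort((np.arange(n), values))
    keep = np.zeros(n, dtype=bool)
    keep[order[k : n - k]] = True
    return keep


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors for every library.

    Parameters
    ----------
    cm
        Count matrix with at least two samples, each with >= 1 nonzero gene.
    trim_m, trim_a
        Fractions trimmed from each tail of the M and A distributions.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes.to_numpy(dtype=float)
    sample_ids = list(cm.counts.columns)
    if len(sample_ids) < 2:
        raise ValidationError("TMM needs at least two samples")
    if (counts.sum(axis=0) <= 0).any():
        raise ValidationError("every sample needs at least one nonzero gene")

    # Reference: sample whose upper quartile of nonzero counts-per-million is
    # closest to the mean upper quartile.
    cpm = counts / lib * 1e6
    uq = np.array(
        [np.percentile(cpm[counts[:, j] > 0, j], 75) for j in range(len(sample_ids))]
    )
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))

    kr_all = counts[:, ref_j]
    nr = lib[ref_j]
    raw = np.ones(len(sample_ids), dtype=float)
    for j, sid in enumerate(sample_ids):
        if j == ref_j:
            continue
        ks_all = counts[:, j]
        ns = lib[j]
        both = (ks_all > 0) & (kr_all > 0)
        ks, kr = ks_all[both], kr_all[both]
        if ks.size == 0:
            log.warning("TMM: no genes shared with reference for %s; factor 1", sid)
            continue
        ps, pr = ks / ns, kr / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        keep = _trim_keep_mask(m, trim_m) & _trim_keep_mask(a, trim_a)
        if keep.sum() < MIN_GENES_AFTER_TRIM:
            log.warning(
                "TMM: only %d genes survive trimming for %s; falling back to factor 1",
                int(keep.sum()),
                sid,
            )
            continue
        var = (ns - ks[keep]) / (ns * ks[keep]) + (nr - kr[keep]) / (nr * kr[keep])
        w = 1.0 / var
        raw[j] = 2.0 ** (float(np.sum(w * m[keep]) / np.sum(w)))

    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormalizationFactors(
        pd.Series(factors, index=sample_ids), reference_sample_id=sample_ids[ref_j]
    )


def rpkm(
    cm: CountMatrix,
    ann: GeneAnnotation,
    nf: NormalizationFactors | None = None,
) -> ExpressionMatrix:
    """RPKM per gene and sample; effective library sizes when `nf` is given."""
    lengths = ann.lengths_for(cm.gene_ids).to_numpy(dtype=float)
    if nf is None:
        eff = cm.library_sizes.astype(float)
    else:
        eff = nf.effective_library_sizes(cm)
    eff = eff.reindex(cm.counts.columns)
    if (eff <= 0).any():
        zero = eff.index[eff <= 0].tolist()
        raise ValidationError(f"zero or negative library size for samples {zero}")
    vals = 1e9 * cm.counts.to_numpy(dtype=float) / (eff.to_numpy()[None, :] * lengths[:, None])
    df = pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)
    return ExpressionMatrix(df, cm.samples)


def log_transform(
    em: ExpressionMatrix, base: int = 10, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log_base(rpkm + pseudocount); monotone in rpkm."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    if base not in (2, 10):
        raise ValidationError("log base must be 2 or 10")
    vals = np.log(em.values.to_numpy(dtype=float) + pseudocount) / np.log(base)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=em.values.index, columns=em.values.columns), em.samples
    )
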