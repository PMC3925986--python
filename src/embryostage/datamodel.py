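"""Core tabular data model shared by every pipeline stage.

The pipeline operates on pooled-embryo RNA-seq count tables collected along an
ordered developmental stage series (oocyte through blastocyst).  A blastocyst
is physically split into a pure trophectoderm half (``TE``) and a half that
contains the inner cell mass plus some trophectoderm (``ICMTE``); both appear
as ordinary "stages" in the sample sheet.

All containers are thin, validated wrappers around :class:`pandas.DataFrame` /
:class:`pandas.Series`; gene and sample identifiers are opaque strings, and
cross-species joins happen only through :class:`OrthologTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("embryostage")

#: The default ordered stage series (the collection schedule used throughout).
DEFAULT_STAGE_ORDER: tuple[str, ...] = (
    "oocyte",
    "1cell",
    "2cell",
    "4cell",
    "8cell",
    "morula",
    "ICMTE",
    "TE",
)

#: Stages forming the linear cleavage series used for ZGA detection
#: (the two blastocyst halves are parallel endpoints, not consecutive stages).
CLEAVAGE_STAGES: tuple[str, ...] = (
    "oocyte",
    "1cell",
    "2cell",
    "4cell",
    "8cell",
    "morula",
)

SAMPLE_SHEET_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "stage",
    "condition",
    "species",
    "replicate",
)


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sequencing library.

    Parameters
    ----------
    table
        Columns ``sample_id, stage, condition, species, replicate``.
    stage_order
        The configured total order on stage labels.  Every ``stage`` entry
        must be drawn from it; unknown labels are rejected, never coerced.
    """

    table: pd.DataFrame
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        tab = self.table.reset_index(drop=True)[list(SAMPLE_SHEET_COLUMNS)].copy()
        tab["sample_id"] = tab["sample_id"].astype(str)
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        bad = sorted(set(tab["stage"]) - set(self.stage_order))
        if bad:
            raise ValidationError(
                f"stage labels {bad} not in configured stage order {list(self.stage_order)}"
            )
        rep = pd.to_numeric(tab["replicate"], errors="coerce")
        if rep.isna().any() or (rep < 1).any() or (rep != rep.round()).any():
            raise ValidationError("replicate must be a positive integer for every sample")
        tab["replicate"] = rep.astype(int)
        object.__setattr__(self, "table", tab)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def stage_of(self) -> pd.Series:
        """Stage label per sample, indexed by sample id."""
        return self.table.set_index("sample_id")["stage"]

    def samples_for_stage(self, stage: str, condition: str | None = None) -> list[str]:
        tab = self.table
        sel = tab["stage"] == stage
        if condition is not None:
            sel &= tab["condition"] == condition
        return tab.loc[sel, "sample_id"].tolist()

    def stages_present(self) -> list[str]:
        """Stages that have at least one sample, in configured order."""
        have = set(self.table["stage"])
        return [s for s in self.stage_order if s in have]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise ValidationError(f"unknown sample ids: {sorted(missing)}")
        tab = self.table[self.table["sample_id"].isin(wanted)]
        return SampleSheet(tab, self.stage_order)


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples non-negative integer read counts plus sample metadata."""

    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        cts = self.counts
        if cts.index.duplicated().any():
            dup = cts.index[cts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        sheet_ids = set(self.samples.sample_ids)
        col_ids = set(map(str, cts.columns))
        if col_ids - sheet_ids:
            raise ValidationError(
                f"samples missing from sheet: {sorted(col_ids - sheet_ids)}"
            )
        if sheet_ids - col_ids:
            raise ValidationError(
                f"sheet samples absent from count table: {sorted(sheet_ids - col_ids)}"
            )
        arr = cts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("counts contain missing values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at gene {cts.index[g]!r}, sample {cts.columns[s]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at gene {cts.index[g]!r}, sample {cts.columns[s]!r}"
            )
        cts = cts.astype(np.int64)
        cts.index = cts.index.astype(str)
        cts.index.name = "gene_id"
        cts.columns = cts.columns.astype(str)
        object.__setattr__(self, "counts", cts)

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Column sums (mapped reads per library)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.samples.subset(sample_ids))

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.samples)


@dataclass(frozen=True)
class GeneAnnotation:
    """Exonic gene lengths (bp) and optional category memberships."""

    lengths: pd.Series
    categories: pd.DataFrame | None = None  # columns: gene_id, category_id[, category_name]

    def __post_init__(self) -> None:
        lengths = self.lengths
        if lengths.index.duplicated().any():
            raise ValidationError("duplicate gene ids in annotation")
        vals = pd.to_numeric(lengths, errors="coerce")
        if vals.isna().any() or (vals < 1).any():
            bad = lengths.index[(vals.isna()) | (vals < 1)].tolist()
            raise ValidationError(f"gene lengths must be >= 1 bp; offending: {bad[:5]}")
        lengths = vals.astype(np.int64)
        lengths.index = lengths.index.astype(str)
        lengths.index.name = "gene_id"
        lengths.name = "length_bp"
        object.__setattr__(self, "lengths", lengths)

    @property
    def gene_ids(self) -> list[str]:
        return self.lengths.index.tolist()

    def lengths_for(self, gene_ids: Sequence[str]) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.lengths.index]
        if missing:
            raise ValidationError(f"genes missing from annotation: {missing[:5]}")
        return self.lengths.loc[list(gene_ids)]


@dataclass(frozen=True)
class OrthologTable:
    """One-to-one ortholog pairs between two species.

    Any id appearing in more than one pair disqualifies *all* pairs that
    mention it (none of the conflicting pairs is kept); the number dropped
    is logged.
    """

    pairs: pd.DataFrame  # columns gene_a, gene_b

    def __post_init__(self) -> None:
        pairs = self.pairs
        if list(pairs.columns[:2]) != ["gene_a", "gene_b"]:
            pairs = pairs.iloc[:, :2].copy()
            pairs.columns = ["gene_a", "gene_b"]
        pairs = pairs.astype(str).reset_index(drop=True)
        dup_a = pairs["gene_a"].duplicated(keep=False)
        dup_b = pairs["gene_b"].duplicated(keep=False)
        conflicted = dup_a | dup_b
        n_drop = int(conflicted.sum())
        if n_drop:
            log.warning(
                "ortholog table: dropped %d pairs violating one-to-one mapping", n_drop
            )
            pairs = pairs[~conflicted].reset_index(drop=True)
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def a_to_b(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict[str, str]:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples RPKM (or log-RPKM) values with sample metadata."""

    values: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        vals = self.values
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if set(map(str, vals.columns)) != set(self.samples.sample_ids):
            raise ValidationError("expression columns do not match sample sheet")
        vals = vals.astype(float)
        vals.index = vals.index.astype(str)
        vals.index.name = "gene_id"
        vals.columns = vals.columns.astype(str)
        object.__setattr__(self, "values", vals)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    def stage_means(self, stages: Sequence[str] | None = None) -> pd.DataFrame:
        """Mean expression per stage (columns ordered by the configured series)."""
        stage_of = self.samples.stage_of()
        order = list(stages) if stages is not None else self.samples.stages_present()
        out = {}
        for st in order:
            ids = [s for s in self.values.columns if stage_of[s] == st]
            if ids:
                out[st] = self.values[ids].mean(axis=1)
        return pd.DataFrame(out)

    def mean_for_samples(self, sample_ids: Sequence[str]) -> pd.Series:
        return self.values[list(sample_ids)].mean(axis=1)
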