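"""Readers and writers for every tabular format the pipeline touches.

Count tables come as TSV (first column ``gene_id``, one column per sample) or
MatrixMarket triplets (``.mtx`` with ``.rows``/``.cols`` id sidecars); sample
sheets, gene annotations and ortholog tables are TSV.  All writers round-trip
bit-exactly through their readers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import (
    DEFAULT_STAGE_ORDER,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    OrthologTable,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger("embryostage")


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> None:
    """Plain-text run log: one line per pipeline step with parameters."""
    logger = logging.getLogger("embryostage")
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    if logfile is not None:
        handler = logging.FileHandler(logfile)
        handler.setFormatter(fmt)
        logger.addHandler(handler)
    elif not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def read_sample_sheet(
    path: str | Path, stage_order: Sequence[str] = DEFAULT_STAGE_ORDER
) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(table, tuple(stage_order))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> Path:
    path = Path(path)
    sheet.table.to_csv(path, sep="\t", index=False)
    return path


def read_counts(
    path: str | Path,
    sample_sheet_path: str | Path,
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> CountMatrix:
    """Load a count table plus its sample sheet.

    TSV by default; a ``.mtx`` path is read as a MatrixMarket triplet with
    ``<stem>.rows`` / ``<stem>.cols`` one-id-per-line sidecars.  The sheet
    must cover every count column; gene order follows the file.
    """
    path = Path(path)
    sheet = read_sample_sheet(sample_sheet_path, stage_order)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = Path(path.with_suffix(".rows")).read_text().split()
        samples = Path(path.with_suffix(".cols")).read_text().split()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        table = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        table = pd.read_csv(path, sep="\t", index_col=0)
        table.index.name = "gene_id"
    return CountMatrix(table, sheet.subset(list(map(str, table.columns))))


def write_counts(cm: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        path.with_suffix(".rows").write_text("\n".join(cm.counts.index) + "\n")
        path.with_suffix(".cols").write_text("\n".join(cm.counts.columns) + "\n")
    else:
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    return path


def read_annotation(path: str | Path) -> GeneAnnotation:
    """TSV with columns ``gene_id`` and ``length_bp``."""
    table = pd.read_csv(path, sep="\t")
    if "gene_id" not in table.columns or "length_bp" not in table.columns:
        raise ValidationError("annotation needs 'gene_id' and 'length_bp' columns")
    return GeneAnnotation(table.set_index("gene_id")["length_bp"])


def write_annotation(ann: GeneAnnotation, path: str | Path) -> Path:
    path = Path(path)
    out = ann.lengths.rename_axis("gene_id").reset_index()
    out.to_csv(path, sep="\t", index=False)
    return path


def read_orthologs(path: str | Path) -> OrthologTable:
    """Two-column TSV of one-to-one ortholog pairs (header optional)."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty ortholog file: {path}") from None
    if len(table) == 0:
        raise ValidationError(f"ortholog file has no pairs: {path}")
    if table.shape[1] < 2:
        raise ValidationError("ortholog table needs two columns")
    pairs = table.iloc[:, :2].copy()
    pairs.columns = ["gene_a", "gene_b"]
    return OrthologTable(pairs)


def write_orthologs(ot: OrthologTable, path: str | Path) -> Path:
    path = Path(path)
    ot.pairs.to_csv(path, sep="\t", index=False)
    return path


def read_expression(
    path: str | Path,
    sample_sheet_path: str | Path,
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> ExpressionMatrix:
    sheet = read_sample_sheet(sample_sheet_path, stage_order)
    table = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(table, sheet.subset(list(map(str, table.columns))))


def write_expression(em: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_gene_list(path: str | Path) -> frozenset[str]:
    text = Path(path).read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


def write_gene_list(genes, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(sorted(genes)) + ("\n" if genes else ""))
    return path
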