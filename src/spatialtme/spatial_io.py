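"""Dataset I/O, validation, cell-level QC and count normalization.

A dataset on disk is a directory with

* ``cells.tsv`` — one row per cell: ``cell_id, x_um, y_um, fov_id,
  core_id, patient_id, region, cell_type`` (tab-separated, header row).
* ``matrix.mtx`` — MatrixMarket coordinate format, integer counts,
  genes x cells, column order identical to ``cells.tsv`` row order.
* ``genes.tsv`` / ``barcodes.tsv`` — one identifier per line.
* optionally ``survival.tsv`` — ``patient_id, time_months, event``.

All downstream stages assume the invariants enforced here: unique cell
ids, finite coordinates in micrometres, region labels in {T, B, N}, and
a one-to-one mapping from each field of view (FOV) to a single
(core, patient, region) triple.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CELL_COLUMNS = [
    "cell_id",
    "x_um",
    "y_um",
    "fov_id",
    "core_id",
    "patient_id",
    "region",
    "cell_type",
]

REGIONS = ("T", "B", "N")


class ValidationError(ValueError):
    """A dataset violated one of the declared invariants."""


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells count matrix with an optional normalized view.

    ``counts`` holds raw non-negative integer counts; ``normalized``,
    when present, is the log-normalized view (same shape, CSR float)
    produced by :func:`normalize` and consumed by all differential
    expression, correlation and ligand-receptor operations.
    """

    genes: np.ndarray
    cells: np.ndarray
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValidationError("counts contain non-integer entries")
        if self.normalized is not None:
            self.normalized = sp.csr_matrix(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise ValidationError("normalized view shape differs from counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.genes == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not in matrix")
        return int(idx[0])

    def totals(self) -> np.ndarray:
        """Per-cell transcript totals (column sums of the raw counts)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        cols = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return ExpressionMatrix(
            genes=self.genes,
            cells=self.cells[cols],
            counts=self.counts[:, cols],
            normalized=None if self.normalized is None else self.normalized[:, cols],
        )

    def normalized_dense(self, genes: Iterable[str] | None = None) -> np.ndarray:
        """Dense (genes x cells) slice of the normalized view."""
        if self.normalized is None:
            raise ValidationError("normalized view missing; call normalize() first")
        if genes is None:
            return self.normalized.toarray()
        rows = [self.gene_index(g) for g in genes]
        return self.normalized[rows, :].toarray()


@dataclass
class QCReport:
    min_transcripts: int
    n_cells_before: int
    n_cells_after: int
    per_fov: pd.DataFrame = field(repr=False)


def validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table against the declared invariants.

    Returns the table with a fresh RangeIndex; raises
    :class:`ValidationError` with the offending values otherwise.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cell table missing columns: {missing}")
    cells = cells.reset_index(drop=True)
    if len(cells) == 0:
        raise ValidationError("cell table is empty")
    dup = cells["cell_id"][cells["cell_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell_id values: {sorted(set(dup))[:5]}")
    coords = cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = cells.loc[~np.isfinite(coords).all(axis=1), "cell_id"].tolist()[:5]
        raise ValidationError(f"non-finite coordinates for cells: {bad}")
    bad_region = sorted(set(cells["region"]) - set(REGIONS))
    if bad_region:
        raise ValidationError(f"unknown region labels: {bad_region} (expected {REGIONS})")
    fov_map = cells.groupby("fov_id")[["core_id", "patient_id", "region"]].nunique()
    ambiguous = fov_map[(fov_map > 1).any(axis=1)].index.tolist()
    if ambiguous:
        raise ValidationError(
            f"FOVs mapping to more than one (core, patient, region): {ambiguous[:5]}"
        )
    return cells


def _check_alignment(cells: pd.DataFrame, matrix: ExpressionMatrix) -> None:
    if matrix.n_cells != len(cells):
        raise ValidationError(
            f"matrix has {matrix.n_cells} cells but cell table has {len(cells)}"
        )
    cell_ids = cells["cell_id"].to_numpy(dtype=object)
    if not np.array_equal(matrix.cells, cell_ids):
        extra = set(matrix.cells) - set(cell_ids)
        if extra:
            raise ValidationError(
                f"barcodes absent from cell table: {sorted(extra)[:5]}"
            )
        raise ValidationError("barcode order differs from cell table order")


def write_dataset(
    cells: pd.DataFrame,
    matrix: ExpressionMatrix,
    outdir: str | Path,
    survival: pd.DataFrame | None = None,
) -> Path:
    """Write the standard dataset layout; returns the directory path."""
    cells = validate_cells(cells)
    _check_alignment(cells, matrix)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # shortest round-trippable float repr: exact read-back, still deterministic
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    coo = matrix.counts.tocoo()
    # deterministic triplet order: column-major like most exporters
    order = np.lexsort((coo.row, coo.col))
    buf = _io.StringIO()
    buf.write("%%MatrixMarket matrix coordinate integer general\n")
    buf.write(f"{matrix.n_genes} {matrix.n_cells} {coo.nnz}\n")
    rows, cols, data = coo.row[order], coo.col[order], coo.data[order]
    for r, c, v in zip(rows, cols, data):
        buf.write(f"{r + 1} {c + 1} {int(v)}\n")
    (outdir / "matrix.mtx").write_text(buf.getvalue())
    (outdir / "genes.tsv").write_text("\n".join(map(str, matrix.genes)) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(map(str, matrix.cells)) + "\n")
    if survival is not None:
        survival.to_csv(outdir / "survival.tsv", sep="\t", index=False)
    return outdir


def read_dataset(indir: str | Path) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Read and validate a dataset directory -> (cell table, matrix)."""
    indir = Path(indir)
    for name in ("cells.tsv", "matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise ValidationError(f"missing {name} in {indir}")
    cells = pd.read_csv(
        indir / "cells.tsv", sep="\t", float_precision="round_trip",
        dtype={"cell_id": str, "fov_id": str, "core_id": str,
               "patient_id": str},
    )
    cells = validate_cells(cells)
    genes = np.array((indir / "genes.tsv").read_text().split(), dtype=object)
    barcodes = np.array((indir / "barcodes.tsv").read_text().split(), dtype=object)
    counts = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx"))
    if counts.shape[1] == 0:
        raise ValidationError(f"matrix in {indir} has zero cells")
    if counts.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"matrix shape {counts.shape} does not match {len(genes)} genes "
            f"x {len(barcodes)} barcodes"
        )
    matrix = ExpressionMatrix(genes=genes, cells=barcodes, counts=counts)
    _check_alignment(cells, matrix)
    return cells, matrix


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "time_months", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise ValidationError(f"survival table missing columns: {sorted(missing)}")
    if (surv["time_months"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0/1")
    return surv


def qc_filter_cells(
    cells: pd.DataFrame,
    matrix: ExpressionMatrix,
    min_transcripts: int = 20,
) -> tuple[pd.DataFrame, ExpressionMatrix, QCReport]:
    """Drop cells whose transcript total is below ``min_transcripts``.

    Low-count cells are commonly segmentation artifacts in imaging-based
    spatial transcriptomics; the threshold is a convention (default 20)
    and is echoed into the QC report together with per-FOV before/after
    counts.
    """
    if min_transcripts < 0:
        raise ValidationError("min_transcripts must be >= 0")
    cells = validate_cells(cells)
    _check_alignment(cells, matrix)
    totals = matrix.totals()
    keep = totals >= min_transcripts
    if not keep.any():
        raise ValidationError(
            f"QC with min_transcripts={min_transcripts} removes every cell; "
            "review the threshold"
        )
    per_fov = (
        pd.DataFrame({"fov_id": cells["fov_id"], "keep": keep})
        .groupby("fov_id")["keep"]
        .agg(n_before="size", n_after="sum")
        .reset_index()
    )
    report = QCReport(
        min_transcripts=min_transcripts,
        n_cells_before=len(cells),
        n_cells_after=int(keep.sum()),
        per_fov=per_fov,
    )
    return cells.loc[keep].reset_index(drop=True), matrix.subset_cells(keep), report


def normalize(
    matrix: ExpressionMatrix,
    target_total: float = 500.0,
    pseudo: float = 1.0,
) -> ExpressionMatrix:
    """Attach the log-normalized view: per-cell total scaling then log.

    Each cell's counts are scaled to ``target_total`` and transformed as
    ``log(pseudo + x)`` (natural log; with the default ``pseudo=1`` this
    is log1p, so zeros stay zero and sparsity is preserved). The result
    is invariant to multiplying any one cell's counts by a scalar.
    """
    totals = matrix.totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(
            f"{zero.size} cells have zero total counts (e.g. "
            f"{matrix.cells[zero[:3]].tolist()}); run QC first"
        )
    scaled = matrix.counts.astype(float).multiply(target_total / totals)  # coo
    scaled = sp.csr_matrix(scaled)
    if pseudo == 1.0:
        scaled.data = np.log1p(scaled.data)
        norm = scaled
    else:
        dense = scaled.toarray()
        norm = sp.csr_matrix(np.log(pseudo + dense) - np.log(pseudo))
        # subtract log(pseudo) so zero counts map to zero and the view stays sparse
    return ExpressionMatrix(
        genes=matrix.genes, cells=matrix.cells, counts=matrix.counts, normalized=norm
    )
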