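"""Readers, writers and validated in-memory containers for count data.

Two on-disk layouts are supported for count matrices:

* a Matrix Market triplet bundle — ``matrix.mtx`` plus gene and barcode
  sidecar TSVs, the 10x-style convention with genes as rows (an
  ``orientation`` flag accepts transposed deposits);
* a dense TSV with gene rows and barcode columns.

Counts are held as a sparse genes × barcodes integer matrix regardless of
the on-disk orientation.  Cell annotations travel in a separate TSV with
``barcode``, ``cell_type`` and ``source`` columns; the label ``debris`` is
reserved for the classifier's synthetic competing class and is rejected in
annotation input.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("probcell")

#: reserved class label for the synthetic low-quality competing category
DEBRIS_LABEL = "debris"

#: label used when no probability clears the calling threshold
UNASSIGNED_LABEL = "unassigned"

#: default batch label when none is supplied
DEFAULT_BATCH = "batch0"


class ProbcellError(ValueError):
    """Base class for validation errors raised by this package."""


@dataclass
class CountMatrix:
    """Raw integer counts, genes × barcodes.

    Parameters
    ----------
    gene_ids, barcode_ids
        Unique identifier lists matching the matrix dimensions.
    counts
        Non-negative integer matrix, ``(n_genes, n_barcodes)``; any
        scipy-sparse or dense array is accepted and stored as CSC.
    batch_of, sample_of
        Optional ``barcode -> label`` maps. Barcodes without a batch label
        fall back to ``"batch0"``.
    """

    gene_ids: list
    barcode_ids: list
    counts: sp.spmatrix
    batch_of: dict = field(default_factory=dict)
    sample_of: dict = field(default_factory=dict)

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcode_ids = [str(b) for b in self.barcode_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ProbcellError("duplicate id: gene identifiers are not unique")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise ProbcellError("duplicate id: barcode identifiers are not unique")
        m = sp.csc_matrix(self.counts)
        if m.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise ProbcellError(
                "invalid count: matrix shape %s does not match %d genes x %d barcodes"
                % (m.shape, len(self.gene_ids), len(self.barcode_ids))
            )
        data = m.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ProbcellError("invalid count: entries must be non-negative integers")
        self.counts = m.astype(np.int64)
        known = set(self.barcode_ids)
        for name, mapping in (("batch", self.batch_of), ("sample", self.sample_of)):
            unknown = set(mapping) - known
            if unknown:
                raise ProbcellError(
                    f"invalid count: {name} labels refer to unknown barcodes {sorted(unknown)[:3]}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    def total_counts(self) -> np.ndarray:
        """Per-barcode total UMI."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Per-barcode number of genes with a nonzero count."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def batches(self) -> np.ndarray:
        """Per-barcode batch labels, defaulting to ``batch0``."""
        return np.array([self.batch_of.get(b, DEFAULT_BATCH) for b in self.barcode_ids])

    def subset_barcodes(self, keep) -> "CountMatrix":
        keep = list(keep)
        idx = {b: i for i, b in enumerate(self.barcode_ids)}
        cols = [idx[b] for b in keep]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            barcode_ids=keep,
            counts=self.counts[:, cols],
            batch_of={b: self.batch_of[b] for b in keep if b in self.batch_of},
            sample_of={b: self.sample_of[b] for b in keep if b in self.sample_of},
        )


@dataclass
class CellAnnotation:
    """A per-barcode cell-type label with its dataset of origin."""

    barcode_id: str
    cell_type: str
    source: str = ""

    def __post_init__(self):
        if self.cell_type == DEBRIS_LABEL:
            raise ProbcellError(f'reserved label: "{DEBRIS_LABEL}" cannot be used as a cell type')


# ---------------------------------------------------------------------------
# count matrix I/O
# ---------------------------------------------------------------------------

_MTX_NAME = "matrix.mtx"
_GENE_NAMES = ("genes.tsv", "features.tsv")
_BARCODE_NAME = "barcodes.tsv"


def _read_id_column(path: str) -> list:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str, format: str = "matrix-market-triplet",
                orientation: str = "genes-rows") -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        For ``matrix-market-triplet``, a directory holding ``matrix.mtx``
        with ``genes.tsv`` (or ``features.tsv``) and ``barcodes.tsv``
        sidecars. For ``dense-tsv``, a TSV file with gene rows.
    format
        ``"matrix-market-triplet"`` or ``"dense-tsv"``.
    orientation
        Whether the stored matrix has ``"genes-rows"`` (default, 10x
        convention) or ``"barcodes-rows"``.
    """
    if format == "matrix-market-triplet":
        if not os.path.isdir(path):
            raise ProbcellError(f"incomplete matrix bundle: {path} is not a directory")
        mtx = os.path.join(path, _MTX_NAME)
        bc = os.path.join(path, _BARCODE_NAME)
        gene_path = next(
            (os.path.join(path, n) for n in _GENE_NAMES if os.path.exists(os.path.join(path, n))),
            None,
        )
        if not os.path.exists(mtx) or gene_path is None or not os.path.exists(bc):
            raise ProbcellError(f"incomplete matrix bundle: missing matrix or sidecar in {path}")
        try:
            m = scipy.io.mmread(mtx)
        except ValueError as e:
            raise ProbcellError(f"incomplete matrix bundle: {e}") from e
        genes = _read_id_column(gene_path)
        barcodes = _read_id_column(bc)
        if orientation == "barcodes-rows":
            m = m.T
        if m.shape != (len(genes), len(barcodes)):
            raise ProbcellError(
                "incomplete matrix bundle: matrix shape %s does not match sidecars (%d genes, %d barcodes)"
                % (m.shape, len(genes), len(barcodes))
            )
        return CountMatrix(gene_ids=genes, barcode_ids=barcodes, counts=m)
    elif format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        m = df.to_numpy()
        if orientation == "barcodes-rows":
            return CountMatrix(gene_ids=list(df.columns), barcode_ids=list(df.index),
                               counts=sp.csc_matrix(m.T))
        return CountMatrix(gene_ids=list(df.index), barcode_ids=list(df.columns),
                           counts=sp.csc_matrix(m))
    raise ProbcellError(f"unknown format: {format}")


def write_counts(m: CountMatrix, path: str, format: str = "matrix-market-triplet") -> str:
    """Write a count matrix; ``read_counts`` inverts it bit-exactly."""
    if format == "matrix-market-triplet":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(os.path.join(path, _MTX_NAME), sp.coo_matrix(m.counts), field="integer")
        with open(os.path.join(path, _GENE_NAMES[0]), "w") as fh:
            fh.writelines(g + "\n" for g in m.gene_ids)
        with open(os.path.join(path, _BARCODE_NAME), "w") as fh:
            fh.writelines(b + "\n" for b in m.barcode_ids)
        return path
    elif format == "dense-tsv":
        df = pd.DataFrame(m.counts.toarray(), index=m.gene_ids, columns=m.barcode_ids)
        df.to_csv(path, sep="\t")
        return path
    raise ProbcellError(f"unknown format: {format}")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str) -> list:
    """Read a barcode/cell_type/source TSV into CellAnnotation records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "cell_type", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ProbcellError(f"annotation table missing columns: {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        logger.warning("ignoring unknown annotation columns: %s", sorted(extra))
    if df["barcode"].duplicated().any():
        dups = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise ProbcellError(f"duplicate annotation: {dups[:3]}")
    return [
        CellAnnotation(barcode_id=r.barcode, cell_type=r.cell_type, source=r.source)
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations, path: str) -> str:
    pd.DataFrame(
        {
            "barcode": [a.barcode_id for a in annotations],
            "cell_type": [a.cell_type for a in annotations],
            "source": [a.source for a in annotations],
        }
    ).to_csv(path, sep="\t", index=False)
    return path


def validate_annotations(annotations, m: CountMatrix) -> None:
    """Check every annotated barcode exists in the companion matrix."""
    known = set(m.barcode_ids)
    missing = [a.barcode_id for a in annotations if a.barcode_id not in known]
    if missing:
        raise ProbcellError(f"annotation refers to unknown barcodes: {missing[:3]}")
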