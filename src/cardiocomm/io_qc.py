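"""10x-style count-matrix I/O and barcode-level quality control.

The QC stage applies four per-barcode filters, jointly and with strict
inequalities: total UMIs > 400, detected genes > 200, transcriptome
complexity log10(genes)/log10(UMIs) > 0.8, and mitochondrial UMI
fraction < 0.23.  Barcodes failing any rule are rejected; a report
tallies failures per rule.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "read_10x",
    "write_10x",
    "compute_cell_qc",
    "apply_qc_filter",
    "mito_gene_set",
]


@dataclass
class CountMatrix:
    """Sparse gene x barcode matrix of non-negative integer UMI counts."""

    genes: pd.Index
    barcodes: pd.Index
    counts: sparse.csr_matrix
    dataset: str = ""

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.barcodes = pd.Index(self.barcodes)
        if not sparse.issparse(self.counts):
            self.counts = sparse.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.genes.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.barcodes.has_duplicates:
            raise ValueError("duplicate barcode identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if self.counts.nnz and not np.allclose(data, np.round(data)):
                raise ValueError("non-integral counts")
            self.counts = self.counts.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_barcodes(self, barcodes) -> "CountMatrix":
        """Return a new matrix restricted to ``barcodes`` (in that order)."""
        idx = self.barcodes.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            missing = pd.Index(barcodes)[idx < 0]
            raise KeyError(f"barcodes not in matrix: {list(missing[:5])} ...")
        return CountMatrix(self.genes, pd.Index(barcodes), self.counts[:, idx],
                           dataset=self.dataset)

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes.equals(other.genes)
            and self.barcodes.equals(other.barcodes)
            and (self.counts != other.counts).nnz == 0
        )


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {directory}")


def _read_id_column(path: Path) -> pd.Index:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return pd.Index(df.iloc[:, 0])


def read_10x(path, dataset: str | None = None) -> CountMatrix:
    """Read a 10x triplet directory (matrix.mtx + features.tsv + barcodes.tsv).

    MatrixMarket indices are 1-based with genes as rows; gzipped members
    are accepted.  ``features.tsv`` may also be named ``genes.tsv``; only
    its first column (the identifier) is used.
    """
    directory = Path(path)
    mtx = _find(directory, "matrix.mtx")
    try:
        features = _find(directory, "features.tsv")
    except FileNotFoundError:
        features = _find(directory, "genes.tsv")
    barcodes = _find(directory, "barcodes.tsv")

    counts = spio.mmread(str(mtx)).tocsr()
    genes = _read_id_column(features)
    cells = _read_id_column(barcodes)
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix dims {counts.shape} do not match features/barcodes "
            f"({len(genes)}, {len(cells)})"
        )
    return CountMatrix(genes, cells, counts,
                       dataset=dataset if dataset is not None else directory.name)


def write_10x(matrix: CountMatrix, path, gzipped: bool = False) -> Path:
    """Write a CountMatrix as a 10x triplet directory; returns the directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    mtx_path = directory / ("matrix.mtx.gz" if gzipped else "matrix.mtx")
    if gzipped:
        with gzip.open(mtx_path, "wb") as fh:
            spio.mmwrite(fh, coo, field="integer")
    else:
        spio.mmwrite(str(mtx_path), coo, field="integer")

    def _write_ids(name: str, ids: pd.Index, extra: list[str] | None = None) -> None:
        fname = directory / (name + (".gz" if gzipped else ""))
        rows = ids if extra is None else ["\t".join([i] + extra) for i in ids]
        text = "\n".join(rows) + "\n"
        if gzipped:
            with gzip.open(fname, "wt") as fh:
                fh.write(text)
        else:
            fname.write_text(text)

    _write_ids("features.tsv", matrix.genes, extra=["Gene Expression"])
    _write_ids("barcodes.tsv", matrix.barcodes)
    return directory


@dataclass(frozen=True)
class QCThresholds:
    """Strict (exclusive) per-barcode QC thresholds."""

    min_umi_exclusive: float = 400
    min_genes_exclusive: float = 200
    min_log_ratio_exclusive: float = 0.8
    max_mito_exclusive: float = 0.23

    def __post_init__(self) -> None:
        vals = (self.min_umi_exclusive, self.min_genes_exclusive,
                self.min_log_ratio_exclusive, self.max_mito_exclusive)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("thresholds must be finite")
        if not 0 < self.max_mito_exclusive < 1:
            raise ValueError("mito threshold must lie in (0, 1)")


def mito_gene_set(genes: pd.Index, mito_genes=None, mito_prefix: str = "mt-") -> pd.Index:
    """Mitochondrial genes, either an explicit list or by name prefix."""
    if mito_genes is not None:
        wanted = pd.Index(mito_genes)
        missing = wanted.difference(genes)
        if len(missing):
            warnings.warn(f"{len(missing)} mito genes not in matrix: "
                          f"{list(missing[:5])}", stacklevel=2)
        return wanted.intersection(genes)
    return genes[genes.str.startswith(mito_prefix)]


def compute_cell_qc(matrix: CountMatrix, mito_genes=None,
                    mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-barcode QC metrics.

    Returns a DataFrame indexed by barcode with columns ``n_umi``,
    ``n_genes``, ``log10_genes_per_umi`` and ``mito_ratio``.  The
    complexity ratio log10(n_genes)/log10(n_umi) is NaN when undefined
    (n_umi < 2); barcodes with zero UMIs are reported, never dropped,
    with ``mito_ratio`` defined as 0.
    """
    counts = matrix.counts.tocsc()
    n_umi = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()

    mito = mito_gene_set(matrix.genes, mito_genes, mito_prefix)
    mito_idx = matrix.genes.get_indexer(mito)
    mito_umi = (np.asarray(counts[mito_idx, :].sum(axis=0)).ravel()
                if len(mito_idx) else np.zeros_like(n_umi))

    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(
            (n_umi >= 2) & (n_genes >= 1),
            np.log10(np.maximum(n_genes, 1)) / np.log10(np.maximum(n_umi, 2)),
            np.nan,
        )
        mito_ratio = np.where(n_umi > 0, mito_umi / np.maximum(n_umi, 1), 0.0)

    return pd.DataFrame(
        {
            "n_umi": n_umi.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "log10_genes_per_umi": log_ratio,
            "mito_ratio": mito_ratio,
        },
        index=matrix.barcodes,
    )


@dataclass
class QCReport:
    """Retention summary; per-rule counts tally every barcode failing that rule."""

    n_input: int
    n_retained: int
    n_fail_umi: int
    n_fail_genes: int
    n_fail_complexity: int
    n_fail_mito: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("n_input", "n_retained", "n_fail_umi", "n_fail_genes",
              "n_fail_complexity", "n_fail_mito")}
        d["thresholds"] = {
            "min_umi_exclusive": self.thresholds.min_umi_exclusive,
            "min_genes_exclusive": self.thresholds.min_genes_exclusive,
            "min_log_ratio_exclusive": self.thresholds.min_log_ratio_exclusive,
            "max_mito_exclusive": self.thresholds.max_mito_exclusive,
        }
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def apply_qc_filter(metrics: pd.DataFrame,
                    thresholds: QCThresholds | None = None
                    ) -> tuple[pd.Index, QCReport]:
    """Retain barcodes passing all four rules (strict inequalities).

    An undefined complexity ratio (NaN) fails the complexity rule, so
    barcodes with fewer than two UMIs can never pass.  Returns the
    retained barcode index (input order preserved) and a QCReport.
    """
    thr = thresholds or QCThresholds()
    pass_umi = metrics["n_umi"].to_numpy() > thr.min_umi_exclusive
    pass_genes = metrics["n_genes"].to_numpy() > thr.min_genes_exclusive
    ratio = metrics["log10_genes_per_umi"].to_numpy()
    pass_ratio = np.greater(ratio, thr.min_log_ratio_exclusive,
                            where=~np.isnan(ratio),
                            out=np.zeros(len(ratio), dtype=bool))
    pass_mito = metrics["mito_ratio"].to_numpy() < thr.max_mito_exclusive

    keep = pass_umi & pass_genes & pass_ratio & pass_mito
    report = QCReport(
        n_input=len(metrics),
        n_retained=int(keep.sum()),
        n_fail_umi=int((~pass_umi).sum()),
        n_fail_genes=int((~pass_genes).sum()),
        n_fail_complexity=int((~pass_ratio).sum()),
        n_fail_mito=int((~pass_mito).sum()),
        thresholds=thr,
    )
    return metrics.index[keep], report
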