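"""Per-group pseudobulk aggregation, normalization, and marker genes.

Pseudobulk profiles are the un-normalized mean counts of each gene
across the cells of a group (cluster x dataset by default).  Two named
quantities enter the normalization exactly once: the group's cell
number via the mean, and its library size via within-group scaling of
the summed counts to counts-per-``scale``.  Upper-quartile factors for
bulk-style sample normalization are also provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io_qc import CountMatrix

__all__ = [
    "PseudobulkTable",
    "aggregate_pseudobulk",
    "normalize_pseudobulk",
    "upper_quartile",
    "upper_quartile_factors",
    "average_expression_reference",
    "marker_genes",
]

log = logging.getLogger(__name__)


@dataclass
class PseudobulkTable:
    """Gene x group expression with raw and normalized layers.

    ``raw_sum`` and ``raw_mean`` are DataFrames (genes x groups, columns
    a MultiIndex over the group-by keys); ``norm`` is filled in by
    :func:`normalize_pseudobulk`.  ``raw_mean * n_cells == raw_sum``.
    """

    raw_sum: pd.DataFrame
    raw_mean: pd.DataFrame
    n_cells: pd.Series
    total_counts: pd.Series
    norm: pd.DataFrame | None = None
    groupby: tuple[str, ...] = ("cluster", "dataset")

    @property
    def genes(self) -> pd.Index:
        return self.raw_sum.index

    @property
    def groups(self) -> pd.Index:
        return self.raw_sum.columns


def _align_annotation(matrix: CountMatrix, ann: pd.DataFrame) -> pd.DataFrame:
    extra = ann.index.difference(matrix.barcodes)
    if len(extra):
        raise KeyError(
            f"annotation references {len(extra)} barcodes absent from the "
            f"matrix, e.g. {list(extra[:3])}")
    missing = matrix.barcodes.difference(ann.index)
    if len(missing):
        raise KeyError(
            f"{len(missing)} matrix barcodes lack annotation, "
            f"e.g. {list(missing[:3])}")
    return ann.reindex(matrix.barcodes)


def aggregate_pseudobulk(matrix: CountMatrix, ann: pd.DataFrame,
                         groupby: tuple[str, ...] = ("cluster", "dataset")
                         ) -> PseudobulkTable:
    """Mean and summed counts per gene for every non-empty group.

    Every matrix barcode must be annotated and vice versa.  Groups are
    the observed combinations of the ``groupby`` columns; empty groups
    cannot occur (only observed combinations are emitted) and the
    theoretical combinations that received no cells are logged.
    """
    ann = _align_annotation(matrix, ann)
    keys = pd.MultiIndex.from_frame(ann[list(groupby)])
    uniq = keys.unique().sort_values()
    codes = uniq.get_indexer(keys)

    n_cells = pd.Series(np.bincount(codes, minlength=len(uniq)), index=uniq,
                        name="n_cells")
    indicator = sparse.csr_matrix(
        (np.ones(len(codes)), (np.arange(len(codes)), codes)),
        shape=(len(codes), len(uniq)))
    raw_sum = pd.DataFrame(np.asarray((matrix.counts @ indicator).todense()),
                           index=matrix.genes, columns=uniq)
    raw_mean = raw_sum / n_cells.to_numpy()[None, :]

    level_values = [ann[c].unique() for c in groupby]
    n_possible = int(np.prod([len(v) for v in level_values]))
    if n_possible > len(uniq):
        log.info("pseudobulk: %d of %d possible %s combinations have no cells",
                 n_possible - len(uniq), n_possible, "x".join(groupby))

    return PseudobulkTable(
        raw_sum=raw_sum, raw_mean=raw_mean, n_cells=n_cells,
        total_counts=raw_sum.sum(axis=0), groupby=tuple(groupby))


def normalize_pseudobulk(table: PseudobulkTable, scale: float = 1e6
                         ) -> PseudobulkTable:
    """Scale each group's summed counts to counts-per-``scale``.

    ``norm[g, grp] = scale * raw_sum[g, grp] / total_counts[grp]``, so
    every group's normalized column sums to ``scale``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    zero = table.total_counts[table.total_counts <= 0]
    if len(zero):
        raise ValueError(f"groups with zero total counts: {list(zero.index)}")
    norm = scale * table.raw_sum / table.total_counts.to_numpy()[None, :]
    return replace(table, norm=norm)


def upper_quartile(values, quantile: float = 0.75, nonzero: bool = True) -> float:
    """Linear-interpolation quantile of (by default) the nonzero values."""
    v = np.asarray(values, dtype=float)
    if nonzero:
        v = v[v > 0]
    if v.size == 0:
        raise ValueError("no nonzero values")
    return float(np.quantile(v, quantile))


def upper_quartile_factors(samples: pd.DataFrame, quantile: float = 0.75
                           ) -> pd.Series:
    """Per-sample scaling factors from upper-quartile normalization.

    ``factor_s = UQ_s / gmean(UQ)`` where UQ_s is the 75th percentile of
    the sample's nonzero values; dividing each sample by its factor
    equalizes upper quartiles while preserving the overall scale.
    """
    uqs = {}
    for col in samples.columns:
        try:
            uqs[col] = upper_quartile(samples[col].to_numpy(), quantile)
        except ValueError:
            raise ValueError(f"sample {col!r} has no nonzero values") from None
    uq = pd.Series(uqs, name="uq_factor")
    return uq / stats.gmean(uq.to_numpy())


def average_expression_reference(matrix: CountMatrix, ann: pd.DataFrame
                                 ) -> pd.DataFrame:
    """Mean counts per gene for every (cluster, timepoint) group."""
    return aggregate_pseudobulk(matrix, ann, groupby=("cluster", "timepoint")).raw_mean


def marker_genes(matrix: CountMatrix, ann: pd.DataFrame, cluster: str,
                 min_detection: float = 0.25, alpha: float = 0.05,
                 target_sum: float = 1e4) -> pd.DataFrame:
    """Cluster markers by two-sided rank-sum test (cluster vs rest).

    Candidates are genes detected in at least ``min_detection`` of the
    cluster's cells; the Wilcoxon rank-sum p-value (on per-cell
    counts-per-``target_sum``) is Bonferroni-corrected over the tested
    genes and markers are retained at adjusted p < ``alpha``, ranked by
    average log2 fold change then p-value.
    """
    ann = _align_annotation(matrix, ann)
    in_cluster = (ann["cluster"] == cluster).to_numpy()
    if in_cluster.sum() == 0:
        raise KeyError(f"cluster {cluster!r} absent from annotation")
    if in_cluster.sum() < 3:
        raise ValueError(f"cluster {cluster!r} has fewer than 3 cells")

    counts = matrix.counts.tocsc()
    det_frac = np.asarray((counts[:, in_cluster] > 0).mean(axis=1)).ravel()
    cand = np.flatnonzero(det_frac >= min_detection)
    if cand.size == 0:
        return pd.DataFrame(columns=["gene", "detection_frac", "log2fc",
                                     "pvalue", "p_adj"]).set_index("gene")

    totals = np.maximum(np.asarray(counts.sum(axis=0)).ravel(), 1)
    X = counts[cand, :].toarray() / totals[None, :] * target_sum
    Xin, Xout = X[:, in_cluster], X[:, ~in_cluster]

    res = stats.mannwhitneyu(Xin, Xout, axis=1, alternative="two-sided",
                             method="asymptotic")
    pvals = np.asarray(res.pvalue, dtype=float)
    # constant genes (all ties) carry no evidence
    flat = (X.max(axis=1) - X.min(axis=1)) == 0
    pvals[flat | ~np.isfinite(pvals)] = 1.0

    eps = 1e-9
    lfc = np.log2((Xin.mean(axis=1) + eps) / (Xout.mean(axis=1) + eps))
    p_adj = np.minimum(pvals * cand.size, 1.0)

    out = pd.DataFrame({
        "gene": matrix.genes[cand],
        "detection_frac": det_frac[cand],
        "log2fc": lfc,
        "pvalue": pvals,
        "p_adj": p_adj,
    })
    out = out[out["p_adj"] < alpha]
    out = out.sort_values(["log2fc", "pvalue", "gene"],
                          ascending=[False, True, True], kind="mergesort")
    return out.set_index("gene")
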