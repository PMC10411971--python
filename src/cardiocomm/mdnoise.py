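"""Nonparametric M-D differential expression with a simulated-noise null.

For each gene the contrast between two expression vectors is summarized
by the pair (M, D): M is the log2 ratio and D the absolute difference
of the (zero-replaced) normalized values.  A noise distribution of
(|M|, D) pairs is built from within-condition replicate comparisons;
for replicate-free designs technical replicates are simulated by
multinomial subsampling of each library.  The differential probability
q of a gene is the fraction of noise points it dominates in both
coordinates (ties count toward the noise, a conservative choice), and
genes are called differential at q strictly above a threshold —
q > 0.99 for bulk contrasts, with a lower default of 0.8 available for
pseudobulk condition-enrichment screens.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NoiseNull",
    "compute_md",
    "cpm",
    "simulate_technical_replicates",
    "build_null",
    "differential_probability",
    "call_degs",
    "noiseq_sim",
]


def compute_md(x1, x2, k: float = 0.5):
    """(M, D) for paired expression values; zeros are replaced by ``k``.

    M = log2(x1'/x2'), D = |x1' - x2'|.  Accepts scalars or arrays;
    negative input is an error.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if (x1 < 0).any() or (x2 < 0).any():
        raise ValueError("expression values must be non-negative")
    x1p = np.where(x1 == 0, k, x1)
    x2p = np.where(x2 == 0, k, x2)
    m = np.log2(x1p / x2p)
    d = np.abs(x1p - x2p)
    if m.ndim == 0:
        return float(m), float(d)
    return m, d


def cpm(x, scale: float = 1e6) -> np.ndarray:
    """Scale a non-negative vector to counts-per-``scale``."""
    x = np.asarray(x, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("vector sums to zero")
    return x / total * scale


def simulate_technical_replicates(sample, pnr: float = 0.2, nss: int = 5,
                                  nv: float = 0.02,
                                  rng: np.random.Generator | int | None = None
                                  ) -> np.ndarray:
    """Multinomial technical replicates of a count vector.

    Each of the ``nss`` replicates draws ``round(pnr * total)`` reads
    with probabilities proportional to the counts perturbed by
    uniform(-nv, nv) relative noise.  Returns an (nss, n_genes) integer
    array; every replicate has the same total.
    """
    sample = np.asarray(sample, dtype=float)
    total = sample.sum()
    if total <= 0:
        raise ValueError("sample must contain counts")
    if not 0 < pnr <= 1:
        raise ValueError("pnr must lie in (0, 1]")
    if nss < 2:
        raise ValueError("need at least 2 simulated replicates")
    rng = np.random.default_rng(rng)
    size = int(round(pnr * total))
    reps = np.empty((nss, sample.size), dtype=np.int64)
    for i in range(nss):
        probs = sample * (1.0 + rng.uniform(-nv, nv, size=sample.size))
        probs = np.maximum(probs, 0.0)
        reps[i] = rng.multinomial(size, probs / probs.sum())
    return reps


@dataclass
class NoiseNull:
    """Pooled (|M|, D) noise points from within-condition comparisons."""

    m: np.ndarray  # |M|, >= 0
    d: np.ndarray  # D, >= 0

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).ravel()
        self.d = np.asarray(self.d, dtype=float).ravel()
        if self.m.size != self.d.size:
            raise ValueError("m and d must have equal length")
        if self.m.size == 0:
            raise ValueError("noise distribution is empty")
        if (self.m < 0).any() or (self.d < 0).any():
            raise ValueError("noise points must be non-negative")

    def __len__(self) -> int:
        return self.m.size


def build_null(replicates_by_condition: Mapping[str, np.ndarray],
               k: float = 0.5, normalize: bool = True) -> NoiseNull:
    """Pool (|M|, D) over all within-condition replicate pairs and genes.

    ``replicates_by_condition`` maps condition -> (n_replicates, n_genes)
    array.  With ``normalize`` each replicate is scaled to CPM first so
    that replicates of different depth are comparable.  The pooled size
    is n_genes * sum over conditions of C(n_rep, 2).
    """
    ms, ds = [], []
    for cond, reps in replicates_by_condition.items():
        reps = np.asarray(reps, dtype=float)
        if reps.ndim != 2:
            raise ValueError(f"replicates for {cond!r} must be 2-D")
        if reps.shape[0] < 2:
            continue
        mat = np.vstack([cpm(r) for r in reps]) if normalize else reps
        for i, j in combinations(range(mat.shape[0]), 2):
            m, d = compute_md(mat[i], mat[j], k=k)
            ms.append(np.abs(m))
            ds.append(d)
    if not ms:
        raise ValueError("no within-condition replicate pair available")
    return NoiseNull(np.concatenate(ms), np.concatenate(ds))


def differential_probability(m, d, null: NoiseNull, chunk: int = 512):
    """q = fraction of noise points with |M_null| <= |M| and D_null <= D.

    Non-strict domination: ties count for the noise, so q is
    conservative.  ``m`` may be signed; its absolute value is used.
    Accepts scalars or aligned arrays and returns the same shape.
    """
    m_arr = np.atleast_1d(np.abs(np.asarray(m, dtype=float)))
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    if m_arr.shape != d_arr.shape:
        raise ValueError("m and d must have the same shape")
    q = np.empty(m_arr.size, dtype=float)
    nm, nd = null.m, null.d
    for start in range(0, m_arr.size, chunk):
        sl = slice(start, start + chunk)
        dom = (nm[None, :] <= m_arr[sl, None]) & (nd[None, :] <= d_arr[sl, None])
        q[sl] = dom.sum(axis=1) / len(null)
    if np.isscalar(m) or np.asarray(m).ndim == 0:
        return float(q[0])
    return q


def call_degs(m, d, null: NoiseNull, genes=None,
              q_threshold: float = 0.99) -> pd.DataFrame:
    """Per-gene q and calls at q strictly above ``q_threshold``.

    Returns a DataFrame (gene, M, D, q, call) sorted by q descending,
    then |M| descending, ties broken by gene id.
    """
    m = np.asarray(m, dtype=float)
    d = np.asarray(d, dtype=float)
    if genes is None:
        genes = pd.Index([f"gene{i}" for i in range(m.size)])
    q = differential_probability(m, d, null)
    out = pd.DataFrame({"gene": pd.Index(genes), "M": m, "D": d, "q": q,
                        "call": q > q_threshold})
    out["_absM"] = np.abs(out["M"])
    out = out.sort_values(["q", "_absM", "gene"],
                          ascending=[False, False, True], kind="mergesort")
    return out.drop(columns="_absM").reset_index(drop=True)


def noiseq_sim(x1, x2, genes=None, pnr: float = 0.2, nss: int = 5,
               nv: float = 0.02, k: float = 0.5, q_threshold: float = 0.99,
               rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Replicate-free M-D differential expression between two libraries.

    Technical replicates are simulated from each count vector, the noise
    distribution pooled over both sides' replicate pairs, and the signal
    (M, D) computed between the CPM-normalized libraries themselves.
    """
    rng = np.random.default_rng(rng)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must share the gene universe")
    reps = {
        "cond1": simulate_technical_replicates(x1, pnr=pnr, nss=nss, nv=nv, rng=rng),
        "cond2": simulate_technical_replicates(x2, pnr=pnr, nss=nss, nv=nv, rng=rng),
    }
    null = build_null(reps, k=k)
    m, d = compute_md(cpm(x1), cpm(x2), k=k)
    return call_degs(m, d, null, genes=genes, q_threshold=q_threshold)
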