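"""Synthetic multi-dataset scRNA-seq counts with planted ground truth.

The generator emulates a seven-dataset comparative design — one
uninjured library (``UN``) and injured libraries at 1, 3 and 7 days
post-injury under a regenerative condition (``PBS``) and a
macrophage-delayed condition (``CL``) — over twelve inflammatory-cell
clusters (nine macrophage, two neutrophil, one hybrid).  Counts are
negative binomial with a shared dispersion and log-normal cell
library-size factors.  Ground truth that downstream stages must
recover is planted explicitly:

* condition-dependent cluster proportions (resident macrophage
  clusters enriched under PBS),
* condition-enriched genes (negative-binomial mean shifted by
  2**log2fc in one cluster under one condition),
* condition-specific ligand-receptor pairs (ligand high only in the
  sender cluster, receptor high only in the receiver cluster, under
  the stated condition).

A fixed (config, dataset) pair yields bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .io_qc import CountMatrix

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "PlantedDEG",
    "PlantedLR",
    "parse_dataset_id",
    "generate_dataset",
    "generate_all",
    "default_config",
    "write_truth",
    "read_truth",
]

DEFAULT_DATASETS = ("UN", "PBS1d", "PBS3d", "PBS7d", "CL1d", "CL3d", "CL7d")

# Zebrafish mitochondrial protein-coding genes (mt- prefixed).
MITO_GENES = (
    "mt-nd1", "mt-nd2", "mt-nd3", "mt-nd4", "mt-nd4l", "mt-nd5", "mt-nd6",
    "mt-co1", "mt-co2", "mt-co3", "mt-atp6", "mt-atp8", "mt-cyb",
)


def parse_dataset_id(dataset: str) -> tuple[str, int]:
    """Split a dataset id into (condition, timepoint in days post injury).

    ``"UN"`` maps to ``("UN", 0)``; otherwise the id is a condition
    prefix followed by the timepoint, e.g. ``"PBS3d" -> ("PBS", 3)``.
    """
    if dataset == "UN":
        return "UN", 0
    for cond in ("PBS", "CL"):
        if dataset.startswith(cond) and dataset.endswith("d"):
            return cond, int(dataset[len(cond):-1])
    raise ValueError(f"cannot parse dataset id {dataset!r}")


@dataclass(frozen=True)
class PlantedDEG:
    gene: str
    cluster: str
    condition: str
    log2fc: float


@dataclass(frozen=True)
class PlantedLR:
    ligand: str
    receptor: str
    sender: str
    receiver: str
    condition: str


@dataclass
class SimConfig:
    """Full specification of the synthetic experiment.

    ``cluster_profiles`` maps cluster name -> baseline per-gene
    negative-binomial mean (length ``n_genes``, aligned with
    ``genes``).  ``proportions`` maps dataset -> {cluster: fraction}
    and each entry must sum to 1.
    """

    genes: list[str]
    cluster_profiles: dict[str, np.ndarray]
    n_cells_per_dataset: dict[str, int]
    proportions: dict[str, dict[str, float]]
    planted_degs: list[PlantedDEG] = field(default_factory=list)
    planted_lr: list[PlantedLR] = field(default_factory=list)
    mito_genes: tuple[str, ...] = MITO_GENES
    nb_dispersion: float = 0.1
    libsize_lognormal: tuple[float, float] = (0.0, 0.35)
    lr_high: float = 50.0
    damaged_cell_frac: float = 0.02
    damaged_mito_fraction: float = 0.35
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def clusters(self) -> list[str]:
        return list(self.cluster_profiles)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        gene_set = set(self.genes)
        if len(gene_set) != self.n_genes:
            raise ValueError("duplicate gene names")
        for name, prof in self.cluster_profiles.items():
            if len(prof) != self.n_genes:
                raise ValueError(f"profile for {name} has wrong length")
            if np.min(prof) < 0:
                raise ValueError(f"negative mean in profile for {name}")
        for ds, props in self.proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"proportions for {ds} sum to {total}, not 1")
            unknown = set(props) - set(self.cluster_profiles)
            if unknown:
                raise ValueError(f"unknown clusters in proportions[{ds}]: {unknown}")
        for deg in self.planted_degs:
            if deg.gene not in gene_set:
                raise ValueError(f"planted DEG gene {deg.gene!r} not in gene universe")
            if deg.cluster not in self.cluster_profiles:
                raise ValueError(f"planted DEG cluster {deg.cluster!r} unknown")
        for lr in self.planted_lr:
            for g in (lr.ligand, lr.receptor):
                if g not in gene_set:
                    raise ValueError(f"planted LR gene {g!r} not in gene universe")
            for c in (lr.sender, lr.receiver):
                if c not in self.cluster_profiles:
                    raise ValueError(f"planted LR cluster {c!r} unknown")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated dataset."""

    cluster_of: pd.Series           # barcode -> cluster
    deg_table: pd.DataFrame         # gene, cluster, condition, log2fc
    lr_table: pd.DataFrame          # ligand, receptor, sender, receiver, condition
    cluster_counts: pd.DataFrame    # dataset, cluster, n_cells


def _dataset_rng(config: SimConfig, dataset: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(dataset.encode())])


def _adjusted_profiles(config: SimConfig, condition: str) -> dict[str, np.ndarray]:
    """Baseline profiles with planted DEG shifts and LR boosts applied."""
    gene_pos = {g: i for i, g in enumerate(config.genes)}
    profiles = {c: p.astype(float).copy() for c, p in config.cluster_profiles.items()}
    for deg in config.planted_degs:
        if deg.condition == condition:
            profiles[deg.cluster][gene_pos[deg.gene]] *= 2.0 ** deg.log2fc
    for lr in config.planted_lr:
        if lr.condition == condition:
            profiles[lr.sender][gene_pos[lr.ligand]] = config.lr_high
            profiles[lr.receiver][gene_pos[lr.receptor]] = config.lr_high
    return profiles


def generate_dataset(config: SimConfig, dataset: str
                     ) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate one dataset: counts, per-barcode annotation, and truth.

    Cluster sizes are drawn multinomially from the dataset's proportion
    vector; cells are shuffled so barcode order carries no cluster
    signal.  The annotation has columns ``cluster``, ``condition``,
    ``timepoint`` and ``dataset`` indexed by barcode.
    """
    config.validate()
    if dataset not in config.n_cells_per_dataset or dataset not in config.proportions:
        raise KeyError(f"unknown dataset id {dataset!r}")
    condition, timepoint = parse_dataset_id(dataset)
    rng = _dataset_rng(config, dataset)

    clusters = [c for c in config.clusters if config.proportions[dataset].get(c, 0) > 0]
    probs = np.array([config.proportions[dataset][c] for c in clusters], dtype=float)
    n = config.n_cells_per_dataset[dataset]
    sizes = rng.multinomial(n, probs / probs.sum())

    profiles = _adjusted_profiles(config, condition)
    mu_lib, sigma_lib = config.libsize_lognormal
    lib = rng.lognormal(mu_lib, sigma_lib, size=n)
    damaged = rng.random(n) < config.damaged_cell_frac
    mito_idx = np.array([config.genes.index(g) for g in config.mito_genes
                         if g in set(config.genes)], dtype=int)

    r = 1.0 / config.nb_dispersion
    blocks, labels = [], []
    start = 0
    for cname, size in zip(clusters, sizes):
        if size == 0:
            continue
        prof = profiles[cname]
        mu = prof[:, None] * lib[None, start:start + size]
        if len(mito_idx):
            dmg = damaged[start:start + size]
            if dmg.any():
                msum = prof[mito_idx].sum()
                osum = prof.sum() - msum
                if msum > 0:
                    f = config.damaged_mito_fraction
                    factor = (f / (1.0 - f)) * (osum / msum)
                    mu[np.ix_(mito_idx, np.flatnonzero(dmg))] *= factor
        lam = rng.gamma(r, mu / r)
        counts = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(counts.astype(np.int32)))
        labels.extend([cname] * size)
        start += size

    counts = sparse.hstack(blocks, format="csc") if blocks else \
        sparse.csc_matrix((config.n_genes, 0), dtype=np.int32)
    order = rng.permutation(counts.shape[1])
    counts = counts[:, order].tocsr()
    labels = np.asarray(labels)[order]

    barcodes = pd.Index([f"{dataset}_b{i:05d}" for i in range(len(labels))])
    matrix = CountMatrix(pd.Index(config.genes), barcodes, counts, dataset=dataset)
    ann = pd.DataFrame(
        {"cluster": labels, "condition": condition,
         "timepoint": timepoint, "dataset": dataset},
        index=barcodes,
    )
    truth = SyntheticTruth(
        cluster_of=ann["cluster"].copy(),
        deg_table=pd.DataFrame([vars(d) for d in config.planted_degs],
                               columns=["gene", "cluster", "condition", "log2fc"]),
        lr_table=pd.DataFrame([vars(p) for p in config.planted_lr],
                              columns=["ligand", "receptor", "sender",
                                       "receiver", "condition"]),
        cluster_counts=pd.DataFrame(
            {"dataset": dataset, "cluster": clusters, "n_cells": sizes}),
    )
    return matrix, ann, truth


def generate_all(config: SimConfig
                 ) -> tuple[dict[str, CountMatrix], pd.DataFrame, SyntheticTruth]:
    """Generate every configured dataset; annotation rows are concatenated."""
    matrices, anns, counts_tables, cluster_of = {}, [], [], []
    truth = None
    for ds in config.n_cells_per_dataset:
        m, a, t = generate_dataset(config, ds)
        matrices[ds] = m
        anns.append(a)
        counts_tables.append(t.cluster_counts)
        cluster_of.append(t.cluster_of)
        truth = t
    ann = pd.concat(anns)
    merged = SyntheticTruth(
        cluster_of=pd.concat(cluster_of),
        deg_table=truth.deg_table,
        lr_table=truth.lr_table,
        cluster_counts=pd.concat(counts_tables, ignore_index=True),
    )
    return matrices, ann, merged


def write_truth(truth: SyntheticTruth, path) -> dict[str, Path]:
    """Write truth tables as TSV; returns {name: path}. Round-trips exactly."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    cl = truth.cluster_of.rename("cluster").rename_axis("barcode").reset_index()
    for name, df in (
        ("cluster_assignments", cl),
        ("planted_degs", truth.deg_table),
        ("planted_lr", truth.lr_table),
        ("cluster_counts", truth.cluster_counts),
    ):
        p = directory / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        out[name] = p
    return out


def read_truth(path) -> SyntheticTruth:
    directory = Path(path)

    def _read(name, **kw):
        p = directory / f"{name}.tsv"
        return pd.read_csv(p, sep="\t", **kw) if p.stat().st_size else pd.DataFrame()

    cl = pd.read_csv(directory / "cluster_assignments.tsv", sep="\t",
                     dtype={"barcode": str, "cluster": str})
    cluster_of = (cl.set_index("barcode")["cluster"] if len(cl)
                  else pd.Series(dtype=str, name="cluster"))
    cluster_of.index.name = None
    deg = pd.read_csv(directory / "planted_degs.tsv", sep="\t")
    lr = pd.read_csv(directory / "planted_lr.tsv", sep="\t")
    counts = pd.read_csv(directory / "cluster_counts.tsv", sep="\t")
    return SyntheticTruth(cluster_of=cluster_of, deg_table=deg,
                          lr_table=lr, cluster_counts=counts)


# ---------------------------------------------------------------------------
# Default study configuration

_CLUSTERS = ("Mac1", "Mac2", "Mac3", "Mac4", "Mac5", "Mac6", "Mac7",
             "Mac8", "Mac9", "Neu1", "Neu2", "MN")

# Condition-dependent cluster proportions.  Resident macrophage clusters
# (Mac2, Mac3) expand under the regenerative condition and collapse under
# macrophage delay; neutrophils resolve under PBS but are retained under CL.
_PROPORTIONS = {
    "UN":    {"Mac1": .10, "Mac2": .26, "Mac3": .24, "Mac4": .10, "Mac5": .05,
              "Mac6": .04, "Mac7": .03, "Mac8": .07, "Mac9": .04,
              "Neu1": .02, "Neu2": .01, "MN": .04},
    "PBS1d": {"Mac1": .16, "Mac2": .12, "Mac3": .10, "Mac4": .12, "Mac5": .08,
              "Mac6": .05, "Mac7": .04, "Mac8": .02, "Mac9": .02,
              "Neu1": .15, "Neu2": .10, "MN": .04},
    "PBS3d": {"Mac1": .12, "Mac2": .18, "Mac3": .13, "Mac4": .09, "Mac5": .06,
              "Mac6": .05, "Mac7": .04, "Mac8": .02, "Mac9": .02,
              "Neu1": .14, "Neu2": .11, "MN": .04},
    "PBS7d": {"Mac1": .10, "Mac2": .25, "Mac3": .15, "Mac4": .07, "Mac5": .05,
              "Mac6": .04, "Mac7": .03, "Mac8": .03, "Mac9": .02,
              "Neu1": .12, "Neu2": .10, "MN": .04},
    "CL1d":  {"Mac1": .18, "Mac2": .05, "Mac3": .05, "Mac4": .13, "Mac5": .09,
              "Mac6": .07, "Mac7": .05, "Mac8": .01, "Mac9": .01,
              "Neu1": .16, "Neu2": .15, "MN": .05},
    "CL3d":  {"Mac1": .16, "Mac2": .03, "Mac3": .04, "Mac4": .12, "Mac5": .08,
              "Mac6": .07, "Mac7": .05, "Mac8": .01, "Mac9": .01,
              "Neu1": .19, "Neu2": .19, "MN": .05},
    "CL7d":  {"Mac1": .15, "Mac2": .02, "Mac3": .04, "Mac4": .11, "Mac5": .08,
              "Mac6": .08, "Mac7": .05, "Mac8": .01, "Mac9": .01,
              "Neu1": .21, "Neu2": .19, "MN": .05},
}

# Planted ligand-receptor pairs, high only in (sender, receiver) under the
# stated condition; gene names follow zebrafish orthologs of pairs the
# crosstalk stage should recover.
_PLANTED_LR = (
    PlantedLR("pltpa", "abca1a", "Mac2", "Neu1", "PBS"),
    PlantedLR("hmgb1a", "cxcr4b", "Mac3", "Neu1", "PBS"),
    PlantedLR("mfge8a", "itgav", "Mac2", "Neu2", "PBS"),
    PlantedLR("calr", "lrp1ab", "Neu1", "Mac4", "PBS"),
    PlantedLR("tgfb1a", "tgfbr2a", "Mac1", "Neu2", "CL"),
    PlantedLR("il15", "il15ra", "Mac1", "Neu1", "CL"),
    PlantedLR("fn1a", "itga5", "Mac4", "Neu2", "CL"),
    PlantedLR("dla", "notch2", "Neu2", "Mac1", "CL"),
)

# Condition-enriched genes (cluster, condition, log2 fold change).
_PLANTED_DEGS = (
    ("hmox1a", "Mac2", "PBS", 2.0),
    ("hbaa1", "Mac2", "PBS", 3.0),
    ("prdx2", "Mac2", "PBS", 2.0),
    ("timp4.3", "Mac3", "PBS", 3.0),
    ("cd74a", "Mac3", "PBS", 2.0),
    ("mrc1b", "Mac3", "PBS", 2.0),
    ("anxa1a", "Mac4", "PBS", 2.0),
    ("raraa", "Neu1", "PBS", 2.0),
    ("il1b", "Mac1", "CL", 2.0),
    ("tnfb", "Mac1", "CL", 2.0),
    ("ncf1", "Neu2", "CL", 2.0),
    ("cxcr1", "Neu2", "CL", 2.0),
    ("marco", "Mac1", "PBS", 2.0),
    ("vegfaa", "Mac1", "PBS", 2.0),
)


def default_config(n_genes: int = 1000, n_cells: int = 2000, seed: int = 0,
                   datasets: tuple[str, ...] = DEFAULT_DATASETS,
                   mito_fraction: float = 0.08) -> SimConfig:
    """Desk-scale default configuration: seven datasets, twelve clusters.

    Baseline per-gene means are log-normal (median ~0.8 counts/cell);
    each cluster receives a disjoint block of 12 markers boosted 6x so
    that cluster identity is recoverable.  Planted DEG and LR genes use
    dedicated, named genes.  ``n_cells`` applies to every dataset.
    """
    named_degs = [g for g, *_ in _PLANTED_DEGS]
    named_lr = sorted({g for p in _PLANTED_LR for g in (p.ligand, p.receptor)})
    named = list(dict.fromkeys(named_degs + named_lr)) + list(MITO_GENES)
    n_bg = n_genes - len(named)
    if n_bg < 12 * len(_CLUSTERS):
        raise ValueError("n_genes too small for default config")
    genes = [f"g{i:04d}" for i in range(n_bg)] + named

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xC0FFEE])
    # median 0.45 counts/cell so a unit-libsize cell has ~1.2 UMIs per gene
    # in the universe, keeping log10(genes)/log10(UMIs) above the QC cutoff
    base = rng.lognormal(np.log(0.45), 1.4, size=n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    # planted LR genes: near-silent baseline everywhere
    for g in named_lr:
        base[gene_pos[g]] = 0.05
    # named DEG genes: moderate baseline so fold changes are measurable
    for g in named_degs:
        base[gene_pos[g]] = rng.lognormal(np.log(3.0), 0.3)
    mito_idx = np.array([gene_pos[g] for g in MITO_GENES])

    profiles: dict[str, np.ndarray] = {}
    marker_pool = rng.permutation(n_bg)
    for i, cname in enumerate(_CLUSTERS):
        prof = base.copy()
        markers = marker_pool[i * 12:(i + 1) * 12]
        prof[markers] *= 6.0
        # mito genes sized so their expected UMI share is mito_fraction
        other = prof.sum() - prof[mito_idx].sum()
        prof[mito_idx] = mito_fraction / (1 - mito_fraction) * other / len(mito_idx)
        profiles[cname] = prof

    return SimConfig(
        genes=genes,
        cluster_profiles=profiles,
        n_cells_per_dataset={ds: n_cells for ds in datasets},
        proportions={ds: dict(_PROPORTIONS[ds]) for ds in datasets},
        planted_degs=[PlantedDEG(*row) for row in _PLANTED_DEGS],
        planted_lr=list(_PLANTED_LR),
        seed=seed,
    )


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed (profiles unchanged)."""
    return replace(config, seed=seed)
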