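import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import sparse

from cardiocomm.io_qc import CountMatrix
from cardiocomm.simulate import SimConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230727)


def random_count_matrix(rng, n_genes=20, n_cells=15, density=0.3,
                        max_count=50, dataset="toy", mito_frac=0.1):
    """Dense-random small CountMatrix with a few mt- prefixed genes."""
    n_mito = max(1, int(n_genes * mito_frac))
    genes = [f"mt-g{i}" for i in range(n_mito)] + \
            [f"g{i:03d}" for i in range(n_genes - n_mito)]
    counts = rng.integers(0, max_count, size=(n_genes, n_cells))
    counts[rng.random((n_genes, n_cells)) > density] = 0
    barcodes = [f"bc{i:04d}" for i in range(n_cells)]
    return CountMatrix(pd.Index(genes), pd.Index(barcodes),
                       sparse.csr_matrix(counts), dataset=dataset)


def two_condition_config(n_genes=60, n_cells=1200, seed=0, clusters=("A", "B"),
                         proportions=None, planted_degs=(), planted_lr=(),
                         datasets=("PBS3d", "CL3d"), dispersion=0.1,
                         gene_means=2.0):
    """Minimal hand-built SimConfig for targeted generator tests."""
    genes = [f"g{i:03d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    profiles = {c: np.full(n_genes, float(gene_means)) if np.isscalar(gene_means)
                else np.asarray(gene_means, dtype=float).copy()
                for c in clusters}
    if proportions is None:
        proportions = {c: 1.0 / len(clusters) for c in clusters}
    if any(isinstance(v, dict) for v in proportions.values()):
        per_dataset = {ds: dict(proportions[ds]) for ds in datasets}
    else:
        per_dataset = {ds: dict(proportions) for ds in datasets}
    return SimConfig(
        genes=genes,
        cluster_profiles=profiles,
        n_cells_per_dataset={ds: n_cells for ds in datasets},
        proportions=per_dataset,
        planted_degs=list(planted_degs),
        planted_lr=list(planted_lr),
        mito_genes=(),
        nb_dispersion=dispersion,
        damaged_cell_frac=0.0,
        seed=seed,
    )
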