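import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from scmvcc import SimSpec, simulate_counts
from scmvcc import preprocess as pp
from scmvcc import views as vw


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset: 90 cells, 120 genes, 3 clusters."""
    spec = SimSpec(n_cells=90, n_genes=120, n_clusters=3, dropout_mid=-1.0, seed=11)
    return simulate_counts(spec)


@pytest.fixture(scope="session")
def small_bundle(small_sim):
    """Preprocessed views for the compact dataset (thresholds fit its size)."""
    x, truth = small_sim
    filt = pp.filter_cells_genes(x, min_genes_per_cell=10, min_cells_per_gene=2)
    keep = set(filt.cell_ids)
    t = truth[np.array([c in keep for c in x.cell_ids])]
    sel = pp.select_top_genes(pp.normalize_log(filt), n_top=80)
    scaled = pp.scale_genes(sel)
    d = vw.pairwise_distances(scaled)
    a_knn = vw.build_knn_adjacency(d, k=8)
    a_dm = vw.build_dm_adjacency(vw.dm_affinity(d, k_bw=8), k=8)
    return vw.assemble_views(a_knn, a_dm, scaled, t=2), t


def random_unit_rows(rng, n, c):
    z = rng.normal(size=(n, c))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
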