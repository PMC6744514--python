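import numpy as np
import pytest
import scipy.sparse as sp

from cortexmap.containers import NormalizedMatrix
from cortexmap.qc import normalize_log_cpm, remove_gene_families
from cortexmap.simulate import SimulationConfig, generate_dataset


def make_norm(X, gene_ids=None, barcodes=None):
    """Wrap a dense genes x cells array as a NormalizedMatrix."""
    X = np.asarray(X, float)
    if gene_ids is None:
        gene_ids = np.array([f"g{i}" for i in range(X.shape[0])], dtype=object)
    if barcodes is None:
        barcodes = np.array([f"c{i}" for i in range(X.shape[1])], dtype=object)
    return NormalizedMatrix(sp.csr_matrix(X), np.asarray(gene_ids, dtype=object),
                            np.asarray(barcodes, dtype=object))


@pytest.fixture(scope="session")
def sim_clean():
    """Two-condition dataset with planted types only (no QC artifacts, no
    condition effects); shared across embedding/transfer tests."""
    cfg = SimulationConfig(seed=11, cells_per_cluster=150, doublet_rate=0.0,
                           lowq_rate=0.0, de_fold=1.0)
    em, gt = generate_dataset(cfg)
    return cfg, em, gt


@pytest.fixture(scope="session")
def sim_clean_norm(sim_clean):
    _, em, _ = sim_clean
    return normalize_log_cpm(remove_gene_families(em))


@pytest.fixture(scope="session")
def sim_clean_space(sim_clean, sim_clean_norm):
    """CCA-aligned embedding of the two conditions of the clean dataset,
    plus true labels in embedding order."""
    from cortexmap import embed

    _, em, gt = sim_clean
    norm = sim_clean_norm
    mask_a = (em.cell_meta["condition"] == "ctrl").to_numpy()
    a = norm.subset_cells(mask_a)
    b = norm.subset_cells(~mask_a)
    genes = embed.select_variable_genes(a, b)
    space = embed.cca_align(a, b, genes, n_cc=20)
    order = np.concatenate([np.flatnonzero(mask_a), np.flatnonzero(~mask_a)])
    truth = gt.cells.cluster.to_numpy()[order]
    return space, order, truth, a, b


@pytest.fixture(scope="session")
def sim_qc():
    """Default-condition dataset including doublets and low-quality cells."""
    cfg = SimulationConfig(seed=12, cells_per_cluster=120)
    em, gt = generate_dataset(cfg)
    return cfg, em, gt
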