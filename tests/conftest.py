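import warnings

import numpy as np
import pytest

import hepascope as h

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)

#: QC thresholds scaled to the small synthetic gene universes used in tests
#: (the library defaults assume ~20k-gene data; subgroup IV cells detect only
#: ~10% of genes, so the gene floor must sit below that)
SMALL_THR = h.QCThresholds(min_genes_per_cell=50)


@pytest.fixture(scope="session")
def small_invitro():
    """2 donors x 4 conditions x 100 cells, 600 genes."""
    cfg = h.SimConfig(n_donors=2, n_cells_per_donor_condition=100, n_genes=600,
                      marker_module_size=25, seed=7)
    return h.simulate_invitro(cfg)


@pytest.fixture(scope="session")
def small_norm(small_invitro):
    """The small in-vitro dataset, QC'd and log-normalized."""
    adata, truth = small_invitro
    f = h.filter_cells_genes(adata, SMALL_THR)
    scores = h.doublet_scores(f, seed=7)
    g = h.apply_doublet_and_mito_filter(f, scores, SMALL_THR)
    nm = h.post_norm_filter(h.lognormalize(g), SMALL_THR)
    return nm, truth


@pytest.fixture(scope="session")
def small_invivo():
    """1 donor, 800 cells along the lobule axis, 600 genes."""
    cfg = h.SimConfig(n_donors=1, n_cells_per_donor_condition=800, n_genes=600,
                      marker_module_size=25, seed=11)
    return h.simulate_invivo(cfg)


@pytest.fixture(scope="session")
def small_invivo_norm(small_invivo):
    adata, truth = small_invivo
    f = h.filter_cells_genes(adata, SMALL_THR)
    nm = h.post_norm_filter(h.lognormalize(f), SMALL_THR)
    return nm, truth


def toy_counts(counts, barcodes=None, genes=None, **obs_cols):
    """Small dense count AnnData for hand-constructed fixtures."""
    import pandas as pd
    import scipy.sparse as sp
    from anndata import AnnData

    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = barcodes or [f"C{i}" for i in range(n)]
    genes = genes or [f"G{j}" for j in range(g)]
    obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    for k, v in obs_cols.items():
        obs[k] = v
    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["is_mito"] = [str(x).startswith("MT-") for x in genes]
    return AnnData(X=sp.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)
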