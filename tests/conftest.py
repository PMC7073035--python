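import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from dsbscore.simulate import SimConfig, simulate_sc_trajectory


@pytest.fixture(scope="session")
def default_scene():
    """The default synthetic lineage scene (1500 cells, seed 0) with truth."""
    return simulate_sc_trajectory(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_adata(counts, genes=None, barcodes=None, batch=None) -> AnnData:
    counts = np.asarray(counts)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"G{j}" for j in range(g)]
    barcodes = list(barcodes) if barcodes is not None else [f"c{i:04d}" for i in range(n)]
    ad = AnnData(X=sparse.csr_matrix(counts.astype(np.int64)),
                 obs=pd.DataFrame(index=barcodes),
                 var=pd.DataFrame(index=genes))
    if batch is not None:
        ad.obs["batch"] = batch
    return ad
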