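import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

from stemtyper.pipeline import run_pipeline, synthetic_config
from stemtyper.simulate import simulate_counts


def make_adata(X: np.ndarray, genes=None, barcodes=None, lognorm=None) -> ad.AnnData:
    """Small helper: dense matrix (cells x genes) -> AnnData with optional lognorm layer."""
    n, g = X.shape
    genes = list(genes) if genes is not None else [f"G{j}" for j in range(g)]
    barcodes = list(barcodes) if barcodes is not None else [f"C{i}" for i in range(n)]
    a = ad.AnnData(
        X=sp.csr_matrix(np.asarray(X, dtype=float)),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )
    if lognorm is not None:
        a.layers["lognorm"] = sp.csr_matrix(np.asarray(lognorm, dtype=float))
    return a


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic sample (3 lines x 2 subclusters x 60 cells), seed 0."""
    return simulate_counts(seed=0)


@pytest.fixture(scope="session")
def pipeline_result(default_sim):
    """Full QC -> PCA -> clustering run on the default simulation."""
    adata, truth = default_sim
    return run_pipeline(adata.copy(), synthetic_config(0)), truth
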