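import anndata as ad
import numpy as np
import pandas as pd
import pytest

from dptcell import SynthConfig, generate_expression, preprocess

# T-cell-only composition used for classifier/recovery checks: 20% planted DP
T_ONLY_FRACTIONS = {"AB_T": 0.48, "GD_T": 0.32, "DP_T": 0.20}


def make_adata(counts, genes=None, cells=None, donor="d1", **obs_cols):
    """Small AnnData from a dense count array, preprocessed."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(g)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n)]
    obs = pd.DataFrame({"donor": donor, **obs_cols}, index=pd.Index(cells, name="cell_id"))
    adata = ad.AnnData(
        X=counts.astype(float), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.layers["counts"] = counts
    return adata


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default two-donor mixed-population dataset (seed 7), preprocessed."""
    adata, truth = generate_expression(SynthConfig(seed=7))
    preprocess(adata)
    return adata, truth


@pytest.fixture(scope="session")
def t_cell_dataset():
    """Two donors x 750 T cells with 20% planted DP (seed 7), preprocessed."""
    cfg = SynthConfig(seed=7, fractions=dict(T_ONLY_FRACTIONS), n_genes=300)
    adata, truth = generate_expression(cfg)
    preprocess(adata)
    return adata, truth
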