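import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from pavasc import syndata, sc_qc_stats


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with planted markers and LR channels."""
    params = syndata.SimExprParams(
        n_populations=4,
        n_samples_per_condition=2,
        cells_per_sample=300,
        n_genes=400,
        marker_genes_per_population=8,
        condition_de_genes=20,
        n_mito_genes=5,
        active_lr_channels=[
            ("pop00", "pop01", "LIGA", "RECA"),
            ("pop02", "pop03", "LIGB", "RECB"),
        ],
        seed=11,
    )
    adata, truth = syndata.simulate_counts(params)
    return params, adata, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, adata, _ = small_sim
    return sc_qc_stats.lognormalize(adata)


@pytest.fixture(scope="session")
def vessel_noise_free():
    params = syndata.SimImageParams(
        seed=5, channel_snr=np.inf, positive_nucleus_fraction=0.25
    )
    img, truth = syndata.simulate_vessel_image(params)
    return params, img, truth


def make_norm_adata(X, labels=None, samples=None, gene_names=None):
    """Wrap a dense cells x genes array of normalized values as AnnData."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    if labels is not None:
        obs["population"] = list(labels)
    if samples is not None:
        obs["sample"] = list(samples)
    if gene_names is None:
        gene_names = [f"g{j}" for j in range(g)]
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    return AnnData(X=X, obs=obs, var=var)
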