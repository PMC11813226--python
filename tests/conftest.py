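import numpy as np
import pandas as pd
import pytest

from crossnet import CountDataset


def make_dataset(counts: np.ndarray, groups, tissue="T", lengths=None) -> CountDataset:
    """Wrap a raw count array (genes x samples) into a CountDataset."""
    genes = [f"g{i:04d}" for i in range(counts.shape[0])]
    samples = [f"{tissue}_s{j:03d}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"animal_id": [f"a{j:03d}" for j in range(counts.shape[1])],
         "tissue": tissue, "group": list(groups)},
        index=pd.Index(samples, name="sample_id"),
    )
    if lengths is None:
        lengths = np.full(counts.shape[0], 1000)
    return CountDataset(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        gene_lengths=pd.Series(lengths, index=pd.Index(genes, name="gene_id")),
        meta=meta,
        tissue=tissue,
    )


def nb_counts(rng, mu, phi, n):
    """Direct gamma-Poisson NB draws, genes x n."""
    mu = np.asarray(mu, float)[:, None]
    phi = np.broadcast_to(np.asarray(phi, float)[:, None], (mu.shape[0], n))
    lam = rng.gamma(1.0 / phi, mu * phi)
    return rng.poisson(lam)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_null_dataset(rng):
    """500 null NB genes, 8 vs 8 samples."""
    mu = rng.lognormal(np.log(100), 1.0, size=500)
    counts = nb_counts(rng, mu, 3.0 / mu + 0.05, 16)
    return make_dataset(counts, ["a"] * 8 + ["b"] * 8)
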