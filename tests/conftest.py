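import anndata as ad
import numpy as np
import pandas as pd
import pytest

import advint
from advint.preprocess import LogScaleNormalizer, normalize_log_scale
from advint.simdata import LABEL_KEY


def make_adata(X, labels=None, gene_ids=None, cell_ids=None) -> ad.AnnData:
    X = np.asarray(X, dtype=np.float64)
    n, d = X.shape
    obs = pd.DataFrame(index=cell_ids or [f"c{i}" for i in range(n)])
    if labels is not None:
        obs[LABEL_KEY] = pd.Categorical(labels)
    var = pd.DataFrame(index=gene_ids or [f"g{j}" for j in range(d)])
    return ad.AnnData(X=X, obs=obs, var=var)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated dataset: 9 types, fast enough for unit tests."""
    cfg = advint.SimConfig(n_cells=900, n_genes=120, n_types=9, n_key_genes=27, seed=11)
    return advint.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_split(small_sim):
    data, truth = small_sim
    train_raw, test_raw = advint.split_train_test(data, 0.8, seed=3)
    norm = LogScaleNormalizer().fit(np.asarray(train_raw.X))
    train, _ = normalize_log_scale(train_raw, norm)
    test, _ = normalize_log_scale(test_raw, norm)
    return train, test, truth


@pytest.fixture(scope="session")
def small_model(small_split):
    train, _, _ = small_split
    return advint.train_classifier(train, arch=(32,), epochs=30, seed=5)


@pytest.fixture(scope="session")
def tiny_model():
    """A small random-weight MLP over 12 genes for oracle checks."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(60, 12))
    y = np.array(["a", "b", "c"] * 20)
    model = advint.CellTypeMLP(hidden_layer_sizes=(8,), epochs=15, random_state=0)
    return model.fit(X, y)
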