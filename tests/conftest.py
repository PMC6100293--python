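import numpy as np
import pandas as pd
import pytest

from pepqsar.aaindex import filter_complete, load_bundled
from pepqsar.encoding import autoscale
from pepqsar.synthetic import default_properties, generate_peptide_dataset


@pytest.fixture(scope="session")
def bundled_entries():
    return load_bundled()


@pytest.fixture(scope="session")
def properties7(bundled_entries):
    """The seven complete bundled property scales."""
    return filter_complete(bundled_entries)


@pytest.fixture(scope="session")
def panel():
    """Default 20-scale descriptor panel (60 tripeptide columns)."""
    return default_properties()


@pytest.fixture(scope="session")
def dataset(panel):
    """Default synthetic 91-tripeptide dataset, seed 1."""
    return generate_peptide_dataset(seed=1, properties=panel)


@pytest.fixture(scope="session")
def scaled_training(dataset):
    """(Z, y_scaled, y, scaling) for the full synthetic dataset."""
    y = np.array([p.activity for p in dataset.peptides])
    raw = dataset.matrix  # already autoscaled by the generator
    # re-derive scaling including the response so models can back-transform
    Z, scaling = autoscale(raw, activities=y, scale_response=True)
    return Z, scaling.scale_y(y), y, scaling


def random_design(n_rows, n_cols, rng, prefix="x"):
    """Standardized random design matrix as a DataFrame."""
    X = rng.normal(size=(n_rows, n_cols))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.DataFrame(X, columns=[f"{prefix}{j}" for j in range(1, n_cols + 1)])
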