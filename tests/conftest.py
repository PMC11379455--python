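"""Shared fixtures: a small seeded synthetic experiment and its matrix."""

import numpy as np
import pandas as pd
import pytest

from cytobinary.signatures import ClassificationMatrix
from cytobinary.simulate import default_spec, generate_experiment


@pytest.fixture(scope="session")
def small_spec():
    """Down-scaled study (18 samples x 600 cells) for fast unit tests."""
    return default_spec(n_cells_per_sample=600, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_spec):
    experiment, truth = generate_experiment(small_spec)
    return experiment, truth


@pytest.fixture(scope="session")
def small_matrix(small_spec):
    return small_spec.classification_matrix()


@pytest.fixture()
def tiny_matrix():
    """Two mutually exclusive lineages over two markers."""
    return ClassificationMatrix(
        pd.DataFrame(
            {"CD3": ["+", "-"], "CD19": ["-", "+"]}, index=["T", "B"]
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
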