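"""Shared fixtures: synthetic datasets at the scales the tests exercise."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nksig.io import ExpressionMatrix, SampleMetadata
from nksig.preprocess import preprocess_chain
from nksig.simulate import generate_microarray


@pytest.fixture(scope="session")
def default_dataset():
    """Full study-scale dataset: 10+10 paired samples, 2000 features,
    30 planted effects of 1.5 log2, sigma 0.3, two batches."""
    matrix, metadata, truth = generate_microarray(seed=11)
    return matrix, metadata, truth


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    matrix, metadata, truth = default_dataset
    return preprocess_chain(matrix, metadata), metadata, truth


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced scale for selection tests: 200 features, 5 planted two-fold
    shifts, sigma 0.3 (a fixed-seed instance where the construction's
    expectations hold exactly)."""
    matrix, metadata, truth = generate_microarray(
        d=200, n_expressed=60, n_up=3, n_down=2, n_exclusive_each=0,
        effect_log2=1.0, seed=6)
    return matrix, metadata, truth


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    matrix, metadata, truth = small_dataset
    return preprocess_chain(matrix, metadata), metadata, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null dataset: same design, no planted effects."""
    matrix, metadata, truth = generate_microarray(
        n_up=0, n_down=0, n_exclusive_each=0, seed=7)
    return preprocess_chain(matrix, metadata), metadata, truth


@pytest.fixture()
def tiny_matrix():
    """Hand-sized log2 matrix with two clear groups for direct checks."""
    rng = np.random.default_rng(42)
    base = rng.uniform(3, 7, size=8)
    data = {}
    for i in range(3):
        data[f"b{i}"] = base + rng.normal(0, 0.05, 8)
    for i in range(3):
        shifted = base.copy()
        shifted[:2] += 2.0     # first two features up in dim
        data[f"d{i}"] = shifted + rng.normal(0, 0.05, 8)
    df = pd.DataFrame(data, index=[f"miR-{j}" for j in range(8)])
    matrix = ExpressionMatrix(df, "log2")
    meta = SampleMetadata(pd.DataFrame({
        "group": ["bright"] * 3 + ["dim"] * 3,
        "donor": [f"d{i}" for i in range(3)] * 2,
        "batch": ["b1", "b1", "b2"] * 2,
    }, index=pd.Index(list(data), name="sample_id")))
    return matrix, meta
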