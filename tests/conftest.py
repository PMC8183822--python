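"""Shared fixtures: small synthetic MAGIC datasets reused across modules."""

import numpy as np
import pytest

from magicgp import (
    default_map, simulate_founders, build_funnel_design, simulate_population,
    simulate_magic_dataset, qc_and_standardize, grm,
)


@pytest.fixture(scope="session")
def small_map():
    return default_map(n_chrom=3, markers_per_chrom=60, rng_seed=0)


@pytest.fixture(scope="session")
def founders(small_map):
    return simulate_founders(small_map, rng_seed=1)


@pytest.fixture(scope="session")
def small_population(small_map, founders):
    design = build_funnel_design(founders, 90, rng_seed=2)
    return simulate_population(design, founders, small_map, rng_seed=3)


@pytest.fixture(scope="session")
def magic_dataset():
    """120 lines, 3 environments, moderate GxE and heritability."""
    return simulate_magic_dataset(
        n_lines=120, markers_per_chrom=60,
        environments=["E1", "E2", "E3"],
        target_h2={"E1": 0.66, "E2": 0.47, "E3": 0.30},
        main_var=1.0, dev_var=0.3, rng_seed=7,
    )


@pytest.fixture(scope="session")
def marker_matrix(magic_dataset):
    X = qc_and_standardize(magic_dataset.population.dosages)
    X.line_ids = list(magic_dataset.population.line_ids)
    return X


@pytest.fixture(scope="session")
def gb_kernel(marker_matrix):
    return grm(marker_matrix)


@pytest.fixture(scope="session")
def polygenic_trait(marker_matrix):
    """Dense-architecture standardized phenotype at h2 = 0.6."""
    rng = np.random.default_rng(42)
    X = marker_matrix.X
    b = rng.normal(0, 1, X.shape[1])
    g = X @ b
    g = g / g.std(ddof=1)
    y = g + rng.normal(0, np.sqrt(1 / 0.6 - 1), len(g))
    y = (y - y.mean()) / y.std(ddof=1)
    return y, g
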