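import numpy as np
import pytest

from cohortnet.synthetic import (
    CohortTable,
    SyntheticSpec,
    VariableSchema,
    generate_cohorts,
)


def small_schema():
    """Two variables of each type."""
    return (
        VariableSchema("smoker", "binary", (0.0,)),
        VariableSchema("medicated", "binary", (0.5,)),
        VariableSchema("drunk", "ordinal", (-0.5, 0.3, 1.0)),
        VariableSchema("mood", "ordinal", (-0.2, 0.6)),
        VariableSchema("fitness", "continuous"),
        VariableSchema("income", "continuous"),
    )


def small_corr(rho: float = 0.3) -> np.ndarray:
    corr = np.full((6, 6), rho)
    np.fill_diagonal(corr, 1.0)
    return corr


@pytest.fixture
def small_spec() -> SyntheticSpec:
    return SyntheticSpec(
        schema=small_schema(),
        latent_corr=small_corr(),
        n_pain=60,
        n_nopain=120,
        seed=7,
    )


@pytest.fixture
def small_table(small_spec) -> CohortTable:
    return generate_cohorts(small_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_symmetric_weights(rng: np.random.Generator, p: int, density: float = 0.7) -> np.ndarray:
    """Random signed symmetric weight matrix with zero diagonal."""
    w = rng.uniform(-1, 1, size=(p, p))
    keep = rng.random((p, p)) < density
    w = np.where(keep, w, 0.0)
    w = np.triu(w, 1)
    return w + w.T
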