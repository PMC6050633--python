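import numpy as np
import pytest

from balancesel import Composition, CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_composition(rng, n_samples=10, n_taxa=5, scale=1.0):
    values = rng.lognormal(mean=0.0, sigma=scale, size=(n_samples, n_taxa))
    return Composition(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(n_samples)),
        taxon_ids=tuple(f"t{j}" for j in range(n_taxa)),
    )


def make_count_table(rng, n_samples=6, n_taxa=4, lam=20.0, zero_rate=0.2):
    values = rng.poisson(lam, size=(n_samples, n_taxa)).astype(float)
    mask = rng.random(values.shape) < zero_rate
    values[mask] = 0.0
    # keep every row non-empty
    empty = values.sum(axis=1) == 0
    values[empty, 0] = 1.0
    return CountTable(
        values=values,
        sample_ids=tuple(f"s{i}" for i in range(n_samples)),
        taxon_ids=tuple(f"t{j}" for j in range(n_taxa)),
    )


@pytest.fixture
def composition(rng):
    return make_composition(rng)


@pytest.fixture
def count_table(rng):
    return make_count_table(rng)
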