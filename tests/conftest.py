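import numpy as np
import pytest

from crossanno import ConfusionModel, CountVector, FamilyUniverse


def make_universe(n_aligned: int, n_existing: int) -> FamilyUniverse:
    """A universe with generic ids: aligned A000..., existing = first
    n_existing-1 aligned ids plus EXTRA."""
    aligned = tuple(f"A{i:03d}" for i in range(n_aligned))
    existing = aligned[: n_existing - 1] + ("EXTRA",)
    return FamilyUniverse(aligned, existing)


def random_model(rng: np.random.Generator, n: int, m: int) -> ConfusionModel:
    universe = make_universe(n, m)
    alpha = rng.dirichlet(np.ones(n), size=m).T  # columns on the simplex
    beta = rng.dirichlet(np.ones(m))
    return ConfusionModel(alpha, beta, universe)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture
def two_family_universe() -> FamilyUniverse:
    return make_universe(2, 2)


def count_vector(universe: FamilyUniverse, counts) -> CountVector:
    return CountVector(universe.aligned_ids, np.asarray(counts, dtype=np.int64))
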