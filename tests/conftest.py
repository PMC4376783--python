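import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from triadnet import SpeciesFamilyMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> SpeciesFamilyMatrix:
    """3 families × 3 species with hand-checkable overlaps."""
    df = pd.DataFrame(
        [[2, 0, 1], [1, 1, 0], [0, 3, 1]],
        index=["f1", "f2", "f3"],
        columns=["sp1", "sp2", "sp3"],
    )
    return SpeciesFamilyMatrix(df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150327)


def random_matrix(rng: np.random.Generator, n_families: int, n_species: int,
                  max_count: int = 5) -> SpeciesFamilyMatrix:
    counts = rng.integers(0, max_count + 1, size=(n_families, n_species))
    df = pd.DataFrame(counts,
                      index=[f"f{i}" for i in range(n_families)],
                      columns=[f"s{j}" for j in range(n_species)])
    return SpeciesFamilyMatrix(df)
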