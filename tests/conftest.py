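import numpy as np
import pytest

from ddiconv.experiments import DESK_PROTOCOL  # noqa: F401  (shared by acceptance tests)
from ddiconv.features import DrugFeatureTable
from ddiconv.synth import FIXTURE_SCALES, generate, make_fixture


@pytest.fixture(scope="session")
def toy_table() -> DrugFeatureTable:
    """Three drugs, two modalities, hand-written token sets."""
    return DrugFeatureTable(
        drugs=["d1", "d2", "d3"],
        modalities=["substructure", "target"],
        tokens={
            ("d1", "substructure"): frozenset({"a", "b"}),
            ("d2", "substructure"): frozenset({"b", "c"}),
            ("d1", "target"): frozenset({"t1"}),
            ("d2", "target"): frozenset({"t1", "t2"}),
            # d3 has no tokens anywhere
        },
    )


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """Tiny on-disk dataset: 20 drugs, 3 events, noise-free."""
    out = tmp_path_factory.mktemp("tiny")
    paths, config, oracle = make_fixture("tiny", out)
    return paths, config, oracle


@pytest.fixture(scope="session")
def small_data():
    """In-memory small-scale panel: 120 drugs, 8 events, 10% label noise."""
    return generate(FIXTURE_SCALES["small"])


def random_bit_matrix(rng: np.random.Generator, n: int, v: int, p: float = 0.3) -> np.ndarray:
    return (rng.random((n, v)) < p).astype(np.uint8)
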