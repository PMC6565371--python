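import numpy as np
import pytest

from kgcascade import KnowledgeGraph, PlantedKGSpec, Triplet, make_translation_kg


@pytest.fixture
def tiny_graph() -> KnowledgeGraph:
    """Five hand-enumerable facts over four entities and two relations.

    a -r0-> b, a -r0-> c, b -r1-> c, c -r0-> d, d -r1-> a
    """
    return KnowledgeGraph(
        ["a", "b", "c", "d"],
        ["r0", "r1"],
        [
            Triplet(0, 0, 1),
            Triplet(0, 0, 2),
            Triplet(1, 1, 2),
            Triplet(2, 0, 3),
            Triplet(3, 1, 0),
        ],
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted translation KG (50 entities, 2 relations, no noise)."""
    return make_translation_kg(PlantedKGSpec(seed=0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
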