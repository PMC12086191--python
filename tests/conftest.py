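import numpy as np
import pytest

from drugvec.embeddings import EmbeddingStore
from drugvec.relations import (PathwayCatalog, PathwayEntry, RelationSet,
                               YearAnnotations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_store():
    """Five drugs and five genes in K=4, fixed values."""
    rng = np.random.default_rng(7)
    ids = [f"d{i}" for i in range(5)] + [f"g{i}" for i in range(5)]
    return EmbeddingStore(ids, rng.normal(size=(10, 4)))


@pytest.fixture
def tiny_relations():
    pairs = [("d0", "g0"), ("d0", "g1"), ("d1", "g1"), ("d2", "g2"),
             ("d3", "g3")]
    return RelationSet.from_pairs(
        pairs,
        drug_universe=[f"d{i}" for i in range(5)],
        gene_universe=[f"g{i}" for i in range(5)])


@pytest.fixture
def tiny_catalog():
    return PathwayCatalog([
        PathwayEntry("pA", "pathway A",
                     frozenset({"d0", "d1"}), frozenset({"g0", "g1", "g4"})),
        PathwayEntry("pB", "pathway B",
                     frozenset({"d2", "d3", "d4"}), frozenset({"g2", "g3"})),
    ])


@pytest.fixture
def tiny_years():
    years = YearAnnotations(
        drug_year={f"d{i}": 1980 + 5 * i for i in range(5)},
        gene_year={f"g{i}": 1982 + 5 * i for i in range(5)},
        pair_year={("d0", "g0"): 1985, ("d0", "g1"): 2001,
                   ("d1", "g1"): 1990, ("d2", "g2"): 2010},
        # ("d3", "g3") deliberately has no co-appearance year
    )
    years.validate()
    return years


@pytest.fixture
def planted_store():
    """Ten drugs; each gene g{i} = d{i} + v* exactly (noise-free)."""
    rng = np.random.default_rng(11)
    vstar = np.array([1.5, -0.5, 2.0])
    drugs = rng.normal(size=(10, 3))
    ids = [f"d{i}" for i in range(10)] + [f"g{i}" for i in range(10)]
    store = EmbeddingStore(ids, np.vstack([drugs, drugs + vstar]))
    relations = RelationSet.from_pairs(
        [(f"d{i}", f"g{i}") for i in range(10)],
        drug_universe=[f"d{i}" for i in range(10)],
        gene_universe=[f"g{i}" for i in range(10)])
    return store, relations, vstar
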