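import numpy as np
import pytest

from kgsynergy.kg import KnowledgeGraph, Triple
from kgsynergy.synthetic import SyntheticSpec, generate_planted_kg


@pytest.fixture
def toy_kg() -> KnowledgeGraph:
    """Small typed graph: 2 drugs, 2 proteins, a pathology hub."""
    triples = [
        ("drugA", "targets", "prot1"),
        ("drugB", "targets", "prot2"),
        ("prot1", "increases", "prot2"),
        ("prot1", "association", "prot2"),
        ("prot1", "increases", "disease1"),
        ("prot2", "decreases", "disease1"),
        ("prot2", "causes_no_change", "prot1"),
        ("drugA", "has_synergism_with", "drugB"),
    ]
    types = {
        "drugA": "Drug",
        "drugB": "Drug",
        "prot1": "Protein",
        "prot2": "Protein",
        "disease1": "Pathology",
    }
    return KnowledgeGraph.from_triples([Triple(*t) for t in triples], entity_type=types)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted KG for training-loop tests (fast to embed)."""
    spec = SyntheticSpec(
        n_entities=100, n_relations=4, n_drugs=20, triple_budget=600, n_pairs=120, seed=0
    )
    kg, truth = generate_planted_kg(spec)
    return spec, kg, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
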