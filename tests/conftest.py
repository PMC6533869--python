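"""Shared fixtures: tiny ontologies, random DAGs, and a small trained model."""

from __future__ import annotations

import numpy as np
import pytest

from neurodict.fixtures import FixtureSpec, make_negative_corpus, make_toy_world
from neurodict.model import ModelConfig
from neurodict.ontology import Concept, Ontology, build_ancestry_matrix
from neurodict.train import TrainPlan, build_training_set, sample_negatives, train


def make_ontology(edges: dict[str, list[str]], synonyms: dict[str, list[str]] | None = None):
    """Ontology from {id: [parent ids]}; names default to the id."""
    synonyms = synonyms or {}
    return Ontology(
        {
            cid: Concept(id=cid, name=cid, synonyms=synonyms.get(cid, []), parents=parents)
            for cid, parents in edges.items()
        }
    )


def random_dag(n: int, seed: int) -> Ontology:
    """Random DAG: node i may take 1-3 parents among 0..i-1 (node 0 is a root)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    edges: dict[str, list[str]] = {"n0": []}
    for i in range(1, n):
        k = min(i, int(rng.integers(1, 4)))
        parents = sorted(rng.choice(i, size=k, replace=False).tolist())
        edges[f"n{i}"] = [f"n{p}" for p in parents]
    return make_ontology(edges)


def ancestry_row_oracle(ontology: Ontology) -> dict[str, dict[str, float]]:
    """Memoized depth-first evaluation of the ancestry recursion, per row."""
    memo: dict[str, dict[str, float]] = {}

    def row(cid: str) -> dict[str, float]:
        if cid not in memo:
            r: dict[str, float] = {}
            parents = ontology[cid].parents
            if parents:
                w = 1.0 / len(parents)
                for p in parents:
                    for j, c in row(p).items():
                        r[j] = r.get(j, 0.0) + w * c
            r[cid] = r.get(cid, 0.0) + 1.0
            memo[cid] = r
        return memo[cid]

    return {cid: row(cid) for cid in ontology.concepts}


def closure_oracle(ontology: Ontology, cid: str) -> set[str]:
    """Breadth-first ancestor enumeration."""
    seen = {cid}
    frontier = [cid]
    while frontier:
        nxt = []
        for c in frontier:
            for p in ontology[c].parents:
                if p not in seen:
                    seen.add(p)
                    nxt.append(p)
        frontier = nxt
    return seen


@pytest.fixture
def chain_ontology():
    return make_ontology({"root": [], "c1": ["root"], "c2": ["c1"]})


@pytest.fixture
def diamond_ontology():
    return make_ontology({"root": [], "a": ["root"], "b": ["root"], "c": ["a", "b"]})


SMALL_SPEC = FixtureSpec(
    n_concepts=10, branching=3, synonyms_per_concept=2, vocab_size=30,
    word_dim=16, n_docs=6, mentions_per_doc=2, seed=11, max_depth=3,
    multi_parent_rate=0.0,
)


@pytest.fixture(scope="session")
def small_world():
    return make_toy_world(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_model(small_world):
    """A model trained to memorize the small fixture (used across modules)."""
    world = small_world
    positives = build_training_set(world.ontology)
    negatives = sample_negatives(
        make_negative_corpus(world.spec), len(positives), seed=world.spec.seed
    )
    config = ModelConfig(
        word_dim=world.spec.word_dim, concept_dim=32, conv_filters=32, seed=0
    )
    plan = TrainPlan(epochs=200, batch_size=16, ensemble_size=1, seeds=[0])
    ancestry = build_ancestry_matrix(world.ontology)
    return train(config, plan, positives, negatives, world.word_table, ancestry)
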