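"""Deterministic synthetic ontologies, word vectors and annotated corpora.

The generator emulates the data the recognizer consumes in practice — a
taxonomy whose concept names grow more specific with depth, synonym strings
that paraphrase a name word-by-word, pretrained vectors that place synonymous
words close together, and documents with planted mentions:

* every concept's name is its own modifier token followed by its (primary)
  parent's full name, so deeper concepts have longer, more specific names;
* every surface token belongs to a small synonym group; training synonyms
  substitute group members word-by-word, and *held-out* paraphrases use group
  members that never appear in training, so ranking them correctly requires
  generalizing through word-vector geometry rather than memorization;
* the word-vector fixture draws each group near a shared centroid
  (within-group cosine > 0.8), mimicking what unsupervised pretraining gives
  real synonyms;
* documents embed mention surface forms inside filler sentences drawn from a
  disjoint vocabulary, which doubles as the negative-sampling corpus.

Everything is a pure function of the spec (integer-seeded PCG64 streams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ontology import Concept, Ontology
from .wordvec import WordVectorTable, make_fixture_vectors

__all__ = [
    "FixtureSpec",
    "ToyWorld",
    "make_toy_ontology",
    "make_toy_world",
    "make_demo_ontology",
    "make_annotated_corpus",
    "make_negative_corpus",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_concepts: int = 30
    branching: int = 3  # max children per node in the primary tree
    synonyms_per_concept: int = 3
    vocab_size: int = 60  # filler / negative-corpus vocabulary
    word_dim: int = 25
    n_docs: int = 10
    mentions_per_doc: int = 3
    seed: int = 0
    held_out_per_concept: int = 2
    max_depth: int = 5
    multi_parent_rate: float = 0.1  # chance of one extra is_a parent per concept

    def __post_init__(self):
        if min(self.n_concepts, self.branching, self.synonyms_per_concept,
               self.vocab_size, self.word_dim, self.n_docs) < 1:
            raise ValueError("all fixture counts must be >= 1")
        if self.mentions_per_doc < 0 or self.held_out_per_concept < 0:
            raise ValueError("mentions_per_doc and held_out_per_concept must be >= 0")
        capacity = 1 + sum(self.branching**d for d in range(1, self.max_depth + 1))
        if self.n_concepts > capacity:
            raise ValueError(
                f"branching {self.branching} with max_depth {self.max_depth} "
                f"fits at most {capacity} concepts, requested {self.n_concepts}"
            )

    @property
    def group_size(self) -> int:
        # name + training synonyms + held-out paraphrase slots
        return 1 + self.synonyms_per_concept + self.held_out_per_concept


@dataclass
class ToyWorld:
    """A full synthetic workspace bundling the per-format fixtures."""

    spec: FixtureSpec
    ontology: Ontology
    synonym_groups: list[list[str]]
    word_table: WordVectorTable
    held_out: list[tuple[tuple[str, ...], str]]  # (tokens, gold concept id)
    ontology_vocab: list[str]
    negative_vocab: list[str]


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64([spec.seed, stream]))


def _concept_id(i: int) -> str:
    return f"TOY:{i:07d}"


def _group(spec: FixtureSpec, i: int) -> list[str]:
    return [f"t{i:03d}{chr(97 + m)}" for m in range(spec.group_size)]


def _negative_vocab(spec: FixtureSpec) -> list[str]:
    return [f"neg{i:03d}" for i in range(spec.vocab_size)]


def _build_structure(spec: FixtureSpec):
    """Primary tree (plus optional extra parents) and per-concept name slots.

    ``slots[i]`` lists the synonym-group index of each token of concept i's
    name, own modifier first; member m of each slot yields surface variant m.
    """
    rng = _rng(spec, 0)
    parents: list[list[int]] = [[]]
    depth = [0]
    children_count = [0]
    slots: list[list[int]] = [[0]]
    for i in range(1, spec.n_concepts):
        eligible = [
            j for j in range(i)
            if children_count[j] < spec.branching and depth[j] < spec.max_depth
        ]
        p = int(eligible[rng.integers(len(eligible))])
        children_count[p] += 1
        par = [p]
        if rng.random() < spec.multi_parent_rate:
            extras = [j for j in range(i) if j != p]
            if extras:
                par.append(int(extras[rng.integers(len(extras))]))
        parents.append(par)
        depth.append(depth[p] + 1)
        children_count.append(0)
        slots.append([i] + slots[p])
    return parents, slots


def _surface(spec: FixtureSpec, slots: list[int], member: int) -> str:
    return " ".join(_group(spec, g)[member] for g in slots)


def make_toy_ontology(spec: FixtureSpec) -> Ontology:
    """A rooted concept DAG with compositional names and word-level synonyms."""
    parents, slots = _build_structure(spec)
    concepts = {}
    for i in range(spec.n_concepts):
        concepts[_concept_id(i)] = Concept(
            id=_concept_id(i),
            name=_surface(spec, slots[i], 0),
            synonyms=[
                _surface(spec, slots[i], m)
                for m in range(1, 1 + spec.synonyms_per_concept)
            ],
            parents=[_concept_id(p) for p in parents[i]],
        )
    return Ontology(concepts)


def make_toy_world(spec: FixtureSpec) -> ToyWorld:
    """Ontology + matching word vectors + held-out paraphrases in one bundle."""
    _, slots = _build_structure(spec)
    ontology = make_toy_ontology(spec)
    groups = [_group(spec, i) for i in range(spec.n_concepts)]
    ontology_vocab = [tok for g in groups for tok in g]
    negative_vocab = _negative_vocab(spec)
    word_table = make_fixture_vectors(
        vocab=ontology_vocab + negative_vocab,
        dim=spec.word_dim,
        seed=spec.seed,
        synonym_groups=groups,
    )
    held_out = []
    for i in range(spec.n_concepts):
        for k in range(spec.held_out_per_concept):
            member = 1 + spec.synonyms_per_concept + k
            tokens = tuple(_surface(spec, slots[i], member).split())
            held_out.append((tokens, _concept_id(i)))
    return ToyWorld(
        spec=spec,
        ontology=ontology,
        synonym_groups=groups,
        word_table=word_table,
        held_out=held_out,
        ontology_vocab=ontology_vocab,
        negative_vocab=negative_vocab,
    )


def make_demo_ontology() -> Ontology:
    """A three-concept demo taxonomy: a cardiovascular root, "heart defect",
    and its more specific child "conotruncal heart defect".

    Used to demonstrate overlap resolution: in a sentence containing the
    child's name, the span "heart defect" also matches the parent concept, and
    the longer, more specific match must win.
    """
    return Ontology(
        {
            "DEMO:0000001": Concept(
                id="DEMO:0000001", name="cardiovascular abnormality"
            ),
            "DEMO:0000002": Concept(
                id="DEMO:0000002", name="heart defect",
                synonyms=["cardiac defect"], parents=["DEMO:0000001"],
            ),
            "DEMO:0000003": Concept(
                id="DEMO:0000003", name="conotruncal heart defect",
                parents=["DEMO:0000002"],
            ),
        }
    )


#: Generic clinical-note filler vocabulary for the demo negative corpus.
DEMO_FILLER = (
    "the patient was diagnosed with a severe condition today clinic report "
    "noted follow up visit history exam normal stable mild chronic acute "
    "review plan"
).split()


def make_demo_world(seed: int = 0, word_dim: int = 16):
    """Word vectors and a negative corpus to go with :func:`make_demo_ontology`.

    Returns (ontology, word_table, negative_corpus).  Like the unrelated text
    a practitioner would sample negatives from, the corpus is mostly generic
    filler but also contains concept-name words in isolation (never two
    adjacent, so no negative n-gram equals a concept surface form): this
    teaches the NONE class that a lone "defect" or "heart" outside a concept
    phrase is not a mention.
    """
    ontology = make_demo_ontology()
    vocab = sorted(
        {w for c in ontology.concepts.values() for s in c.labels() for w in s.split()}
    )
    table = make_fixture_vectors(vocab + DEMO_FILLER, dim=word_dim, seed=seed)
    rng = np.random.Generator(np.random.PCG64([seed, 3]))
    corpus: list[str] = []
    for i in range(400):
        if i % 4 == 3:  # isolated ontology word between filler runs
            corpus.append(vocab[int(rng.integers(len(vocab)))])
        else:
            corpus.append(DEMO_FILLER[int(rng.integers(len(DEMO_FILLER)))])
    return ontology, table, corpus


def make_annotated_corpus(
    ontology: Ontology, spec: FixtureSpec
) -> tuple[list[tuple[str, str]], dict[str, set[str]]]:
    """Documents with planted mentions plus their gold concept sets.

    Each document carries ``mentions_per_doc`` distinct concepts, each mention
    a verbatim name-or-synonym surface form wrapped in filler words from the
    negative vocabulary, one sentence per mention plus one pure-filler
    sentence.
    """
    rng = _rng(spec, 1)
    filler = _negative_vocab(spec)
    ids = sorted(ontology.concepts)
    n_mentions = min(spec.mentions_per_doc, len(ids))
    documents, gold = [], {}
    for d in range(spec.n_docs):
        doc_id = f"doc{d:03d}"
        chosen = [ids[int(i)] for i in rng.choice(len(ids), size=n_mentions, replace=False)]
        sentences = []
        for cid in chosen:
            labels = ontology[cid].labels()
            mention = labels[int(rng.integers(len(labels)))]
            pre = " ".join(filler[int(i)] for i in rng.integers(len(filler), size=int(rng.integers(2, 5))))
            post = " ".join(filler[int(i)] for i in rng.integers(len(filler), size=int(rng.integers(2, 5))))
            sentences.append(f"{pre} {mention} {post}.")
        sentences.append(
            " ".join(filler[int(i)] for i in rng.integers(len(filler), size=6)) + "."
        )
        documents.append((doc_id, " ".join(sentences)))
        gold[doc_id] = set(chosen)
    return documents, gold


def make_negative_corpus(spec: FixtureSpec) -> list[str]:
    """>= 10 * vocab_size tokens from a vocabulary disjoint from the ontology's."""
    rng = _rng(spec, 2)
    vocab = _negative_vocab(spec)
    n = 10 * spec.vocab_size
    return [vocab[int(i)] for i in rng.integers(len(vocab), size=n)]
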