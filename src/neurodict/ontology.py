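"""Concept DAG handling: OBO parsing, ancestor closures, the ancestry matrix.

An ontology here is a set of concepts with ``is_a`` (taxonomic) edges, as in
the Human Phenotype Ontology or SNOMED-CT.  The taxonomy enters the model
through the *ancestry matrix* ``A``: row ``i`` carries a weight for concept
``i`` itself and for each of its ancestors, defined recursively as

    row(i) = unit(i)                                   if i is a root
    row(i) = unit(i) + mean over parents p of row(p)   otherwise

so that composing raw per-concept embeddings through ``A`` gives each concept
the "global location" of its parents plus its own "novel" offset.  With
multiple inheritance the parents' rows are averaged; weights reaching a shared
ancestor along several paths accumulate additively, as the recursion implies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import obonet
import scipy.sparse as sp

__all__ = [
    "Concept",
    "Ontology",
    "AncestryMatrix",
    "OntologyStructureError",
    "parse_obo",
    "write_obo",
    "ancestors",
    "build_ancestry_matrix",
    "build_closed_subset",
]


class OntologyStructureError(ValueError):
    """Raised for cyclic or dangling ``is_a`` structure."""


_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass
class Concept:
    """One ontology term: id, canonical name, synonyms, parent ids."""

    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)

    def labels(self) -> list[str]:
        """Name plus synonyms, each distinct string once, name first."""
        seen = {self.name}
        out = [self.name]
        for s in self.synonyms:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out


class Ontology:
    """A concept DAG keyed by id, with roots and a topological order.

    ``topo_order`` lists every concept id with each parent before all of its
    children.  ``alt_ids`` maps alternative (merged) ids to primary ids.
    """

    def __init__(self, concepts: dict[str, Concept], alt_ids: dict[str, str] | None = None):
        self.concepts = dict(concepts)
        self.alt_ids = dict(alt_ids or {})
        for c in self.concepts.values():
            for p in c.parents:
                if p not in self.concepts:
                    raise OntologyStructureError(
                        f"concept {c.id!r} has dangling is_a target {p!r}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.parents:
                g.add_edge(p, c.id)  # parent -> child
        try:
            self.topo_order: list[str] = list(nx.lexicographical_topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise OntologyStructureError(
                f"is_a graph contains a cycle through {cycle[0][0]!r}"
            ) from None
        self.roots: list[str] = sorted(i for i, c in self.concepts.items() if not c.parents)
        if self.concepts and not self.roots:
            raise OntologyStructureError("ontology has no root concepts")
        self._children: dict[str, list[str]] = {i: [] for i in self.concepts}
        for c in self.concepts.values():
            for p in c.parents:
                self._children[p].append(c.id)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[concept_id]

    def resolve(self, concept_id: str) -> str:
        """Map an id (possibly an alt_id alias) to its primary id."""
        if concept_id in self.concepts:
            return concept_id
        if concept_id in self.alt_ids:
            return self.alt_ids[concept_id]
        raise KeyError(f"unknown concept id {concept_id!r}")

    def children(self, concept_id: str) -> list[str]:
        return list(self._children[concept_id])


def parse_obo(path) -> Ontology:
    """Read an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    Non-obsolete ``[Term]`` stanzas become concepts; ``synonym`` lines
    contribute the quoted label string regardless of scope qualifier
    (EXACT/BROAD/...); ``alt_id`` lines are recorded as aliases.  A cycle or a
    dangling ``is_a`` target raises :class:`OntologyStructureError`.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    concepts: dict[str, Concept] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # obonet materializes dangling is_a targets as attribute-less nodes
            referrers = [u for u, v in graph.in_edges(node)]
            raise OntologyStructureError(
                f"is_a target {node!r} (referenced by {referrers[0]!r}) is not defined"
            )
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            synonyms.append(m.group(1) if m else raw)
        concepts[node] = Concept(
            id=node,
            name=data["name"],
            synonyms=synonyms,
            parents=sorted(data.get("is_a", [])),
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return Ontology(concepts, alt_ids)


def write_obo(ontology: Ontology, path) -> None:
    """Write the ontology back to OBO so subset extraction round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: neurodict-export\n")
        for cid in ontology.topo_order:
            c = ontology[cid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {c.id}\n")
            fh.write(f"name: {c.name}\n")
            for alt, primary in sorted(ontology.alt_ids.items()):
                if primary == cid:
                    fh.write(f"alt_id: {alt}\n")
            for s in c.synonyms:
                fh.write(f'synonym: "{s}" EXACT []\n')
            for p in c.parents:
                fh.write(f"is_a: {p}\n")


def ancestors(ontology: Ontology, concept_id: str) -> set[str]:
    """Reflexive-transitive closure over parent edges (includes the id itself)."""
    if concept_id not in ontology:
        raise KeyError(f"unknown concept id {concept_id!r}")
    closure: set[str] = set()
    stack = [concept_id]
    while stack:
        cid = stack.pop()
        if cid in closure:
            continue
        closure.add(cid)
        stack.extend(ontology[cid].parents)
    return closure


@dataclass
class AncestryMatrix:
    """Sparse n×n matrix of ancestor coefficients with its id↔row index.

    ``A[i, j]`` is nonzero only when ``j`` is an ancestor of ``i`` or ``j == i``;
    the diagonal is 1 and a root's row is its own unit vector.
    """

    ids: list[str]
    row_of: dict[str, int]
    A: sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.ids)


def build_ancestry_matrix(ontology: Ontology) -> AncestryMatrix:
    """Evaluate the ancestry recursion in topological order.

    Rows are indexed by ``topo_order``, which guarantees every parent row is
    complete before it is averaged into a child row.
    """
    ids = list(ontology.topo_order)
    row_of = {cid: i for i, cid in enumerate(ids)}
    rows: list[dict[int, float]] = []
    for cid in ids:
        row: dict[int, float] = {}
        parents = ontology[cid].parents
        if parents:
            w = 1.0 / len(parents)
            for p in parents:
                for j, coef in rows[row_of[p]].items():
                    row[j] = row.get(j, 0.0) + w * coef
        i = row_of[cid]
        row[i] = row.get(i, 0.0) + 1.0
        rows.append(row)
    data, ri, ci = [], [], []
    for i, row in enumerate(rows):
        for j, coef in row.items():
            ri.append(i)
            ci.append(j)
            data.append(coef)
    n = len(ids)
    A = sp.coo_matrix((np.asarray(data), (ri, ci)), shape=(n, n)).tocsr()
    return AncestryMatrix(ids=ids, row_of=row_of, A=A)


def build_closed_subset(
    ontology: Ontology, seed_ids: set[str]
) -> tuple[Ontology, dict[str, int]]:
    """Restrict the ontology to the ancestor closure of ``seed_ids``.

    Returns the closed sub-ontology (parent edges restricted to the retained
    set, which closure makes a no-op) and bookkeeping counts satisfying
    ``total = seeds + added_ancestors``.
    """
    seeds = set(seed_ids)
    for s in seeds:
        if s not in ontology:
            raise KeyError(f"unknown seed concept id {s!r}")
    # collective BFS: the union of per-seed closures in one pass
    keep: set[str] = set(seeds)
    stack = list(seeds)
    while stack:
        cid = stack.pop()
        for p in ontology[cid].parents:
            if p not in keep:
                keep.add(p)
                stack.append(p)
    concepts = {
        cid: Concept(
            id=cid,
            name=ontology[cid].name,
            synonyms=list(ontology[cid].synonyms),
            parents=[p for p in ontology[cid].parents if p in keep],
        )
        for cid in keep
    }
    alt_ids = {a: p for a, p in ontology.alt_ids.items() if p in keep}
    counts = {
        "seeds": len(seeds),
        "added_ancestors": len(keep) - len(seeds),
        "total": len(keep),
    }
    return Ontology(concepts, alt_ids), counts
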