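"""Pretrained word vectors: loading, total lookup, deterministic fixtures.

The model consumes word embeddings produced in a separate unsupervised step
(e.g. fastText on MEDLINE abstracts); here they are read from the plain
word2vec text format ("V D" header, then one token + D floats per line).
Lookup is total: out-of-vocabulary tokens resolve to the zero vector by
default, or to a stable hash-seeded unit vector under the ``hash-random``
policy, so the encoder never sees a missing input.
"""

from __future__ import annotations

import hashlib
import logging
import warnings

import numpy as np

__all__ = ["WordVectorTable", "WordVectorFormatError", "load_word_vectors", "save_word_vectors", "make_fixture_vectors"]

logger = logging.getLogger(__name__)

OOV_POLICIES = ("zero", "hash-random")


class WordVectorFormatError(ValueError):
    """Malformed word2vec-style text file (bad header, arity, or field)."""


class WordVectorTable:
    """token -> R^dim mapping with a configurable out-of-vocabulary policy."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int, oov_policy: str = "zero"):
        if oov_policy not in OOV_POLICIES:
            raise ValueError(f"oov_policy must be one of {OOV_POLICIES}, got {oov_policy!r}")
        for tok, v in vectors.items():
            if v.shape != (dim,):
                raise ValueError(f"vector for {tok!r} has shape {v.shape}, expected ({dim},)")
        self.vectors = vectors
        self.dim = dim
        self.oov_policy = oov_policy

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, token: str) -> bool:
        return token in self.vectors

    def lookup(self, token: str) -> np.ndarray:
        """Vector for ``token``; OOV tokens follow the table's policy."""
        v = self.vectors.get(token)
        if v is not None:
            return v
        if self.oov_policy == "zero":
            return np.zeros(self.dim)
        return _hash_random_vector(token, self.dim)

    def encode_tokens(self, tokens: list[str]) -> np.ndarray:
        """Stack lookups into a (len(tokens), dim) matrix."""
        return np.stack([self.lookup(t) for t in tokens])


def _hash_random_vector(token: str, dim: int) -> np.ndarray:
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    seed = int.from_bytes(digest[:4], "little")
    rng = np.random.Generator(np.random.PCG64(seed))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def load_word_vectors(path, oov_policy: str = "zero") -> WordVectorTable:
    """Parse a word2vec text file; duplicate tokens keep the first row."""
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise WordVectorFormatError("line 1: header must be 'V D'")
        try:
            n_rows, dim = int(header[0]), int(header[1])
        except ValueError:
            raise WordVectorFormatError("line 1: non-integer header field") from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != dim + 1:
                raise WordVectorFormatError(
                    f"line {lineno}: expected token + {dim} floats, got {len(parts)} fields"
                )
            token = parts[0]
            try:
                vec = np.array([float(x) for x in parts[1:]])
            except ValueError:
                raise WordVectorFormatError(f"line {lineno}: non-numeric field") from None
            if token in vectors:
                logger.warning("duplicate token %r at line %d; keeping first", token, lineno)
                continue
            vectors[token] = vec
    if len(vectors) != n_rows:
        warnings.warn(
            f"header declared {n_rows} rows, file yielded {len(vectors)} distinct tokens",
            stacklevel=2,
        )
    return WordVectorTable(vectors, dim, oov_policy)


def save_word_vectors(table: WordVectorTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dim}\n")
        for token, vec in table.vectors.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def make_fixture_vectors(
    vocab: list[str],
    dim: int,
    seed: int,
    synonym_groups: list[list[str]] | None = None,
    oov_policy: str = "zero",
    group_spread: float = 0.25,
) -> WordVectorTable:
    """Deterministic unit-norm vectors for tests.

    Tokens in one synonym group are drawn near a shared random centroid
    (``v = normalize(centroid + group_spread * noise)``), which at the default
    spread keeps within-group cosines above 0.8 — emulating the property that
    pretrained embeddings place synonyms close together, while unrelated
    tokens stay near-orthogonal in high dimension.
    """
    if not vocab:
        raise ValueError("vocab must be non-empty")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    group_of: dict[str, int] = {}
    if synonym_groups:
        for gi, group in enumerate(synonym_groups):
            for tok in group:
                group_of[tok] = gi
    rng = np.random.Generator(np.random.PCG64(seed))
    centroids = {}
    if synonym_groups:
        for gi in range(len(synonym_groups)):
            c = rng.standard_normal(dim)
            centroids[gi] = c / np.linalg.norm(c)
    vectors: dict[str, np.ndarray] = {}
    for token in vocab:
        noise = rng.standard_normal(dim)
        if token in group_of:
            v = centroids[group_of[token]] + group_spread * noise / np.linalg.norm(noise)
        else:
            v = noise
        vectors[token] = v / np.linalg.norm(v)
    return WordVectorTable(vectors, dim, oov_policy)
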