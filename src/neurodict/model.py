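"""The neural dictionary: phrase encoder, concept embeddings, softmax scoring.

A phrase of T tokens is represented by its word vectors x^(1..T).  The encoder
projects each token with a single convolution of filter width one, applies an
ELU nonlinearity, and aggregates with max-over-time pooling:

    v = max_t ELU(W x^(t) + b)            (elementwise max across tokens)

A fully connected layer, ReLU and l2 normalization give the phrase embedding

    e = normalize(ReLU(U v))

Each concept c has a learnable *raw* embedding (its features novel relative to
its ancestors); the *final* embedding actually scored is the raw embedding
composed through the taxonomy's ancestry matrix, H = A·H̄.  Scores are a
softmax over dot products H·e plus a per-concept bias.  A dummy NONE class —
one extra row of H̄, identity-composed, with its own bias — absorbs phrases
that match no concept when the model is trained with negative examples.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .ontology import AncestryMatrix
from .wordvec import WordVectorTable

__all__ = [
    "NONE_ID",
    "ModelConfig",
    "EncoderParams",
    "PhraseEncoding",
    "ScoreDistribution",
    "NeuralDictionary",
    "elu",
    "encode_phrase",
    "compose_final_embeddings",
    "score_concepts",
    "batch_score",
    "pad_token_batch",
    "pooled_conv",
    "top_k",
    "ensemble_scores",
    "save_checkpoint",
    "load_checkpoint",
]

NONE_ID = "NONE"
_NORM_EPS = 1e-12

#: The four published ablation variants, mapping name -> (use_hierarchy, use_negatives).
VARIANTS = {
    "NCR": (True, True),
    "NCR-H": (False, True),
    "NCR-N": (True, False),
    "NCR-HN": (False, False),
}

#: Default annotation score threshold per variant, as selected on validation data.
VARIANT_THRESHOLDS = {"NCR": 0.85, "NCR-H": 0.8, "NCR-N": 0.8, "NCR-HN": 0.75}


@dataclass
class ModelConfig:
    word_dim: int = 100
    concept_dim: int = 1024
    conv_filters: int = 1024
    dense_dim: int | None = None  # output of the dense layer; must equal concept_dim
    use_hierarchy: bool = True
    use_negatives: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dense_dim is None:
            self.dense_dim = self.concept_dim
        if min(self.word_dim, self.concept_dim, self.conv_filters, self.dense_dim) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.dense_dim != self.concept_dim:
            raise ValueError("dense_dim must equal concept_dim")

    @classmethod
    def for_variant(cls, variant: str, **kwargs) -> "ModelConfig":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
        use_hierarchy, use_negatives = VARIANTS[variant]
        return cls(use_hierarchy=use_hierarchy, use_negatives=use_negatives, **kwargs)


@dataclass
class EncoderParams:
    """W: (conv_filters, word_dim); b: (conv_filters,); U: (concept_dim, conv_filters)."""

    W: np.ndarray
    b: np.ndarray
    U: np.ndarray

    def __post_init__(self):
        f, d = self.W.shape
        if self.b.shape != (f,):
            raise ValueError(f"b has shape {self.b.shape}, expected ({f},)")
        if self.U.shape[1] != f:
            raise ValueError(f"U has shape {self.U.shape}, expected (*, {f})")
        for a in (self.W, self.b, self.U):
            if not np.all(np.isfinite(a)):
                raise ValueError("encoder parameters must be finite")


@dataclass
class PhraseEncoding:
    """pooled: the max-pooled conv output v; embedding: the unit-norm phrase vector e."""

    pooled: np.ndarray
    embedding: np.ndarray


def elu(z: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(z > 0, z, alpha * np.expm1(np.minimum(z, 0.0)))


def encode_phrase(params: EncoderParams, token_vectors: np.ndarray) -> PhraseEncoding:
    """Encode a (T, word_dim) stack of word vectors into a PhraseEncoding.

    The embedding has unit l2 norm except in the degenerate case where every
    ReLU output is zero, which maps to the zero vector (guarded denominator).
    """
    X = np.asarray(token_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("token_vectors must be a non-empty (T, word_dim) array")
    if X.shape[1] != params.W.shape[1]:
        raise ValueError(
            f"word dim mismatch: vectors have {X.shape[1]}, W expects {params.W.shape[1]}"
        )
    v = elu(X @ params.W.T + params.b).max(axis=0)
    r = np.maximum(params.U @ v, 0.0)
    norm = np.linalg.norm(r)
    e = r / max(norm, _NORM_EPS)
    return PhraseEncoding(pooled=v, embedding=e)


def compose_final_embeddings(
    raw: np.ndarray, ancestry: AncestryMatrix | None, use_hierarchy: bool
) -> np.ndarray:
    """H = A·H̄ (hierarchy on) or H = H̄ (ablation); a trailing NONE row, if the
    raw matrix has one more row than the ancestry index, passes through
    unchanged (it has no taxonomy parents)."""
    if not use_hierarchy:
        return raw
    if ancestry is None:
        raise ValueError("use_hierarchy=True requires an ancestry matrix")
    n = ancestry.n
    extra = raw.shape[0] - n
    if extra not in (0, 1):
        raise ValueError(
            f"raw has {raw.shape[0]} rows; ancestry matrix indexes {n} concepts"
        )
    H = np.empty_like(raw)
    H[:n] = ancestry.A @ raw[:n]
    if extra:
        H[n:] = raw[n:]
    return H


@dataclass
class ScoreDistribution:
    """Softmax probabilities over concept ids (plus NONE when present)."""

    ids: list[str]  # concept ids, model order, NONE excluded
    probs: np.ndarray  # length len(ids) (+1 with the NONE prob last)
    has_none: bool = False

    def __post_init__(self):
        expected = len(self.ids) + (1 if self.has_none else 0)
        if self.probs.shape != (expected,):
            raise ValueError(f"probs has shape {self.probs.shape}, expected ({expected},)")

    @property
    def none_prob(self) -> float:
        return float(self.probs[-1]) if self.has_none else 0.0

    def concept_probs(self) -> np.ndarray:
        return self.probs[: len(self.ids)]

    def prob_of(self, concept_id: str) -> float:
        if concept_id == NONE_ID:
            return self.none_prob
        return float(self.probs[self.ids.index(concept_id)])


class NeuralDictionary:
    """A trained (or initialized) neural dictionary over one ontology.

    Holds the encoder parameters, the raw concept embedding matrix H̄ (with a
    trailing NONE row when negatives are used), the per-row bias, the concept
    id index aligned with the ancestry matrix, and the word-vector table used
    to resolve tokens.
    """

    def __init__(
        self,
        config: ModelConfig,
        concept_ids: list[str],
        params: EncoderParams,
        raw_embeddings: np.ndarray,
        bias: np.ndarray,
        ancestry: AncestryMatrix | None,
        word_table: WordVectorTable,
    ):
        self.config = config
        self.concept_ids = list(concept_ids)
        n_rows = len(concept_ids) + (1 if config.use_negatives else 0)
        if raw_embeddings.shape != (n_rows, config.concept_dim):
            raise ValueError(
                f"raw embeddings have shape {raw_embeddings.shape}, "
                f"expected ({n_rows}, {config.concept_dim})"
            )
        if bias.shape != (n_rows,):
            raise ValueError(f"bias has shape {bias.shape}, expected ({n_rows},)")
        if config.use_hierarchy and (ancestry is None or ancestry.ids != self.concept_ids):
            raise ValueError("ancestry matrix must be indexed exactly by concept_ids")
        self.params = params
        self.raw_embeddings = raw_embeddings
        self.bias = bias
        self.ancestry = ancestry
        self.word_table = word_table

    @property
    def n_concepts(self) -> int:
        return len(self.concept_ids)

    @property
    def has_none(self) -> bool:
        return self.config.use_negatives

    def final_embeddings(self) -> np.ndarray:
        return compose_final_embeddings(
            self.raw_embeddings, self.ancestry, self.config.use_hierarchy
        )

    def encode(self, tokens: list[str]) -> PhraseEncoding:
        if not tokens:
            raise ValueError("phrase must contain at least one token")
        return encode_phrase(self.params, self.word_table.encode_tokens(tokens))

    @classmethod
    def initialize(
        cls,
        config: ModelConfig,
        concept_ids: list[str],
        ancestry: AncestryMatrix | None,
        word_table: WordVectorTable,
    ) -> "NeuralDictionary":
        """Glorot-uniform weights, zero biases and embeddings, seeded by config.seed."""
        rng = np.random.Generator(np.random.PCG64(config.seed))

        def glorot(shape):
            limit = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-limit, limit, size=shape)

        params = EncoderParams(
            W=glorot((config.conv_filters, config.word_dim)),
            b=np.zeros(config.conv_filters),
            U=glorot((config.concept_dim, config.conv_filters)),
        )
        n_rows = len(concept_ids) + (1 if config.use_negatives else 0)
        raw = glorot((n_rows, config.concept_dim))
        bias = np.zeros(n_rows)
        return cls(config, concept_ids, params, raw, bias, ancestry, word_table)


def score_concepts(model: NeuralDictionary, phrase: list[str]) -> ScoreDistribution:
    """Softmax over all concepts (and NONE) for a tokenized phrase."""
    enc = model.encode(phrase)
    logits = model.final_embeddings() @ enc.embedding + model.bias
    logits -= logits.max()
    expl = np.exp(logits)
    probs = expl / expl.sum()
    return ScoreDistribution(ids=model.concept_ids, probs=probs, has_none=model.has_none)


def batch_score(model: NeuralDictionary, phrases: list[list[str]]) -> np.ndarray:
    """Vectorized :func:`score_concepts` over many phrases.

    Returns a (len(phrases), n_rows) matrix of softmax probabilities, rows
    matching ``concept_ids`` (+ NONE last when present).  Agrees with the
    per-phrase path; phrases are padded and masked before max-pooling.
    """
    if not phrases:
        return np.zeros((0, model.n_concepts + (1 if model.has_none else 0)))
    if any(not p for p in phrases):
        raise ValueError("phrases must be non-empty token sequences")
    X, mask = pad_token_batch(model.word_table, phrases)
    v, _ = pooled_conv(model.params, X, mask)
    r = np.maximum(v @ model.params.U.T, 0.0)
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    e = r / np.maximum(norms, _NORM_EPS)
    logits = e @ model.final_embeddings().T + model.bias
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    return expl / expl.sum(axis=1, keepdims=True)


def pad_token_batch(
    word_table: WordVectorTable, phrases: list[list[str]]
) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length phrases into (B, Tmax, word_dim) plus a bool mask."""
    B = len(phrases)
    tmax = max(len(p) for p in phrases)
    X = np.zeros((B, tmax, word_table.dim))
    mask = np.zeros((B, tmax), dtype=bool)
    for i, toks in enumerate(phrases):
        X[i, : len(toks)] = word_table.encode_tokens(toks)
        mask[i, : len(toks)] = True
    return X, mask


def pooled_conv(
    params: EncoderParams, X: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Masked max-over-time pooling of ELU(W x + b) for a padded batch.

    Returns (pooled (B, F), argmax token index (B, F)); the argmax is the
    first maximizing token per filter, used to route gradients.
    """
    act = elu(X @ params.W.T + params.b)  # (B, T, F)
    act = np.where(mask[:, :, None], act, -np.inf)
    idx = act.argmax(axis=1)
    v = np.take_along_axis(act, idx[:, None, :], axis=1)[:, 0, :]
    return v, idx


def top_k(dist: ScoreDistribution, k: int) -> list[tuple[str, float]]:
    """The k best non-NONE concepts, descending score, ties by concept id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = sorted(
        zip(dist.ids, dist.concept_probs()), key=lambda p: (-p[1], p[0])
    )
    return [(cid, float(s)) for cid, s in pairs[:k]]


def ensemble_scores(dists: list[ScoreDistribution]) -> ScoreDistribution:
    """Average the prediction probabilities of seed-varied models."""
    if not dists:
        raise ValueError("need at least one distribution")
    first = dists[0]
    for d in dists[1:]:
        if d.ids != first.ids or d.has_none != first.has_none:
            raise ValueError("distributions cover different concept sets")
    probs = np.mean([d.probs for d in dists], axis=0)
    return ScoreDistribution(ids=first.ids, probs=probs, has_none=first.has_none)


def save_checkpoint(model: NeuralDictionary, path) -> None:
    """Serialize the full model (config, parameters, index, word table) to one
    .npz archive; load_checkpoint round-trips it bitwise."""
    arrays = {
        "config_json": np.array(json.dumps(asdict(model.config))),
        "concept_ids": np.array(model.concept_ids, dtype=object),
        "W": model.params.W,
        "b": model.params.b,
        "U": model.params.U,
        "raw_embeddings": model.raw_embeddings,
        "bias": model.bias,
        "wv_tokens": np.array(list(model.word_table.vectors), dtype=object),
        "wv_matrix": (
            np.stack(list(model.word_table.vectors.values()))
            if model.word_table.vectors
            else np.zeros((0, model.word_table.dim))
        ),
        "wv_dim": np.array(model.word_table.dim),
        "wv_oov_policy": np.array(model.word_table.oov_policy),
        "has_ancestry": np.array(model.ancestry is not None),
    }
    if model.ancestry is not None:
        A = model.ancestry.A
        arrays.update(
            anc_data=A.data, anc_indices=A.indices, anc_indptr=A.indptr,
            anc_shape=np.array(A.shape),
        )
    np.savez(path, **arrays)


def load_checkpoint(path) -> NeuralDictionary:
    with np.load(path, allow_pickle=True) as z:
        config = ModelConfig(**json.loads(str(z["config_json"])))
        concept_ids = [str(x) for x in z["concept_ids"]]
        params = EncoderParams(W=z["W"], b=z["b"], U=z["U"])
        tokens = [str(t) for t in z["wv_tokens"]]
        mat = z["wv_matrix"]
        table = WordVectorTable(
            {t: mat[i] for i, t in enumerate(tokens)},
            dim=int(z["wv_dim"]),
            oov_policy=str(z["wv_oov_policy"]),
        )
        ancestry = None
        if bool(z["has_ancestry"]):
            A = sp.csr_matrix(
                (z["anc_data"], z["anc_indices"], z["anc_indptr"]),
                shape=tuple(z["anc_shape"]),
            )
            ancestry = AncestryMatrix(
                ids=concept_ids, row_of={c: i for i, c in enumerate(concept_ids)}, A=A
            )
        return NeuralDictionary(
            config, concept_ids, params, z["raw_embeddings"], z["bias"], ancestry, table
        )
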