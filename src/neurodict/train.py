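"""Training: ontology-derived examples, NONE negatives, Adam on cross-entropy.

The only labeled data is the ontology itself: every distinct name-or-synonym
string of a concept is one positive example for that concept.  Random n-grams
from an unrelated corpus, labeled with the dummy NONE class, reduce false
positives on phrases that match no concept.  The trainable parameters are the
encoder weights W and U (the conv bias b rides along), the raw concept
embedding matrix H̄ and the per-row bias; word vectors are frozen inputs.
Cross-entropy between the softmax output and the labels is minimized with
Adam, reshuffling the examples across minibatches at the start of every epoch.

All arithmetic is float64 NumPy, so a fixed (config, plan, data) triple yields
a bitwise-identical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    NONE_ID,
    ModelConfig,
    NeuralDictionary,
    compose_final_embeddings,
    pad_token_batch,
    pooled_conv,
)
from .ontology import AncestryMatrix, Ontology

__all__ = [
    "TrainingExample",
    "TrainPlan",
    "TrainingDivergedError",
    "build_training_set",
    "sample_negatives",
    "train",
    "train_ensemble",
]

_NORM_EPS = 1e-12


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class TrainingExample:
    tokens: tuple[str, ...]
    label: str  # concept id, or NONE_ID

    def __post_init__(self):
        if not self.tokens:
            raise ValueError("training example must have at least one token")


@dataclass
class TrainPlan:
    learning_rate: float = 0.002
    batch_size: int = 256
    epochs: int = 100
    negative_ratio: float = 1.0  # negatives per positive, sampled once before training
    ensemble_size: int = 10
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.negative_ratio < 0:
            raise ValueError("negative_ratio must be non-negative")
        if not self.seeds:
            self.seeds = list(range(self.ensemble_size))
        if len(self.seeds) != self.ensemble_size:
            raise ValueError("need exactly ensemble_size seeds")


def build_training_set(ontology: Ontology, tokenizer=None) -> list[TrainingExample]:
    """One example per distinct (name-or-synonym string, concept) pair."""
    if tokenizer is None:
        from .annotate import tokenize_phrase

        tokenizer = tokenize_phrase
    examples = []
    for cid in ontology.topo_order:
        for label_str in ontology[cid].labels():
            tokens = tuple(tokenizer(label_str))
            if not tokens:
                warnings.warn(f"label {label_str!r} of {cid} tokenizes to nothing; skipped",
                              stacklevel=2)
                continue
            examples.append(TrainingExample(tokens=tokens, label=cid))
    return examples


def sample_negatives(
    corpus_tokens: list[str], count: int, seed: int, max_len: int = 10
) -> list[TrainingExample]:
    """``count`` random n-grams from an unrelated corpus, labeled NONE.

    Lengths are uniform on {1..max_len} (phenotypic phrases are assumed to be
    at most 10 tokens long) and start positions uniform over the corpus.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if len(corpus_tokens) < max_len:
        raise ValueError(f"negative corpus must have at least {max_len} tokens")
    rng = np.random.Generator(np.random.PCG64(seed))
    out = []
    for _ in range(count):
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, len(corpus_tokens) - length + 1))
        out.append(
            TrainingExample(tokens=tuple(corpus_tokens[start : start + length]), label=NONE_ID)
        )
    return out


def _label_indices(examples, concept_ids, use_negatives):
    row_of = {cid: i for i, cid in enumerate(concept_ids)}
    none_row = len(concept_ids)
    labels = np.empty(len(examples), dtype=np.int64)
    for i, ex in enumerate(examples):
        if ex.label == NONE_ID:
            if not use_negatives:
                raise ValueError("NONE-labeled example but use_negatives is false")
            labels[i] = none_row
        else:
            labels[i] = row_of[ex.label]
    return labels


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _forward_backward(model: NeuralDictionary, X, mask, labels):
    """Mean cross-entropy over the batch and gradients for (W, b, U, H̄, bias)."""
    params = model.params
    n = model.n_concepts
    use_h = model.config.use_hierarchy

    v, pool_idx = pooled_conv(params, X, mask)  # (B, F)
    h = v @ params.U.T  # (B, C)
    r = np.maximum(h, 0.0)
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    denom = np.maximum(norms, _NORM_EPS)
    e = r / denom
    H = compose_final_embeddings(model.raw_embeddings, model.ancestry, use_h)
    logits = e @ H.T + model.bias
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    probs = expl / expl.sum(axis=1, keepdims=True)
    B = X.shape[0]
    loss = float(-np.log(probs[np.arange(B), labels] + 1e-300).mean())

    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    dbias = dlogits.sum(axis=0)
    dH = dlogits.T @ e  # (rows, C)
    if use_h:
        dHraw = np.empty_like(dH)
        dHraw[:n] = model.ancestry.A.T @ dH[:n]
        dHraw[n:] = dH[n:]
    else:
        dHraw = dH
    de = dlogits @ H  # (B, C)
    # through e = r / max(||r||, eps): subtract the radial component where norm > eps
    radial = (e * de).sum(axis=1, keepdims=True)
    dr = np.where(norms > _NORM_EPS, (de - e * radial) / denom, de / denom)
    dh = dr * (h > 0)
    dU = dh.T @ v
    dv = dh @ params.U  # (B, F)
    dact = np.zeros(X.shape[:2] + (params.W.shape[0],))
    np.put_along_axis(dact, pool_idx[:, None, :], dv[:, None, :], axis=1)
    Z = X @ params.W.T + params.b
    dZ = dact * np.where(Z > 0, 1.0, np.exp(np.minimum(Z, 0.0)))
    dW = np.einsum("btf,btd->fd", dZ, X)
    db = dZ.sum(axis=(0, 1))
    return loss, (dW, db, dU, dHraw, dbias)


def train(
    config: ModelConfig,
    plan: TrainPlan,
    positives: list[TrainingExample],
    negatives: list[TrainingExample],
    word_table,
    ancestry: AncestryMatrix,
    log_path=None,
) -> NeuralDictionary:
    """Train one neural dictionary; returns it with ``loss_history`` attached."""
    if not positives:
        raise ValueError("positives must be non-empty")
    if config.use_negatives and not negatives:
        raise ValueError("use_negatives=True requires negative examples")
    if not config.use_negatives and negatives:
        raise ValueError("negatives supplied but use_negatives is false")

    model = NeuralDictionary.initialize(config, ancestry.ids, ancestry, word_table)
    examples = list(positives) + list(negatives)
    labels_all = _label_indices(examples, model.concept_ids, config.use_negatives)
    # token vectors are frozen: resolve each distinct phrase once
    phrases = [list(ex.tokens) for ex in examples]

    rng = np.random.Generator(np.random.PCG64(config.seed))
    params_list = [
        model.params.W, model.params.b, model.params.U, model.raw_embeddings, model.bias
    ]
    opt = _Adam([p.shape for p in params_list], plan.learning_rate)
    history = []
    for epoch in range(1, plan.epochs + 1):
        order = rng.permutation(len(examples))
        losses = []
        for lo in range(0, len(examples), plan.batch_size):
            batch = order[lo : lo + plan.batch_size]  # last partial batch kept
            X, mask = pad_token_batch(word_table, [phrases[i] for i in batch])
            loss, grads = _forward_backward(model, X, mask, labels_all[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.step(params_list, grads)
            losses.append(loss * len(batch))
        history.append(sum(losses) / len(examples))
    model.loss_history = history
    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("epoch\tmean_loss\n")
            for i, loss in enumerate(history, start=1):
                fh.write(f"{i}\t{loss!r}\n")
    return model


def train_ensemble(
    config: ModelConfig,
    plan: TrainPlan,
    positives,
    negatives,
    word_table,
    ancestry: AncestryMatrix,
) -> list[NeuralDictionary]:
    """One model per plan seed; predictions are averaged at inference time."""
    if len(set(plan.seeds)) != len(plan.seeds):
        warnings.warn("duplicate seeds in ensemble plan", stacklevel=2)
    return [
        train(replace(config, seed=s), plan, positives, negatives, word_table, ancestry)
        for s in plan.seeds
    ]
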