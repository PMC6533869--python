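"""Concept recognition in running text.

The document annotator scans every within-sentence n-gram of one to seven
tokens, scores each against the (ensemble) neural dictionary, keeps candidates
whose softmax probability clears a threshold, and resolves overlapping
candidates to a consistent non-overlapping set: of two overlapping n-grams
matched to the *same* concept the smaller survives; matched to *different*
concepts the longer survives, favoring the more specific concept (e.g.
"conotruncal heart defect" over "heart defect").
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .model import NeuralDictionary, ScoreDistribution, batch_score

__all__ = [
    "TokenizedDocument",
    "Candidate",
    "Annotation",
    "tokenize",
    "tokenize_phrase",
    "extract_ngrams",
    "score_spans",
    "filter_by_threshold",
    "resolve_overlaps",
    "annotate_text",
]

DEFAULT_MIN_NGRAM = 1
DEFAULT_MAX_NGRAM = 7

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_SENT_BOUNDARY_RE = re.compile(r"[.?!;]\s")


@dataclass
class TokenizedDocument:
    """Lowercased tokens per sentence with 0-based half-open char offsets."""

    doc_id: str
    sentences: list[list[str]]
    char_offsets: list[list[tuple[int, int]]]


@dataclass(frozen=True)
class Candidate:
    """A scored token span: (first, last) inclusive token indices in one sentence."""

    sentence_index: int
    span: tuple[int, int]
    concept: str
    score: float

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


@dataclass(frozen=True)
class Annotation:
    """A surviving mention: character span in the original text plus concept."""

    doc_id: str
    start: int
    end: int
    text: str
    concept: str
    score: float


def tokenize(text: str, doc_id: str = "doc") -> TokenizedDocument:
    """Lowercase, split sentences on [.?!;] followed by whitespace, and take
    maximal alphanumeric runs as tokens; offsets index the original string.
    Sentences without any token are dropped (empty text yields none)."""
    boundaries = [m.start() + 1 for m in _SENT_BOUNDARY_RE.finditer(text)]
    starts = [0] + boundaries
    ends = boundaries + [len(text)]
    sentences: list[list[str]] = []
    offsets: list[list[tuple[int, int]]] = []
    for s, e in zip(starts, ends):
        toks, offs = [], []
        for m in _TOKEN_RE.finditer(text, s, e):
            toks.append(m.group(0).lower())
            offs.append((m.start(), m.end()))
        if toks:
            sentences.append(toks)
            offsets.append(offs)
    return TokenizedDocument(doc_id=doc_id, sentences=sentences, char_offsets=offsets)


def tokenize_phrase(phrase: str) -> list[str]:
    """Tokenize an isolated phrase (no sentence splitting)."""
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(phrase)]


def extract_ngrams(
    doc: TokenizedDocument,
    min_len: int = DEFAULT_MIN_NGRAM,
    max_len: int = DEFAULT_MAX_NGRAM,
) -> list[tuple[int, int, int]]:
    """All (sentence_index, first, last) spans of min_len..max_len tokens.
    Spans never cross sentence boundaries."""
    if not (1 <= min_len <= max_len):
        raise ValueError("need 1 <= min_len <= max_len")
    spans = []
    for si, toks in enumerate(doc.sentences):
        for first in range(len(toks)):
            for last in range(first + min_len - 1, min(first + max_len, len(toks))):
                spans.append((si, first, last))
    return spans


def _as_models(model_or_ensemble) -> list[NeuralDictionary]:
    if isinstance(model_or_ensemble, NeuralDictionary):
        return [model_or_ensemble]
    models = list(model_or_ensemble)
    if not models:
        raise ValueError("empty ensemble")
    return models


def ensemble_distribution(model_or_ensemble, phrase: list[str]) -> ScoreDistribution:
    """Ensemble-averaged score distribution for one tokenized phrase."""
    models = _as_models(model_or_ensemble)
    probs = np.mean([batch_score(m, [phrase])[0] for m in models], axis=0)
    return ScoreDistribution(ids=models[0].concept_ids, probs=probs, has_none=models[0].has_none)


def score_spans(model_or_ensemble, doc: TokenizedDocument, spans) -> list[Candidate]:
    """Best non-NONE concept and its ensemble-averaged probability per span.

    Spans whose overall best class is NONE still yield their best non-NONE
    concept here; the threshold filter is what discards them.
    """
    if not spans:
        return []
    models = _as_models(model_or_ensemble)
    phrases = [doc.sentences[si][first : last + 1] for si, first, last in spans]
    probs = np.mean([batch_score(m, phrases) for m in models], axis=0)
    ids = models[0].concept_ids
    concept_probs = probs[:, : len(ids)]
    order = np.argsort(np.array(ids))  # lexicographic tie-break on equal scores
    sorted_probs = concept_probs[:, order]
    best_sorted = sorted_probs.argmax(axis=1)  # first (smallest id) argmax wins
    candidates = []
    for row, (si, first, last) in enumerate(spans):
        j = order[best_sorted[row]]
        candidates.append(
            Candidate(
                sentence_index=si,
                span=(first, last),
                concept=ids[j],
                score=float(concept_probs[row, j]),
            )
        )
    return candidates


def filter_by_threshold(candidates: list[Candidate], threshold: float) -> list[Candidate]:
    """Keep candidates whose softmax probability is at least the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [c for c in candidates if c.score >= threshold]


def _overlaps(a: Candidate, b: Candidate) -> bool:
    return (
        a.sentence_index == b.sentence_index
        and a.span[0] <= b.span[1]
        and b.span[0] <= a.span[1]
    )


def _sort_key(c: Candidate):
    return (c.sentence_index, c.span[0], c.span[1], c.concept)


def _loser(a: Candidate, b: Candidate) -> Candidate:
    """Which of an overlapping pair is dropped.

    Same concept -> the longer span; different concepts -> the shorter span.
    Equal lengths -> the lower score, then the lexicographically larger
    concept id, then the later span in document order.
    """
    if a.length != b.length:
        longer, shorter = (a, b) if a.length > b.length else (b, a)
        return longer if a.concept == b.concept else shorter
    if a.score != b.score:
        return a if a.score < b.score else b
    if a.concept != b.concept:
        return a if a.concept > b.concept else b
    return max(a, b, key=_sort_key)


def resolve_overlaps(candidates: list[Candidate], doc: TokenizedDocument) -> list[Annotation]:
    """Greedy fixed point of the pairwise overlap rules, then char mapping.

    Candidates are processed in a deterministic order (sentence, start, end,
    concept id); each step removes one member of the first overlapping pair,
    so the procedure terminates with a pairwise non-overlapping set that does
    not depend on the input order.
    """
    alive = sorted(set(candidates), key=_sort_key)
    changed = True
    while changed:
        changed = False
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                if _overlaps(alive[i], alive[j]):
                    alive.remove(_loser(alive[i], alive[j]))
                    changed = True
                    break
            if changed:
                break
    annotations = []
    for c in alive:
        offs = doc.char_offsets[c.sentence_index]
        start = offs[c.span[0]][0]
        end = offs[c.span[1]][1]
        annotations.append(
            Annotation(
                doc_id=doc.doc_id,
                start=start,
                end=end,
                text=" ".join(doc.sentences[c.sentence_index][c.span[0] : c.span[1] + 1]),
                concept=c.concept,
                score=c.score,
            )
        )
    return annotations


def annotate_text(
    model_or_ensemble,
    text: str,
    threshold: float,
    doc_id: str = "doc",
    min_len: int = DEFAULT_MIN_NGRAM,
    max_len: int = DEFAULT_MAX_NGRAM,
) -> list[Annotation]:
    """tokenize -> n-grams -> score -> threshold -> overlap resolution."""
    doc = tokenize(text, doc_id=doc_id)
    spans = extract_ngrams(doc, min_len=min_len, max_len=max_len)
    candidates = score_spans(model_or_ensemble, doc, spans)
    survivors = filter_by_threshold(candidates, threshold)
    return sorted(resolve_overlaps(survivors, doc), key=lambda a: (a.start, a.end))
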