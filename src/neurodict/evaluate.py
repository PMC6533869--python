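"""Document-level evaluation: micro/macro/ancestor-extended metrics, R@k,
and validation-set threshold selection.

Evaluation is at the document-concept-set level: for document d, R_d is the
set of reported concepts and L_d the set of label (gold) concepts.  Micro
metrics pool counts over documents; macro metrics average per-document
precision and recall, assigning a per-document precision of 1.0 when R_d is
empty and a recall of 1.0 when L_d is empty.  The extended variants first
replace each set by its ancestor closure E(S), crediting answers that are
taxonomically close; the Jaccard index is the pooled intersection-over-union
of the extended sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import extract_ngrams, filter_by_threshold, resolve_overlaps, score_spans, tokenize
from .model import top_k
from .ontology import Ontology, ancestors

__all__ = [
    "DocumentEval",
    "EvalReport",
    "f1_score",
    "micro_metrics",
    "macro_metrics",
    "extended_metrics",
    "evaluate_documents",
    "recall_at_k",
    "select_threshold",
    "DEFAULT_THRESHOLD_GRID",
]

#: 0.05 steps over [0.5, 0.95]; brackets the published per-variant thresholds.
DEFAULT_THRESHOLD_GRID = [round(0.5 + 0.05 * i, 2) for i in range(10)]


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class DocumentEval:
    doc_id: str
    reported: set[str]
    labels: set[str]


@dataclass
class EvalReport:
    micro_p: float
    micro_r: float
    micro_f1: float
    macro_p: float
    macro_r: float
    macro_f1: float
    ext_p: float
    ext_r: float
    ext_f1: float
    jaccard: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _ratio(num: int, den: int) -> float:
    # empty-denominator convention: a vacuous component counts as perfect
    return num / den if den else 1.0


def micro_metrics(docs: list[DocumentEval]) -> tuple[float, float, float]:
    if not docs:
        raise ValueError("need at least one document")
    tp = sum(len(d.reported & d.labels) for d in docs)
    p = _ratio(tp, sum(len(d.reported) for d in docs))
    r = _ratio(tp, sum(len(d.labels) for d in docs))
    return p, r, f1_score(p, r)


def macro_metrics(docs: list[DocumentEval]) -> tuple[float, float, float]:
    if not docs:
        raise ValueError("need at least one document")
    p = sum(_ratio(len(d.reported & d.labels), len(d.reported)) for d in docs) / len(docs)
    r = sum(_ratio(len(d.reported & d.labels), len(d.labels)) for d in docs) / len(docs)
    return p, r, f1_score(p, r)


def _closure(concept_set: set[str], ontology: Ontology) -> set[str]:
    out: set[str] = set()
    for cid in concept_set:
        out |= ancestors(ontology, cid)
    return out


def extended_metrics(
    docs: list[DocumentEval], ontology: Ontology
) -> tuple[float, float, float, float]:
    """Micro-pooled P/R/F1 and Jaccard over ancestor-extended sets."""
    if not docs:
        raise ValueError("need at least one document")
    tp = rep = lab = inter = union = 0
    for d in docs:
        er = _closure(d.reported, ontology)
        el = _closure(d.labels, ontology)
        tp += len(er & el)
        rep += len(er)
        lab += len(el)
        inter += len(er & el)
        union += len(er | el)
    p = _ratio(tp, rep)
    r = _ratio(tp, lab)
    return p, r, f1_score(p, r), _ratio(inter, union)


def evaluate_documents(docs: list[DocumentEval], ontology: Ontology) -> EvalReport:
    mp, mr, mf = micro_metrics(docs)
    map_, mar, maf = macro_metrics(docs)
    ep, er, ef, jac = extended_metrics(docs, ontology)
    return EvalReport(mp, mr, mf, map_, mar, maf, ep, er, ef, jac)


def recall_at_k(model_or_ensemble, phrases: list[tuple[list[str], str]], k: int) -> float:
    """Fraction of (tokens, gold concept) pairs whose gold concept is in the
    ensemble's top k."""
    from .annotate import ensemble_distribution, _as_models

    if not phrases:
        raise ValueError("phrases must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    known = set(_as_models(model_or_ensemble)[0].concept_ids)
    hits = 0
    for tokens, gold in phrases:
        if gold not in known:
            raise KeyError(f"gold concept {gold!r} not in model concept set")
        dist = ensemble_distribution(model_or_ensemble, list(tokens))
        if gold in {cid for cid, _ in top_k(dist, k)}:
            hits += 1
    return hits / len(phrases)


def select_threshold(
    model_or_ensemble,
    validation_docs: list[tuple[str, str]],
    gold: dict[str, set[str]],
    grid: list[float] = DEFAULT_THRESHOLD_GRID,
    min_len: int = 1,
    max_len: int = 7,
) -> float:
    """Grid value maximizing micro F1 of the annotator on the validation set;
    ties go to the largest threshold (favoring precision).

    Spans are scored once; only the filter and overlap resolution are redone
    per grid value.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if any(not 0.0 <= t <= 1.0 for t in grid):
        raise ValueError("grid values must lie in [0, 1]")
    scored = []
    for doc_id, text in validation_docs:
        doc = tokenize(text, doc_id=doc_id)
        spans = extract_ngrams(doc, min_len=min_len, max_len=max_len)
        scored.append((doc, score_spans(model_or_ensemble, doc, spans)))
    best_t, best_f1 = None, -1.0
    for t in sorted(grid):
        docs = []
        for doc, candidates in scored:
            annos = resolve_overlaps(filter_by_threshold(candidates, t), doc)
            docs.append(
                DocumentEval(
                    doc_id=doc.doc_id,
                    reported={a.concept for a in annos},
                    labels=set(gold.get(doc.doc_id, set())),
                )
            )
        _, _, f1 = micro_metrics(docs)
        if f1 >= best_f1:  # >= so the largest tied threshold wins
            best_t, best_f1 = t, f1
    return best_t
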