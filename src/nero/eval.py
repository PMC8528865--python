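"""Entity-level NER evaluation protocol.

BIO encoding over whitespace/punctuation tokens, document-level k-fold
splits, exact span+label precision/recall/F1 per class and micro-averaged,
and a dictionary baseline tagger (longest left-to-right surface match with
majority labels) so the full train/predict/score loop runs without any
external model.

Conventions: nested entities are flattened to the outermost mention before
encoding or scoring (inner retention behind a flag); a precision or recall
with an empty denominator is 0 and the report flags that it happened; entity
boundaries that fall inside a token snap outward to token edges.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._text import tokenize
from .io import AnnotatedDocument, Corpus, EntityMention

__all__ = [
    "BIOSequence",
    "EvalReport",
    "to_bio",
    "decode_bio",
    "to_conll",
    "entity_prf",
    "kfold_split",
    "DictionaryTagger",
    "cross_validate_tagger",
]


@dataclass
class BIOSequence:
    tokens: list[str]
    spans: list[tuple[int, int]]
    tags: list[str]

    def __post_init__(self) -> None:
        if not (len(self.tokens) == len(self.spans) == len(self.tags)):
            raise ValueError("tokens, spans and tags must align")
        prev = "O"
        for t in self.tags:
            if t.startswith("I-"):
                cls = t[2:]
                if prev == "O" or prev[2:] != cls:
                    raise ValueError(f"I-{cls} cannot follow {prev}")
            prev = t


@dataclass
class EvalReport:
    """Per-class and micro-averaged entity-level scores."""

    per_class: dict[str, dict[str, float]]
    micro: dict[str, float]
    n_folds: int = 1
    zero_division_hit: bool = False


def flatten_outermost(entities: list[EntityMention]) -> list[EntityMention]:
    """Drop mentions strictly contained in another mention (nesting)."""
    kept: list[EntityMention] = []
    ents = sorted(entities, key=lambda e: (e.start, -(e.end - e.start), e.id))
    for e in ents:
        if any(
            (o.start <= e.start and e.end <= o.end and (o.start, o.end) != (e.start, e.end))
            for o in ents
        ):
            continue
        kept.append(e)
    # among exact-duplicate spans keep the first by id order
    seen: set[tuple[int, int]] = set()
    out = []
    for e in kept:
        if e.span in seen:
            continue
        seen.add(e.span)
        out.append(e)
    return out


def to_bio(doc: AnnotatedDocument, keep_inner: bool = False) -> BIOSequence:
    """Encode a document as token-level BIO tags.

    Nested mentions are flattened to the outermost unless ``keep_inner`` (in
    which case inner mentions still lose to the outer one at shared tokens —
    BIO is inherently flat — but are used where tokens are free). Boundaries
    inside a token snap outward.
    """
    toks = tokenize(doc.text)
    tags = ["O"] * len(toks)
    entities = doc.entities if keep_inner else flatten_outermost(doc.entities)
    for e in sorted(entities, key=lambda e: (e.start, e.end)):
        covered = [
            i
            for i, (_, s, t) in enumerate(toks)
            if s < e.end and e.start < t  # snap outward: any overlap counts
        ]
        if not covered or any(tags[i] != "O" for i in covered):
            continue
        tags[covered[0]] = f"B-{e.label}"
        for i in covered[1:]:
            tags[i] = f"I-{e.label}"
    return BIOSequence(
        tokens=[t for t, _, _ in toks],
        spans=[(s, t) for _, s, t in toks],
        tags=tags,
    )


def decode_bio(seq: BIOSequence) -> list[tuple[int, int, str]]:
    """(start, end, label) spans encoded by the tags."""
    out = []
    cur: tuple[int, int, str] | None = None
    for (start, end), tag in zip(seq.spans, seq.tags):
        if tag.startswith("B-"):
            if cur:
                out.append(cur)
            cur = (start, end, tag[2:])
        elif tag.startswith("I-") and cur:
            cur = (cur[0], end, cur[2])
        else:
            if cur:
                out.append(cur)
            cur = None
    if cur:
        out.append(cur)
    return out


def to_conll(doc: AnnotatedDocument, keep_inner: bool = False) -> str:
    """CoNLL-2003-style two-column (token, tag) export."""
    seq = to_bio(doc, keep_inner)
    return "\n".join(f"{t}\t{tag}" for t, tag in zip(seq.tokens, seq.tags)) + "\n"


# ---------------------------------------------------------------------------
# scoring


def _prf(tp: int, fp: int, fn: int) -> tuple[dict[str, float], bool]:
    zero_hit = (tp + fp == 0) or (tp + fn == 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return (
        {"tp": tp, "fp": fp, "fn": fn, "precision": p, "recall": r, "f1": f1},
        zero_hit,
    )


def entity_prf(
    gold: Corpus, pred: Corpus, flatten: bool = True, n_folds: int = 1
) -> EvalReport:
    """Exact span+label matching between two corpora over the same documents.

    Per-class true/false positives and negatives are multiset matches of
    (start, end, label) within each document; micro scores pool counts over
    classes.
    """
    if set(gold.documents) != set(pred.documents):
        raise ValueError("gold and predicted corpora cover different documents")
    tp: Counter[str] = Counter()
    fp: Counter[str] = Counter()
    fn: Counter[str] = Counter()
    for doc_id, gdoc in gold.documents.items():
        pdoc = pred.documents[doc_id]
        g_ents = flatten_outermost(gdoc.entities) if flatten else gdoc.entities
        p_ents = flatten_outermost(pdoc.entities) if flatten else pdoc.entities
        g_keys = Counter((e.start, e.end, e.label) for e in g_ents)
        p_keys = Counter((e.start, e.end, e.label) for e in p_ents)
        matched = g_keys & p_keys
        for (_, _, label), c in matched.items():
            tp[label] += c
        for (_, _, label), c in (p_keys - g_keys).items():
            fp[label] += c
        for (_, _, label), c in (g_keys - p_keys).items():
            fn[label] += c
    classes = sorted(set(tp) | set(fp) | set(fn))
    per_class = {}
    zero_hit = False
    for cls in classes:
        scores, hit = _prf(tp[cls], fp[cls], fn[cls])
        per_class[cls] = scores
        zero_hit |= hit
    micro, hit = _prf(sum(tp.values()), sum(fp.values()), sum(fn.values()))
    zero_hit |= hit
    return EvalReport(
        per_class=per_class, micro=micro, n_folds=n_folds, zero_division_hit=zero_hit
    )


def kfold_split(
    corpus: Corpus, k: int = 10, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Document-level k-fold partition, fold sizes within +/- 1.

    Fold assignment is a seeded shuffle of the sorted document ids, so splits
    are stable across runs and platforms.
    """
    ids = sorted(corpus.documents)
    if k < 2 or k > len(ids):
        raise ValueError(f"k={k} invalid for {len(ids)} documents")
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    folds = [list(f) for f in np.array_split(shuffled, k)]
    out = []
    for i in range(k):
        test = folds[i]
        train = [d for j, f in enumerate(folds) if j != i for d in f]
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# dictionary baseline


class DictionaryTagger(BaseEstimator):
    """Surface-memorizing baseline: longest case-sensitive match, left to
    right, each surface mapped to its most frequent training label (ties to
    the lexicographically smallest label).

    Attributes after ``fit``: ``lexicon_`` (surface -> label),
    ``max_len_`` (longest memorized surface).
    """

    def fit(self, corpus: Corpus, y=None):
        votes: dict[str, Counter[str]] = defaultdict(Counter)
        for doc in corpus.documents.values():
            for e in doc.entities:
                votes[e.text][e.label] += 1
        self.lexicon_ = {
            surface: min(c.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            for surface, c in votes.items()
        }
        self.max_len_ = max((len(s) for s in self.lexicon_), default=0)
        return self

    def predict_document(self, doc: AnnotatedDocument) -> list[EntityMention]:
        text = doc.text
        out: list[EntityMention] = []
        i = 0
        tid = 0
        n = len(text)
        while i < n:
            hit = None
            limit = min(self.max_len_, n - i)
            for L in range(limit, 0, -1):
                surface = text[i : i + L]
                if surface in self.lexicon_:
                    hit = (surface, self.lexicon_[surface])
                    break
            if hit:
                surface, label = hit
                tid += 1
                out.append(
                    EntityMention(
                        f"T{tid}", i, i + len(surface), surface, label, "tagger"
                    )
                )
                i += len(surface)
            else:
                i += 1
        return out

    def predict(self, corpus: Corpus) -> Corpus:
        pred = Corpus()
        for doc_id in sorted(corpus.documents):
            doc = corpus.documents[doc_id]
            pred.add(
                AnnotatedDocument(
                    doc_id, doc.text, self.predict_document(doc), []
                )
            )
        return pred


def cross_validate_tagger(
    corpus: Corpus, k: int = 10, seed: int = 0
) -> EvalReport:
    """k-fold cross-validated dictionary-tagger scores (pooled over folds)."""
    folds = kfold_split(corpus, k, seed)
    gold_all, pred_all = Corpus(), Corpus()
    for train_ids, test_ids in folds:
        train = Corpus({d: corpus.documents[d] for d in train_ids})
        test = Corpus({d: corpus.documents[d] for d in test_ids})
        tagger = DictionaryTagger().fit(train)
        pred = tagger.predict(test)
        for d in test_ids:
            gold_all.add(test.documents[d])
            pred_all.add(pred.documents[d])
    report = entity_prf(gold_all, pred_all)
    report.n_folds = k
    return report
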