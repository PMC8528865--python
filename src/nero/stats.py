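"""Corpus composition statistics.

Everything reported about an annotated corpus's make-up lives here: class and
action frequency tables with shares and top-k mass, the fraction of mentions
annotated at the most specific ontology level, the fraction carrying an
ambiguity (union-class) label, rule-based action normalization (``binds``,
``binding`` -> ``bind``; ``does not bind`` -> ``do not bind``), and
inter-annotator agreement on doubly annotated documents (span-level F1, exact
and relaxed, plus token-level Cohen's kappa).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

from ._text import tokenize
from .io import Corpus, doubly_annotated_pairs
from .ontology import Ontology

__all__ = [
    "FrequencyTable",
    "AgreementReport",
    "entity_frequencies",
    "share",
    "top_k_share",
    "specificity_fraction",
    "ambiguity_fraction",
    "normalize_action",
    "action_frequencies",
    "inter_annotator_agreement",
]


@dataclass
class FrequencyTable:
    """Item counts with a deterministic ranking.

    Ranking is by count descending, ties broken lexicographically, over items
    with positive count only.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def ranking(self) -> list[str]:
        return sorted(
            (i for i, c in self.counts.items() if c > 0),
            key=lambda i: (-self.counts[i], i),
        )

    def ranked_counts(self) -> list[int]:
        return [self.counts[i] for i in self.ranking]

    def share(self, item: str) -> float:
        if self.total == 0:
            raise ValueError("share undefined on an empty table")
        return self.counts.get(item, 0) / self.total

    def top_k_share(self, k: int) -> float:
        if k < 1:
            raise ValueError("k must be >= 1")
        if self.total == 0:
            raise ValueError("top_k_share undefined on an empty table")
        ranked = self.ranking
        return sum(self.counts[i] for i in ranked[:k]) / self.total

    def to_rows(self) -> list[tuple[str, int, float, int]]:
        """(item, count, share, rank) rows in rank order."""
        total = self.total
        return [
            (item, self.counts[item], self.counts[item] / total, r)
            for r, item in enumerate(self.ranking, start=1)
        ]


def share(ft: FrequencyTable, item: str) -> float:
    return ft.share(item)


def top_k_share(ft: FrequencyTable, k: int) -> float:
    return ft.top_k_share(k)


# ---------------------------------------------------------------------------
# entity-side statistics


def entity_frequencies(
    corpus: Corpus, onto: Ontology, rollup: bool = False
) -> FrequencyTable:
    """Class mention counts.

    ``rollup=False`` (default) counts labels exactly as annotated — the mode
    in which per-class shares are usually reported. ``rollup=True`` credits
    each mention to every superclass as well (union classes included), so the
    root's count equals the total number of mentions.
    """
    counts: Counter[str] = Counter()
    for doc in corpus.documents.values():
        for e in doc.entities:
            if e.label not in onto:
                raise KeyError(
                    f"unknown class {e.label!r} in document {doc.id!r}; "
                    "run validate_corpus"
                )
            if rollup:
                counts.update(onto.ancestors(e.label))
            else:
                counts[e.label] += 1
    return FrequencyTable(dict(counts))


def specificity_fraction(
    corpus: Corpus, onto: Ontology, *, unions_specific: bool = False
) -> float:
    """Fraction of mentions annotated at the most specific ontology level.

    A label is "most specific" when it has no subclasses and is not an
    ambiguity class; ``unions_specific=True`` flips the latter for
    sensitivity analysis.
    """
    n = total = 0
    for doc in corpus.documents.values():
        for e in doc.entities:
            total += 1
            if onto.is_most_specific(e.label, unions_specific=unions_specific):
                n += 1
    if total == 0:
        raise ValueError("specificity undefined on an empty corpus")
    return n / total


def ambiguity_fraction(corpus: Corpus, onto: Ontology) -> float:
    """Fraction of mentions labeled with union (ambiguity) classes."""
    n = total = 0
    for doc in corpus.documents.values():
        for e in doc.entities:
            total += 1
            if e.label not in onto:
                raise KeyError(f"unknown class {e.label!r}")
            if onto.classes[e.label].is_union:
                n += 1
    if total == 0:
        raise ValueError("ambiguity undefined on an empty corpus")
    return n / total


# ---------------------------------------------------------------------------
# action normalization

NEGATION_CUES: tuple[str, ...] = ("do not", "does not", "did not", "not", "no")

_IRREGULAR: dict[str, str] | None = None


def _irregular_table() -> dict[str, str]:
    global _IRREGULAR
    if _IRREGULAR is None:
        table: dict[str, str] = {}
        text = (resources.files("nero.data") / "verb_lemmas.tsv").read_text(
            encoding="utf-8"
        )
        for i, line in enumerate(text.splitlines()):
            if i == 0 or not line.strip():
                continue
            form, lemma = line.split("\t")
            table[form.strip()] = lemma.strip()
        _IRREGULAR = table
    return _IRREGULAR


def _strip_suffix(word: str) -> str:
    """Deterministic suffix rules for regular English verb inflection."""
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith("es") and len(word) > 4 and (
        word[:-2].endswith(("s", "x", "z", "ch", "sh", "o"))
    ):
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")) and len(word) > 3:
        return word[:-1]
    for suffix in ("ing", "ed"):
        if word.endswith(suffix) and len(word) - len(suffix) >= 3:
            stem = word[: -len(suffix)]
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] in "bdgmnprt":
                stem = stem[:-1]
            return stem
    return word


def lemmatize_verb(word: str) -> str:
    table = _irregular_table()
    if word in table:
        return table[word]
    return _strip_suffix(word)


def normalize_action(action_text: str, cues: tuple[str, ...] = NEGATION_CUES) -> str:
    """Canonical form of an action term.

    Case-folds, canonicalizes a leading negation cue to ``do not``, and
    lemmatizes the head verb by table + suffix rules. Idempotent; unknown
    forms pass through case-folded.

    >>> normalize_action("does not Bind")
    'do not bind'
    """
    if not action_text or not action_text.strip():
        raise ValueError("empty action text")
    text = " ".join(action_text.casefold().split())
    negated = False
    for cue in sorted(cues, key=len, reverse=True):
        if text == cue:
            break
        if text.startswith(cue + " "):
            negated = True
            text = text[len(cue) + 1 :]
            break
    tokens = text.split()
    tokens[0] = lemmatize_verb(tokens[0])
    norm = " ".join(tokens)
    return f"do not {norm}" if negated else norm


def action_frequencies(corpus: Corpus, normalized: bool = True) -> FrequencyTable:
    """Event action-term counts, raw or normalized; total == event count."""
    counts: Counter[str] = Counter()
    for doc in corpus.documents.values():
        for ev in doc.events:
            term = ev.action_text
            if ev.polarity == "negated" and not any(
                term.casefold().startswith(c) for c in NEGATION_CUES
            ):
                term = f"do not {term}"
            counts[normalize_action(term) if normalized else term] += 1
    return FrequencyTable(dict(counts))


# ---------------------------------------------------------------------------
# inter-annotator agreement


@dataclass
class AgreementReport:
    """Pairwise annotation agreement on doubly annotated documents.

    ``per_pair`` maps (doc id, (annotator a, annotator b)) to exact and
    relaxed span precision/recall/F1 (layer a as reference); ``pooled_f1`` is
    the micro-averaged exact F1 over all pairs; ``kappa_token`` is Cohen's
    kappa over whitespace/punctuation tokens labeled with the covering
    entity's class or ``O``.
    """

    per_pair: dict[tuple[str, tuple[str, str]], dict[str, dict[str, float]]]
    pooled_f1: float
    kappa_token: float


def _prf(tp: int, n_gold: int, n_pred: int) -> dict[str, float]:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return {"precision": p, "recall": r, "f1": f1}


def _relaxed_tp(gold: list, pred: list) -> int:
    """Greedy one-to-one matching on label equality + span overlap."""
    used = [False] * len(gold)
    tp = 0
    for e in sorted(pred, key=lambda e: (e.start, e.end)):
        for i, g in enumerate(gold):
            if used[i] or g.label != e.label:
                continue
            if g.start < e.end and e.start < g.end:
                used[i] = True
                tp += 1
                break
    return tp


def _token_labels(doc, entities) -> list[str]:
    ents = sorted(entities, key=lambda e: (e.start, e.end))
    labels = []
    for _, start, end in tokenize(doc.text):
        lab = "O"
        for e in ents:
            if e.start < end and start < e.end:
                lab = e.label
                break
        labels.append(lab)
    return labels


def inter_annotator_agreement(corpus: Corpus) -> AgreementReport:
    pairs = doubly_annotated_pairs(corpus)
    if not pairs:
        raise ValueError("no doubly annotated documents")
    per_pair: dict = {}
    pooled_tp = pooled_gold = pooled_pred = 0
    tok_a: list[str] = []
    tok_b: list[str] = []
    for doc_id, a, b in pairs:
        doc = corpus.documents[doc_id]
        gold = [e for e in doc.entities if e.annotator == a]
        pred = [e for e in doc.entities if e.annotator == b]
        gold_keys = Counter((e.start, e.end, e.label) for e in gold)
        pred_keys = Counter((e.start, e.end, e.label) for e in pred)
        tp_exact = sum((gold_keys & pred_keys).values())
        per_pair[(doc_id, (a, b))] = {
            "exact": _prf(tp_exact, len(gold), len(pred)),
            "relaxed": _prf(_relaxed_tp(gold, pred), len(gold), len(pred)),
        }
        pooled_tp += tp_exact
        pooled_gold += len(gold)
        pooled_pred += len(pred)
        tok_a.extend(_token_labels(doc, gold))
        tok_b.extend(_token_labels(doc, pred))
    pooled = _prf(pooled_tp, pooled_gold, pooled_pred)
    return AgreementReport(
        per_pair=per_pair,
        pooled_f1=pooled["f1"],
        kappa_token=_cohen_kappa(tok_a, tok_b),
    )


def _cohen_kappa(a: list[str], b: list[str]) -> float:
    # direct computation, so perfect agreement on a single class gives 1.0
    # rather than 0/0
    n = len(a)
    if n == 0:
        raise ValueError("no tokens")
    po = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    pe = sum(ca[k] * cb.get(k, 0) for k in ca) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)
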