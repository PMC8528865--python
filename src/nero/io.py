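"""Standoff-annotated corpus model and brat-dialect I/O.

A document is raw text plus entity mentions (character spans labeled with an
ontology class) and event mentions (an action trigger span connecting one or
more entities, optionally negated). Annotations are standoff: stored apart
from the text and addressed by 0-based half-open code-point offsets.

On disk a document is a ``.txt`` file plus one ``.ann`` file per annotator in
the brat dialect::

    T1\tGeneOrProtein 0 3\tp53
    T2\tAction 4 9\tbinds
    E1\tAction:T2 Arg1:T1 Arg2:T3
    A1\tNegated E1

A single-file TSV fallback reader (columns doc_id, start, end, text, label,
annotator) is provided for deposits that use a flat schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import ALIASES, Ontology

__all__ = [
    "EntityMention",
    "EventMention",
    "AnnotatedDocument",
    "Corpus",
    "Violation",
    "StandoffError",
    "read_standoff",
    "write_standoff",
    "read_tsv_corpus",
    "save_corpus",
    "load_corpus",
    "corpus_to_json",
    "validate_corpus",
    "doubly_annotated_pairs",
]

TRIGGER_LABEL = "Action"


class StandoffError(ValueError):
    """Malformed or inconsistent standoff annotation file."""


@dataclass(frozen=True)
class EntityMention:
    id: str
    start: int
    end: int
    text: str
    label: str
    annotator: str = "A"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class EventMention:
    id: str
    trigger_start: int
    trigger_end: int
    action_text: str
    arguments: tuple[tuple[str, str], ...]  # (role, entity id)
    polarity: str = "asserted"  # or "negated"
    annotator: str = "A"

    @property
    def trigger_span(self) -> tuple[int, int]:
        return (self.trigger_start, self.trigger_end)


@dataclass
class AnnotatedDocument:
    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    events: list[EventMention] = field(default_factory=list)

    def annotators(self) -> set[str]:
        return {e.annotator for e in self.entities} | {
            ev.annotator for ev in self.events
        }

    def layer(self, annotator: str) -> "AnnotatedDocument":
        """The single-annotator view of this document."""
        return AnnotatedDocument(
            id=self.id,
            text=self.text,
            entities=[e for e in self.entities if e.annotator == annotator],
            events=[e for e in self.events if e.annotator == annotator],
        )


@dataclass
class Corpus:
    documents: dict[str, AnnotatedDocument] = field(default_factory=dict)

    @property
    def annotators(self) -> set[str]:
        out: set[str] = set()
        for d in self.documents.values():
            out |= d.annotators()
        return out

    def n_entities(self) -> int:
        return sum(len(d.entities) for d in self.documents.values())

    def n_events(self) -> int:
        return sum(len(d.events) for d in self.documents.values())

    def add(self, doc: AnnotatedDocument) -> None:
        if doc.id in self.documents:
            existing = self.documents[doc.id]
            if existing.text != doc.text:
                raise StandoffError(
                    f"document {doc.id!r}: text differs between layers"
                )
            existing.entities.extend(doc.entities)
            existing.events.extend(doc.events)
        else:
            self.documents[doc.id] = doc


@dataclass(frozen=True)
class Violation:
    doc_id: str
    annotation_id: str | None
    message: str


# ---------------------------------------------------------------------------
# brat standoff


def read_standoff(
    text_file: str | Path,
    annotation_file: str | Path,
    annotator: str = "A",
    doc_id: str | None = None,
) -> AnnotatedDocument:
    """Read one ``.txt``/``.ann`` pair into a document.

    Entity ``T`` lines are cross-checked against the text: the quoted surface
    must equal the substring at the span, else a :class:`StandoffError` names
    the offending annotation id.
    """
    text_file, annotation_file = Path(text_file), Path(annotation_file)
    text = text_file.read_text(encoding="utf-8")
    if doc_id is None:
        doc_id = text_file.stem
    entities: list[EntityMention] = []
    events: list[EventMention] = []
    triggers: dict[str, tuple[int, int, str]] = {}
    negated: set[str] = set()
    raw_events: list[tuple[str, str, list[tuple[str, str]], int]] = []

    for lineno, line in enumerate(
        annotation_file.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        try:
            tag, rest = line.split("\t", 1)
        except ValueError:
            raise StandoffError(f"{annotation_file}:{lineno}: malformed line")
        if tag.startswith("T"):
            try:
                head, surface = rest.split("\t", 1)
                label, start_s, end_s = head.split(" ")
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise StandoffError(
                    f"{annotation_file}:{lineno}: malformed T line"
                ) from None
            label = ALIASES.get(label, label)
            if not (0 <= start < end <= len(text)):
                raise StandoffError(
                    f"{annotation_file}:{lineno}: span ({start},{end}) out of "
                    f"range for annotation {tag}"
                )
            if text[start:end] != surface:
                raise StandoffError(
                    f"annotation {tag}: surface {surface!r} != document "
                    f"substring {text[start:end]!r}"
                )
            if label == TRIGGER_LABEL:
                triggers[tag] = (start, end, surface)
            else:
                entities.append(
                    EntityMention(tag, start, end, surface, label, annotator)
                )
        elif tag.startswith("E"):
            parts = rest.split()
            if not parts or ":" not in parts[0]:
                raise StandoffError(f"{annotation_file}:{lineno}: malformed E line")
            _, trig_id = parts[0].split(":", 1)
            args = []
            for p in parts[1:]:
                role, ent_id = p.split(":", 1)
                args.append((role, ent_id))
            raw_events.append((tag, trig_id, args, lineno))
        elif tag.startswith("A"):
            parts = rest.split()
            if len(parts) >= 2 and parts[0] == "Negated":
                negated.add(parts[1])
        # other line types (comments, normalizations) are ignored

    ent_ids = {e.id for e in entities}
    for ev_id, trig_id, args, lineno in raw_events:
        if trig_id not in triggers:
            raise StandoffError(
                f"{annotation_file}:{lineno}: event {ev_id} references "
                f"unknown trigger {trig_id}"
            )
        for role, ent_id in args:
            if ent_id not in ent_ids:
                raise StandoffError(
                    f"{annotation_file}:{lineno}: event {ev_id} argument "
                    f"{role} references unknown entity {ent_id}"
                )
        if not args:
            raise StandoffError(
                f"{annotation_file}:{lineno}: event {ev_id} has no arguments"
            )
        start, end, surface = triggers[trig_id]
        events.append(
            EventMention(
                id=ev_id,
                trigger_start=start,
                trigger_end=end,
                action_text=surface,
                arguments=tuple(args),
                polarity="negated" if ev_id in negated else "asserted",
                annotator=annotator,
            )
        )
    return AnnotatedDocument(doc_id, text, entities, events)


def write_standoff(
    doc: AnnotatedDocument,
    text_file: str | Path,
    annotation_file: str | Path,
    annotator: str | None = None,
) -> None:
    """Write one annotator layer (or a single-layer document) as .txt + .ann.

    Annotation ids are reassigned in span order so output is deterministic;
    a later :func:`read_standoff` reproduces an equal document up to ids.
    """
    layer = doc if annotator is None else doc.layer(annotator)
    Path(text_file).write_text(layer.text, encoding="utf-8")
    lines: list[str] = []
    t_counter = 0
    ent_tid: dict[str, str] = {}
    for e in sorted(layer.entities, key=lambda e: (e.start, e.end, e.label)):
        t_counter += 1
        tid = f"T{t_counter}"
        ent_tid[e.id] = tid
        lines.append(f"{tid}\t{e.label} {e.start} {e.end}\t{e.text}")
    e_counter = 0
    a_counter = 0
    for ev in sorted(layer.events, key=lambda v: (v.trigger_start, v.trigger_end)):
        t_counter += 1
        trig = f"T{t_counter}"
        lines.append(
            f"{trig}\t{TRIGGER_LABEL} {ev.trigger_start} {ev.trigger_end}\t"
            f"{ev.action_text}"
        )
        e_counter += 1
        eid = f"E{e_counter}"
        args = " ".join(f"{role}:{ent_tid[ent]}" for role, ent in ev.arguments)
        lines.append(f"{eid}\t{TRIGGER_LABEL}:{trig} {args}")
        if ev.polarity == "negated":
            a_counter += 1
            lines.append(f"A{a_counter}\tNegated {eid}")
    Path(annotation_file).write_text(
        "\n".join(lines) + ("\n" if lines else ""), encoding="utf-8"
    )


def save_corpus(corpus: Corpus, out_dir: str | Path) -> None:
    """Write every document as ``<id>.txt`` + ``<id>.<annotator>.ann``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for doc_id in sorted(corpus.documents):
        doc = corpus.documents[doc_id]
        (out / f"{doc_id}.txt").write_text(doc.text, encoding="utf-8")
        for ann in sorted(doc.annotators()) or ["A"]:
            write_standoff(
                doc, out / f"{doc_id}.txt", out / f"{doc_id}.{ann}.ann", ann
            )


def load_corpus(in_dir: str | Path) -> Corpus:
    """Read a directory written by :func:`save_corpus`."""
    corpus = Corpus()
    in_dir = Path(in_dir)
    for txt in sorted(in_dir.glob("*.txt")):
        doc_id = txt.stem
        for ann_file in sorted(in_dir.glob(f"{doc_id}.*.ann")):
            annotator = ann_file.name[len(doc_id) + 1 : -4]
            corpus.add(read_standoff(txt, ann_file, annotator, doc_id=doc_id))
    return corpus


def read_tsv_corpus(path: str | Path) -> Corpus:
    """Flat-TSV fallback: doc_id, start, end, text, label[, annotator].

    Only entities are representable in this schema. Document text is not part
    of the file; the document text is reconstructed as the maximal covered
    prefix is unknown, so mentions are attached to a text of spaces long
    enough to hold them, with surfaces written in place.
    """
    corpus = Corpus()
    rows: dict[str, list[tuple[int, int, str, str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if lineno == 1 and cols[0].strip().lower() in {"doc_id", "doc"}:
                continue
            if len(cols) < 5:
                raise StandoffError(f"{path}:{lineno}: expected >= 5 columns")
            doc_id, start_s, end_s, text, label = cols[:5]
            annotator = cols[5] if len(cols) > 5 and cols[5] else "A"
            rows.setdefault(doc_id, []).append(
                (int(start_s), int(end_s), text, ALIASES.get(label, label), annotator)
            )
    for doc_id, ents in rows.items():
        length = max(e[1] for e in ents)
        chars = [" "] * length
        for start, end, text, _, _ in ents:
            if end - start != len(text):
                raise StandoffError(
                    f"document {doc_id!r}: span ({start},{end}) does not match "
                    f"surface length of {text!r}"
                )
            chars[start:end] = list(text)
        doc = AnnotatedDocument(doc_id, "".join(chars))
        for i, (start, end, text, label, annotator) in enumerate(
            sorted(ents), start=1
        ):
            doc.entities.append(
                EntityMention(f"T{i}", start, end, text, label, annotator)
            )
        corpus.add(doc)
    return corpus


def corpus_to_json(corpus: Corpus) -> str:
    """Full document model as JSON (one object per document)."""
    docs = []
    for doc_id in sorted(corpus.documents):
        d = corpus.documents[doc_id]
        docs.append(
            {
                "id": d.id,
                "text": d.text,
                "entities": [
                    {
                        "id": e.id,
                        "start": e.start,
                        "end": e.end,
                        "text": e.text,
                        "label": e.label,
                        "annotator": e.annotator,
                    }
                    for e in d.entities
                ],
                "events": [
                    {
                        "id": v.id,
                        "trigger_start": v.trigger_start,
                        "trigger_end": v.trigger_end,
                        "action_text": v.action_text,
                        "polarity": v.polarity,
                        "arguments": [list(a) for a in v.arguments],
                        "annotator": v.annotator,
                    }
                    for v in d.events
                ],
            }
        )
    return json.dumps(docs, ensure_ascii=False, indent=1)


# ---------------------------------------------------------------------------
# validation


def validate_corpus(corpus: Corpus, onto: Ontology | None = None) -> list[Violation]:
    """All invariant violations in the corpus (empty list == valid).

    Checks spans against text, surface/substring equality, entity-id
    uniqueness per (document, annotator) layer, event argument resolution,
    and — when an ontology is given — label resolvability. Overlapping or
    nested entities are *not* violations.
    """
    out: list[Violation] = []
    for doc_id, doc in corpus.documents.items():
        seen_ids: set[tuple[str, str]] = set()
        ent_ids_by_annotator: dict[str, set[str]] = {}
        for e in doc.entities:
            key = (e.annotator, e.id)
            if key in seen_ids:
                out.append(Violation(doc_id, e.id, "duplicate entity id in layer"))
            seen_ids.add(key)
            ent_ids_by_annotator.setdefault(e.annotator, set()).add(e.id)
            if not (0 <= e.start < e.end <= len(doc.text)):
                out.append(
                    Violation(doc_id, e.id, f"span {e.span} out of range")
                )
                continue
            if doc.text[e.start : e.end] != e.text:
                out.append(
                    Violation(
                        doc_id,
                        e.id,
                        f"surface {e.text!r} != substring "
                        f"{doc.text[e.start:e.end]!r}",
                    )
                )
            if onto is not None and e.label not in onto:
                out.append(Violation(doc_id, e.id, f"unknown class {e.label!r}"))
        for ev in doc.events:
            if not (0 <= ev.trigger_start < ev.trigger_end <= len(doc.text)):
                out.append(
                    Violation(doc_id, ev.id, f"trigger span {ev.trigger_span} out of range")
                )
            if not ev.arguments:
                out.append(Violation(doc_id, ev.id, "event has no arguments"))
            layer_ids = ent_ids_by_annotator.get(ev.annotator, set())
            for role, ent_id in ev.arguments:
                if ent_id not in layer_ids:
                    out.append(
                        Violation(
                            doc_id, ev.id, f"argument {role} -> unknown entity {ent_id}"
                        )
                    )
            if ev.polarity not in {"asserted", "negated"}:
                out.append(
                    Violation(doc_id, ev.id, f"bad polarity {ev.polarity!r}")
                )
    return out


def doubly_annotated_pairs(corpus: Corpus) -> list[tuple[str, str, str]]:
    """All (doc id, annotator a, annotator b) unordered pairs, a < b."""
    pairs = []
    for doc_id in sorted(corpus.documents):
        anns = sorted(corpus.documents[doc_id].annotators())
        for i in range(len(anns)):
            for j in range(i + 1, len(anns)):
                pairs.append((doc_id, anns[i], anns[j]))
    return pairs
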