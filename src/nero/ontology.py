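"""Ambiguity-aware named-entity class hierarchy.

The ontology is a single-rooted class tree for *textual* entities in
biomedical text. On top of plain subsumption it carries *union* (ambiguity)
classes: a class such as ``GeneOrProtein`` that is equivalent to the
disjunction of two concrete classes, used when the sentence does not resolve
whether a mention denotes the gene or its product. A union class subsumes
each of its members, so subsumption queries run over the parent tree plus
member->union edges.

The packaged hierarchy ships as a TSV (``name  parent  union_members``) under
``nero/data/nero_classes.tsv``; classes whose placement is reconstructed
rather than explicitly enumerated in the source hierarchy are flagged
``provisional``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "OntologyClass",
    "Ontology",
    "OntologyError",
    "load_ontology",
    "ALIASES",
]

# printed-spelling aliases normalized on read (e.g. a typo in the source
# material for AminoAcidOrPeptide)
ALIASES: dict[str, str] = {
    "AminaoAcidOrPeptide": "AminoAcidOrPeptide",
}


class OntologyError(ValueError):
    """Structural problem in a hierarchy table (cycle, dangling parent, ...)."""


@dataclass(frozen=True)
class OntologyClass:
    """One class in the hierarchy.

    ``union_members`` is empty for ordinary classes; for an ambiguity class it
    holds the >= 2 concrete classes the label is equivalent to.
    """

    name: str
    parent: str | None = None
    union_members: frozenset[str] = field(default_factory=frozenset)
    provisional: bool = False

    @property
    def is_union(self) -> bool:
        return bool(self.union_members)


class Ontology:
    """Validated class tree with union-class (ambiguity) semantics.

    Parameters
    ----------
    classes:
        Iterable of :class:`OntologyClass`; exactly one must have
        ``parent is None`` (the root).
    """

    def __init__(self, classes: Iterable[OntologyClass]):
        self.classes: dict[str, OntologyClass] = {}
        for c in classes:
            if c.name in self.classes:
                raise OntologyError(f"duplicate class name: {c.name!r}")
            self.classes[c.name] = c
        roots = [c.name for c in self.classes.values() if c.parent is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {roots!r}")
        self.root: str = roots[0]
        self._children: dict[str, set[str]] = {n: set() for n in self.classes}
        for c in self.classes.values():
            if c.parent is not None:
                if c.parent not in self.classes:
                    raise OntologyError(
                        f"class {c.name!r} references unknown parent {c.parent!r}"
                    )
                self._children[c.parent].add(c.name)
            for m in c.union_members:
                if m not in self.classes:
                    raise OntologyError(
                        f"union class {c.name!r} references unknown member {m!r}"
                    )
            if c.union_members and len(c.union_members) < 2:
                raise OntologyError(f"union class {c.name!r} has < 2 members")
        self._check_acyclic()
        # subsumption closure: ancestors via parent links plus member->union
        # edges, computed once by fixed-point iteration
        self._superclosure: dict[str, frozenset[str]] = self._build_closure()

    # -- construction helpers -------------------------------------------------

    def _check_acyclic(self) -> None:
        for name in self.classes:
            seen = set()
            cur: str | None = name
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle in parent links at {cur!r}")
                seen.add(cur)
                cur = self.classes[cur].parent

    def _build_closure(self) -> dict[str, frozenset[str]]:
        # edges: child -> parent, member -> union
        edges: dict[str, set[str]] = {n: set() for n in self.classes}
        for c in self.classes.values():
            if c.parent is not None:
                edges[c.name].add(c.parent)
            for m in c.union_members:
                edges[m].add(c.name)
        closure: dict[str, set[str]] = {}
        for start in self.classes:
            reach = {start}
            frontier = [start]
            while frontier:
                nxt = []
                for node in frontier:
                    for sup in edges[node]:
                        if sup not in reach:
                            reach.add(sup)
                            nxt.append(sup)
                frontier = nxt
            closure[start] = reach
        return {k: frozenset(v) for k, v in closure.items()}

    # -- queries --------------------------------------------------------------

    def _get(self, name: str) -> OntologyClass:
        try:
            return self.classes[name]
        except KeyError:
            raise KeyError(f"unknown ontology class: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    def children(self, name: str) -> frozenset[str]:
        self._get(name)
        return frozenset(self._children[name])

    def ancestors(self, name: str) -> frozenset[str]:
        """Superclasses of ``name`` (reflexive), unions included."""
        self._get(name)
        return self._superclosure[name]

    def is_subsumed_by(self, a: str, b: str) -> bool:
        """True iff every textual entity of class ``a`` is also of class ``b``.

        Holds when ``b`` is reachable from ``a`` along parent links, or when
        ``b`` is an ambiguity class one of whose members subsumes ``a``
        (transitively): ``Gene`` is subsumed by ``GeneOrProtein``.
        """
        self._get(b)
        return b in self._superclosure[self._get(a).name]

    def resolution_set(self, c: str) -> frozenset[str]:
        """Concrete readings of a label: members for a union class, else {c}."""
        cls = self._get(c)
        if cls.is_union:
            return cls.union_members
        return frozenset({c})

    def is_most_specific(self, c: str, *, unions_specific: bool = False) -> bool:
        """True iff ``c`` has no subclasses and is a resolved (non-union) label.

        ``unions_specific=True`` counts childless union classes as specific,
        for sensitivity analysis of specificity statistics.
        """
        cls = self._get(c)
        if self._children[c]:
            return False
        if cls.is_union and not unions_specific:
            return False
        return True

    def union_classes(self) -> list[str]:
        return sorted(n for n, c in self.classes.items() if c.is_union)

    def leaves(self) -> list[str]:
        return sorted(n for n in self.classes if self.is_most_specific(n))


def _parse_row(line: str, lineno: int) -> OntologyClass | None:
    if not line.strip():
        return None
    cols = line.rstrip("\n").split("\t")
    name = ALIASES.get(cols[0].strip(), cols[0].strip())
    parent = cols[1].strip() if len(cols) > 1 and cols[1].strip() else None
    if parent is not None:
        parent = ALIASES.get(parent, parent)
    members: frozenset[str] = frozenset()
    if len(cols) > 2 and cols[2].strip():
        members = frozenset(ALIASES.get(m.strip(), m.strip())
                            for m in cols[2].split("|") if m.strip())
    provisional = len(cols) > 3 and cols[3].strip().lower() in {"yes", "1", "true"}
    if not name:
        raise OntologyError(f"row {lineno}: empty class name")
    return OntologyClass(name, parent, members, provisional)


def load_ontology(path: str | Path | None = None) -> Ontology:
    """Load a hierarchy table; with no ``path``, the packaged class tree.

    The table is TSV with columns ``name``, ``parent``, ``union_members``
    (pipe-separated, may be empty) and an optional ``provisional`` flag; a
    header row is detected and skipped. Exactly one row must have an empty
    parent (the root). Raises :class:`OntologyError` naming the offending row
    on duplicate names, dangling parents or cycles.
    """
    if path is None:
        ref = resources.files("nero.data") / "nero_classes.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    rows: list[OntologyClass] = []
    for i, line in enumerate(lines):
        if i == 0 and line.split("\t")[0].strip().lower() == "name":
            continue
        row = _parse_row(line, i + 1)
        if row is not None:
            rows.append(row)
    if not rows:
        raise OntologyError("empty hierarchy table")
    return Ontology(rows)
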