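"""Domain model for structured plant morphological descriptions.

The extraction pipeline turns a telegraphic Spanish description into four
kinds of objects: :class:`Structure` (a plant part such as "hojas"),
:class:`Character` (a property of a structure such as its shape, colouration
or a length range), :class:`Relation` (a preposition-mediated link between
two structures, e.g. "con" seeds → aryl) and :class:`ConstraintSpan`
(a delimited prepositional or verbal phrase that is carried along but not
fully structured).

Numeric bounds are stored as :class:`decimal.Decimal` so that values such as
"3.3" round-trip textually through the XML serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

#: Tag letters used throughout the pipeline.
#: E entity/name, A adjective (character state), Z numeral/range, R adverb,
#: D determiner, C conjunction, S preposition, U unit of measurement,
#: G dimension (area) symbol, V verb, F punctuation, X unknown.
TAGS = frozenset("EAZRDCSUGVFX")

GENDERS = ("masculine", "feminine", "unknown")
NUMBERS = ("singular", "plural", "unknown")

#: Numeric token shapes accepted under the Z tag: plain numbers, ranges and
#: the open-ended atypical forms "-22" / "13-".
import re

NUMERIC_RE = re.compile(
    r"""^(
        -?\d+(\.\d+)?(-\d+(\.\d+)?)?   # 5 | 5.5 | 5-18 | -22
        | \d+(\.\d+)?-                 # 13-
    )$""",
    re.VERBOSE,
)


@dataclass
class Token:
    """A word, number or symbol: the atom all annotation rules operate on."""

    surface: str
    norm: str
    tag: str
    gender: str = "unknown"
    number: str = "unknown"
    index: int = 0
    in_parens: bool = False


@dataclass
class Chunk:
    """A comma-delimited unit of a clause; the atomic processing scope."""

    id: str  # T{taxon}L{clause}S{chunk}
    raw: str
    tokens: list[Token] = field(default_factory=list)


@dataclass
class Clause:
    """A period/colon/semicolon-delimited unit describing one structure."""

    id: str  # T{taxon}L{clause}
    raw: str
    chunks: list[Chunk] = field(default_factory=list)
    main_structure_id: Optional[str] = None


@dataclass
class Structure:
    """A botanical part (e.g. "hojas", "ápice")."""

    id: str
    name: str
    name_en: Optional[str] = None
    constraint: Optional[str] = None
    modifier: Optional[str] = None
    ontology_id: Optional[str] = None
    notes: Optional[str] = None
    clause_id: Optional[str] = None
    # grammatical features of the head token: association working state,
    # not part of the serialized record
    gender: str = field(default="unknown", compare=False)
    number: str = field(default="unknown", compare=False)


@dataclass
class Character:
    """A named property of a structure, plain-valued or a numeric range."""

    id: str
    structure_id: str
    name: str
    value: str
    char_type: str = "plain"  # or "range_value"
    from_: Optional[Decimal] = None
    to: Optional[Decimal] = None
    from_unit: Optional[str] = None
    to_unit: Optional[str] = None
    atypical_from: Optional[Decimal] = None
    atypical_to: Optional[Decimal] = None
    constraint: Optional[str] = None
    notes: Optional[str] = None


@dataclass
class Relation:
    """A preposition-named link between two structures ("con"/"sin")."""

    id: str
    name: str
    from_structure_id: str
    to_structure_id: str
    negated: bool = False
    clause_id: Optional[str] = None


@dataclass
class ConstraintSpan:
    """A delimited, unstructured prepositional or verbal phrase."""

    kind: str  # constraint_preposition | constraint_verb | verb_string
    text: str
    attached_to: str  # Structure or Character id
    clause_id: Optional[str] = None


SPAN_KINDS = ("constraint_preposition", "constraint_verb", "verb_string")


@dataclass
class AnnotatedDescription:
    """All objects extracted from one taxon description."""

    taxon_name: str
    clauses: list[Clause] = field(default_factory=list)
    structures: list[Structure] = field(default_factory=list)
    characters: list[Character] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    constraint_spans: list[ConstraintSpan] = field(default_factory=list)


class IdFactory:
    """Deterministic per-description id scheme: "o1", "o2", ... in creation order."""

    def __init__(self) -> None:
        self._n = 0

    def next_id(self, kind: str = "structure") -> str:
        if kind not in ("structure", "character", "relation"):
            raise ValueError(f"unknown id kind: {kind!r}")
        self._n += 1
        return f"o{self._n}"


def validate(description: AnnotatedDescription) -> list[str]:
    """Check every model invariant; return violation messages (empty = valid).

    Violations are data, not exceptions: downstream code decides whether a
    partially invalid annotation is usable.
    """
    out: list[str] = []
    struct_ids: set[str] = set()
    all_ids: list[str] = []

    for s in description.structures:
        if not s.name:
            out.append(f"structure {s.id}: empty name")
        if s.id in struct_ids:
            out.append(f"structure id {s.id} not unique")
        struct_ids.add(s.id)
        all_ids.append(s.id)

    for c in description.characters:
        all_ids.append(c.id)
        if c.structure_id not in struct_ids:
            out.append(f"character {c.id}: unresolved structure_id {c.structure_id!r}")
        if c.char_type == "range_value":
            if c.from_ is None or c.to is None:
                out.append(f"character {c.id}: range_value requires from and to")
            elif c.from_ > c.to:
                out.append(
                    f"character {c.id}: range lower bound {c.from_} exceeds upper bound {c.to}"
                )
        if c.atypical_to is not None and c.to is not None and not c.atypical_to > c.to:
            out.append(f"character {c.id}: atypical_to {c.atypical_to} not above to {c.to}")
        if c.atypical_from is not None and c.from_ is not None and not c.atypical_from < c.from_:
            out.append(
                f"character {c.id}: atypical_from {c.atypical_from} not below from {c.from_}"
            )

    for r in description.relations:
        all_ids.append(r.id)
        if not r.name:
            out.append(f"relation {r.id}: empty name")
        if r.from_structure_id not in struct_ids:
            out.append(f"relation {r.id}: unresolved from_structure_id")
        if r.to_structure_id not in struct_ids:
            out.append(f"relation {r.id}: unresolved to_structure_id")

    if len(all_ids) != len(set(all_ids)):
        out.append("object ids not unique across the description")

    for sp in description.constraint_spans:
        if sp.kind not in SPAN_KINDS:
            out.append(f"constraint span kind {sp.kind!r} unknown")

    for cl in description.clauses:
        for ch in cl.chunks:
            idxs = [t.index for t in ch.tokens]
            if idxs != list(range(len(idxs))):
                out.append(f"chunk {ch.id}: token indices not contiguous from 0")
            for t in ch.tokens:
                if t.tag not in TAGS:
                    out.append(f"chunk {ch.id}: token {t.surface!r} has unknown tag {t.tag!r}")
                if t.tag == "Z" and not NUMERIC_RE.match(t.norm):
                    out.append(f"chunk {ch.id}: Z token {t.norm!r} is not numeric")

    return out
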