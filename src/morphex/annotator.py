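"""Semantic analysis: from tagged chunks to structures, characters, relations.

Chunks of a clause are processed strictly left to right, because a chunk
often omits the structure its states describe ("alternas", "4-10 × 1-3.3
cm.") and the association step must look back at previously created
structures.  Association uses gender–number agreement with a recency
preference: a character links to the most recent structure whose gender and
number both agree with the state's head token (unmarked values agree with
anything), falling back to the clause's main structure.  This simple
heuristic is right most of the time and wrong in a documented way: a state
that agrees with a nearer substructure sticks to it even when it logically
describes the main structure — the behaviour is kept as-is.

Prepositional phrases headed by "con"/"sin" are structured into relations
between the outer and inner structure; every other prepositional phrase and
every verbal phrase is only delimited (constraint_preposition /
verb_string), though entity tokens inside are still extracted as structures
so later chunks can associate against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

from . import chunk_parser, preprocess
from .core_model import (
    AnnotatedDescription,
    Character,
    Chunk,
    Clause,
    ConstraintSpan,
    IdFactory,
    Relation,
    Structure,
    Token,
)
from .glossary import REPEATED_CHARACTER_NOTE, Glossary
from .tagging import ARTICLES, KnowledgeBase, Lexicon, morphology, tag

#: measurement character names; 2-D expressions are length × width
DIM_NAMES = ("length", "width")

#: phonological variants normalised before conjunction handling
CONJ_NORMALISE = {"u": "o", "e": "y"}

PSEUDO_STRUCTURE_NAME = "planta"
PSEUDO_STRUCTURE_NOTE = "estructura implícita"


class MeasurementParseError(ValueError):
    """The token sequence does not follow the numeric range grammar."""


@dataclass
class MeasurementDim:
    value: str
    from_: Optional[Decimal] = None
    to: Optional[Decimal] = None
    atypical_from: Optional[Decimal] = None
    atypical_to: Optional[Decimal] = None


@dataclass
class Measurement:
    """1 or 2 dimensions plus a shared unit and an optional explicit name."""

    dims: list[MeasurementDim] = field(default_factory=list)
    unit: Optional[str] = None
    name: Optional[str] = None  # from a "de <noun>" tail, e.g. height
    consumed: int = 0  # tokens eaten from the sequence


def agree(a: str, b: str) -> bool:
    """Gender/number agreement: equal, or either side unmarked."""
    return a == b or a == "unknown" or b == "unknown"


@dataclass
class ClauseContext:
    """Association state while a clause's chunks are processed."""

    clause_id: str
    structures_so_far: list[Structure] = field(default_factory=list)
    main_structure_id: Optional[str] = None
    current_structure_id: Optional[str] = None  # last core-region structure
    deferred_spans: list[ConstraintSpan] = field(default_factory=list)


def associate(
    gender: str, number: str, context: ClauseContext
) -> Optional[str]:
    """Pick the structure a character belongs to.

    Most recent structure whose gender and number both agree wins; otherwise
    the clause's main structure; ``None`` if the clause has produced no
    structure at all (caller attaches to the whole-plant pseudo-structure).
    """
    for s in reversed(context.structures_so_far):
        if agree(gender, s.gender) and agree(number, s.number):
            return s.id
    return context.main_structure_id


def parse_measurement(
    tokens: list[Token], start: int, glossary: Glossary
) -> Measurement:
    """Parse a numeric range expression starting at ``tokens[start]``.

    Grammar (per dimension): ``[(a-)] n[-m] [(-b)]`` where the parenthesised
    parts are atypical extremes; dimensions are joined by the area symbol
    "×"; a trailing unit applies to every dimension; a trailing
    "de <noun>" names the measured character (e.g. "de altura" → height).
    """
    i = start
    m = Measurement()
    n = len(tokens)

    def numeric(tok: Token) -> str:
        if tok.tag != "Z":
            raise MeasurementParseError(f"expected numeral, got {tok.surface!r}")
        return tok.norm

    while True:
        dim = MeasurementDim(value="")
        if i < n and tokens[i].tag == "Z" and tokens[i].in_parens:
            text = numeric(tokens[i])
            if not text.endswith("-"):
                raise MeasurementParseError(
                    f"atypical prefix {text!r} should end with '-'"
                )
            dim.atypical_from = Decimal(text[:-1])
            i += 1
        if i >= n or tokens[i].tag != "Z" or tokens[i].in_parens:
            raise MeasurementParseError("missing main numeral")
        main = numeric(tokens[i])
        if main.startswith("-") or main.endswith("-"):
            raise MeasurementParseError(f"open-ended main range {main!r}")
        dim.value = main
        if "-" in main:
            lo, hi = main.split("-")
            dim.from_, dim.to = Decimal(lo), Decimal(hi)
            if dim.from_ > dim.to:
                raise MeasurementParseError(f"inverted range {main!r}")
        i += 1
        if i < n and tokens[i].tag == "Z" and tokens[i].in_parens:
            text = numeric(tokens[i])
            if not text.startswith("-"):
                raise MeasurementParseError(
                    f"atypical suffix {text!r} should start with '-'"
                )
            dim.atypical_to = Decimal(text[1:])
            i += 1
        m.dims.append(dim)
        if i < n and tokens[i].tag == "G":
            i += 1
            continue
        break

    if len(m.dims) > 2:
        raise MeasurementParseError("more than two dimensions")
    if i < n and tokens[i].tag == "U":
        m.unit = tokens[i].norm
        i += 1
    if (
        i + 1 < n
        and tokens[i].tag == "S"
        and tokens[i].norm == "de"
        and tokens[i + 1].tag == "E"
    ):
        term_en, _src = glossary.translate(tokens[i + 1].norm)
        m.name = term_en
        i += 2
    m.consumed = i - start
    return m


def measurement_characters(
    m: Measurement, ids: IdFactory, structure_id: str
) -> list[Character]:
    """Materialise one character per measurement dimension."""
    chars: list[Character] = []
    for k, dim in enumerate(m.dims):
        if len(m.dims) == 2:
            name = DIM_NAMES[k]
        else:
            name = m.name or "length"
        c = Character(
            id=ids.next_id("character"),
            structure_id=structure_id,
            name=name,
            value=dim.value,
        )
        if dim.from_ is not None:
            c.char_type = "range_value"
            c.from_, c.to = dim.from_, dim.to
        c.atypical_from, c.atypical_to = dim.atypical_from, dim.atypical_to
        if m.unit is not None:
            c.from_unit = c.to_unit = m.unit
        chars.append(c)
    return chars


def render_measurement(m: Measurement) -> str:
    """Inverse of :func:`parse_measurement` on canonical forms."""
    parts: list[str] = []
    for k, dim in enumerate(m.dims):
        if k:
            parts.append("×")
        if dim.atypical_from is not None:
            parts.append(f"({dim.atypical_from}-)")
        parts.append(dim.value)
        if dim.atypical_to is not None:
            parts.append(f"(-{dim.atypical_to})")
    if m.unit:
        parts.append(m.unit)
    return " ".join(parts)


class Annotator:
    """The rule engine; holds the language resources and runs the pipeline."""

    def __init__(
        self,
        lexicon: Optional[Lexicon] = None,
        kb: Optional[KnowledgeBase] = None,
        glossary: Optional[Glossary] = None,
        abbreviations: Optional[preprocess.AbbreviationTable] = None,
    ) -> None:
        self.lexicon = lexicon or Lexicon.default()
        self.kb = kb or KnowledgeBase()
        self.glossary = glossary or Glossary()
        self.abbreviations = (
            abbreviations
            if abbreviations is not None
            else preprocess.AbbreviationTable.default()
        )

    # ------------------------------------------------------------ pipeline

    def annotate(
        self, taxon_name: str, description: str, taxon_index: int = 1,
        keep_tokens: bool = False,
    ) -> AnnotatedDescription:
        """Run the full pipeline on one description."""
        desc = AnnotatedDescription(taxon_name=taxon_name)
        ids = IdFactory()
        self._pseudo: Optional[Structure] = None
        text = preprocess.normalize(description, self.abbreviations)
        for li, clause_raw in enumerate(preprocess.segment_clauses(text), start=1):
            clause_id = f"T{taxon_index}L{li}"
            clause = Clause(id=clause_id, raw=clause_raw)
            ctx = ClauseContext(clause_id=clause_id)
            for si, chunk_raw in enumerate(
                preprocess.segment_chunks(clause_raw), start=1
            ):
                chunk = tag(
                    chunk_raw, self.lexicon, self.kb, chunk_id=f"{clause_id}S{si}"
                )
                clause.chunks.append(chunk)
                if chunk.tokens:
                    chunk_parser.parse(chunk)  # shape check; rules run on sequence
                    self._process_chunk(chunk, ctx, desc, ids)
            clause.main_structure_id = ctx.main_structure_id
            self._flush_deferred(ctx, desc, ids)
            if not keep_tokens:
                for ch in clause.chunks:
                    ch.tokens = []
            desc.clauses.append(clause)
        return desc

    # ----------------------------------------------------------- internals

    def _pseudo_structure(
        self, desc: AnnotatedDescription, ids: IdFactory, clause_id: str
    ) -> Structure:
        if self._pseudo is None:
            self._pseudo = Structure(
                id=ids.next_id("structure"),
                name=PSEUDO_STRUCTURE_NAME,
                name_en="plant",
                notes=PSEUDO_STRUCTURE_NOTE,
                clause_id=clause_id,
                gender="unknown",
                number="unknown",
            )
            desc.structures.append(self._pseudo)
        return self._pseudo

    def _anchor_id(
        self, ctx: ClauseContext, desc: AnnotatedDescription, ids: IdFactory
    ) -> str:
        if ctx.current_structure_id:
            return ctx.current_structure_id
        if ctx.main_structure_id:
            return ctx.main_structure_id
        return self._pseudo_structure(desc, ids, ctx.clause_id).id

    def _associate_id(
        self,
        head: Token,
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
    ) -> tuple[str, bool]:
        sid = associate(head.gender, head.number, ctx)
        if sid is None:
            return self._pseudo_structure(desc, ids, ctx.clause_id).id, True
        return sid, False

    def _flush_deferred(
        self, ctx: ClauseContext, desc: AnnotatedDescription, ids: IdFactory
    ) -> None:
        for span in ctx.deferred_spans:
            span.attached_to = ctx.main_structure_id or self._pseudo_structure(
                desc, ids, ctx.clause_id
            ).id
        ctx.deferred_spans.clear()

    def _make_structure(
        self,
        name_tok: Token,
        modifier_tok: Optional[Token],
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
        core: bool,
    ) -> Structure:
        name_en, _src = self.glossary.translate(name_tok.norm)
        s = Structure(
            id=ids.next_id("structure"),
            name=name_tok.surface,
            name_en=name_en,
            modifier=modifier_tok.surface if modifier_tok else None,
            clause_id=ctx.clause_id,
            gender=name_tok.gender,
            number=name_tok.number,
        )
        desc.structures.append(s)
        ctx.structures_so_far.append(s)
        if ctx.main_structure_id is None:
            ctx.main_structure_id = s.id
        if core:
            ctx.current_structure_id = s.id
        return s

    # -- chunk-level dispatch ------------------------------------------------

    def _process_chunk(
        self,
        chunk: Chunk,
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
    ) -> None:
        tokens = chunk.tokens
        fb = self._first_break(tokens)
        core, rest = tokens[:fb], tokens[fb:]
        if core:
            self._process_core(core, ctx, desc, ids, forced_structure=None)
        while rest:
            head = rest[0]
            if head.tag == "V" or (head.norm == "que" and self._next_is_verb(rest)):
                text = " ".join(t.surface for t in rest)
                span = ConstraintSpan(
                    kind="verb_string", text=text, attached_to="",
                    clause_id=ctx.clause_id,
                )
                if ctx.current_structure_id or ctx.main_structure_id:
                    span.attached_to = self._anchor_id(ctx, desc, ids)
                else:
                    ctx.deferred_spans.append(span)
                desc.constraint_spans.append(span)
                rest = []
            elif head.tag == "S" and head.norm in ("con", "sin"):
                end = self._region_end(rest, stop_any_s=True)
                self._process_con_region(rest[:end], ctx, desc, ids)
                rest = rest[end:]
            else:
                end = self._region_end(rest, stop_any_s=False)
                region = rest[:end]
                anchor = self._anchor_or_defer(ctx, desc, ids)
                span = ConstraintSpan(
                    kind="constraint_preposition",
                    text=" ".join(t.surface for t in region),
                    attached_to=anchor or "",
                    clause_id=ctx.clause_id,
                )
                if anchor is None:
                    ctx.deferred_spans.append(span)
                desc.constraint_spans.append(span)
                # entities inside are extracted for later association
                for t in region:
                    if t.tag == "E" and not t.in_parens:
                        self._make_structure(t, None, ctx, desc, ids, core=False)
                rest = rest[end:]

    def _anchor_or_defer(
        self, ctx: ClauseContext, desc: AnnotatedDescription, ids: IdFactory
    ) -> Optional[str]:
        if ctx.structures_so_far:
            return ctx.structures_so_far[-1].id
        if ctx.main_structure_id:
            return ctx.main_structure_id
        return None

    def _next_is_verb(self, tokens: list[Token]) -> bool:
        for t in tokens[1:]:
            if t.in_parens:
                continue
            return t.tag == "V"
        return False

    def _is_connector_a(self, tokens: list[Token], i: int) -> bool:
        if tokens[i].norm != "a":
            return False
        prev = next(
            (t for t in reversed(tokens[:i]) if not t.in_parens and t.tag != "R"),
            None,
        )
        nxt = next(
            (t for t in tokens[i + 1 :] if not t.in_parens and t.tag != "R"), None
        )
        return (
            prev is not None
            and nxt is not None
            and prev.tag in ("A", "X")
            and nxt.tag in ("A", "X")
        )

    def _is_measure_de(self, tokens: list[Token], i: int) -> bool:
        return (
            tokens[i].norm == "de"
            and i > 0
            and tokens[i - 1].tag in ("U", "Z")
            and i + 1 < len(tokens)
            and tokens[i + 1].tag == "E"
        )

    def _first_break(self, tokens: list[Token]) -> int:
        for i, t in enumerate(tokens):
            if t.in_parens:
                continue
            if t.tag == "V":
                return i
            if t.norm == "que" and self._next_is_verb(tokens[i:]):
                return i
            if t.tag == "S":
                if self._is_connector_a(tokens, i):
                    continue
                if self._is_measure_de(tokens, i):
                    continue
                return i
        return len(tokens)

    def _region_end(self, tokens: list[Token], stop_any_s: bool) -> int:
        """End of a prepositional region that starts at ``tokens[0]``."""
        for j in range(1, len(tokens)):
            t = tokens[j]
            if t.in_parens:
                continue
            if t.tag == "V":
                return j
            if t.tag == "S" and not self._is_connector_a(tokens, j) and not (
                self._is_measure_de(tokens, j)
            ):
                if stop_any_s or t.norm in ("con", "sin"):
                    return j
        return len(tokens)

    # -- core region ---------------------------------------------------------

    def _process_core(
        self,
        tokens: list[Token],
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
        forced_structure: Optional[Structure],
    ) -> None:
        """Apply the E/A/Z/R/D rules to a chunk's core (or "con" inner) region.

        ``forced_structure`` short-circuits association: characters created
        inside a con/sin phrase always describe the inner structure.
        """
        structure = forced_structure
        pending_quant: Optional[Token] = None
        objects: dict[int, object] = {}  # top-level token index -> object
        i = 0
        n = len(tokens)
        while i < n:
            t = tokens[i]
            if t.in_parens:
                i += 1
                continue
            if t.tag == "F":
                i += 1
                continue
            if t.tag == "D":
                if t.norm in ARTICLES:
                    pass  # consumed silently
                elif structure is not None:
                    structure.constraint = _join_constraint(
                        structure.constraint, t.surface
                    )
                else:
                    pending_quant = t
                i += 1
                continue
            if t.tag == "E":
                if structure is None or forced_structure is None:
                    modifier = None
                    if (
                        i + 1 < n
                        and tokens[i + 1].tag == "E"
                        and not tokens[i + 1].in_parens
                    ):
                        modifier = tokens[i + 1]
                    structure = self._make_structure(
                        t, modifier, ctx, desc, ids, core=forced_structure is None
                    )
                    objects[t.index] = structure
                    if modifier is not None:
                        i += 1
                    if pending_quant is not None:
                        structure.constraint = _join_constraint(
                            structure.constraint, pending_quant.surface
                        )
                        pending_quant = None
                i += 1
                continue
            if t.tag == "Z":
                i = self._handle_measurement(
                    tokens, i, ctx, desc, ids, structure, forced_structure, objects
                )
                continue
            if t.tag in ("A", "X", "R", "C") or (
                t.tag == "S" and self._is_connector_a(tokens, i)
            ):
                j = i
                while j < n and (
                    tokens[j].in_parens
                    or tokens[j].tag in ("A", "X", "R", "C")
                    or (tokens[j].tag == "S" and self._is_connector_a(tokens, j))
                ):
                    j += 1
                self._process_states(
                    tokens[i:j], ctx, desc, ids, forced_structure, objects
                )
                i = j
                continue
            i += 1
        # a quantifier with no entity in its chunk modifies the clause's
        # current structure ("varias por racimo")
        if pending_quant is not None:
            target = (
                structure
                or _structure_by_id(desc, ctx.current_structure_id)
                or _structure_by_id(desc, ctx.main_structure_id)
                or self._pseudo_structure(desc, ids, ctx.clause_id)
            )
            target.constraint = _join_constraint(target.constraint, pending_quant.surface)
        self._attach_parenthetical_constraints(tokens, objects, ctx, desc)

    def _handle_measurement(
        self,
        tokens: list[Token],
        i: int,
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
        structure: Optional[Structure],
        forced_structure: Optional[Structure],
        objects: dict[int, object],
    ) -> int:
        try:
            m = parse_measurement(tokens, i, self.glossary)
        except MeasurementParseError as err:
            # preserve the whole numeric stretch as a plain character
            j = i
            while j < len(tokens) and tokens[j].tag in ("Z", "G", "U"):
                j += 1
            sid = (
                forced_structure.id
                if forced_structure is not None
                else self._associate_id(tokens[i], ctx, desc, ids)[0]
            )
            c = Character(
                id=ids.next_id("character"),
                structure_id=sid,
                name="length",
                value=" ".join(t.surface for t in tokens[i:j]),
                notes=f"no estructurado: {err}",
            )
            desc.characters.append(c)
            objects[tokens[i].index] = c
            return j
        if forced_structure is not None:
            sid, pseudo = forced_structure.id, False
        else:
            sid, pseudo = self._associate_id(tokens[i], ctx, desc, ids)
        chars = measurement_characters(m, ids, sid)
        if pseudo:
            for c in chars:
                c.notes = PSEUDO_STRUCTURE_NOTE
        desc.characters.extend(chars)
        objects[tokens[i].index] = chars[0]
        return i + m.consumed

    def _process_states(
        self,
        seq: list[Token],
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
        forced_structure: Optional[Structure],
        objects: dict[int, object],
    ) -> None:
        """The A/C/R machinery for one state sequence of a region.

        The sequence is split into conjunct groups at conjunction tokens;
        within a group, adjacent states with the same character-name set are
        merged into a single character value (the "a"-connected colouration
        pattern).  In a coordination every conjunct becomes its own
        character, all sharing the character name resolved from the first
        conjunct and the structure link of the first conjunct; the
        conjunction word goes into the notes of the later conjuncts.
        """
        top = [t for t in seq if not t.in_parens]
        groups: list[list[Token]] = [[]]
        conj_words: list[Optional[str]] = [None]
        for t in top:
            if t.tag == "C":
                groups.append([])
                conj_words.append(CONJ_NORMALISE.get(t.norm, t.norm))
            else:
                groups[-1].append(t)
        groups_runs: list[list[dict]] = []
        for g in groups:
            groups_runs.append(self._merge_runs(g))
        # character name shared across a coordination, from the first state
        shared_names: Optional[list[str]] = None
        first_head: Optional[Token] = None
        is_coordination = sum(1 for runs in groups_runs if runs) > 1
        structure_id: Optional[str] = None
        for gi, runs in enumerate(groups_runs):
            for run in runs:
                head: Token = run["head"]
                state_en, names, _known = self.glossary.resolve_state(head.norm)
                if is_coordination:
                    if shared_names is None:
                        shared_names = names
                        first_head = head
                    names = shared_names
                pseudo = False
                if forced_structure is not None:
                    sid = forced_structure.id
                elif is_coordination:
                    if structure_id is None:
                        structure_id, pseudo = self._associate_id(
                            first_head or head, ctx, desc, ids
                        )
                    sid = structure_id
                else:
                    sid, pseudo = self._associate_id(head, ctx, desc, ids)
                notes_parts: list[str] = []
                if pseudo:
                    notes_parts.append(PSEUDO_STRUCTURE_NOTE)
                if len(names) > 1:
                    notes_parts.append(REPEATED_CHARACTER_NOTE)
                if is_coordination and gi > 0 and conj_words[gi]:
                    notes_parts.append(f"conjunción: {conj_words[gi]}")
                if not run["known"]:
                    notes_parts.append("estado no reconocido")
                for name in names:
                    c = Character(
                        id=ids.next_id("character"),
                        structure_id=sid,
                        name=name,
                        value=run["value"],
                        constraint=run["constraint"],
                        notes="; ".join(notes_parts) or None,
                    )
                    desc.characters.append(c)
                    if run["index"] not in objects:
                        objects[run["index"]] = c
        # stray adverbs with no state in their group modify the structure
        for gi, g in enumerate(groups):
            if groups_runs[gi]:
                continue
            for t in g:
                if t.tag == "R":
                    target = (
                        forced_structure
                        or _structure_by_id(desc, ctx.current_structure_id)
                        or _structure_by_id(desc, ctx.main_structure_id)
                    )
                    if target is not None:
                        target.constraint = _join_constraint(
                            target.constraint, t.surface
                        )

    def _merge_runs(self, group: list[Token]) -> list[dict]:
        """Merge a conjunct group into character-value runs.

        Adjacent states (possibly joined by the connector "a") merge while
        their character-name sets coincide; adverbs become the constraint of
        the run that follows them (child rule), or of the preceding run.
        """
        runs: list[dict] = []
        pending_adverbs: list[Token] = []
        for t in group:
            if t.tag == "R":
                pending_adverbs.append(t)
                continue
            if t.tag == "S":  # connector "a"
                if runs:
                    runs[-1]["pending_connector"] = t
                continue
            names = sorted(self.glossary.resolve_state(t.norm)[1])
            known = self.glossary.resolve_state(t.norm)[2]
            last = runs[-1] if runs else None
            if (
                last is not None
                and last["names"] == names
                and not pending_adverbs
            ):
                conn = last.pop("pending_connector", None)
                if conn is not None:
                    last["value"] += f" {conn.surface}"
                last["value"] += f" {t.surface}"
            else:
                if last is not None:
                    last.pop("pending_connector", None)
                runs.append(
                    {
                        "head": t,
                        "names": names,
                        "known": known,
                        "value": t.surface,
                        "index": t.index,
                        "constraint": (
                            " ".join(a.surface for a in pending_adverbs) or None
                        ),
                    }
                )
                pending_adverbs = []
        if pending_adverbs and runs:  # trailing adverbs modify the last state
            extra = " ".join(a.surface for a in pending_adverbs)
            runs[-1]["constraint"] = _join_constraint(runs[-1]["constraint"], extra)
        for r in runs:
            r.pop("pending_connector", None)
        return runs

    def _attach_parenthetical_constraints(
        self,
        tokens: list[Token],
        objects: dict[int, object],
        ctx: ClauseContext,
        desc: AnnotatedDescription,
    ) -> None:
        """A parenthetical aside becomes the constraint of the object built
        from the token just before the parenthesis ("alternas (rara vez
        opuestas)")."""
        i = 0
        n = len(tokens)
        while i < n:
            if not tokens[i].in_parens:
                i += 1
                continue
            j = i
            while j < n and tokens[j].in_parens:
                j += 1
            if tokens[i].tag != "Z":  # measurement atypicals handled elsewhere
                text = " ".join(t.surface for t in tokens[i:j])
                target = None
                for k in range(i - 1, -1, -1):
                    if tokens[k].index in objects:
                        target = objects[tokens[k].index]
                        break
                if target is None and ctx.structures_so_far:
                    target = ctx.structures_so_far[-1]
                if target is not None:
                    target.constraint = _join_constraint(target.constraint, text)
            i = j

    # -- con / sin regions ---------------------------------------------------

    def _process_con_region(
        self,
        region: list[Token],
        ctx: ClauseContext,
        desc: AnnotatedDescription,
        ids: IdFactory,
    ) -> None:
        prep = region[0]
        inner_tokens = region[1:]
        first_e = next(
            (t for t in inner_tokens if t.tag == "E" and not t.in_parens), None
        )
        if first_e is None:
            # nothing to relate to: fall back to a delimited span
            anchor = self._anchor_or_defer(ctx, desc, ids)
            span = ConstraintSpan(
                kind="constraint_preposition",
                text=" ".join(t.surface for t in region),
                attached_to=anchor or "",
                clause_id=ctx.clause_id,
            )
            if anchor is None:
                ctx.deferred_spans.append(span)
            desc.constraint_spans.append(span)
            return
        from_id = self._anchor_id(ctx, desc, ids)
        pos = inner_tokens.index(first_e)
        modifier = None
        if (
            pos + 1 < len(inner_tokens)
            and inner_tokens[pos + 1].tag == "E"
            and not inner_tokens[pos + 1].in_parens
        ):
            modifier = inner_tokens[pos + 1]
        inner = self._make_structure(first_e, modifier, ctx, desc, ids, core=False)
        desc.relations.append(
            Relation(
                id=ids.next_id("relation"),
                name=prep.norm,
                from_structure_id=from_id,
                to_structure_id=inner.id,
                negated=prep.norm == "sin",
                clause_id=ctx.clause_id,
            )
        )
        remainder = [
            t
            for t in inner_tokens
            if t is not first_e and t is not modifier
        ]
        if remainder:
            self._process_core(
                remainder, ctx, desc, ids, forced_structure=inner
            )


def _join_constraint(existing: Optional[str], extra: str) -> str:
    return f"{existing} {extra}" if existing else extra


def _structure_by_id(
    desc: AnnotatedDescription, sid: Optional[str]
) -> Optional[Structure]:
    if sid is None:
        return None
    return next((s for s in desc.structures if s.id == sid), None)
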