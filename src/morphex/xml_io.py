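"""Tabular input and XML (optionally JSON-mirrored) output.

Input is a delimited UTF-8 table with a scientific-name column and a
description column.  Output is one ``<description>`` document per taxon:
a ``<statement>`` per clause carrying the clause text, structures with
their characters nested inside, relations between structures, and the
delimited prepositional/verbal spans.  Attribute order is fixed and the
serialization is byte-deterministic so golden-file comparisons work.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path
from typing import Optional

import pandas as pd
from lxml import etree

from .core_model import (
    AnnotatedDescription,
    Character,
    Chunk,
    Clause,
    ConstraintSpan,
    Relation,
    Structure,
    validate,
)

log = logging.getLogger(__name__)

TAXON_COLUMNS = ("taxon", "scientific_name", "name", "taxon_name")
DESCRIPTION_COLUMNS = ("description", "descripcion", "descripción")


class FormatError(ValueError):
    """The input table lacks the required columns."""


class SchemaError(ValueError):
    """An XML file does not follow the description schema."""


class ValidationError(ValueError):
    """Refusing to serialize a model that fails :func:`validate`."""


@dataclass
class DescriptionRecord:
    taxon_name: str
    description: str


def read_table(path: str | Path, delimiter: str = "\t") -> list[DescriptionRecord]:
    """Read (taxon, description) records from a delimited UTF-8 table.

    The header row is recognised by column names (a taxon-like column and a
    description column, case-insensitive).  Rows with empty cells are
    skipped with a warning.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    taxon_col = next((cols[c] for c in TAXON_COLUMNS if c in cols), None)
    desc_col = next((cols[c] for c in DESCRIPTION_COLUMNS if c in cols), None)
    if taxon_col is None or desc_col is None:
        raise FormatError(
            f"expected a taxon column ({'/'.join(TAXON_COLUMNS)}) and a "
            f"description column; found {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        taxon, desc = row[taxon_col].strip(), row[desc_col].strip()
        if not taxon or not desc:
            log.warning("row %d skipped: empty taxon or description", i + 1)
            continue
        records.append(DescriptionRecord(taxon_name=taxon, description=desc))
    return records


def write_table(
    records: list[DescriptionRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    pd.DataFrame(
        [(r.taxon_name, r.description) for r in records],
        columns=["taxon", "description"],
    ).to_csv(path, sep=delimiter, index=False)


def structurally_equal(a: AnnotatedDescription, b: AnnotatedDescription) -> bool:
    """Model equality up to object-list ordering (ids are compared)."""

    def okey(o) -> tuple:
        oid = getattr(o, "id", "")
        num = int(oid[1:]) if oid[1:].isdigit() else -1
        return (num, oid)

    def skey(s: ConstraintSpan) -> tuple:
        return (s.clause_id or "", s.kind, s.text, s.attached_to)

    return (
        a.taxon_name == b.taxon_name
        and a.clauses == b.clauses
        and sorted(a.structures, key=okey) == sorted(b.structures, key=okey)
        and sorted(a.characters, key=okey) == sorted(b.characters, key=okey)
        and sorted(a.relations, key=okey) == sorted(b.relations, key=okey)
        and sorted(a.constraint_spans, key=skey) == sorted(b.constraint_spans, key=skey)
    )


# ------------------------------------------------------------------ writing

def _dec(x: Optional[Decimal]) -> Optional[str]:
    return None if x is None else str(x)


def _set(el: etree._Element, **attrs: Optional[str]) -> None:
    for k, v in attrs.items():
        if v is not None:
            el.set(k, v)


def to_element(annotated: AnnotatedDescription) -> etree._Element:
    root = etree.Element("description")
    _set(root, taxon_name=annotated.taxon_name)
    by_clause_chars: dict[str, list[Character]] = {}
    for c in annotated.characters:
        by_clause_chars.setdefault(c.structure_id, []).append(c)
    for clause in annotated.clauses:
        st = etree.SubElement(root, "statement")
        _set(st, id=clause.id, text=clause.raw, main_structure=clause.main_structure_id)
        for ch in clause.chunks:
            ck = etree.SubElement(st, "chunk")
            _set(ck, id=ch.id, text=ch.raw)
        for s in annotated.structures:
            if s.clause_id != clause.id:
                continue
            se = etree.SubElement(st, "structure")
            _set(
                se,
                id=s.id,
                name=s.name,
                name_en=s.name_en,
                constraint=s.constraint,
                modifier=s.modifier,
                ontology_id=s.ontology_id,
                notes=s.notes,
            )
            for c in by_clause_chars.get(s.id, []):
                ce = etree.SubElement(se, "character")
                _set(
                    ce,
                    id=c.id,
                    name=c.name,
                    value=c.value,
                    char_type=None if c.char_type == "plain" else c.char_type,
                    **{"from": _dec(c.from_)},
                    to=_dec(c.to),
                    from_unit=c.from_unit,
                    to_unit=c.to_unit,
                    atypical_from=_dec(c.atypical_from),
                    atypical_to=_dec(c.atypical_to),
                    constraint=c.constraint,
                    notes=c.notes,
                )
        for r in annotated.relations:
            if r.clause_id != clause.id:
                continue
            re_ = etree.SubElement(st, "relation")
            _set(
                re_,
                id=r.id,
                name=r.name,
                **{"from": r.from_structure_id},
                to=r.to_structure_id,
                negated="true" if r.negated else None,
            )
        for sp in annotated.constraint_spans:
            if sp.clause_id != clause.id:
                continue
            spe = etree.SubElement(st, sp.kind)
            _set(spe, text=sp.text, attached_to=sp.attached_to)
    return root


def write_xml(annotated: AnnotatedDescription, path: str | Path) -> None:
    """Serialize a validated model; identical models give identical bytes."""
    problems = validate(annotated)
    if problems:
        raise ValidationError("; ".join(problems))
    root = to_element(annotated)
    etree.indent(root, space="  ")
    data = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=False
    )
    Path(path).write_bytes(data + b"\n")


def to_json_dict(annotated: AnnotatedDescription) -> dict:
    """A 1:1 JSON mirror of the XML document (convenience, same schema)."""

    def elem_to_dict(el: etree._Element) -> dict:
        d: dict = {"element": el.tag, **el.attrib}
        kids = [elem_to_dict(k) for k in el]
        if kids:
            d["children"] = kids
        return d

    return elem_to_dict(to_element(annotated))


def write_json(annotated: AnnotatedDescription, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(to_json_dict(annotated), ensure_ascii=False, indent=2) + "\n",
        encoding="utf-8",
    )


# ------------------------------------------------------------------ reading

_STRUCTURE_ATTRS = {
    "id", "name", "name_en", "constraint", "modifier", "ontology_id", "notes"
}
_CHARACTER_ATTRS = {
    "id", "name", "value", "char_type", "from", "to", "from_unit", "to_unit",
    "atypical_from", "atypical_to", "constraint", "notes",
}
_RELATION_ATTRS = {"id", "name", "from", "to", "negated"}


def _extra(el: etree._Element, known: set[str]) -> dict[str, str]:
    extra = {k: v for k, v in el.attrib.items() if k not in known}
    if extra:
        log.warning("unknown attributes on <%s> preserved: %s", el.tag, extra)
    return extra


def _maybe_dec(v: Optional[str]) -> Optional[Decimal]:
    return None if v is None else Decimal(v)


def read_xml(path: str | Path) -> AnnotatedDescription:
    """Parse a description document back into the model.

    ``read_xml(write_xml(x))`` is structurally identical to ``x``.  Unknown
    attributes are kept in a pass-through ``extra`` mapping with a warning.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as err:
        raise SchemaError(f"{path}: line {err.lineno}: {err.msg}") from err
    root = tree.getroot()
    if root.tag != "description":
        raise SchemaError(f"{path}: root element is <{root.tag}>, not <description>")
    out = AnnotatedDescription(taxon_name=root.get("taxon_name", ""))
    for st in root.iterchildren("statement"):
        clause = Clause(
            id=st.get("id", ""),
            raw=st.get("text", ""),
            main_structure_id=st.get("main_structure"),
        )
        for el in st:
            if el.tag == "chunk":
                clause.chunks.append(Chunk(id=el.get("id", ""), raw=el.get("text", "")))
            elif el.tag == "structure":
                s = Structure(
                    id=el.get("id", ""),
                    name=el.get("name", ""),
                    name_en=el.get("name_en"),
                    constraint=el.get("constraint"),
                    modifier=el.get("modifier"),
                    ontology_id=el.get("ontology_id"),
                    notes=el.get("notes"),
                    clause_id=clause.id,
                )
                s.extra = _extra(el, _STRUCTURE_ATTRS)
                out.structures.append(s)
                for ce in el.iterchildren("character"):
                    c = Character(
                        id=ce.get("id", ""),
                        structure_id=s.id,
                        name=ce.get("name", ""),
                        value=ce.get("value", ""),
                        char_type=ce.get("char_type", "plain"),
                        from_=_maybe_dec(ce.get("from")),
                        to=_maybe_dec(ce.get("to")),
                        from_unit=ce.get("from_unit"),
                        to_unit=ce.get("to_unit"),
                        atypical_from=_maybe_dec(ce.get("atypical_from")),
                        atypical_to=_maybe_dec(ce.get("atypical_to")),
                        constraint=ce.get("constraint"),
                        notes=ce.get("notes"),
                    )
                    c.extra = _extra(ce, _CHARACTER_ATTRS)
                    out.characters.append(c)
            elif el.tag == "relation":
                r = Relation(
                    id=el.get("id", ""),
                    name=el.get("name", ""),
                    from_structure_id=el.get("from", ""),
                    to_structure_id=el.get("to", ""),
                    negated=el.get("negated") == "true",
                    clause_id=clause.id,
                )
                r.extra = _extra(el, _RELATION_ATTRS)
                out.relations.append(r)
            elif el.tag in ("constraint_preposition", "constraint_verb", "verb_string"):
                out.constraint_spans.append(
                    ConstraintSpan(
                        kind=el.tag,
                        text=el.get("text", ""),
                        attached_to=el.get("attached_to", ""),
                        clause_id=clause.id,
                    )
                )
            else:
                log.warning("unknown element <%s> ignored", el.tag)
        out.clauses.append(clause)
    return out
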