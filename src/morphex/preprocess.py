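"""Normalization and segmentation of raw description text.

Taxonomic descriptions arrive as a single string per taxon.  Processing
scopes follow botanical writing conventions: clauses (terminated by period,
colon or semicolon) fully describe one structure, and comma-delimited chunks
within a clause are the atomic units the annotation rules see.

The tricky part is that periods also occur inside decimal numbers ("3.3")
and after unit abbreviations ("cm.") mid-clause, and commas occur inside
parenthetical asides; neither may trigger a split.
"""

from __future__ import annotations

import importlib.resources
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

QUOTE_CHARS = "\"'“”‘’«»′″"

# "x" used as a dimension (area) separator between numbers
_X_BETWEEN_NUMBERS = re.compile(r"(?<=[\d)])\s*[x×]\s*(?=[\d(])")


@dataclass
class AbbreviationTable:
    """Maps abbreviations (with trailing period) to period-free expansions."""

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            if not k.endswith("."):
                raise ValueError(f"abbreviation {k!r} must end with a period")
            if "." in v:
                raise ValueError(f"expansion {v!r} must not contain periods")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbbreviationTable":
        entries: dict[str, str] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            abbrev, expansion = line.split("\t")[:2]
            entries[abbrev] = expansion
        return cls(entries)

    @classmethod
    def default(cls) -> "AbbreviationTable":
        ref = importlib.resources.files("morphex.data") / "abbreviations.tsv"
        with importlib.resources.as_file(ref) as p:
            return cls.from_tsv(p)


def normalize(text: str, table: AbbreviationTable | None = None) -> str:
    """Standardise raw description text.

    Applies NFC unicode normalization, strips single/double quotes, expands
    abbreviations from *table*, rewrites "x" between numbers to the dimension
    symbol "×" and collapses whitespace.  Accents are preserved.
    """
    text = unicodedata.normalize("NFC", text)
    text = text.translate({ord(c): None for c in QUOTE_CHARS})
    if table is not None:
        for abbrev, expansion in table.entries.items():
            # word-boundary on the left; the trailing period is part of the key
            text = re.sub(
                r"(?<![\w.])" + re.escape(abbrev) + r"(?!\w)", expansion, text
            )
    text = _X_BETWEEN_NUMBERS.sub(" × ", text)
    text = re.sub(r"\s+", " ", text).strip()
    return text


def _split_outside_parens(text: str, is_sep) -> list[str]:
    """Split *text* at positions where ``is_sep(text, i)`` holds at paren depth 0."""
    parts: list[str] = []
    depth = 0
    start = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif depth == 0 and is_sep(text, i):
            parts.append(text[start:i])
            start = i + 1
    parts.append(text[start:])
    return [p.strip() for p in parts if p.strip()]


def _is_clause_sep(text: str, i: int) -> bool:
    ch = text[i]
    if ch in ":;":
        return True
    if ch != ".":
        return False
    # A period inside a decimal number never splits.
    if i > 0 and i + 1 < len(text) and text[i - 1].isdigit() and text[i + 1].isdigit():
        return False
    # A period splits only when followed by whitespace + a non-numeric,
    # non-parenthesis token, or at end of text.  This keeps "cm.," and
    # "cm. 4-10" mid-clause.
    j = i + 1
    if j >= len(text):
        return True
    if not text[j].isspace():
        return False
    while j < len(text) and text[j].isspace():
        j += 1
    if j >= len(text):
        return True
    return not (text[j].isdigit() or text[j] == "(")


def segment_clauses(text: str) -> list[str]:
    """Split normalized text into clause strings at '.', ':' and ';'.

    Separators inside parentheses or decimal numbers are ignored; empty
    segments are dropped.
    """
    return _split_outside_parens(text, _is_clause_sep)


def segment_chunks(clause: str) -> list[str]:
    """Split a clause at top-level commas; parenthetical commas do not split."""
    return _split_outside_parens(clause, lambda t, i: t[i] == ",")
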