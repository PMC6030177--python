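"""Spanish→English term translation and state→character-name resolution.

Character names ("shape", "colouration", "architecture", ...) rarely appear
in descriptions; only states do ("elíptica", "blanca", "simple").  The
pipeline therefore translates each Spanish state to English and looks the
English term up in a character-name index distilled from plant-glossary
controlled vocabularies.  Both resources ship as frozen TSV snapshots so
results are reproducible offline; user glossaries can be layered on top.

A state may be indexed under several character names (e.g. "elliptic" under
both "arrangement" and "shape"); all of them are reported and flagged for
expert disambiguation downstream.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

#: verbatim note attached to every duplicate emitted for a multi-name state
REPEATED_CHARACTER_NOTE = "Carácter repetido"

#: character name used when a state is absent from the index
UNKNOWN_CHARACTER = "unknown_character"


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _data_path(name: str) -> Path:
    ref = importlib.resources.files("morphex.data") / name
    with importlib.resources.as_file(ref) as p:
        return p


@dataclass
class BilingualGlossary:
    """Spanish norm-term → (English term, source tag).

    Lookup is total: bundled glossary, then user layers (later layers win),
    then identity with source "untranslated".
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "BilingualGlossary":
        g = cls()
        g.load_tsv(_data_path("glossary_es_en.tsv"), source="glossary")
        return g

    def load_tsv(self, path: str | Path, source: str = "user") -> None:
        for row in _read_tsv(Path(path)):
            self.entries[row[0]] = (row[1], source)

    def translate(self, term_es: str) -> tuple[str, str]:
        key = term_es.lower()
        if key in self.entries:
            return self.entries[key]
        return (term_es, "untranslated")


@dataclass
class CharacterNameIndex:
    """English state term → alphabetically ordered candidate character names."""

    entries: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CharacterNameIndex":
        idx = cls()
        idx.load_tsv(_data_path("character_names.tsv"))
        return idx

    def load_tsv(self, path: str | Path) -> None:
        for row in _read_tsv(Path(path)):
            names = self.entries.setdefault(row[0], [])
            if row[1] not in names:
                names.append(row[1])
        for names in self.entries.values():
            names.sort()

    def character_names(self, state_en: str) -> list[str]:
        return list(self.entries.get(state_en.lower(), []))


@dataclass
class Glossary:
    """Facade bundling translation and character-name resolution."""

    bilingual: BilingualGlossary = field(default_factory=BilingualGlossary.default)
    index: CharacterNameIndex = field(default_factory=CharacterNameIndex.default)

    def translate(self, term_es: str) -> tuple[str, str]:
        return self.bilingual.translate(term_es)

    def character_names(self, state_en: str) -> list[str]:
        return self.index.character_names(state_en)

    def resolve_state(self, state_es: str) -> tuple[str, list[str], bool]:
        """Translate a Spanish state and resolve its candidate character names.

        Returns ``(state_en, names, known)``; unknown states map to the
        ``unknown_character`` placeholder with ``known=False`` — never a crash.
        """
        state_en, _src = self.translate(state_es)
        names = self.character_names(state_en)
        if not names:
            return (state_en, [UNKNOWN_CHARACTER], False)
        return (state_en, names, True)
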