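"""Token-role tagging for telegraphic Spanish botanical text.

General-purpose POS taggers are reliable on closed-class Spanish words
(prepositions, determiners, conjunctions, adverbs) but mislabel the
Latin-derived open-class vocabulary of taxonomic descriptions.  This module
therefore combines

* a bundled lexicon of closed-class function words, measurement units and
  common botanical nouns (E) and character states (A),
* a :class:`KnowledgeBase` of token roles learned from the corpus itself by
  an iterative, rule-driven bootstrapping loop, and
* a suffix heuristic for grammatical gender and number (with an explicit
  exception list), which the association stage needs for agreement checks.

Numerals, ranges and the dimension symbol "×" are recognised structurally
and always receive Z/G tags, whatever the lexicon says.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from .core_model import Chunk, Token

CLOSED_TAGS = frozenset("SCDRUV")
OPEN_TAGS = frozenset("EA")

# numbers, ranges and the open-ended atypical forms "-22" / "13-"
_NUM = r"\d+(?:\.\d+)?"
TOKEN_RE = re.compile(
    rf"""
      (?P<num>-{_NUM}|{_NUM}-{_NUM}|{_NUM}-(?!\w)|{_NUM})
    | (?P<dim>×)
    | (?P<word>[^\W\d_]+(?:-[^\W\d_]+)*\.?)
    | (?P<punct>[^\s()])
    """,
    re.VERBOSE | re.UNICODE,
)

#: suffix → (gender, number); consulted in order, longest suffix first
_SUFFIX_RULES = [
    ("as", ("feminine", "plural")),
    ("os", ("masculine", "plural")),
    ("es", ("unknown", "plural")),
    ("a", ("feminine", "singular")),
    ("o", ("masculine", "singular")),
    ("e", ("unknown", "singular")),
    ("s", ("unknown", "plural")),
]

ARTICLES = frozenset({"el", "la", "los", "las", "un", "una", "unos", "unas", "lo"})


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
class Lexicon:
    """Token → tag map plus gender/number exceptions.

    Closed-class entries (S/C/D/R/U/V) may be multi-word ("a lo largo de",
    "rara vez"); they are matched greedily, longest first, during
    tokenization.
    """

    entries: dict[str, str] = field(default_factory=dict)
    exceptions: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # one tag per token: the dict structure itself keeps the closed-class
        # lists disjoint from the open-class (E/A) entries
        self._multiword = sorted(
            (k for k in self.entries if " " in k), key=lambda k: -k.count(" ")
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, exceptions_path: str | Path | None = None
    ) -> "Lexicon":
        entries = {r[0]: r[1] for r in _read_tsv(Path(path))}
        exceptions = {}
        if exceptions_path is not None:
            exceptions = {r[0]: (r[1], r[2]) for r in _read_tsv(Path(exceptions_path))}
        return cls(entries, exceptions)

    @classmethod
    def default(cls) -> "Lexicon":
        return cls.from_tsv(_data_path("lexicon.tsv"), _data_path("exceptions.tsv"))

    def multiword_entries(self) -> list[str]:
        return list(self._multiword)


@dataclass
class KBEntry:
    tag: str
    rule: str
    iteration: int


@dataclass
class KnowledgeBase:
    """Token roles learned from the corpus; grows monotonically."""

    entries: dict[str, KBEntry] = field(default_factory=dict)

    def add(self, norm: str, tag: str, rule: str, iteration: int) -> bool:
        """Record a learned role; existing knowledge is never overwritten."""
        if norm in self.entries:
            return False
        self.entries[norm] = KBEntry(tag, rule, iteration)
        return True

    def save_tsv(self, path: str | Path) -> None:
        lines = ["# token\ttag\trule\titeration"]
        for norm in sorted(self.entries):
            e = self.entries[norm]
            lines.append(f"{norm}\t{e.tag}\t{e.rule}\t{e.iteration}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnowledgeBase":
        return cls(
            {r[0]: KBEntry(r[1], r[2], int(r[3])) for r in _read_tsv(Path(path))}
        )


def morphology(norm: str, lexicon: Lexicon | None = None) -> tuple[str, str]:
    """Gender and number of a Spanish token by suffix heuristic.

    The exception list (nouns whose ending belies their gender, e.g. "base",
    "ápice") wins over the suffix rules.  Words that do not mark gender
    ("verde") come out as unknown, which the association stage treats as
    agreeing with anything.  Non-alphabetic tokens are fully unknown.
    """
    if lexicon is not None and norm in lexicon.exceptions:
        return lexicon.exceptions[norm]
    if not norm or not all(c.isalpha() or c == "-" for c in norm) or not norm[0].isalpha():
        return ("unknown", "unknown")
    for suffix, gn in _SUFFIX_RULES:
        if norm.endswith(suffix) and len(norm) > len(suffix):
            return gn
    return ("unknown", "unknown")


def _norm(surface: str) -> str:
    stripped = surface.rstrip(".").lower()
    return stripped if stripped else surface


def _raw_tokens(text: str) -> list[tuple[str, bool]]:
    """Split into (surface, in_parens) pairs, dropping the parens themselves."""
    out: list[tuple[str, bool]] = []
    depth = 0
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            depth += 1
            i += 1
            continue
        if ch == ")":
            depth = max(0, depth - 1)
            i += 1
            continue
        if ch.isspace():
            i += 1
            continue
        m = TOKEN_RE.match(text, i)
        if m is None:  # pragma: no cover - TOKEN_RE's punct branch is total
            i += 1
            continue
        out.append((m.group(0), depth > 0))
        i = m.end()
    return out


def _merge_multiword(
    pairs: list[tuple[str, bool]], lexicon: Lexicon
) -> list[tuple[str, bool]]:
    merged: list[tuple[str, bool]] = []
    i = 0
    mw = [e.split(" ") for e in lexicon.multiword_entries()]
    while i < len(pairs):
        hit = None
        for words in mw:
            n = len(words)
            if i + n <= len(pairs) and [
                _norm(s) for s, _ in pairs[i : i + n]
            ] == words and len({p for _, p in pairs[i : i + n]}) == 1:
                hit = n
                break
        if hit:
            surface = " ".join(s for s, _ in pairs[i : i + hit])
            merged.append((surface, pairs[i][1]))
            i += hit
        else:
            merged.append(pairs[i])
            i += 1
    return merged


def tag(
    raw: str,
    lexicon: Lexicon,
    kb: KnowledgeBase | None = None,
    chunk_id: str = "S1",
) -> Chunk:
    """Tokenize and tag one chunk.

    Lookup order: structural (numbers → Z, "×" → G), lexicon, knowledge
    base, unknown (X).  Gender and number come from :func:`morphology`.
    """
    kb = kb or KnowledgeBase()
    tokens: list[Token] = []
    pairs = _merge_multiword(_raw_tokens(raw), lexicon)
    for idx, (surface, in_parens) in enumerate(pairs):
        norm = _norm(surface)
        m = TOKEN_RE.match(surface)
        if m and m.lastgroup == "num" and m.end() == len(surface):
            t = "Z"
        elif surface == "×":
            t = "G"
        elif m and m.lastgroup == "punct":
            t = "F"
        elif norm in lexicon.entries:
            t = lexicon.entries[norm]
        elif norm in kb.entries:
            t = kb.entries[norm].tag
        else:
            t = "X"
        gender, number = ("unknown", "unknown") if t in "ZGF" else morphology(norm, lexicon)
        tokens.append(
            Token(
                surface=surface,
                norm=norm,
                tag=t,
                gender=gender,
                number=number,
                index=idx,
                in_parens=in_parens,
            )
        )
    return Chunk(id=chunk_id, raw=raw, tokens=tokens)


# --------------------------------------------------------------- bootstrap

@dataclass
class BootstrapRule:
    """A pattern over a tagged token sequence that assigns roles to unknowns.

    ``apply`` returns {norm: tag} for X-tagged tokens the rule can resolve.
    Rules never touch closed-class or structurally tagged tokens.
    """

    id: str
    apply: Callable[[list[Token]], dict[str, str]]


def _a_propagation(tokens: list[Token]) -> dict[str, str]:
    # tokens linked by the preposition "a": if one is a character state (A),
    # the others play the same role.
    out: dict[str, str] = {}
    i = 0
    while i < len(tokens):
        if tokens[i].tag in ("A", "X"):
            group = [tokens[i]]
            j = i + 1
            while (
                j + 1 < len(tokens)
                and tokens[j].tag == "S"
                and tokens[j].norm == "a"
                and tokens[j + 1].tag in ("A", "X")
            ):
                group.append(tokens[j + 1])
                j += 2
            if len(group) > 1 and any(t.tag == "A" for t in group):
                for t in group:
                    if t.tag == "X":
                        out[t.norm] = "A"
            i = j
        else:
            i += 1
    return out


def _coordination_propagation(tokens: list[Token]) -> dict[str, str]:
    # extension rule: conjuncts across "o"/"u"/"y"/"e" share the state role
    out: dict[str, str] = {}
    for i in range(1, len(tokens) - 1):
        if tokens[i].tag == "C" and tokens[i].norm in ("o", "u", "y", "e"):
            left, right = tokens[i - 1], tokens[i + 1]
            pair = {left.tag, right.tag}
            if pair == {"A", "X"}:
                unknown = left if left.tag == "X" else right
                out[unknown.norm] = "A"
    return out


DEFAULT_RULES = [
    BootstrapRule("a_state_propagation", _a_propagation),
    BootstrapRule("coordination_state_propagation", _coordination_propagation),
]


def bootstrap(
    corpus: Iterable[str],
    lexicon: Lexicon,
    kb: Optional[KnowledgeBase] = None,
    rules: Optional[list[BootstrapRule]] = None,
    max_iterations: int = 10,
) -> KnowledgeBase:
    """Grow *kb* by iterating the rules to a fixpoint over *corpus*.

    Each cycle re-tags every chunk with the current knowledge and applies
    each rule; newly resolved tokens are added with their rule id and the
    iteration number.  Stops when a full pass adds nothing or after
    *max_iterations* cycles.  The knowledge base only ever grows.
    """
    kb = kb if kb is not None else KnowledgeBase()
    rules = rules if rules is not None else DEFAULT_RULES
    chunks = list(corpus)
    for iteration in range(1, max_iterations + 1):
        added = False
        for raw in chunks:
            tagged = tag(raw, lexicon, kb)
            for rule in rules:
                for norm, role in sorted(rule.apply(tagged.tokens).items()):
                    if norm in lexicon.entries:
                        continue  # never overwrite lexical knowledge
                    if kb.add(norm, role, rule.id, iteration):
                        added = True
        if not added:
            break
    return kb
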