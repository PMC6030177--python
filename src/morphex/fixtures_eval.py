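"""Synthetic telegraphic descriptions with gold annotations, and scoring.

The generator emulates the dominant chunk grammars of Costa Rican plant
descriptions — noun + state, bare state, measurement with unit and measured
noun ("6-30 m de altura"), two-dimension expressions with atypical extremes,
coordinations, adverb constraints, con/sin prepositional relations and the
non-adjacent agreement pattern in which a plural state skips an intervening
singular substructure.  Because the generator builds the gold annotation by
construction, a corpus of any size carries an exact expected output, which
turns the whole pipeline into a property test: precision, recall and F-1
must be 100% on every aspect for in-grammar corpora.

The scores mirror the four evaluation aspects commonly reported for this
task: identification of structures, character structuring, association of
characters to structures, and association of conjunctions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Sequence

from .core_model import (
    AnnotatedDescription,
    Character,
    Clause,
    IdFactory,
    Relation,
    Structure,
    validate,
)
from .glossary import REPEATED_CHARACTER_NOTE, Glossary
from .xml_io import DescriptionRecord

ASPECTS = ("structures", "characters", "association", "conjunctions")


class AlignmentError(ValueError):
    """Predicted and gold corpora have different lengths."""


# --------------------------------------------------------------- vocabulary

#: (surface, gender, number); gender/number as the tagger will derive them
NOUNS = {
    ("feminine", "plural"): [
        "hojas", "flores", "semillas", "venas", "brácteas", "estípulas",
        "ramas", "yemas", "espinas", "glándulas",
    ],
    ("masculine", "plural"): [
        "frutos", "pétalos", "sépalos", "tallos", "pelos", "racimos",
        "estambres", "domacios", "tricomas",
    ],
    ("masculine", "singular"): [
        "ápice", "margen", "envés", "arilo", "ovario", "estigma", "tallo",
    ],
    ("feminine", "singular"): [
        "base", "lámina", "corteza", "corola", "panícula", "vena",
    ],
}

#: adjective stems (add o/a/os/as) with their single character name
ADJ_FAMILIES = [
    ("blanc", "colouration"), ("roj", "colouration"), ("negr", "colouration"),
    ("amarillent", "colouration"), ("pálid", "colouration"), ("verdos", "colouration"),
    ("agud", "shape"), ("obtus", "shape"), ("redondead", "shape"),
    ("cordad", "shape"), ("oblong", "shape"), ("lanceolad", "shape"),
    ("ovad", "shape"), ("acuminad", "shape"), ("caudad", "shape"),
    ("enter", "architecture"), ("aserrad", "architecture"), ("dentad", "architecture"),
    ("crenad", "architecture"), ("lobulad", "architecture"),
    ("altern", "arrangement"), ("opuest", "arrangement"),
    ("fasciculad", "arrangement"), ("dispers", "arrangement"),
    ("glabr", "pubescence"), ("tomentos", "pubescence"), ("hirsut", "pubescence"),
    ("decidu", "duration"), ("coriáce", "texture"), ("lis", "texture"),
    ("rugos", "texture"),
]

#: "elíptico" resolves to two character names (repeated-character path)
TWO_NAME_FAMILY = ("elíptic", ("arrangement", "shape"))

ADVERBS = [
    "levemente", "finamente", "densamente", "esparcidamente", "ligeramente",
    "escasamente", "usualmente",
]
QUANTIFIERS = {
    ("feminine", "plural"): ["varias", "numerosas", "muchas", "pocas"],
    ("masculine", "plural"): ["varios", "numerosos", "muchos", "pocos"],
}
UNITS = ["cm", "mm", "m"]
DIM_NOUNS = [("altura", "height"), ("longitud", "length"),
             ("diámetro", "diameter"), ("ancho", "width")]

_SUFFIX = {
    ("masculine", "singular"): "o",
    ("feminine", "singular"): "a",
    ("masculine", "plural"): "os",
    ("feminine", "plural"): "as",
}

DEFAULT_WEIGHTS = {
    # shares of the four classic chunk grammars, as observed in printed
    # frequency tables for tree descriptions
    "name_adj": 0.175,
    "adj_only": 0.125,
    "measure_unit": 0.098,
    "dimension": 0.042,
    # extension patterns exercising the remaining rule paths
    "name_adj_conj": 0.14,
    "adverb_adj": 0.14,
    "agreement_fallback": 0.14,
    "con_relation": 0.14,
}


@dataclass
class FixtureGrammar:
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern weights sum to {total}, expected 1")


@dataclass
class GoldAnnotation:
    """The exact annotation a correct pipeline must produce for one record."""

    record: DescriptionRecord
    annotation: AnnotatedDescription
    conjunction_groups: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)


@dataclass
class AspectScore:
    precision: float
    recall: float
    f1: float
    undefined_precision: bool = False


@dataclass
class AspectScores:
    scores: dict[str, AspectScore]

    def to_rows(self) -> list[dict]:
        return [
            {
                "aspect": a,
                "precision": round(s.precision, 1),
                "recall": round(s.recall, 1),
                "f1": round(s.f1, 1),
            }
            for a, s in self.scores.items()
        ]


# --------------------------------------------------------------- generation

class _GoldBuilder:
    """Accumulates gold objects for one description in creation order."""

    def __init__(self, taxon_name: str, glossary: Glossary) -> None:
        self.ids = IdFactory()
        self.desc = AnnotatedDescription(taxon_name=taxon_name)
        self.glossary = glossary
        self.groups: list[tuple[str, tuple[str, ...]]] = []

    def structure(
        self, name: str, clause_id: str, constraint: Optional[str] = None,
        modifier: Optional[str] = None,
    ) -> Structure:
        s = Structure(
            id=self.ids.next_id("structure"),
            name=name,
            name_en=self.glossary.translate(name)[0],
            constraint=constraint,
            modifier=modifier,
            clause_id=clause_id,
        )
        self.desc.structures.append(s)
        return s

    def character(self, structure: Structure, name: str, value: str, **kw) -> Character:
        c = Character(
            id=self.ids.next_id("character"),
            structure_id=structure.id,
            name=name,
            value=value,
            **kw,
        )
        self.desc.characters.append(c)
        return c

    def state(
        self, structure: Structure, value: str, constraint: Optional[str] = None,
        conj: Optional[str] = None, names: Optional[Sequence[str]] = None,
    ) -> list[Character]:
        """Gold characters for one state, honouring the repeated-character rule."""
        if names is None:
            _en, names, _known = self.glossary.resolve_state(value.split()[0])
        notes = []
        if len(names) > 1:
            notes.append(REPEATED_CHARACTER_NOTE)
        if conj:
            notes.append(f"conjunción: {conj}")
        return [
            self.character(
                structure, n, value,
                constraint=constraint, notes="; ".join(notes) or None,
            )
            for n in names
        ]


def _inflect(stem: str, gender: str, number: str) -> str:
    return stem + _SUFFIX[(gender, number)]


def generate(
    grammar: FixtureGrammar | None,
    n_clauses: int,
    seed: int,
    glossary: Glossary | None = None,
) -> tuple[list[DescriptionRecord], list[GoldAnnotation]]:
    """Deterministically generate *n_clauses* one-clause records with gold."""
    grammar = grammar or FixtureGrammar()
    glossary = glossary or Glossary()
    rng = random.Random(seed)
    patterns = sorted(grammar.weights)
    weights = [grammar.weights[p] for p in patterns]
    records: list[DescriptionRecord] = []
    golds: list[GoldAnnotation] = []
    for i in range(n_clauses):
        pattern = rng.choices(patterns, weights=weights)[0]
        taxon = f"Taxon fixtum {i + 1}"
        builder = _GoldBuilder(taxon, glossary)
        chunks = _PATTERNS[pattern](rng, builder, clause_id=f"T{i + 1}L1")
        clause_raw = ", ".join(chunks)
        builder.desc.clauses.append(
            Clause(
                id=f"T{i + 1}L1",
                raw=clause_raw,
                main_structure_id=(
                    builder.desc.structures[0].id if builder.desc.structures else None
                ),
            )
        )
        assert not validate(builder.desc), validate(builder.desc)
        records.append(DescriptionRecord(taxon, clause_raw + "."))
        golds.append(GoldAnnotation(records[-1], builder.desc, builder.groups))
    return records, golds


def _pick_noun(rng: random.Random, numbers=("plural", "singular")) -> tuple[str, str, str]:
    keys = [k for k in NOUNS if k[1] in numbers]
    gender, number = rng.choice(keys)
    return rng.choice(NOUNS[(gender, number)]), gender, number


def _pick_adjs(rng: random.Random, k: int, allow_two_name: bool = False):
    # distinct character names: same-name adjacent states would merge into
    # one character value and the gold would no longer be by-construction
    fams: list[tuple[str, Optional[str]]] = []
    names: set[str] = set()
    while len(fams) < k:
        stem, cname = rng.choice(ADJ_FAMILIES)
        if cname not in names:
            fams.append((stem, cname))
            names.add(cname)
    if allow_two_name and rng.random() < 0.25:
        fams[rng.randrange(k)] = (TWO_NAME_FAMILY[0], None)
    return fams


def _p_name_adj(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    fams = _pick_adjs(rng, rng.choice([1, 2]), allow_two_name=True)
    s = b.structure(noun, clause_id)
    words = [noun]
    for stem, _cname in fams:
        form = _inflect(stem, g, n)
        words.append(form)
        b.state(s, form)
    return [" ".join(words)]


def _p_adj_only(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    (stem1, _), (stem2, _) = _pick_adjs(rng, 2)
    s = b.structure(noun, clause_id)
    f1, f2 = _inflect(stem1, g, n), _inflect(stem2, g, n)
    b.state(s, f1)
    b.state(s, f2)
    return [f"{noun} {f1}", f2]


def _range(rng, lo=1, hi=40) -> tuple[Decimal, Decimal, str]:
    a = Decimal(rng.randrange(lo, hi))
    width = rng.randrange(1, 15)
    bb = a + width
    if rng.random() < 0.3:
        bb += Decimal("0.5")
    return a, bb, f"{a}-{bb}"


def _p_measure_unit(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    (stem, _), = _pick_adjs(rng, 1)
    s = b.structure(noun, clause_id)
    form = _inflect(stem, g, n)
    b.state(s, form)
    lo, hi, text = _range(rng)
    unit = rng.choice(UNITS)
    dim_es, dim_en = rng.choice(DIM_NOUNS)
    b.character(
        s, dim_en, text, char_type="range_value", from_=lo, to=hi,
        from_unit=unit, to_unit=unit,
    )
    return [f"{noun} {form}", f"{text} {unit} de {dim_es}"]


def _p_dimension(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    (stem, _), = _pick_adjs(rng, 1)
    s = b.structure(noun, clause_id)
    form = _inflect(stem, g, n)
    b.state(s, form)
    unit = rng.choice(UNITS)
    parts = []
    for name in ("length", "width"):
        lo, hi, text = _range(rng)
        atypical = None
        chunk_text = text
        if rng.random() < 0.5:
            atypical = hi + rng.randrange(1, 5)
            chunk_text = f"{text} (-{atypical})"
        b.character(
            s, name, text, char_type="range_value", from_=lo, to=hi,
            atypical_to=atypical, from_unit=unit, to_unit=unit,
        )
        parts.append(chunk_text)
    return [f"{noun} {form}", f"{parts[0]} × {parts[1]} {unit}"]


def _p_name_adj_conj(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    (stem1, cname1), = _pick_adjs(rng, 1)
    # two more states from the same character family for the coordination
    candidates = sorted(
        {
            c
            for _s, c in ADJ_FAMILIES
            if c != cname1 and sum(1 for _s2, c2 in ADJ_FAMILIES if c2 == c) >= 2
        }
    )
    cname2 = rng.choice(candidates)
    pool = [s for s, c in ADJ_FAMILIES if c == cname2]
    stem2, stem3 = rng.sample(pool, 2)
    s = b.structure(noun, clause_id)
    f1 = _inflect(stem1, g, n)
    b.state(s, f1)
    f2, f3 = _inflect(stem2, g, n), _inflect(stem3, g, n)
    conj = "u" if f3.startswith("o") else "o"
    b.state(s, f2, names=[cname2])
    b.state(s, f3, conj="o", names=[cname2])
    b.groups.append((noun, (f2, f3)))
    return [f"{noun} {f1}", f"{f2} {conj} {f3}"]


def _p_adverb_adj(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    noun, g, n = _pick_noun(rng)
    (stem, _), = _pick_adjs(rng, 1)
    adverb = rng.choice(ADVERBS)
    s = b.structure(noun, clause_id)
    form = _inflect(stem, g, n)
    if rng.random() < 0.3:
        # parenthetical alternative state: "(rara vez <other form>)"
        (stem2, _), = _pick_adjs(rng, 1)
        form2 = _inflect(stem2, g, n)
        b.state(s, form, constraint=f"rara vez {form2}")
        return [f"{noun} {form} (rara vez {form2})"]
    b.state(s, form, constraint=adverb)
    return [f"{noun} {adverb} {form}"]


def _p_agreement_fallback(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    """Plural state skips the singular substructure and links to the main one."""
    if rng.random() < 0.5:
        g_main, g_sub = ("feminine", "plural"), ("masculine", "singular")
    else:
        g_main, g_sub = ("masculine", "plural"), ("feminine", "singular")
    noun = rng.choice(NOUNS[g_main])
    sub = rng.choice(NOUNS[g_sub])
    fams = _pick_adjs(rng, 3)
    s_main = b.structure(noun, clause_id)
    f1 = _inflect(fams[0][0], *g_main)
    b.state(s_main, f1)
    s_sub = b.structure(sub, clause_id)
    f2 = _inflect(fams[1][0], *g_sub)
    b.state(s_sub, f2)
    f3 = _inflect(fams[2][0], *g_main)
    b.state(s_main, f3)  # agreement skips s_sub
    return [f"{noun} {f1}", f"{sub} {f2}", f3]


def _p_con_relation(rng, b: _GoldBuilder, clause_id: str) -> list[str]:
    gn = rng.choice([("feminine", "plural"), ("masculine", "plural")])
    noun = rng.choice(NOUNS[gn])
    quant = rng.choice(QUANTIFIERS[gn])
    noun2, g2, n2 = _pick_noun(rng)
    while noun2 == noun:
        noun2, g2, n2 = _pick_noun(rng)
    s1 = b.structure(noun, clause_id, constraint=quant)
    s2 = b.structure(noun2, clause_id)
    negated = rng.random() < 0.3
    prep = "sin" if negated else "con"
    b.desc.relations.append(
        Relation(
            id=b.ids.next_id("relation"),
            name=prep,
            from_structure_id=s1.id,
            to_structure_id=s2.id,
            negated=negated,
            clause_id=clause_id,
        )
    )
    second = f"{prep} {noun2}"
    if not negated:
        (stem, _), = _pick_adjs(rng, 1)
        form = _inflect(stem, g2, n2)
        b.state(s2, form)
        second = f"{second} {form}"
    return [f"{noun} {quant}", second]


_PATTERNS = {
    "name_adj": _p_name_adj,
    "adj_only": _p_adj_only,
    "measure_unit": _p_measure_unit,
    "dimension": _p_dimension,
    "name_adj_conj": _p_name_adj_conj,
    "adverb_adj": _p_adverb_adj,
    "agreement_fallback": _p_agreement_fallback,
    "con_relation": _p_con_relation,
}


# ------------------------------------------------------------------ scoring

def _struct_key(s: Structure) -> tuple:
    return (s.name, s.modifier)


def _char_key(c: Character) -> tuple:
    return (
        c.name, c.value, c.char_type, str(c.from_), str(c.to),
        c.from_unit, c.to_unit, str(c.atypical_from), str(c.atypical_to),
    )


def extract_conjunction_groups(
    desc: AnnotatedDescription,
) -> list[tuple[str, tuple[str, ...]]]:
    """Recover coordinated state groups from character order and notes."""
    names = {s.id: s.name for s in desc.structures}
    groups: list[tuple[str, tuple[str, ...]]] = []
    head: Optional[Character] = None
    members: list[str] = []
    for c in desc.characters:
        conj = c.notes is not None and "conjunción:" in c.notes
        if (
            conj
            and head is not None
            and c.structure_id == head.structure_id
            and c.name == head.name
        ):
            members.append(c.value)
            continue
        if len(members) > 1 and head is not None:
            groups.append((names.get(head.structure_id, ""), tuple(members)))
        head, members = c, [c.value]
    if len(members) > 1 and head is not None:
        groups.append((names.get(head.structure_id, ""), tuple(members)))
    return groups


def _multiset_matches(pred: list, gold: list) -> int:
    from collections import Counter

    cp, cg = Counter(pred), Counter(gold)
    return sum(min(cp[k], cg[k]) for k in cp)


def score(
    predicted: Sequence[AnnotatedDescription],
    gold: Sequence[GoldAnnotation | AnnotatedDescription],
) -> AspectScores:
    """Micro-averaged precision/recall/F-1 over the four evaluation aspects.

    Matching is exact-string on normalised fields; an association counts
    only when a matched character is linked to a matched structure (by
    structure name); a conjunction counts only when the coordinated group is
    recovered in full.
    """
    if len(predicted) != len(gold):
        raise AlignmentError(
            f"{len(predicted)} predictions vs {len(gold)} gold annotations"
        )
    counts = {a: [0, 0, 0] for a in ASPECTS}  # matches, n_pred, n_gold
    for pred, g in zip(predicted, gold):
        gold_desc = g.annotation if isinstance(g, GoldAnnotation) else g
        gold_groups = (
            g.conjunction_groups
            if isinstance(g, GoldAnnotation)
            else extract_conjunction_groups(gold_desc)
        )
        pn = {s.id: s for s in pred.structures}
        gn = {s.id: s for s in gold_desc.structures}
        ps, gs = [_struct_key(s) for s in pred.structures], [
            _struct_key(s) for s in gold_desc.structures
        ]
        counts["structures"][0] += _multiset_matches(ps, gs)
        counts["structures"][1] += len(ps)
        counts["structures"][2] += len(gs)
        pc = [_char_key(c) for c in pred.characters]
        gc = [_char_key(c) for c in gold_desc.characters]
        counts["characters"][0] += _multiset_matches(pc, gc)
        counts["characters"][1] += len(pc)
        counts["characters"][2] += len(gc)
        pa = [
            (_char_key(c), _struct_key(pn[c.structure_id]))
            for c in pred.characters
            if c.structure_id in pn
        ]
        ga = [
            (_char_key(c), _struct_key(gn[c.structure_id]))
            for c in gold_desc.characters
            if c.structure_id in gn
        ]
        counts["association"][0] += _multiset_matches(pa, ga)
        counts["association"][1] += len(pa)
        counts["association"][2] += len(ga)
        pg = extract_conjunction_groups(pred)
        counts["conjunctions"][0] += _multiset_matches(pg, gold_groups)
        counts["conjunctions"][1] += len(pg)
        counts["conjunctions"][2] += len(gold_groups)
    scores = {}
    for aspect, (m, np_, ng) in counts.items():
        undefined = np_ == 0
        p = 100.0 * m / np_ if np_ else (100.0 if ng == 0 else 0.0)
        r = 100.0 * m / ng if ng else 100.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        scores[aspect] = AspectScore(p, r, f1, undefined_precision=undefined and ng > 0)
    return AspectScores(scores)


def complexity(desc: AnnotatedDescription, clause_id: str) -> str:
    """"simple" for a clause with at most two structures, else "complex"."""
    n = sum(1 for s in desc.structures if s.clause_id == clause_id)
    return "simple" if n <= 2 else "complex"
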