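from decimal import Decimal

import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphex.annotator import (
    ClauseContext,
    MeasurementParseError,
    agree,
    associate,
    measurement_characters,
    parse_measurement,
    render_measurement,
)
from morphex.core_model import IdFactory, Structure, validate
from morphex.preprocess import normalize
from morphex.tagging import tag
from .conftest import HYDRANGEA_CLAUSE, QUERCUS_CLAUSE


def _chars_by_value(desc, value):
    return [c for c in desc.characters if c.value == value]


def _structure_name(desc, sid):
    return next(s.name for s in desc.structures if s.id == sid)


# ----------------------------------------------------------- measurements

class TestMeasurements:
    def _measure(self, annotator, text):
        tokens = tag(normalize(text), annotator.lexicon).tokens
        m = parse_measurement(tokens, 0, annotator.glossary)
        return measurement_characters(m, IdFactory(), "s")

    def test_two_dimension_expression_yields_length_and_width(self, annotator):
        length, width = self._measure(annotator, "5-18 x 1.5-9 cm")
        assert (length.name, length.value, length.char_type) == (
            "length", "5-18", "range_value",
        )
        assert (length.from_, length.to) == (Decimal("5"), Decimal("18"))
        assert (length.from_unit, length.to_unit) == ("cm", "cm")
        assert (width.name, width.from_, width.to) == (
            "width", Decimal("1.5"), Decimal("9"),
        )
        assert (width.from_unit, width.to_unit) == ("cm", "cm")

    def test_atypical_upper_bounds(self, annotator):
        length, width = self._measure(annotator, "9.5-19 (-22) × 4-7 (-8) cm")
        assert (length.from_, length.to, length.atypical_to) == (
            Decimal("9.5"), Decimal("19"), Decimal("22"),
        )
        assert (width.to, width.atypical_to) == (Decimal("7"), Decimal("8"))

    def test_atypical_prefix_sets_lower_bound(self, annotator):
        (char,) = self._measure(annotator, "(2-) 4-10 cm")
        assert (char.atypical_from, char.from_, char.to) == (
            Decimal("2"), Decimal("4"), Decimal("10"),
        )

    def test_unit_with_measured_noun_names_the_character(self, annotator):
        (char,) = self._measure(annotator, "6-30 m de altura")
        assert (char.name, char.from_, char.to, char.from_unit) == (
            "height", Decimal("6"), Decimal("30"), "m",
        )

    def test_malformed_sequence_raises(self, annotator):
        tokens = tag("× 5", annotator.lexicon).tokens
        with pytest.raises(MeasurementParseError):
            parse_measurement(tokens, 0, annotator.glossary)

    def test_malformed_measurement_survives_as_plain_value(self, annotator):
        # inverted range cannot be structured; the text must not be lost
        d = annotator.annotate("x", "hojas simples, 10-4 cm.")
        plain = [c for c in d.characters if c.notes and "no estructurado" in c.notes]
        assert len(plain) == 1 and "10-4" in plain[0].value

    @given(
        lo=st.decimals(min_value=0, max_value=50, places=1),
        width=st.decimals(min_value=Decimal("0.5"), max_value=20, places=1),
        atypical=st.integers(min_value=1, max_value=9),
        unit=st.sampled_from(["cm", "mm", "m"]),
    )
    def test_render_then_parse_is_identity(self, lo, width, atypical, unit):
        annotator = _get_annotator()
        hi = lo + width
        text = f"{lo}-{hi} (-{hi + atypical}) {unit}"
        tokens = tag(text, annotator.lexicon).tokens
        m = parse_measurement(tokens, 0, annotator.glossary)
        assert render_measurement(m) == text
        tokens2 = tag(render_measurement(m), annotator.lexicon).tokens
        m2 = parse_measurement(tokens2, 0, annotator.glossary)
        assert m2 == m


# ------------------------------------------------------------ association

def _ctx(*specs):
    ctx = ClauseContext(clause_id="T1L1")
    for i, (name, g, n) in enumerate(specs, start=1):
        ctx.structures_so_far.append(
            Structure(id=f"o{i}", name=name, gender=g, number=n)
        )
    ctx.main_structure_id = ctx.structures_so_far[0].id if specs else None
    return ctx


class TestAssociate:
    def test_agreement_skips_non_matching_substructures(self):
        ctx = _ctx(
            ("hojas", "feminine", "plural"),
            ("ápice", "masculine", "singular"),
            ("base", "feminine", "singular"),
        )
        assert associate("feminine", "plural", ctx) == "o1"  # glabras → hojas

    def test_recent_agreeing_structure_wins(self):
        ctx = _ctx(
            ("hojas", "feminine", "plural"),
            ("ápice", "masculine", "singular"),
        )
        assert associate("masculine", "singular", ctx) == "o2"

    def test_unknown_agrees_with_anything(self):
        ctx = _ctx(("hojas", "feminine", "plural"), ("base", "feminine", "singular"))
        assert associate("unknown", "unknown", ctx) == "o2"

    def test_fallback_to_main_structure(self):
        ctx = _ctx(("hojas", "feminine", "plural"), ("base", "feminine", "singular"))
        assert associate("masculine", "plural", ctx) == "o1"

    def test_no_structure_returns_none(self):
        assert associate("feminine", "plural", _ctx()) is None

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["masculine", "feminine", "unknown"]),
                st.sampled_from(["singular", "plural", "unknown"]),
            ),
            min_size=1,
            max_size=6,
        ),
        st.sampled_from(["masculine", "feminine", "unknown"]),
        st.sampled_from(["singular", "plural", "unknown"]),
    )
    def test_matches_brute_force_oracle(self, gns, g, n):
        ctx = _ctx(*[(f"s{i}", gg, nn) for i, (gg, nn) in enumerate(gns)])
        # oracle: enumerate all (character, structure) pairs, apply the
        # agreement predicate, prefer the most recent agreeing structure
        agreeing = [
            s.id
            for s in ctx.structures_so_far
            if agree(g, s.gender) and agree(n, s.number)
        ]
        expected = agreeing[-1] if agreeing else ctx.main_structure_id
        assert associate(g, n, ctx) == expected


_ANNOTATOR = None


def _get_annotator():
    global _ANNOTATOR
    if _ANNOTATOR is None:
        from morphex.annotator import Annotator

        _ANNOTATOR = Annotator()
    return _ANNOTATOR


# ------------------------------------------------------- printed examples

@pytest.fixture(scope="module")
def quercus_desc(annotator):
    return annotator.annotate("Quercus salicifolia", QUERCUS_CLAUSE)


@pytest.fixture(scope="module")
def hydrangea_desc(annotator):
    return annotator.annotate("Hydrangea asterolasia", HYDRANGEA_CLAUSE)


class TestQuercusClause:
    @pytest.fixture()
    def desc(self, quercus_desc):
        return quercus_desc

    def test_structures_extracted(self, desc):
        names = [s.name for s in desc.structures]
        assert names[:3] == ["hojas", "ápice", "base"]
        # prepositional-phrase entities extracted for subsequent use
        assert {"tricomas", "vena", "envés"} <= set(names)

    def test_glabras_links_to_hojas_not_base(self, desc):
        (glabras,) = _chars_by_value(desc, "glabras")
        assert _structure_name(desc, glabras.structure_id) == "hojas"

    def test_acuminado_links_to_apex(self, desc):
        (c,) = _chars_by_value(desc, "acuminado")
        assert _structure_name(desc, c.structure_id) == "ápice"

    def test_coordinated_states_follow_their_substructures(self, desc):
        for value, target in [
            ("caudado", "ápice"), ("agudo", "ápice"),
            ("caudada", "base"), ("obtusa", "base"),
        ]:
            (c,) = _chars_by_value(desc, value)
            assert _structure_name(desc, c.structure_id) == target, value
        (agudo,) = _chars_by_value(desc, "agudo")
        assert "conjunción: o" in (agudo.notes or "")
        (obtusa,) = _chars_by_value(desc, "obtusa")
        assert "conjunción: o" in (obtusa.notes or "")  # "u" normalised

    def test_repeated_character_for_ellipticas(self, desc):
        chars = _chars_by_value(desc, "elípticas")
        assert sorted(c.name for c in chars) == ["arrangement", "shape"]
        assert all(c.notes == "Carácter repetido" for c in chars)

    def test_measurement_describes_the_leaves(self, desc):
        (length,) = [c for c in desc.characters if c.name == "length"]
        assert _structure_name(desc, length.structure_id) == "hojas"
        assert (length.from_, length.to, length.atypical_to) == (
            Decimal("4"), Decimal("10"), Decimal("14"),
        )
        (width,) = [c for c in desc.characters if c.name == "width"]
        assert (width.from_, width.to) == (Decimal("1"), Decimal("3.3"))

    def test_prepositional_span_is_delimited_not_lost(self, desc):
        (span,) = [
            s for s in desc.constraint_spans if s.kind == "constraint_preposition"
        ]
        assert span.text == "a lo largo de la vena central por el envés"

    def test_output_validates(self, desc):
        assert validate(desc) == []

    def test_annotation_is_deterministic(self, annotator, desc):
        again = annotator.annotate("Quercus salicifolia", QUERCUS_CLAUSE)
        assert again == desc


class TestHydrangeaFailureMode:
    """The documented association error is reproduced, not fixed."""

    @pytest.fixture()
    def desc(self, hydrangea_desc):
        return hydrangea_desc

    def test_aguda_wrongly_sticks_to_base(self, desc):
        (aguda,) = _chars_by_value(desc, "aguda")
        assert _structure_name(desc, aguda.structure_id) == "base"

    def test_oblonga_correctly_links_to_lamina(self, desc):
        (c,) = _chars_by_value(desc, "oblonga")
        assert _structure_name(desc, c.structure_id) == "lámina"

    def test_adverb_becomes_constraint(self, desc):
        (c,) = _chars_by_value(desc, "acuminada")
        assert c.constraint == "cortamente"


class TestRelationsAndSpans:
    def test_con_phrase_builds_a_relation(self, annotator):
        d = annotator.annotate("x", "semillas varias, con arilo anaranjado.")
        (rel,) = d.relations
        assert rel.name == "con" and not rel.negated
        assert _structure_name(d, rel.from_structure_id) == "semillas"
        assert _structure_name(d, rel.to_structure_id) == "arilo"
        (colour,) = [c for c in d.characters if c.name == "colouration"]
        assert _structure_name(d, colour.structure_id) == "arilo"
        (semillas,) = [s for s in d.structures if s.name == "semillas"]
        assert semillas.constraint == "varias"

    def test_sin_phrase_is_negated(self, annotator):
        d = annotator.annotate("x", "frutos lisos, sin espinas.")
        (rel,) = d.relations
        assert rel.name == "sin" and rel.negated
        assert _structure_name(d, rel.to_structure_id) == "espinas"

    def test_verb_phrase_is_delimited(self, annotator):
        d = annotator.annotate(
            "x", "flores blancas, que salen en grupos de 3 en la parte distal."
        )
        (span,) = [s for s in d.constraint_spans if s.kind == "verb_string"]
        assert span.text.startswith("que salen en grupos")
        assert _structure_name(d, span.attached_to) == "flores"

    def test_verb_span_with_no_prior_structure_defers_to_main(self, annotator):
        d = annotator.annotate("x", "que salen en grupos, flores blancas.")
        (span,) = [s for s in d.constraint_spans if s.kind == "verb_string"]
        assert _structure_name(d, span.attached_to) == "flores"


class TestAdverbAndDeterminerRules:
    def test_adverb_before_state_becomes_its_constraint(self, annotator):
        d = annotator.annotate("x", "margen finamente aserrado.")
        (c,) = _chars_by_value(d, "aserrado")
        assert c.constraint == "finamente" and c.name == "architecture"

    def test_bare_adverb_state_chunk(self, annotator):
        d = annotator.annotate("x", "hojas alternas, levemente revolutas.")
        (c,) = _chars_by_value(d, "revolutas")
        assert c.constraint == "levemente"

    def test_parenthetical_becomes_constraint_of_preceding_state(self, annotator):
        d = annotator.annotate("x", "hojas simples, alternas (rara vez opuestas).")
        (c,) = _chars_by_value(d, "alternas")
        assert c.constraint == "rara vez opuestas"

    def test_quantifier_without_entity_modifies_current_structure(self, annotator):
        d = annotator.annotate("x", "flores blancas, varias por racimo.")
        (flores,) = [s for s in d.structures if s.name == "flores"]
        assert flores.constraint == "varias"
        (span,) = [
            s for s in d.constraint_spans if s.kind == "constraint_preposition"
        ]
        assert span.text == "por racimo"

    def test_article_is_consumed_silently(self, annotator):
        d = annotator.annotate("x", "el margen dentado.")
        (margen,) = [s for s in d.structures if s.name == "margen"]
        assert margen.constraint is None
        (c,) = _chars_by_value(d, "dentado")
        assert _structure_name(d, c.structure_id) == "margen"


class TestEntityRules:
    def test_apposed_noun_becomes_modifier(self, annotator):
        d = annotator.annotate("x", "frutos nueces.")
        (s,) = d.structures
        assert (s.name, s.modifier) == ("frutos", "nueces")

    def test_merged_colouration_states(self, annotator):
        d = annotator.annotate("x", "flores verde amarillento pálido a verdosas.")
        (c,) = [ch for ch in d.characters if ch.name == "colouration"]
        assert c.value == "verde amarillento pálido a verdosas"
        assert _structure_name(d, c.structure_id) == "flores"

    def test_stateless_chunk_uses_whole_plant_pseudo_structure(self, annotator):
        d = annotator.annotate("x", "deciduas.")
        (s,) = d.structures
        assert s.name == "planta" and s.notes == "estructura implícita"
        (c,) = _chars_by_value(d, "deciduas")
        assert c.structure_id == s.id
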