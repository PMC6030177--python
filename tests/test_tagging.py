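import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphex.tagging import (
    KnowledgeBase,
    Lexicon,
    bootstrap,
    morphology,
    tag,
)


class TestTag:
    @pytest.mark.parametrize(
        "text,tags",
        [
            ("hojas simples", ["E", "A"]),
            ("6-30 m de altura", ["Z", "U", "S", "E"]),
            ("zzz", ["X"]),
            ("inflorescencias fasciculadas", ["E", "A"]),
            ("6-30 × 2-10.5 cm", ["Z", "G", "Z", "U"]),
            ("varias por racimo", ["D", "S", "E"]),
            ("el margen dentado", ["D", "E", "A"]),
        ],
    )
    def test_tag_sequences(self, lexicon, text, tags):
        assert [t.tag for t in tag(text, lexicon).tokens] == tags

    def test_numerals_outrank_the_lexicon(self, lexicon):
        tokens = tag("4-10 (-14) × 1-3.3 cm.", lexicon).tokens
        assert [t.tag for t in tokens] == ["Z", "Z", "G", "Z", "U"]
        assert tokens[1].in_parens and tokens[1].norm == "-14"

    def test_multiword_closed_class_entries_merge(self, lexicon):
        tokens = tag("a veces con tricomas a lo largo de la vena", lexicon).tokens
        assert (tokens[0].surface, tokens[0].tag) == ("a veces", "R")
        assert ("a lo largo de", "S") in [(t.surface, t.tag) for t in tokens]

    def test_token_indices_are_contiguous(self, lexicon):
        tokens = tag("hojas simples (rara vez opuestas)", lexicon).tokens
        assert [t.index for t in tokens] == list(range(len(tokens)))

    def test_closed_class_tokens_never_become_states(self, lexicon):
        kb = KnowledgeBase()
        kb.add("con", "A", "bogus", 1)  # must not shadow the lexicon
        assert tag("con", lexicon, kb).tokens[0].tag == "S"


class TestMorphology:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("glabras", ("feminine", "plural")),
            ("acuminado", ("masculine", "singular")),
            ("dispersos", ("masculine", "plural")),
            ("verde", ("unknown", "singular")),
            ("x1", ("unknown", "unknown")),
        ],
    )
    def test_suffix_rules(self, token, expected):
        assert morphology(token) == expected

    def test_exception_list_beats_suffixes(self, lexicon):
        # "base" ends in -e but is feminine singular; "ápice" is masculine
        assert morphology("base", lexicon) == ("feminine", "singular")
        assert morphology("ápice", lexicon) == ("masculine", "singular")
        assert morphology("tricomas", lexicon) == ("masculine", "plural")


class TestBootstrap:
    def test_a_propagation_learns_states(self, lexicon):
        kb = bootstrap(["redondeada a cordada a subcordadísima"], lexicon)
        # "redondeada" and "cordada" are lexical states; the unknown form
        # in the same "a"-chain inherits the role
        assert kb.entries["subcordadísima"].tag == "A"
        assert kb.entries["subcordadísima"].rule == "a_state_propagation"

    def test_empty_corpus_changes_nothing(self, lexicon):
        kb = KnowledgeBase()
        out = bootstrap([], lexicon, kb)
        assert out.entries == {}

    def test_chained_propagation_reaches_exhaustive_closure(self, lexicon):
        # the dependent chunk comes first, so a single pass cannot finish
        corpus = ["zzzb a zzza", "redondeada a zzzb"]
        kb = bootstrap(corpus, lexicon)
        assert {k: e.tag for k, e in kb.entries.items()} == {
            "zzza": "A",
            "zzzb": "A",
        }
        assert kb.entries["zzzb"].iteration == 1
        assert kb.entries["zzza"].iteration == 2
        # brute-force closure: saturate the "linked by a / linked by o"
        # relation starting from known states
        known = {"redondeada"}
        links = [("zzzb", "zzza"), ("redondeada", "zzzb")]
        changed = True
        while changed:
            changed = False
            for x, y in links:
                for a, b in ((x, y), (y, x)):
                    if a in known and b not in known:
                        known.add(b)
                        changed = True
        assert set(kb.entries) == known - {"redondeada"}

    def test_monotone_and_idempotent_at_fixpoint(self, lexicon):
        corpus = ["redondeada a zzzc", "zzzc a zzzd"]
        kb = bootstrap(corpus, lexicon)
        before = dict(kb.entries)
        kb2 = bootstrap(corpus, lexicon, kb)
        assert kb2 is kb and kb.entries == before

    def test_fixpoint_is_order_independent(self, lexicon):
        chunks = ["zzzf a zzze", "redondeada a zzzf", "zzze o zzzg"]
        results = []
        for perm in itertools.permutations(chunks):
            kb = bootstrap(list(perm), lexicon)
            results.append({k: e.tag for k, e in kb.entries.items()})
        assert all(r == results[0] for r in results)

    def test_kb_roundtrips_through_tsv(self, lexicon, tmp_path):
        kb = bootstrap(["redondeada a zzzh"], lexicon)
        p = tmp_path / "kb.tsv"
        kb.save_tsv(p)
        kb2 = KnowledgeBase.from_tsv(p)
        assert kb2.entries == kb.entries


@given(st.text(alphabet="abcdeáéó ,-().×0123456789", max_size=60))
def test_tagging_is_total_and_deterministic(text):
    lexicon = test_tagging_lexicon
    c1, c2 = tag(text, lexicon), tag(text, lexicon)
    assert [t.surface for t in c1.tokens] == [t.surface for t in c2.tokens]
    assert all(t.tag in set("EAZRDCSUGVFX") for t in c1.tokens)


test_tagging_lexicon = Lexicon.default()
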