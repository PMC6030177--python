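import copy

import pytest

from morphex.core_model import validate
from morphex.fixtures_eval import (
    ASPECTS,
    AlignmentError,
    FixtureGrammar,
    complexity,
    extract_conjunction_groups,
    generate,
    score,
)


class TestGenerate:
    def test_empty_request(self):
        assert generate(None, 0, seed=1) == ([], [])

    def test_same_seed_same_output(self):
        a = generate(None, 30, seed=7)
        b = generate(None, 30, seed=7)
        assert a == b

    def test_different_seeds_differ(self):
        a, _ = generate(None, 30, seed=7)
        b, _ = generate(None, 30, seed=8)
        assert [r.description for r in a] != [r.description for r in b]

    def test_gold_annotations_validate(self):
        _, golds = generate(None, 50, seed=2)
        for g in golds:
            assert validate(g.annotation) == []

    def test_pattern_shares_track_the_weights(self):
        # the name+adjective grammar at weight 0.175 over n=1000 clauses:
        # observed share within ±3 points (binomial bound)
        records, _ = generate(None, 1000, seed=9)
        single_chunk = sum(1 for r in records if ", " not in r.description)
        # name_adj (0.175) and 70% of adverb_adj (0.14·0.7≈0.10) are the
        # only single-chunk patterns
        share = single_chunk / 1000
        assert abs(share - (0.175 + 0.14)) < 0.06

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FixtureGrammar(weights={"name_adj": 0.4})


class TestScore:
    def _pair(self, n=15, seed=3):
        _, golds = generate(None, n, seed=seed)
        return [g.annotation for g in golds], golds

    def test_perfect_prediction_scores_100_everywhere(self):
        preds, golds = self._pair()
        s = score(preds, golds).scores
        assert all(s[a].precision == s[a].recall == s[a].f1 == 100.0 for a in ASPECTS)

    def test_empty_predictions_are_zero_with_flag(self):
        preds, golds = self._pair(n=5)
        preds = copy.deepcopy(preds)
        for p in preds:
            p.structures, p.characters, p.relations = [], [], []
        s = score(preds, golds).scores
        assert s["structures"].precision == 0.0 and s["structures"].recall == 0.0
        assert s["structures"].undefined_precision

    def test_one_wrong_association_in_ten(self):
        preds, golds = self._pair(n=40, seed=4)
        # corrupt associations until exactly 10% of characters are mislinked
        preds = copy.deepcopy(preds)
        total = sum(len(p.characters) for p in preds)
        to_break = total // 10
        broken = 0
        for p in preds:
            if broken >= to_break:
                break
            for c in p.characters:
                others = [s.id for s in p.structures if s.id != c.structure_id]
                if others and broken < to_break:
                    c.structure_id = others[0]
                    broken += 1
        s = score(preds, golds).scores
        expected = 100.0 * (total - broken) / total
        assert s["association"].precision == pytest.approx(expected, abs=0.01)
        assert s["association"].recall == pytest.approx(expected, abs=0.01)
        # structure and character identification are untouched
        assert s["structures"].f1 == 100.0
        assert s["characters"].f1 == 100.0

    def test_score_ignores_id_relabeling(self):
        preds, golds = self._pair(n=20, seed=6)
        relabeled = copy.deepcopy(preds)
        for p in relabeled:
            mapping = {s.id: f"q{i}" for i, s in enumerate(p.structures)}
            for s in p.structures:
                s.id = mapping[s.id]
            for c in p.characters:
                c.structure_id = mapping[c.structure_id]
            for r in p.relations:
                r.from_structure_id = mapping[r.from_structure_id]
                r.to_structure_id = mapping[r.to_structure_id]
        s = score(relabeled, golds).scores
        assert all(s[a].f1 == 100.0 for a in ASPECTS)

    def test_length_mismatch_raises(self):
        preds, golds = self._pair(n=4)
        with pytest.raises(AlignmentError):
            score(preds[:-1], golds)


class TestConjunctionGroups:
    def test_groups_recovered_from_notes(self, annotator):
        d = annotator.annotate(
            "x", "hojas simples, ápice acuminado, caudado o agudo."
        )
        assert extract_conjunction_groups(d) == [("ápice", ("caudado", "agudo"))]


class TestComplexity:
    @pytest.mark.parametrize("n_structures,expected", [
        (0, "simple"), (2, "simple"), (3, "complex"),
    ])
    def test_two_structure_threshold(self, annotator, n_structures, expected):
        nouns = ["hojas", "ápice", "base"][:n_structures]
        text = ", ".join(f"{n} zzz" for n in nouns) or "zzz"
        d = annotator.annotate("x", text + ".")
        d.structures = [s for s in d.structures if s.name != "planta"]
        assert complexity(d, d.clauses[0].id) == expected
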