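"""Synthetic corpus generator: pairs, negatives, augmentation, splitting."""

import numpy as np
import pytest

from synthaction import actionlang as al
from synthaction import synthcorpus as sc
from synthaction.errors import AugmentError, ConfigError, SizeError
from synthaction.filters import admissible_procedure


class TestGeneratePairs:
    def test_zero_pairs(self):
        assert sc.generate_pairs(sc.GeneratorConfig(n=0, seed=0)) == []

    def test_seeded_determinism(self):
        a = sc.generate_pairs(sc.GeneratorConfig(n=100, seed=9))
        b = sc.generate_pairs(sc.GeneratorConfig(n=100, seed=9))
        assert [(p.sentence, p.structured) for p in a] == [
            (p.sentence, p.structured) for p in b]

    def test_pair_invariants(self, small_pairs):
        for p in small_pairs:
            seq = al.parse_structured(p.structured, mode="strict")
            for clause in seq.clauses:
                for chem in clause.chemicals:
                    if not chem.is_solution_ref:
                        assert chem.name in p.sentence

    def test_slot_provenance_occurs_on_both_sides(self, small_pairs):
        for p in small_pairs:
            for surface in p.slots.values():
                assert surface in p.sentence
                assert surface in p.structured

    def test_empty_lexicon_rejected(self):
        lex = sc.default_lexicons()
        lex.compounds = ()
        with pytest.raises(ConfigError):
            sc.generate_pairs(sc.GeneratorConfig(n=5, lexicons=lex))

    def test_zero_weights_rejected(self):
        with pytest.raises(ConfigError):
            sc.generate_pairs(sc.GeneratorConfig(
                n=5, action_weights={"Add": 0.0}))

    def test_action_frequencies_follow_weights(self):
        # sampled primary-action distribution tracks the configured weights
        pairs = sc.generate_pairs(sc.GeneratorConfig(n=20000, seed=1))
        counts = {}
        for p in pairs:
            for a in p.actions:
                counts[a] = counts.get(a, 0) + 1
        total = sum(counts.values())
        wt = sum(sc.DEFAULT_ACTION_WEIGHTS.values())
        for action, weight in sc.DEFAULT_ACTION_WEIGHTS.items():
            expected = weight / wt
            if expected * total < 1000:
                continue  # relative tolerance is meaningless at tiny counts
            observed = counts.get(action, 0) / total
            assert abs(observed - expected) / expected < 0.10


class TestNegatives:
    def test_all_negatives_fail_admission(self):
        for record in sc.generate_negatives(100, seed=21):
            ok, violations = admissible_procedure(record)
            assert not ok and violations

    def test_zero_and_determinism(self):
        assert sc.generate_negatives(0) == []
        a = sc.generate_negatives(50, seed=3)
        b = sc.generate_negatives(50, seed=3)
        assert [r.text for r in a] == [r.text for r in b]


class TestClassificationSet:
    def test_positive_fraction(self):
        records = sc.generate_classification_set(5000, seed=17)
        positives = sum(r.label for r in records)
        assert abs(positives / 5000 - 0.336) <= 0.02

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigError):
            sc.generate_classification_set(10, positive_fraction=1.5)


class TestAugment:
    def _augmentable(self, pairs):
        for p in pairs:
            kinds = {k.rsplit("_", 1)[0] for k in p.slots}
            if kinds & {"temperature", "duration", "solvent", "compound",
                        "product"}:
                yield p

    def test_k_zero_returns_empty(self, small_pairs):
        pair = next(self._augmentable(small_pairs))
        assert sc.augment(pair, 0) == []

    def test_k_above_cap_rejected(self, small_pairs):
        with pytest.raises(ValueError):
            sc.augment(small_pairs[0], 5)

    def test_variants_consistent_and_parse_strict(self, small_pairs):
        n_variants = 0
        for pair in list(self._augmentable(small_pairs))[:120]:
            for variant in sc.augment(pair, 4, seed=31):
                seq = al.parse_structured(variant.structured, mode="strict")
                assert seq.action_types == al.parse_structured(
                    pair.structured).action_types
                for surface in variant.slots.values():
                    assert surface in variant.sentence
                    assert surface in variant.structured
                assert variant.origin == "augmented"
                assert variant.parent_id == pair.id
                n_variants += 1
        assert n_variants > 100

    def test_substitution_changes_both_sides_identically(self, small_pairs):
        for pair in list(self._augmentable(small_pairs))[:40]:
            for variant in sc.augment(pair, 2, seed=5):
                changed_sent = variant.sentence != pair.sentence
                changed_struct = variant.structured != pair.structured
                assert changed_sent == changed_struct

    def test_pair_without_slots_raises(self):
        bare = sc.CorpusPair(sentence="The mixture was filtered.",
                             structured="FILTER.", slots={}, id="x")
        with pytest.raises(AugmentError):
            sc.augment(bare, 1)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (20_199, (16_159, 2_020, 2_020)),
        (3_074_038, (2_459_230, 307_404, 307_404)),
        (10, (8, 1, 1)),
    ])
    def test_split_sizes(self, n, expected):
        train, val, test = sc.split(np.arange(n), seed=0)
        assert (len(train), len(val), len(test)) == expected

    def test_partition_property_over_random_sizes(self):
        rng = np.random.default_rng(0)
        for n in rng.integers(3, 10**6, size=100):
            n = int(n)
            train, val, test = sc.split(range(n), seed=int(n))
            assert len(train) + len(val) + len(test) == n
            assert len(set(train) | set(val) | set(test)) == n

    def test_too_small_rejected(self):
        with pytest.raises(SizeError):
            sc.split([1, 2], seed=0)


class TestRuleOracle:
    def test_oracle_inverts_generator(self, small_pairs):
        for p in small_pairs:
            assert sc.rule_oracle_translate(p.sentence) == p.structured

    def test_unknown_sentence_becomes_invalidaction(self):
        out = sc.rule_oracle_translate("The frobnicator was engaged.")
        assert out.startswith("INVALIDACTION")


class TestIO:
    def test_tsv_and_jsonl_roundtrip(self, small_pairs, tmp_path):
        tsv = tmp_path / "pairs.tsv"
        jsonl = tmp_path / "pairs.jsonl"
        sc.write_pairs_tsv(small_pairs[:20], tsv)
        sc.write_pairs_jsonl(small_pairs[:20], jsonl)
        tsv_pairs = sc.read_pairs_tsv(tsv)
        jl_pairs = sc.read_pairs_jsonl(jsonl)
        assert [(p.sentence, p.structured) for p in tsv_pairs] == [
            (p.sentence, p.structured) for p in small_pairs[:20]]
        assert [p.slots for p in jl_pairs] == [
            p.slots for p in small_pairs[:20]]
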