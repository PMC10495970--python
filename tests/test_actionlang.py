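"""Grammar, parser and serializer of the structured action language."""

import pytest

from synthaction import actionlang as al
from synthaction import synthcorpus as sc
from synthaction.errors import (EmptyInput, InvalidSequence, MalformedClause,
                                UnknownAction)


def test_exactly_28_action_types_with_uppercase_surfaces():
    assert len(al.ActionType) == 28
    assert len({a.surface for a in al.ActionType}) == 28
    assert al.ActionType.MakeSolution.surface == "MAKESOLUTION"
    assert al.ActionType.CollectLayer.surface == "COLLECTLAYER"
    assert all(a.surface == a.surface.upper() for a in al.ActionType)


class TestParse:
    def test_partition_with_two_amounts(self):
        seq = al.parse_structured(
            "PARTITION with dichloromethane (10 mL) and water (10 mL).")
        assert len(seq.clauses) == 1
        clause = seq.clauses[0]
        assert clause.action is al.ActionType.Partition
        assert [c.name for c in clause.chemicals] == [
            "dichloromethane", "water"]
        assert [c.amount for c in clause.chemicals] == ["10 mL", "10 mL"]

    def test_clause_count_and_keep_phase(self):
        seq = al.parse_structured(
            "ADD Ethanol; ADD water; FILTER keep precipitate.")
        assert len(seq.clauses) == 3
        assert seq.clauses[2].keep_phase == "precipitate"
        assert seq.clauses[0].chemicals[0].name == "Ethanol"

    def test_sln_is_reserved_not_a_chemical_name(self):
        seq = al.parse_structured("ADD SLN.")
        chem = seq.clauses[0].chemicals[0]
        assert chem.is_solution_ref and chem.name == ""

    def test_nested_parentheses_in_names(self):
        seq = al.parse_structured(
            "MAKESOLUTION with 3-cyano-4-((1-methylethyl)oxy)benzoic acid"
            " (200 mg) and tetrahydrofuran (THF) (10 mL).")
        names = [c.name for c in seq.clauses[0].chemicals]
        assert names == ["3-cyano-4-((1-methylethyl)oxy)benzoic acid",
                         "tetrahydrofuran (THF)"]
        assert [c.amount for c in seq.clauses[0].chemicals] == [
            "200 mg", "10 mL"]

    def test_purify_solvent_list_and_ratio(self):
        seq = al.parse_structured("PURIFY: hexane:ethyl acetate (3:1).")
        clause = seq.clauses[0]
        assert clause.purify_solvents == ["hexane", "ethyl acetate"]
        assert clause.purify_ratio == "3:1"

    def test_trailing_modifiers(self):
        seq = al.parse_structured("STIR at 25 °C for 2 h; WAIT for 30 min.")
        assert seq.clauses[0].temperature == "25 °C"
        assert seq.clauses[0].duration == "2 h"
        assert seq.clauses[1].duration == "30 min"

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInput):
            al.parse_structured("")
        with pytest.raises(EmptyInput):
            al.parse_structured("   ")

    def test_unknown_keyword_strict_vs_lenient(self):
        with pytest.raises(UnknownAction):
            al.parse_structured("FROB with water.", mode="strict")
        seq = al.parse_structured("FROB with water.", mode="lenient")
        assert seq.clauses[0].action is al.ActionType.InvalidAction
        assert "FROB" in seq.clauses[0].free_params

    def test_malformed_payload_strict(self):
        with pytest.raises(MalformedClause):
            al.parse_structured("FILTER keep organic.", mode="strict")
        with pytest.raises(MalformedClause):
            al.parse_structured("CONCENTRATE vigorously.", mode="strict")

    def test_keywords_case_insensitive_on_input(self):
        seq = al.parse_structured("add water; filter keep filtrate.")
        assert seq.clauses[0].action is al.ActionType.Add
        assert al.serialize(seq) == "ADD water; FILTER keep filtrate."


class TestSerialize:
    def test_empty_sequence_invalid(self):
        with pytest.raises(InvalidSequence):
            al.serialize(al.ActionSequence(clauses=[]))

    def test_programmatic_makesolution(self):
        seq = al.ActionSequence(clauses=[al.ActionClause(
            action=al.ActionType.MakeSolution,
            chemicals=[
                al.ChemicalMention(name="A", amount="1 mL"),
                al.ChemicalMention(name="B", amount="2 mg"),
            ])])
        text = al.serialize(seq)
        assert text == "MAKESOLUTION with A (1 mL) and B (2 mg)."
        reparsed = al.parse_structured(text)
        assert al.serialize(reparsed) == text

    def test_quench_extract_roundtrip(self):
        s = "QUENCH with saturated aqueous NH4Cl; EXTRACT with CH2Cl2."
        assert al.serialize(al.parse_structured(s)) == s


class TestValidate:
    def test_wellformed_sequence_has_no_violations(self, table1_structured):
        seq = al.parse_structured(table1_structured[4])
        assert al.validate(seq) == []

    def test_keep_phase_restricted_to_filter_collectlayer(self):
        clause = al.ActionClause(action=al.ActionType.Purify,
                                 keep_phase="filtrate",
                                 purify_solvents=["hexane"])
        violations = al.validate(al.ActionSequence(clauses=[clause]))
        assert len(violations) == 1
        assert violations[0].rule == "keep_scope"
        assert violations[0].clause == 0

    def test_filter_with_layer_phase_invalid(self):
        clause = al.ActionClause(action=al.ActionType.Filter,
                                 keep_phase="organic")
        violations = al.validate(al.ActionSequence(clauses=[clause]))
        assert [v.rule for v in violations] == ["keep_value"]


class TestRoundTripProperties:
    def test_worked_examples_roundtrip_byte_identical(self, table1_structured):
        for s in table1_structured:
            seq = al.parse_structured(s, mode="strict")
            assert al.serialize(seq) == al.normalize(s) == s

    def test_thousand_generated_strings_roundtrip(self):
        pairs = sc.generate_pairs(sc.GeneratorConfig(n=1000, seed=77))
        for p in pairs:
            seq = al.parse_structured(p.structured, mode="strict")
            assert al.serialize(seq) == al.normalize(p.structured)

    def test_parse_determinism(self):
        s = "ADD EDC (374 mg); STIR at 25 °C for 2 h."
        a = al.parse_structured(s)
        b = al.parse_structured(s)
        assert al.serialize(a) == al.serialize(b)
        assert a.action_types == b.action_types

    def test_clause_count_equals_separators_plus_one(self):
        pairs = sc.generate_pairs(sc.GeneratorConfig(n=200, seed=5))
        for p in pairs:
            seq = al.parse_structured(p.structured)
            assert len(seq.clauses) == p.structured.count(";") + 1

    def test_missing_final_period_tolerated(self):
        assert al.serialize(al.parse_structured("ADD water")) == "ADD water."
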