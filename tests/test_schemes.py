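"""Tests for scheme registration, instantiation, embedding and critical
questions."""

import pytest

from eqrbot.af_core import AcceptanceMode
from eqrbot.errors import ConfigurationError, DomainError, InstantiationError
from eqrbot.knowledge_base import parse_kb
from eqrbot.schemes import (
    ArgumentScheme,
    Element,
    evaluate_instances,
    embed_aspt_in_eqr,
    generate_cq_attacks,
    get_scheme,
    instantiate_scheme,
    most_relevant_field,
    most_reliable_expert,
    register_builtin_schemes,
    register_scheme,
    Ontology,
)


def eqr_bindings(frida):
    onto = frida.ontology
    els = onto.elements()
    return {
        "R": els["covid_state"],
        "E": els["nice"],
        "F": els["covid_management"],
        "alpha": els["paracetamol_administering"],
        "S": els["fever_reduction"],
        "A": els["covid_control"],
        "v": els["wellbeing"],
    }


class TestRegistry:
    def test_eqr_has_seven_variables(self):
        assert get_scheme("EQR").variables == frozenset(
            {"R", "E", "F", "alpha", "S", "A", "v"}
        )

    def test_aspt_variables(self):
        assert get_scheme("ASPT").variables == frozenset({"Ft", "G", "T"})

    def test_unknown_scheme_absent(self):
        assert get_scheme("UNKNOWN") is None

    def test_idempotent(self):
        assert register_builtin_schemes() is register_builtin_schemes()

    def test_duplicate_registration_rejected(self):
        clash = get_scheme("ASO")
        with pytest.raises(ConfigurationError):
            register_scheme(clash)

    def test_unused_variable_rejected(self):
        with pytest.raises(ConfigurationError):
            ArgumentScheme("BAD", ("no placeholders",), "none", frozenset({"X"}))


class TestInstantiation:
    def test_eqr_premise_two(self, frida):
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        assert inst.premises[1] == (
            "acting upon the administering of paracetamol (from an expert "
            "the NICE guidelines in a field medical management of COVID-19)"
        )

    def test_missing_binding_names_variable(self, frida):
        bindings = eqr_bindings(frida)
        del bindings["v"]
        with pytest.raises(InstantiationError, match="'v'"):
            instantiate_scheme(get_scheme("EQR"), bindings)

    def test_aspt_cefalexin_conclusion(self):
        inst = instantiate_scheme(
            get_scheme("ASPT"),
            {
                "T": Element("cefalexin", "cefalexin"),
                "Ft": Element("chest", "the chest-infection facts"),
                "G": Element("cure", "cure the infection"),
            },
        )
        assert inst.conclusion == "Treatment cefalexin should be considered"

    def test_unknown_element_rejected_against_ontology(self, frida, frida_kb):
        bindings = eqr_bindings(frida)
        bindings["v"] = Element("ghost", "a ghost value")
        with pytest.raises(DomainError):
            instantiate_scheme(get_scheme("EQR"), bindings, frida_kb)

    def test_substitution_faithfulness(self, frida):
        # every bound text can be read back from the rendered output
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        rendered = " ".join((*inst.premises, inst.conclusion))
        assert "[" not in rendered  # no placeholder survives
        for _, el in inst.bindings:
            assert el.text in rendered


class TestEmbedding:
    def aspt(self, frida):
        els = frida.ontology.elements()
        return instantiate_scheme(
            get_scheme("ASPT"),
            {
                "T": els["paracetamol_administering"],
                "Ft": els["covid_state"],
                "G": els["covid_control"],
            },
        )

    def test_produces_worked_example_bindings(self, frida):
        els = frida.ontology.elements()
        eqr = embed_aspt_in_eqr(
            self.aspt(frida),
            {
                "E": els["nice"],
                "F": els["covid_management"],
                "S": els["fever_reduction"],
                "v": els["wellbeing"],
            },
        )
        assert dict(eqr.bindings) == eqr_bindings(frida)

    def test_alpha_round_trips_to_treatment(self, frida):
        els = frida.ontology.elements()
        eqr = embed_aspt_in_eqr(
            self.aspt(frida),
            {
                "E": els["nice"],
                "F": els["covid_management"],
                "S": els["fever_reduction"],
                "v": els["wellbeing"],
            },
        )
        assert eqr.binding("alpha") == self.aspt(frida).binding("T")

    def test_missing_extra_binding(self, frida):
        els = frida.ontology.elements()
        with pytest.raises(InstantiationError, match="'E'"):
            embed_aspt_in_eqr(
                self.aspt(frida),
                {"F": els["covid_management"], "S": els["fever_reduction"], "v": els["wellbeing"]},
            )

    def test_non_aspt_input_is_type_error(self, frida):
        eqr = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        with pytest.raises(TypeError):
            embed_aspt_in_eqr(eqr, {})


class TestCriticalQuestions:
    def instance(self, frida):
        return instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))

    def attacks_by_cq(self, frida, kb):
        return {
            arg.payload.id
            for arg, (src, dst) in generate_cq_attacks(self.instance(frida), kb)
            if dst == self.instance(frida).id
        }

    def test_all_rebutted_yields_empty_attack_set(self, frida, frida_kb):
        assert generate_cq_attacks(self.instance(frida), frida_kb) == []

    def test_missing_expert_field_link_triggers_cq3(self, frida, frida_kb):
        facts = frozenset(
            f for f in frida_kb.facts if f.predicate != "expert_in"
        )
        kb = parse_kb("").with_ontology(frida.ontology).with_facts(facts)
        assert "EQR.CQ3" in self.attacks_by_cq(frida, kb)

    def test_trustworthy_fact_silences_cq2(self, frida, frida_kb):
        assert "EQR.CQ2" not in self.attacks_by_cq(frida, frida_kb)

    def test_contradictory_entailments_trigger_cq6(self, frida, frida_kb):
        kb = frida_kb.with_facts(
            parse_kb(
                "entails(paracetamol_administering, calm).\n"
                "entails(paracetamol_administering, neg(calm)).\n"
            ).facts
        )
        assert "EQR.CQ6" in self.attacks_by_cq(frida, kb)

    def test_negative_value_triggers_cq10(self, frida, frida_kb):
        from eqrbot.schemes import Value

        onto = frida.ontology
        negative = Ontology(
            experts=onto.experts,
            fields=onto.fields,
            opinions=onto.opinions,
            prop=onto.prop,
            states=onto.states,
            values=(Value(Element("wellbeing", "the patient's wellbeing"), "negative"),),
            acting_upon=onto.acting_upon,
            extras=onto.extras,
        )
        kb = frida_kb.with_ontology(negative)
        assert "EQR.CQ10" in self.attacks_by_cq(frida, kb)

    def test_answer_fact_generates_defeater(self, frida, frida_kb):
        # drop the trustworthy rebuttal so CQ2 fires, then answer it
        facts = frozenset(f for f in frida_kb.facts if f.predicate != "trustworthy")
        kb = (
            parse_kb("cq_answered(eqr_cq2, paracetamol_administering).")
            .with_ontology(frida.ontology)
            .with_facts(facts)
        )
        out = generate_cq_attacks(self.instance(frida), kb)
        ids = [arg.id for arg, _ in out]
        assert any(i.endswith("~eqr_cq2") for i in ids)
        assert any(i.endswith("~eqr_cq2~answer") for i in ids)


class TestEvaluation:
    def test_unattacked_instance_accepted_under_every_semantics(self, frida, frida_kb):
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        for semantics in ("grounded", "complete", "preferred"):
            for attitude in ("skeptical", "credulous"):
                res = evaluate_instances(
                    [inst], frida_kb, AcceptanceMode(semantics, attitude)
                )
                assert res.status(inst) == "accepted"

    def test_undefeated_attack_rejects(self, frida, frida_kb):
        facts = frozenset(f for f in frida_kb.facts if f.predicate != "trustworthy")
        kb = parse_kb("").with_ontology(frida.ontology).with_facts(facts)
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        assert evaluate_instances([inst], kb).status(inst) == "rejected"

    def test_answered_attack_reinstates(self, frida, frida_kb):
        facts = frozenset(f for f in frida_kb.facts if f.predicate != "trustworthy")
        kb = (
            parse_kb("cq_answered(eqr_cq2, paracetamol_administering).")
            .with_ontology(frida.ontology)
            .with_facts(facts)
        )
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        assert evaluate_instances([inst], kb).status(inst) == "accepted"

    def test_adding_rebuttal_never_flips_accepted_to_rejected(self, frida, frida_kb):
        # start from a KB where CQ2 fires; the instance is rejected; adding
        # the rebuttal (or an answer) can only help under grounded semantics
        inst = instantiate_scheme(get_scheme("EQR"), eqr_bindings(frida))
        base = frozenset(f for f in frida_kb.facts if f.predicate != "trustworthy")
        weak = parse_kb("").with_ontology(frida.ontology).with_facts(base)
        strong = weak.with_facts(frida_kb.facts)
        assert evaluate_instances([inst], weak).status(inst) == "rejected"
        assert evaluate_instances([inst], strong).status(inst) == "accepted"
        # and an already-accepted instance stays accepted
        richer = strong.with_facts(
            parse_kb("cq_answered(eqr_cq1, paracetamol_administering).").facts
        )
        assert evaluate_instances([inst], richer).status(inst) == "accepted"


class TestHierarchies:
    def test_singleton_expert_is_most_reliable(self, frida_kb):
        onto = Ontology(
            experts=(Element("who", "the WHO guidelines"),),
        )
        assert most_reliable_expert(frida_kb, onto).id == "who"

    def test_singleton_field_is_most_relevant(self, frida_kb):
        onto = Ontology(fields=(Element("epi", "epidemiology"),))
        assert most_relevant_field(frida_kb, onto).id == "epi"

    def test_dominance_requires_ranking_facts(self, frida, frida_kb):
        assert most_reliable_expert(frida_kb, frida.ontology).id == "nice"
        kb = parse_kb("").with_ontology(frida.ontology).with_facts(
            frozenset(f for f in frida_kb.facts if f.predicate != "more_reliable")
        )
        assert most_reliable_expert(kb, frida.ontology) is None
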