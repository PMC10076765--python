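"""Scenarios: the packaged COVID-19 worked example and a seeded synthetic
generator.

A scenario bundles everything the pipeline needs — knowledge-base text,
ontology, explanation templates, scripted follow-up queries — together
with the outcomes it is expected to reproduce, so every module can be
exercised with no external data.

``run_pipeline`` is the end-to-end path: parse and saturate the knowledge
base, build one treatment-recommendation (EQR) instance per derived
``recommend`` fact, attach the supporting expert/field/alternative-option
instances, evaluate the resulting argumentation framework, and collect
the accepted instances into an explanation repository.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .errors import DomainError
from .explanation import (
    ExplanationRepository,
    ExplanationTemplate,
    build_repository,
    load_builtin_templates,
)
from .chatbot import Query
from .af_core import AcceptanceMode
from .knowledge_base import KnowledgeBase, parse_kb, query, saturate, write_kb
from .schemes import (
    DEFAULT_MODE,
    Element,
    EvaluationResult,
    Ontology,
    Opinion,
    SchemeInstance,
    State,
    Value,
    embed_aspt_in_eqr,
    evaluate_instances,
    get_scheme,
    instantiate_scheme,
    most_reliable_expert,
    most_relevant_field,
    safe_treatments,
)
from .knowledge_base import preferred_element

#: The rendered EQR explanation of the packaged COVID-19 scenario.
EXAMPLE_EXPLANATION = (
    "Given the patient's previous health record and the current fever and "
    "headache (due to COVID-19), the expertise of the NICE guidelines in "
    "the field of medical management of COVID-19 indicates the "
    "administering of paracetamol as an effective treatment. This should "
    "lead to the reduction of fever and headache which will bolster the "
    "goal of controlling the negative effect of the COVID-19 virus and "
    "promote the patient's wellbeing."
)


@dataclass(frozen=True)
class Scenario:
    """A self-consistent test scenario: inputs plus expected outcomes."""

    name: str
    kb_text: str
    ontology: Ontology
    templates: dict[str, ExplanationTemplate] = field(compare=False)
    queries: tuple[Query, ...] = ()
    expected_schemes: tuple[str, ...] = ()
    expected_snippets: tuple[str, ...] = ()
    supports: bool = True
    seed: Optional[int] = None


@dataclass(frozen=True)
class PipelineResult:
    kb: KnowledgeBase
    evaluation: EvaluationResult
    repository: ExplanationRepository


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------


def _eqr_instances(kb: KnowledgeBase) -> list[SchemeInstance]:
    """One embedded ASPT->EQR instance per ``recommend(T)`` fact."""
    onto: Ontology = kb.ontology
    elements = onto.elements()
    state_subst = query(kb, "initial_state(R)")
    if not state_subst:
        raise DomainError("the knowledge base designates no initial_state")
    current = elements[str(state_subst[0]["R"])]
    out = []
    for s in query(kb, "recommend(T)"):
        t = str(s["T"])
        links = query(kb, f"treatment_opinion({t}, O)")
        if not links:
            continue
        opinion: Opinion = onto.opinion(str(links[0]["O"]))
        goal = elements[str(query(kb, f"aims_at({opinion.element.id}, A)")[0]["A"])]
        value = elements[
            str(query(kb, f"promotes({opinion.element.id}, V)")[0]["V"])
        ]
        aspt = instantiate_scheme(
            get_scheme("ASPT"),
            {"Ft": current, "G": goal, "T": opinion.element},
            kb,
        )
        eqr = embed_aspt_in_eqr(
            aspt,
            {
                "E": elements[opinion.expert_id],
                "F": elements[opinion.field_id],
                "S": onto.state_acted_upon(opinion.element.id).element,
                "v": value,
            },
            kb,
        )
        out.append(eqr)
    return out


def _support_instances(
    eqr: SchemeInstance, kb: KnowledgeBase
) -> list[SchemeInstance]:
    """ASEXP/ASF/ASCO instances backing an EQR recommendation, built only
    when their dominance/safety premises hold in the knowledge base."""
    onto: Ontology = kb.ontology
    elements = onto.elements()
    out: list[SchemeInstance] = []
    expert = most_reliable_expert(kb, onto)
    if expert is not None and expert.id == eqr.binding("E").id:
        out.append(instantiate_scheme(get_scheme("ASEXP"), {"E": expert}, kb))
    fld = most_relevant_field(kb, onto)
    if fld is not None and fld.id == eqr.binding("F").id:
        out.append(
            instantiate_scheme(
                get_scheme("ASF"),
                {"F": fld, "R": eqr.binding("R"), "G": eqr.binding("A")},
                kb,
            )
        )
    safe = safe_treatments(kb)
    facts_subst = query(kb, "patient_facts(Ft)")
    if safe and facts_subst:
        chosen = preferred_element(kb, "treatment", safe)
        out.append(
            instantiate_scheme(
                get_scheme("ASCO"),
                {
                    "R": eqr.binding("R"),
                    "Ft": elements[str(facts_subst[0]["Ft"])],
                    "T": elements[chosen],
                },
                kb,
            )
        )
    return out


def run_pipeline(
    scenario: Scenario, mode: AcceptanceMode = DEFAULT_MODE
) -> PipelineResult:
    """Parse, saturate, instantiate, evaluate, and build the repository."""
    kb = parse_kb(scenario.kb_text).with_ontology(scenario.ontology)
    kb = saturate(kb)
    instances: list[SchemeInstance] = _eqr_instances(kb)
    if scenario.supports:
        supports: list[SchemeInstance] = []
        for eqr in instances:
            for sup in _support_instances(eqr, kb):
                if all(sup.id != prev.id for prev in supports):
                    supports.append(sup)
        instances = instances + supports
    evaluation = evaluate_instances(instances, kb, mode)
    repo = build_repository(evaluation, scenario.templates)
    return PipelineResult(kb, evaluation, repo)


# --------------------------------------------------------------------------
# The packaged COVID-19 (Frida) scenario
# --------------------------------------------------------------------------


def _frida_ontology() -> Ontology:
    covid_state = Element(
        "covid_state",
        "the patient's previous health record and the current fever and "
        "headache (due to COVID-19)",
    )
    fever_reduction = Element("fever_reduction", "the reduction of fever and headache")
    covid_control = Element(
        "covid_control", "controlling the negative effect of the COVID-19 virus"
    )
    return Ontology(
        experts=(
            Element("nice", "the NICE guidelines"),
            Element("nhs", "the NHS guidelines"),
        ),
        fields=(
            Element("covid_management", "medical management of COVID-19"),
            Element("general_medicine", "general medicine"),
        ),
        opinions=(
            Opinion(
                Element("paracetamol_administering", "the administering of paracetamol"),
                expert_id="nice",
                field_id="covid_management",
            ),
        ),
        prop=(covid_control,),
        states=(
            State(covid_state, (("covid_control", False),)),
            State(fever_reduction, (("covid_control", True),)),
        ),
        values=(Value(Element("wellbeing", "the patient's wellbeing"), "positive"),),
        acting_upon=(("paracetamol_administering", "fever_reduction"),),
        extras=(
            Element("frida_facts", "her pregnancy and current COVID-19 symptoms"),
            Element("paracetamol", "paracetamol"),
            Element("ibuprofen", "ibuprofen"),
        ),
    )


def frida_scenario() -> Scenario:
    """The packaged end-to-end scenario: a pregnant COVID-19 patient whose
    guideline-derived recommendation is paracetamol, with three scripted
    follow-ups about the expert, the field, and treatment alternatives."""
    kb_text = resources.files("eqrbot").joinpath("data", "frida.kb").read_text()
    return Scenario(
        name="frida",
        kb_text=kb_text,
        ontology=_frida_ontology(),
        templates=load_builtin_templates(),
        queries=(
            Query("expert reliability", "why NICE guidelines"),
            Query("field of expertise", "why is this field relevant to the recommendation"),
            Query("alternative treatment", "are there other drugs available"),
        ),
        expected_schemes=("ASEXP", "ASF", "ASCO"),
        expected_snippets=(EXAMPLE_EXPLANATION,),
        supports=True,
    )


# --------------------------------------------------------------------------
# Random abstract frameworks (for cross-checking the semantics solver)
# --------------------------------------------------------------------------


def generate_framework(
    seed: int, max_arguments: int = 12, attack_density: float = 0.25
):
    """A seeded random abstract framework with 1..``max_arguments``
    arguments; each ordered pair (self-attacks included) becomes an attack
    with probability ``attack_density``."""
    from .af_core import ArgumentationFramework

    rng = random.Random(seed)
    n = rng.randint(1, max_arguments)
    ids = [f"a{i}" for i in range(n)]
    attacks = [(x, y) for x in ids for y in ids if rng.random() < attack_density]
    return ArgumentationFramework(ids, attacks)


# --------------------------------------------------------------------------
# Seeded synthetic scenarios
# --------------------------------------------------------------------------

#: Closed vocabulary for synthetic premise texts, so matcher probes have
#: controllable overlap: shared scaffolding plus one unique token per
#: treatment ("remedyN").
_STATE_TEXT = "the recorded baseline condition of the patient"
_RELIEF_TEXT = "relief of the monitored symptoms after taking remedy{i}"
_GOAL_TEXT = "achieving recovery outcome{i} for the patient"
_OPINION_TEXT = "the prescribing of remedy{i}"

#: Per-instance rebuttal facts drawn with probability p each.
_REBUTTAL_PREDICATES = (
    "most_knowledgeable({e})",
    "trustworthy({e})",
    "expert_in({e}, {f})",
    "opinion_field({o}, {f})",
    "implies({o}, {a})",
    "based_on({o}, baseline_state)",
    "most_relevant({f})",
)


def generate_scenario(
    seed: int,
    n_experts: int = 3,
    n_fields: int = 3,
    n_treatments: int = 5,
    rebuttal_density: float = 1.0,
) -> Scenario:
    """A random ontology with one EQR instance per treatment.

    ``rebuttal_density`` is the probability that any given critical-question
    rebuttal fact is present: at 1.0 every instance is acceptable, at 0.0
    every instance is attacked and undefended (hence rejected under
    grounded semantics).  Byte-identical output for equal arguments.
    """
    if n_experts < 1 or n_fields < 1 or n_treatments < 1:
        raise DomainError("n_experts, n_fields and n_treatments must be >= 1")
    if not 0.0 <= rebuttal_density <= 1.0:
        raise DomainError("rebuttal_density must lie in [0, 1]")
    rng = random.Random(seed)

    experts = tuple(
        Element(f"expert{i}", f"the expert{i} guidance panel") for i in range(n_experts)
    )
    fields_ = tuple(
        Element(f"field{i}", f"the field{i} care discipline") for i in range(n_fields)
    )
    baseline = State(Element("baseline_state", _STATE_TEXT), tuple())
    opinions = []
    states = [baseline]
    props = []
    acting = []
    extras = []
    facts: list[str] = []
    for i in range(n_treatments):
        expert = experts[rng.randrange(n_experts)]
        fld = fields_[rng.randrange(n_fields)]
        o_id = f"opinion{i}"
        a_id = f"outcome{i}"
        s_id = f"relief{i}"
        opinions.append(
            Opinion(Element(o_id, _OPINION_TEXT.format(i=i)), expert.id, fld.id)
        )
        props.append(Element(a_id, _GOAL_TEXT.format(i=i)))
        states.append(State(Element(s_id, _RELIEF_TEXT.format(i=i)), tuple()))
        acting.append((o_id, s_id))
        facts.append(f"recommend(remedy{i}).")
        facts.append(f"treatment_opinion(remedy{i}, {o_id}).")
        facts.append(f"aims_at({o_id}, {a_id}).")
        facts.append(f"promotes({o_id}, wellbeing).")
        extras.append(Element(f"remedy{i}", f"remedy{i}"))
        for pattern in _REBUTTAL_PREDICATES:
            drawn = rng.random()
            if drawn < rebuttal_density:
                facts.append(
                    pattern.format(e=expert.id, f=fld.id, o=o_id, a=a_id) + "."
                )
    # states carry an empty proposition assignment only when Prop is empty;
    # here every state must assign all outcome propositions
    prop_ids = tuple(p.id for p in props)
    states = [
        State(s.element, tuple((p, False) for p in prop_ids)) for s in states
    ]
    facts.append("initial_state(baseline_state).")
    ontology = Ontology(
        experts=experts,
        fields=fields_,
        opinions=tuple(opinions),
        prop=tuple(props),
        states=tuple(states),
        values=(Value(Element("wellbeing", "the wellbeing of the patient"), "positive"),),
        acting_upon=tuple(acting),
        extras=tuple(extras),
    )
    kb_text = write_kb(parse_kb("\n".join(facts)))  # canonical, byte-stable
    scenario = Scenario(
        name=f"synthetic-{seed}",
        kb_text=kb_text,
        ontology=ontology,
        templates=load_builtin_templates(),
        supports=False,
        seed=seed,
    )
    # Per-entry probe queries: each accepted entry is probed with its own
    # tags as context and its own rendered text as request.
    result = run_pipeline(scenario)
    probes = tuple(
        Query(" ".join(e.tags), e.rendered) for e in result.repository.entries
    )
    expected = tuple(e.scheme_name for e in result.repository.entries)
    return Scenario(
        name=scenario.name,
        kb_text=scenario.kb_text,
        ontology=scenario.ontology,
        templates=scenario.templates,
        queries=probes,
        expected_schemes=expected,
        supports=False,
        seed=seed,
    )
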