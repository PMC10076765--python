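"""Argument schemes, the EQR ontology, and critical-question attacks.

A scheme is a premise/conclusion template over a variable set
(``<Prem, Con, Var>``).  Six schemes ship as data files: EQR (acting upon
an expert opinion), ASPT (proposed treatment), ASEXP (expert reliability),
ASF (relevant field), ASO (alternative options) and ASCO (alternative
clinical options).  Instantiating a scheme substitutes each ``[Var]``
placeholder with the natural-language text of a bound ontology element.

Critical questions challenge an EQR instantiation.  Each is compiled to a
declarative trigger over knowledge-base facts (``data/cq_triggers.yaml``);
a triggered question becomes a counter-argument attacking the instance,
and an answering fact ``cq_answered(cq, opinion)`` generates a defeater of
that counter-argument.  The resulting framework is evaluated with
:mod:`eqrbot.af_core`, by default under grounded semantics — the unique,
most cautious extension.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml

from .af_core import (
    AcceptanceMode,
    Argument,
    ArgumentationFramework,
    argument_status,
)
from .errors import ConfigurationError, DomainError, InstantiationError
from .knowledge_base import (
    Atom,
    Fact,
    KnowledgeBase,
    parse_fact,
    query,
    query_conjunction,
)

_PLACEHOLDER = re.compile(r"\[([A-Za-z][A-Za-z0-9_]*)\]")

#: Default acceptance notion for Definitions of explanation acceptability:
#: grounded + skeptical (grounded is unique, so the attitude is moot).
DEFAULT_MODE = AcceptanceMode("grounded", "skeptical")


# --------------------------------------------------------------------------
# Ontology
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Element:
    """An ontology element: a constant id plus its natural-language text."""

    id: str
    text: str


@dataclass(frozen=True)
class Opinion:
    """An expert's viewpoint, tagged with its source expert and field."""

    element: Element
    expert_id: str
    field_id: str


@dataclass(frozen=True)
class State:
    """A state of the world: a truth assignment over the propositions."""

    element: Element
    assignment: tuple[tuple[str, bool], ...] = ()

    def truth(self, prop_id: str) -> bool:
        return dict(self.assignment)[prop_id]


@dataclass(frozen=True)
class Value:
    """A value with a polarity tag: ``positive`` or ``negative``."""

    element: Element
    polarity: str = "positive"


@dataclass(frozen=True)
class Ontology:
    """The sets assumed by the EQR scheme: Experts, Fields, Opinions, Prop,
    States, Values, and the total ``acting_upon`` map from opinions to
    states.  ``extras`` holds auxiliary elements (patient facts, goals,
    treatment names) used by the surrounding schemes."""

    experts: tuple[Element, ...] = ()
    fields: tuple[Element, ...] = ()
    opinions: tuple[Opinion, ...] = ()
    prop: tuple[Element, ...] = ()
    states: tuple[State, ...] = ()
    values: tuple[Value, ...] = ()
    acting_upon: tuple[tuple[str, str], ...] = ()
    extras: tuple[Element, ...] = ()

    def __post_init__(self):
        act = dict(self.acting_upon)
        state_ids = {s.element.id for s in self.states}
        prop_ids = {p.id for p in self.prop}
        expert_ids = {e.id for e in self.experts}
        field_ids = {f.id for f in self.fields}
        for o in self.opinions:
            if o.element.id not in act:
                raise DomainError(f"acting_upon undefined for opinion {o.element.id!r}")
            if act[o.element.id] not in state_ids:
                raise DomainError(f"acting_upon({o.element.id}) is not a known state")
            if o.expert_id not in expert_ids:
                raise DomainError(f"opinion {o.element.id!r} cites unknown expert")
            if o.field_id not in field_ids:
                raise DomainError(f"opinion {o.element.id!r} cites unknown field")
        for s in self.states:
            if {p for p, _ in s.assignment} != prop_ids:
                raise DomainError(
                    f"state {s.element.id!r} must assign a truth value to every proposition"
                )
        for v in self.values:
            if v.polarity not in ("positive", "negative"):
                raise DomainError(f"value {v.element.id!r} has invalid polarity")

    def elements(self) -> dict[str, Element]:
        out = {e.id: e for e in self.experts}
        out.update({f.id: f for f in self.fields})
        out.update({o.element.id: o.element for o in self.opinions})
        out.update({p.id: p for p in self.prop})
        out.update({s.element.id: s.element for s in self.states})
        out.update({v.element.id: v.element for v in self.values})
        out.update({e.id: e for e in self.extras})
        return out

    def opinion(self, opinion_id: str) -> Opinion:
        for o in self.opinions:
            if o.element.id == opinion_id:
                return o
        raise DomainError(f"unknown opinion {opinion_id!r}")

    def state_acted_upon(self, opinion_id: str) -> State:
        target = dict(self.acting_upon)[opinion_id]
        return next(s for s in self.states if s.element.id == target)

    def value(self, value_id: str) -> Value:
        for v in self.values:
            if v.element.id == value_id:
                return v
        raise DomainError(f"unknown value {value_id!r}")


# --------------------------------------------------------------------------
# Schemes and registry
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ArgumentScheme:
    """``<Prem, Con, Var>`` with ``[Var]`` placeholders in the templates."""

    name: str
    premises: tuple[str, ...]
    conclusion: str
    variables: frozenset[str]

    def __post_init__(self):
        used = set()
        for text in (*self.premises, self.conclusion):
            used.update(_PLACEHOLDER.findall(text))
        stray = used - self.variables
        if stray:
            raise ConfigurationError(
                f"scheme {self.name}: placeholder(s) {sorted(stray)} not declared"
            )
        # Variables may legitimately be absent from the *premise* texts only
        # when the conclusion uses them, and vice versa; wholly unused names
        # are a declaration error.
        unused = self.variables - used
        if unused:
            raise ConfigurationError(
                f"scheme {self.name}: variable(s) {sorted(unused)} never used"
            )


def _load_scheme(name: str) -> ArgumentScheme:
    raw = yaml.safe_load(
        resources.files("eqrbot").joinpath("data", "schemes", f"{name}.yaml").read_text()
    )
    return ArgumentScheme(
        name=raw["name"],
        premises=tuple(raw["premises"]),
        conclusion=raw["conclusion"],
        variables=frozenset(raw["variables"]),
    )


BUILTIN_SCHEME_NAMES = ("EQR", "ASPT", "ASEXP", "ASF", "ASO", "ASCO")

_registry: dict[str, ArgumentScheme] = {}


def register_builtin_schemes() -> dict[str, ArgumentScheme]:
    """Load the six shipped schemes into the module registry (idempotent)."""
    if not _registry:
        for name in BUILTIN_SCHEME_NAMES:
            _registry[name] = _load_scheme(name.lower())
    return _registry


def register_scheme(scheme: ArgumentScheme) -> None:
    """Add a custom scheme; re-registering an existing name is an error."""
    register_builtin_schemes()
    if scheme.name in _registry:
        raise ConfigurationError(f"scheme {scheme.name!r} is already registered")
    _registry[scheme.name] = scheme


def get_scheme(name: str) -> Optional[ArgumentScheme]:
    return register_builtin_schemes().get(name)


# --------------------------------------------------------------------------
# Instantiation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SchemeInstance:
    """One grounded binding of a scheme's variables, with rendered texts."""

    scheme: ArgumentScheme
    bindings: tuple[tuple[str, Element], ...]
    premises: tuple[str, ...]
    conclusion: str

    @property
    def id(self) -> str:
        parts = ",".join(f"{var}={el.id}" for var, el in sorted(self.bindings))
        return f"{self.scheme.name}({parts})"

    def binding(self, var: str) -> Element:
        return dict(self.bindings)[var]


def _substitute(text: str, bindings: dict[str, Element]) -> str:
    return _PLACEHOLDER.sub(lambda m: bindings[m.group(1)].text, text)


def instantiate_scheme(
    scheme: ArgumentScheme,
    bindings: dict[str, Element],
    kb: Optional[KnowledgeBase] = None,
) -> SchemeInstance:
    """Ground every scheme variable and render premise/conclusion texts.

    Substitution is pure: neither the scheme nor the knowledge base is
    mutated.  A missing binding raises :class:`InstantiationError` naming
    the variable; when ``kb`` carries an ontology, binding an element
    unknown to it raises :class:`DomainError`.
    """
    missing = sorted(scheme.variables - set(bindings))
    if missing:
        raise InstantiationError(
            f"scheme {scheme.name}: missing binding for variable {missing[0]!r}"
        )
    stray = sorted(set(bindings) - scheme.variables)
    if stray:
        raise InstantiationError(
            f"scheme {scheme.name}: binding for unknown variable {stray[0]!r}"
        )
    if kb is not None and kb.ontology is not None:
        known = kb.ontology.elements()
        for var, el in bindings.items():
            if el.id not in known:
                raise DomainError(
                    f"binding {var}={el.id!r} is not an element of the ontology"
                )
    return SchemeInstance(
        scheme=scheme,
        bindings=tuple(sorted(bindings.items())),
        premises=tuple(_substitute(p, bindings) for p in scheme.premises),
        conclusion=_substitute(scheme.conclusion, bindings),
    )


def embed_aspt_in_eqr(
    aspt: SchemeInstance,
    extra: dict[str, Element],
    kb: Optional[KnowledgeBase] = None,
) -> SchemeInstance:
    """Embed a proposed-treatment instance into the EQR scheme.

    The treatment ``T`` becomes the expert opinion ``alpha``, the patient
    facts ``Ft`` become (part of) the current state ``R``, and the goal
    ``G`` becomes the proposition ``A``; ``extra`` supplies the EQR-only
    variables ``E``, ``F``, ``S`` and ``v`` (and may override ``R``).
    """
    if aspt.scheme.name != "ASPT":
        raise TypeError(f"expected an ASPT instance, got {aspt.scheme.name}")
    bindings = {
        "alpha": aspt.binding("T"),
        "R": extra.get("R", aspt.binding("Ft")),
        "A": aspt.binding("G"),
    }
    for var in ("E", "F", "S", "v"):
        if var not in extra:
            raise InstantiationError(
                f"embedding into EQR: missing extra binding for variable {var!r}"
            )
        bindings[var] = extra[var]
    return instantiate_scheme(get_scheme("EQR"), bindings, kb)


# --------------------------------------------------------------------------
# Critical questions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CriticalQuestion:
    id: str
    atom: str
    text: str
    mode: str
    requires: tuple[str, ...] = ()
    fires_if: tuple[str, ...] = ()


def load_cq_table() -> tuple[CriticalQuestion, ...]:
    raw = yaml.safe_load(
        resources.files("eqrbot").joinpath("data", "cq_triggers.yaml").read_text()
    )
    return tuple(
        CriticalQuestion(
            id=q["id"],
            atom=q["atom"],
            text=q["text"],
            mode=q["mode"],
            requires=tuple(q.get("requires", ())),
            fires_if=tuple(q.get("fires_if", ())),
        )
        for q in raw["questions"]
    )


def critical_questions_for(scheme_name: str) -> tuple[CriticalQuestion, ...]:
    """The EQR scheme carries the ten shipped questions; the auxiliary
    schemes' own question sets are out of scope and attach none."""
    return load_cq_table() if scheme_name == "EQR" else ()


def _cq_subst(instance: SchemeInstance) -> dict[str, Atom]:
    """Pattern variables matching a scheme variable (case-insensitively;
    ``Alpha`` stands for alpha) are bound to the element id."""
    subst: dict[str, Atom] = {}
    for var, el in instance.bindings:
        key = "Alpha" if var == "alpha" else var.upper() if len(var) == 1 else var
        subst[key] = Atom(el.id)
    return subst


def _bind_patterns(patterns: Iterable[str], subst: dict[str, Atom]) -> list[Fact]:
    from .knowledge_base import substitute as kb_substitute

    return [kb_substitute(parse_fact(p), subst) for p in patterns]


def cq_triggered(
    cq: CriticalQuestion, instance: SchemeInstance, kb: KnowledgeBase
) -> bool:
    """Decide from KB facts alone whether the question attacks the instance."""
    subst = _cq_subst(instance)
    if cq.mode == "alternatives":
        return False
    if cq.mode == "negative_value":
        v = instance.binding("v")
        if kb.ontology is not None:
            return kb.ontology.value(v.id).polarity == "negative"
        return False
    if cq.mode == "unless":
        return not query_conjunction(kb, _bind_patterns(cq.requires, subst))
    if cq.mode == "fires_if":
        return bool(query_conjunction(kb, _bind_patterns(cq.fires_if, subst)))
    raise ConfigurationError(f"unknown CQ mode {cq.mode!r}")


def generate_cq_attacks(
    instance: SchemeInstance, kb: KnowledgeBase
) -> list[tuple[Argument, tuple[str, str]]]:
    """Counter-arguments (and their defeaters) raised against an instance.

    For every critical question whose trigger holds, one counter-argument
    attacking the instance is emitted; a ``cq_answered(cq, opinion)`` fact
    additionally emits a defeater attacking that counter-argument.  Output
    is ordered by question id.
    """
    out: list[tuple[Argument, tuple[str, str]]] = []
    opinion_id = None
    bound = dict(instance.bindings)
    if "alpha" in bound:
        opinion_id = bound["alpha"].id
    for cq in critical_questions_for(instance.scheme.name):
        if not cq_triggered(cq, instance, kb):
            continue
        counter_id = f"{instance.id}~{cq.atom}"
        out.append((Argument(counter_id, payload=cq), (counter_id, instance.id)))
        if opinion_id is not None and kb.has_fact(
            Fact("cq_answered", (Atom(cq.atom), Atom(opinion_id)))
        ):
            answer_id = f"{counter_id}~answer"
            out.append((Argument(answer_id, payload=cq), (answer_id, counter_id)))
    return out


# --------------------------------------------------------------------------
# Evaluation bridge
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationResult:
    framework: ArgumentationFramework
    instances: tuple[SchemeInstance, ...]
    statuses: tuple[tuple[str, str], ...]  # (instance id, accepted/rejected)
    mode: AcceptanceMode

    def status(self, instance: SchemeInstance | str) -> str:
        key = instance if isinstance(instance, str) else instance.id
        return dict(self.statuses)[key]

    @property
    def accepted(self) -> tuple[SchemeInstance, ...]:
        st = dict(self.statuses)
        return tuple(i for i in self.instances if st[i.id] == "accepted")


def evaluate_instances(
    instances: Iterable[SchemeInstance],
    kb: KnowledgeBase,
    mode: AcceptanceMode = DEFAULT_MODE,
) -> EvaluationResult:
    """Build the framework of instances, counter-arguments and defeaters,
    then record each instance's status under ``mode``.

    An instance is *acceptable* precisely when its argument is accepted.
    """
    instances = tuple(instances)
    seen: dict[str, SchemeInstance] = {}
    for inst in instances:
        seen[inst.id] = inst
    args: list[Argument] = [Argument(i.id, payload=i) for i in seen.values()]
    attacks: list[tuple[str, str]] = []
    for inst in seen.values():
        for arg, attack in generate_cq_attacks(inst, kb):
            args.append(arg)
            attacks.append(attack)
    af = ArgumentationFramework(args, attacks)
    statuses = tuple((i.id, argument_status(i.id, af, mode)) for i in seen.values())
    return EvaluationResult(af, tuple(seen.values()), statuses, mode)


# --------------------------------------------------------------------------
# Hierarchy helpers backing ASEXP / ASF / ASCO premises
# --------------------------------------------------------------------------


def _dominates_all(kb: KnowledgeBase, predicate: str, candidate: str, others: list[str]) -> bool:
    pairs = {
        (str(s["X"]), str(s["Y"])) for s in query(kb, f"{predicate}(X, Y)")
    }
    # transitive closure
    changed = True
    while changed:
        changed = False
        for a, b in list(pairs):
            for c, d in list(pairs):
                if b == c and (a, d) not in pairs:
                    pairs.add((a, d))
                    changed = True
    return all((candidate, o) in pairs for o in others)


def most_reliable_expert(kb: KnowledgeBase, ontology: Ontology) -> Optional[Element]:
    """The expert dominating all others under ``more_reliable`` ranking
    facts; a singleton expert set is trivially its own most reliable
    element."""
    experts = sorted(ontology.experts, key=lambda e: e.id)
    if len(experts) == 1:
        return experts[0]
    for e in experts:
        others = [o.id for o in experts if o.id != e.id]
        if _dominates_all(kb, "more_reliable", e.id, others):
            return e
    return None


def most_relevant_field(kb: KnowledgeBase, ontology: Ontology) -> Optional[Element]:
    """The field dominating all others under ``more_relevant`` ranking
    facts; a singleton field set wins by default."""
    fields_ = sorted(ontology.fields, key=lambda f: f.id)
    if len(fields_) == 1:
        return fields_[0]
    for f in fields_:
        others = [o.id for o in fields_ if o.id != f.id]
        if _dominates_all(kb, "more_relevant", f.id, others):
            return f
    return None


def safe_treatments(kb: KnowledgeBase) -> list[str]:
    """Treatments with no contraindication against a patient condition and
    no recorded negative side-effect history, sorted by id."""
    conditions = {str(s["C"]) for s in query(kb, "condition(C)")}
    out = []
    for s in query(kb, "treatment(T)"):
        t = str(s["T"])
        contra = {str(x["C"]) for x in query(kb, f"contraindicated({t}, C)")}
        if contra & conditions:
            continue
        if query(kb, f"side_effect_history({t})"):
            continue
        out.append(t)
    return sorted(out)
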