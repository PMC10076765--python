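"""Explanation templates, rendering, and the instantiated-explanations
repository.

An explanation template pairs a scheme with a natural-language text whose
placeholders are drawn from the scheme's variables.  An explanation is a
template filled from an *acceptable* scheme instantiation — rendering a
rejected instance is an error, so nothing the chatbot can say is ever
backed by a defeated argument.  Accepted instances are collected into a
finite repository; the EQR entries are the candidate initial explanations
from which a session starts.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import (
    AcceptabilityError,
    ConfigurationError,
    EmptyRepositoryError,
)
from .schemes import Element, EvaluationResult, SchemeInstance
from .textproc import nlp_filter

_PLACEHOLDER = re.compile(r"\[([A-Za-z][A-Za-z0-9_]*)\]")

#: Binding variables whose texts feed an entry's context tags (expert,
#: field, treatment/opinion).
_TAG_VARS = ("E", "F", "alpha", "T")


@dataclass(frozen=True)
class ExplanationTemplate:
    """Natural-language text with ``[Var]`` placeholders for one scheme."""

    scheme_name: str
    txt: str

    def placeholders(self) -> set[str]:
        return set(_PLACEHOLDER.findall(self.txt))


def load_builtin_templates() -> dict[str, ExplanationTemplate]:
    """One shipped template per scheme, keyed by scheme name."""
    raw = yaml.safe_load(
        resources.files("eqrbot").joinpath("data", "templates.yaml").read_text()
    )
    return {
        entry["scheme"]: ExplanationTemplate(entry["scheme"], entry["txt"])
        for entry in raw
    }


@dataclass(frozen=True)
class Explanation:
    """A rendered explanation: template text with every variable
    substituted from an acceptable scheme instance, plus context tags for
    the retrieval matcher."""

    id: str
    scheme_name: str
    rendered: str
    tags: tuple[str, ...]
    bindings: tuple[tuple[str, Element], ...] = ()

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "scheme": self.scheme_name,
            "rendered": self.rendered,
            "tags": list(self.tags),
            "bindings": {var: [el.id, el.text] for var, el in self.bindings},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Explanation":
        return cls(
            id=data["id"],
            scheme_name=data["scheme"],
            rendered=data["rendered"],
            tags=tuple(data["tags"]),
            bindings=tuple(
                (var, Element(eid, text))
                for var, (eid, text) in sorted(data.get("bindings", {}).items())
            ),
        )


def _context_tags(scheme_name: str, bindings: dict[str, Element]) -> tuple[str, ...]:
    """Lowercase tokens from the scheme name and the bound expert, field
    and treatment/opinion texts."""
    pieces = [scheme_name]
    for var in _TAG_VARS:
        if var in bindings:
            pieces.append(bindings[var].text)
    bag = nlp_filter(" ".join(pieces))
    bag[scheme_name.lower()] += 1  # scheme names are short; keep them even so
    return tuple(sorted(bag))


def render_explanation(
    template: ExplanationTemplate,
    instance: SchemeInstance,
    status: str = "accepted",
) -> Explanation:
    """Fill ``template.txt`` from the instance's bindings.

    Whitespace and punctuation of the template are preserved exactly; only
    the placeholders change.  ``status`` is the instance's evaluation
    outcome — rendering a rejected instance raises
    :class:`AcceptabilityError` (explanations exist only for acceptable
    instantiations).
    """
    if template.scheme_name != instance.scheme.name:
        raise TypeError(
            f"template is for {template.scheme_name}, instance is {instance.scheme.name}"
        )
    if status != "accepted":
        raise AcceptabilityError(
            f"instance {instance.id} is {status}; only acceptable instances "
            "may back an explanation"
        )
    bindings = dict(instance.bindings)
    missing = sorted(template.placeholders() - set(bindings))
    if missing:
        raise ConfigurationError(
            f"template for {template.scheme_name} uses unbound placeholder {missing[0]!r}"
        )
    rendered = _PLACEHOLDER.sub(lambda m: bindings[m.group(1)].text, template.txt)
    return Explanation(
        id=instance.id,
        scheme_name=instance.scheme.name,
        rendered=rendered,
        tags=_context_tags(instance.scheme.name, bindings),
        bindings=tuple(sorted(bindings.items())),
    )


@dataclass(frozen=True)
class ExplanationRepository:
    """The finite set of instantiated explanations, in fixed order."""

    entries: tuple[Explanation, ...]

    @property
    def eqr_entries(self) -> tuple[Explanation, ...]:
        return tuple(e for e in self.entries if e.scheme_name == "EQR")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    # -- persistence (lets the chatbot run without re-evaluation) ---------

    def to_json(self) -> str:
        return json.dumps([e.to_dict() for e in self.entries], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExplanationRepository":
        return cls(tuple(Explanation.from_dict(d) for d in json.loads(text)))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ExplanationRepository":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_repository(
    evaluation: EvaluationResult,
    templates: dict[str, ExplanationTemplate],
) -> ExplanationRepository:
    """One explanation per *accepted* instance, in evaluation order;
    rejected instances are excluded.  An accepted instance whose scheme
    has no template is a configuration error."""
    entries = []
    for inst in evaluation.instances:
        status = evaluation.status(inst)
        if status != "accepted":
            continue
        template = templates.get(inst.scheme.name)
        if template is None:
            raise ConfigurationError(
                f"accepted instance {inst.id} has no template for scheme "
                f"{inst.scheme.name!r}"
            )
        entries.append(render_explanation(template, inst, status))
    return ExplanationRepository(tuple(entries))


def select_initial_eqr(
    repo: ExplanationRepository, seed: int
) -> Explanation:
    """Uniform seeded choice among the EQR entries (all acceptable EQR
    explanations are equally good starting points)."""
    return _choose_initial(repo, random.Random(seed))


def _choose_initial(
    repo: ExplanationRepository, rng: random.Random
) -> Explanation:
    eqr = repo.eqr_entries
    if not eqr:
        raise EmptyRepositoryError("repository holds no EQR explanation")
    return eqr[rng.randrange(len(eqr))]
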