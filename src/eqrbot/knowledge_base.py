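"""Patient/guideline knowledge: predicate facts, Horn rules, preferences.

The knowledge base holds what the decision-support pipeline knows about a
patient and the applicable guidelines, encoded in a small first-order
dialect::

    % comment
    current_state(fever, headache, COVID19).
    condition(pregnancy).
    recommend(paracetamol) :- current_state(fever, headache, COVID19), condition(pregnancy).
    prefer(treatment, paracetamol, ibuprofen).

Dialect rules:

* one statement per line; ``%`` starts a comment; blank lines ignored;
* constants are lowercase identifiers, digit-leading tokens, or
  acronym-style tokens with two or more uppercase letters (``COVID19``,
  ``NICE``);
* variables start with a single uppercase letter followed by non-uppercase
  characters (``X``, ``Goal``, ``E2``);
* one level of classical negation via ``neg(·)`` is allowed on terms;
* rules are Horn: ``head :- b1, ..., bn.`` with no negation-as-failure
  (defeasibility is handled by the argumentation layer, not by the rules),
  and must be safe (every head variable occurs in the body);
* preference facts ``prefer(category, a, b)`` assert a ≻ b within a
  category (guideline, treatment, value); their transitive closure must be
  irreflexive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Optional

from .errors import CapacityError, DomainError, KBParseError, SafetyError

# --------------------------------------------------------------------------
# Terms and statements
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Var:
    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Neg:
    """One-level classical negation wrapper; ``inner`` is Atom or Var."""

    inner: "Atom | Var"

    def __str__(self) -> str:
        return f"neg({self.inner})"


Term = Atom | Var | Neg


@dataclass(frozen=True)
class Fact:
    """A predicate applied to terms; a *pattern* if any term is a variable."""

    predicate: str
    args: tuple[Term, ...]

    def __post_init__(self):
        if not self.predicate or not self.args:
            raise DomainError("facts need a predicate and at least one argument")

    def __str__(self) -> str:
        return f"{self.predicate}({', '.join(map(str, self.args))})"

    @property
    def is_ground(self) -> bool:
        return not any(
            isinstance(t, Var) or (isinstance(t, Neg) and isinstance(t.inner, Var))
            for t in self.args
        )

    def variables(self) -> set[str]:
        out = set()
        for t in self.args:
            if isinstance(t, Var):
                out.add(t.name)
            elif isinstance(t, Neg) and isinstance(t.inner, Var):
                out.add(t.inner.name)
        return out


@dataclass(frozen=True)
class Rule:
    head: Fact
    body: tuple[Fact, ...]

    def __post_init__(self):
        body_vars = set().union(*(b.variables() for b in self.body)) if self.body else set()
        unsafe = self.head.variables() - body_vars
        if unsafe:
            raise SafetyError(
                f"unsafe rule: head variable(s) {sorted(unsafe)} missing from body"
            )

    def __str__(self) -> str:
        return f"{self.head} :- {', '.join(map(str, self.body))}"


_IDENT = re.compile(r"[A-Za-z0-9_]+")


def _classify(token: str) -> Term:
    """Variable iff first char is the only uppercase one; else constant."""
    if token[0].isupper() and not any(c.isupper() for c in token[1:]):
        return Var(token)
    return Atom(token)


# --------------------------------------------------------------------------
# Parser
# --------------------------------------------------------------------------


class _LineParser:
    def __init__(self, text: str, lineno: int):
        self.text = text
        self.lineno = lineno
        self.pos = 0

    def error(self, msg: str):
        raise KBParseError(msg, self.lineno, self.pos + 1)

    def skip_ws(self):
        while self.pos < len(self.text) and self.text[self.pos] in " \t":
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def expect(self, ch: str):
        self.skip_ws()
        if not self.text.startswith(ch, self.pos):
            self.error(f"expected {ch!r}")
        self.pos += len(ch)

    def ident(self) -> str:
        self.skip_ws()
        m = _IDENT.match(self.text, self.pos)
        if not m:
            self.error("expected an identifier")
        self.pos = m.end()
        return m.group()

    def term(self) -> Term:
        name = self.ident()
        self.skip_ws()
        if name == "neg" and self.peek() == "(":
            self.expect("(")
            inner = self.ident()
            self.expect(")")
            node = _classify(inner)
            if isinstance(node, Neg):  # pragma: no cover - _classify never returns Neg
                self.error("nested negation is not allowed")
            return Neg(node)
        return _classify(name)

    def fact(self) -> Fact:
        pred = self.ident()
        if isinstance(_classify(pred), Var):
            self.error(f"predicate {pred!r} must be a constant")
        self.expect("(")
        args = [self.term()]
        self.skip_ws()
        while self.peek() == ",":
            self.expect(",")
            args.append(self.term())
            self.skip_ws()
        self.expect(")")
        return Fact(pred, tuple(args))

    def statement(self) -> Fact | Rule:
        head = self.fact()
        self.skip_ws()
        if self.text.startswith(":-", self.pos):
            self.pos += 2
            body = [self.fact()]
            self.skip_ws()
            while self.peek() == ",":
                self.expect(",")
                body.append(self.fact())
                self.skip_ws()
            self.expect(".")
            try:
                stmt: Fact | Rule = Rule(head, tuple(body))
            except SafetyError:
                raise
            return stmt
        self.expect(".")
        if not head.is_ground:
            self.error("facts must be ground (no variables)")
        return head

    def at_end(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)


def parse_fact(text: str) -> Fact:
    """Parse a single fact/pattern expression such as ``expert_in(E, F)``."""
    p = _LineParser(text.strip(), 1)
    f = p.fact()
    if not p.at_end():
        p.error("trailing characters after fact")
    return f


# --------------------------------------------------------------------------
# Unification and substitution
# --------------------------------------------------------------------------

Subst = dict[str, Term]


def _unify_term(pat: Term, ground: Term, subst: Subst) -> Optional[Subst]:
    if isinstance(pat, Var):
        bound = subst.get(pat.name)
        if bound is None:
            out = dict(subst)
            out[pat.name] = ground
            return out
        return subst if bound == ground else None
    if isinstance(pat, Neg):
        if not isinstance(ground, Neg):
            return None
        return _unify_term(pat.inner, ground.inner, subst)
    return subst if pat == ground else None


def unify(pattern: Fact, ground: Fact, subst: Optional[Subst] = None) -> Optional[Subst]:
    """Match ``pattern`` against a ground fact, extending ``subst``."""
    if pattern.predicate != ground.predicate or len(pattern.args) != len(ground.args):
        return None
    out: Optional[Subst] = dict(subst or {})
    for p, g in zip(pattern.args, ground.args):
        out = _unify_term(p, g, out)
        if out is None:
            return None
    return out


def substitute(pattern: Fact, subst: Subst) -> Fact:
    def sub(t: Term) -> Term:
        if isinstance(t, Var):
            return subst.get(t.name, t)
        if isinstance(t, Neg) and isinstance(t.inner, Var):
            inner = subst.get(t.inner.name, t.inner)
            if isinstance(inner, Neg):
                return inner.inner  # neg(neg(x)) collapses to x
            return Neg(inner) if isinstance(inner, Atom) else Neg(t.inner)
        return t

    return Fact(pattern.predicate, tuple(sub(t) for t in pattern.args))


# --------------------------------------------------------------------------
# Knowledge base
# --------------------------------------------------------------------------

PREFERENCE_CATEGORIES = ("guideline", "treatment", "value")


@dataclass(frozen=True)
class KnowledgeBase:
    facts: frozenset[Fact] = frozenset()
    rules: tuple[Rule, ...] = ()
    ontology: Any = None  # an eqrbot.schemes.Ontology, attached by the pipeline
    preferences: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "preferences", _preference_closure(self.facts))

    def sorted_facts(self) -> list[Fact]:
        cached = self.__dict__.get("_sorted_facts")
        if cached is None:
            cached = sorted(self.facts, key=str)
            object.__setattr__(self, "_sorted_facts", cached)
        return cached

    def with_facts(self, extra: Iterable[Fact]) -> "KnowledgeBase":
        return replace(self, facts=self.facts | frozenset(extra))

    def with_ontology(self, ontology) -> "KnowledgeBase":
        return replace(self, ontology=ontology)

    def has_fact(self, fact: Fact) -> bool:
        return fact in self.facts


def _preference_closure(facts: Iterable[Fact]) -> dict[str, set[tuple[str, str]]]:
    """Transitive closure of ``prefer(category, a, b)`` facts per category;
    rejects cycles (the orders must be strict)."""
    pairs: dict[str, set[tuple[str, str]]] = {}
    for f in facts:
        if f.predicate != "prefer" or len(f.args) != 3:
            continue
        cat, a, b = (str(t) for t in f.args)
        pairs.setdefault(cat, set()).add((a, b))
    for cat, rel in pairs.items():
        changed = True
        while changed:
            changed = False
            for a, b in list(rel):
                for c, d in list(rel):
                    if b == c and (a, d) not in rel:
                        rel.add((a, d))
                        changed = True
        if any(a == b for a, b in rel):
            raise DomainError(f"preference order for {cat!r} contains a cycle")
    return pairs


def parse_kb(text: str) -> KnowledgeBase:
    """Parse the dialect described in the module docstring.

    Parse failures carry the offending line and column.
    """
    facts: set[Fact] = set()
    rules: list[Rule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("%", 1)[0].strip()
        if not line:
            continue
        parser = _LineParser(line, lineno)
        stmt = parser.statement()
        if not parser.at_end():
            parser.error("trailing characters after statement")
        if isinstance(stmt, Rule):
            rules.append(stmt)
        else:
            facts.add(stmt)
    return KnowledgeBase(frozenset(facts), tuple(rules))


def write_kb(kb: KnowledgeBase) -> str:
    """Canonical text form: sorted facts one per line, then sorted rules."""
    lines = [f"{f}." for f in kb.sorted_facts()]
    lines.extend(f"{r}." for r in sorted(kb.rules, key=str))
    return "\n".join(lines) + ("\n" if lines else "")


def query(kb: KnowledgeBase, pattern: Fact | str) -> list[Subst]:
    """All substitutions grounding ``pattern`` against the stored facts.

    A fully ground pattern that is present yields one empty substitution.
    Results are in deterministic (sorted-fact) order.
    """
    pat = parse_fact(pattern) if isinstance(pattern, str) else pattern
    out = []
    for f in kb.sorted_facts():
        s = unify(pat, f)
        if s is not None and s not in out:
            out.append(s)
    return out


def query_conjunction(
    kb: KnowledgeBase, patterns: Iterable[Fact | str], initial: Optional[Subst] = None
) -> list[Subst]:
    """Substitutions satisfying every pattern jointly (shared variables)."""
    pats = [parse_fact(p) if isinstance(p, str) else p for p in patterns]
    substs: list[Subst] = [dict(initial or {})]
    for pat in pats:
        nxt = []
        for s in substs:
            bound = substitute(pat, s)
            for f in kb.sorted_facts():
                s2 = unify(bound, f, s)
                if s2 is not None and s2 not in nxt:
                    nxt.append(s2)
        substs = nxt
        if not substs:
            return []
    return substs


def saturate(kb: KnowledgeBase, max_derivations: int = 10000) -> KnowledgeBase:
    """Least fixed point of forward chaining over the Horn rules.

    Monotone (never removes facts) and idempotent; raises
    :class:`CapacityError` if more than ``max_derivations`` new facts are
    derived.
    """
    facts = set(kb.facts)
    derived = 0
    changed = True
    while changed:
        changed = False
        snapshot = KnowledgeBase(frozenset(facts), ())
        for rule in kb.rules:
            for subst in query_conjunction(snapshot, rule.body):
                head = substitute(rule.head, subst)
                if head not in facts:
                    facts.add(head)
                    derived += 1
                    changed = True
                    if derived > max_derivations:
                        raise CapacityError(
                            f"saturation exceeded {max_derivations} derivations"
                        )
    return replace(kb, facts=frozenset(facts))


def preferred_element(
    kb: KnowledgeBase, category: str, candidates: Iterable[str]
) -> str:
    """A maximal element of the category's preference order restricted to
    ``candidates``; ties (incomparable maximal elements) break
    lexicographically."""
    cands = sorted(set(candidates))
    if not cands:
        raise DomainError("candidates must be non-empty")
    if category not in PREFERENCE_CATEGORIES:
        raise DomainError(f"unknown preference category {category!r}")
    rel = kb.preferences.get(category, set())
    maximal = [c for c in cands if not any((d, c) in rel for d in cands)]
    return maximal[0]
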