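"""Dung abstract argumentation frameworks and their semantics.

An argumentation framework is a pair ``<AR, attacks>`` of a finite set of
arguments and a binary attack relation over them.  The functions in this
module realize the classical semantics chain: conflict-freeness,
acceptability of an argument with respect to a set, admissible sets,
complete extensions, the (unique, least) grounded extension, and the
(subset-maximal) preferred extensions.  Skeptical and credulous argument
status queries are layered on top.

Frameworks here are small — one scheme instance plus the counter-arguments
raised by its critical questions — so complete/preferred extensions are
computed by exhaustive search over conflict-free sets with pruning, guarded
by a configurable argument cap.  :mod:`eqrbot.oracle` provides an
independent, definition-literal enumeration used to cross-check this
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, FrozenSet, Iterable, Iterator

import yaml

from .errors import CapacityError, DomainError

#: Default cap on |AR| for exhaustive complete/preferred enumeration.
DEFAULT_CAP = 20


@dataclass(frozen=True)
class Argument:
    """A node of the framework.

    ``payload`` typically references the scheme instance or the
    critical-question counter-argument the node stands for; abstract test
    arguments leave it ``None``.  Identity (hashing, equality) is by ``id``
    alone so payloads need not be hashable.
    """

    id: str
    payload: Any = field(default=None, compare=False, hash=False)


class ArgumentationFramework:
    """Immutable ``<AR, attacks>`` pair with validated attack relation."""

    def __init__(
        self,
        arguments: Iterable[Argument | str],
        attacks: Iterable[tuple[str, str]] = (),
    ):
        args: dict[str, Argument] = {}
        for a in arguments:
            arg = a if isinstance(a, Argument) else Argument(a)
            if arg.id in args:
                raise DomainError(f"duplicate argument id {arg.id!r}")
            args[arg.id] = arg
        att = set()
        for src, dst in attacks:
            if src not in args:
                raise DomainError(f"attack source {src!r} is not an argument")
            if dst not in args:
                raise DomainError(f"attack target {dst!r} is not an argument")
            att.add((src, dst))
        self._args = dict(sorted(args.items()))
        self._attacks = frozenset(att)
        self._attackers: dict[str, frozenset[str]] = {
            x: frozenset(s for s, t in att if t == x) for x in self._args
        }
        self._targets: dict[str, frozenset[str]] = {
            x: frozenset(t for s, t in att if s == x) for x in self._args
        }

    @property
    def argument_ids(self) -> tuple[str, ...]:
        """All argument ids, sorted (deterministic iteration order)."""
        return tuple(self._args)

    @property
    def arguments(self) -> tuple[Argument, ...]:
        return tuple(self._args.values())

    @property
    def attacks(self) -> FrozenSet[tuple[str, str]]:
        return self._attacks

    def argument(self, x: str) -> Argument:
        self._check_ids([x])
        return self._args[x]

    def attackers_of(self, x: str) -> frozenset[str]:
        self._check_ids([x])
        return self._attackers[x]

    def targets_of(self, x: str) -> frozenset[str]:
        self._check_ids([x])
        return self._targets[x]

    def __len__(self) -> int:
        return len(self._args)

    def __contains__(self, x: str) -> bool:
        return x in self._args

    def __iter__(self) -> Iterator[str]:
        return iter(self._args)

    def _check_ids(self, ids: Iterable[str]) -> None:
        for x in ids:
            if x not in self._args:
                raise DomainError(f"unknown argument id {x!r}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "arguments": list(self.argument_ids),
            "attacks": sorted([s, t] for s, t in self._attacks),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArgumentationFramework":
        return cls(data.get("arguments", ()), [tuple(p) for p in data.get("attacks", ())])

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ArgumentationFramework":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __eq__(self, other) -> bool:
        if not isinstance(other, ArgumentationFramework):
            return NotImplemented
        return self.argument_ids == other.argument_ids and self._attacks == other._attacks

    def __repr__(self) -> str:
        return f"ArgumentationFramework({len(self)} arguments, {len(self._attacks)} attacks)"


@dataclass(frozen=True)
class Extension:
    """A set of collectively acceptable arguments with its semantics label."""

    members: frozenset[str]
    label: str

    def __contains__(self, x: str) -> bool:
        return x in self.members

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class AcceptanceMode:
    """Which semantics to evaluate under, and how cautiously.

    The ``attitude`` is irrelevant for grounded semantics (the grounded
    extension is unique).
    """

    semantics: str = "grounded"
    attitude: str = "skeptical"

    def __post_init__(self):
        if self.semantics not in ("grounded", "preferred", "complete"):
            raise DomainError(f"unknown semantics {self.semantics!r}")
        if self.attitude not in ("skeptical", "credulous"):
            raise DomainError(f"unknown attitude {self.attitude!r}")


def is_conflict_free(S: Iterable[str], af: ArgumentationFramework) -> bool:
    """True iff no member of ``S`` attacks another member (or itself)."""
    s = frozenset(S)
    af._check_ids(s)
    return not any(af.attackers_of(x) & s for x in s)


def is_acceptable(x: str, S: Iterable[str], af: ArgumentationFramework) -> bool:
    """True iff every attacker of ``x`` is attacked by some member of ``S``."""
    s = frozenset(S)
    af._check_ids({x} | s)
    attacked_by_s = frozenset().union(*(af.targets_of(z) for z in s)) if s else frozenset()
    return af.attackers_of(x) <= attacked_by_s


def characteristic_set(S: Iterable[str], af: ArgumentationFramework) -> frozenset[str]:
    """The set of all arguments acceptable w.r.t. ``S`` (monotone in S)."""
    s = frozenset(S)
    af._check_ids(s)
    attacked_by_s = frozenset().union(*(af.targets_of(z) for z in s)) if s else frozenset()
    return frozenset(x for x in af if af.attackers_of(x) <= attacked_by_s)


def is_admissible(S: Iterable[str], af: ArgumentationFramework) -> bool:
    """True iff ``S`` is conflict-free and defends each of its members."""
    s = frozenset(S)
    return is_conflict_free(s, af) and s <= characteristic_set(s, af)


def grounded_extension(af: ArgumentationFramework) -> Extension:
    """The least complete extension: least fixed point of the
    characteristic function, reached from the empty set in at most |AR|
    iterations."""
    current: frozenset[str] = frozenset()
    for _ in range(len(af) + 1):
        nxt = characteristic_set(current, af)
        if nxt == current:
            break
        current = nxt
    return Extension(current, "grounded")


def _conflict_free_sets(af: ArgumentationFramework) -> Iterator[frozenset[str]]:
    """All conflict-free sets, by DFS over the sorted argument list with
    pruning (a candidate is added only if it neither attacks nor is
    attacked by the partial set, and does not attack itself)."""
    ids = af.argument_ids

    def extend(i: int, chosen: tuple[str, ...]) -> Iterator[frozenset[str]]:
        yield frozenset(chosen)
        for j in range(i, len(ids)):
            x = ids[j]
            if x in af.attackers_of(x):
                continue
            if any(x in af.attackers_of(c) or c in af.attackers_of(x) for c in chosen):
                continue
            yield from extend(j + 1, chosen + (x,))

    yield from extend(0, ())


def _check_cap(af: ArgumentationFramework, cap: int) -> None:
    if len(af) > cap:
        raise CapacityError(
            f"exhaustive enumeration capped at {cap} arguments, framework has {len(af)}"
        )


def complete_extensions(
    af: ArgumentationFramework, cap: int = DEFAULT_CAP
) -> tuple[Extension, ...]:
    """All complete extensions: conflict-free sets S with S = F(S), where F
    is the characteristic function.  Deterministic order (by size, then
    sorted members)."""
    _check_cap(af, cap)
    found = []
    for s in _conflict_free_sets(af):
        if characteristic_set(s, af) == s:
            found.append(s)
    found.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return tuple(Extension(s, "complete") for s in found)


def preferred_extensions(
    af: ArgumentationFramework, cap: int = DEFAULT_CAP
) -> tuple[Extension, ...]:
    """The subset-maximal complete extensions."""
    complete = [e.members for e in complete_extensions(af, cap)]
    maximal = [s for s in complete if not any(s < t for t in complete)]
    maximal.sort(key=lambda s: (len(s), tuple(sorted(s))))
    return tuple(Extension(s, "preferred") for s in maximal)


def argument_status(
    x: str, af: ArgumentationFramework, mode: AcceptanceMode = AcceptanceMode()
) -> str:
    """``"accepted"`` or ``"rejected"`` for ``x`` under the given mode.

    Grounded: membership in the (unique) grounded extension.  Preferred /
    complete: skeptical = member of every extension, credulous = member of
    at least one.
    """
    af._check_ids([x])
    if mode.semantics == "grounded":
        return "accepted" if x in grounded_extension(af) else "rejected"
    exts = (
        preferred_extensions(af)
        if mode.semantics == "preferred"
        else complete_extensions(af)
    )
    hit = [x in e for e in exts]
    ok = all(hit) if mode.attitude == "skeptical" else any(hit)
    return "accepted" if ok and exts else "rejected"
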