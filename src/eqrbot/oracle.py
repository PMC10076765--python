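"""Definition-literal brute-force enumeration over all subsets.

Independent cross-check for :mod:`eqrbot.af_core`: every one of the 2^n
subsets of AR is tested directly against the defining clauses of the
semantics (conflict-freeness, S ⊆ F(S), S = F(S), least / maximal
element).  Bitmask arithmetic keeps full enumeration fast up to ~16
arguments; it intentionally shares no code with the production path.
"""

from __future__ import annotations

from .af_core import ArgumentationFramework
from .errors import CapacityError

#: Hard cap: 2^n subsets are enumerated, so n must stay desk-sized.
ORACLE_CAP = 16


def enumerate_semantics(af: ArgumentationFramework) -> dict[str, list[frozenset[str]]]:
    """Enumerate conflict-free, admissible, complete, grounded and
    preferred sets of ``af`` by exhaustive subset search.

    Returns a dict of sorted lists of frozensets; ``"grounded"`` is a
    single-element list.
    """
    ids = af.argument_ids
    n = len(ids)
    if n > ORACLE_CAP:
        raise CapacityError(f"oracle enumerates 2^n subsets; n={n} exceeds {ORACLE_CAP}")
    index = {x: i for i, x in enumerate(ids)}
    attackers = [0] * n  # attackers[i]: bitmask of attackers of ids[i]
    targets = [0] * n  # targets[i]: bitmask of arguments ids[i] attacks
    for s, t in af.attacks:
        attackers[index[t]] |= 1 << index[s]
        targets[index[s]] |= 1 << index[t]

    def attacked_by(mask: int) -> int:
        out = 0
        m = mask
        while m:
            low = m & -m
            out |= targets[low.bit_length() - 1]
            m ^= low
        return out

    def members(mask: int) -> frozenset[str]:
        return frozenset(ids[i] for i in range(n) if mask >> i & 1)

    conflict_free: list[int] = []
    admissible: list[int] = []
    complete: list[int] = []
    for mask in range(1 << n):
        # conflict-free: no internal attack
        if attacked_by(mask) & mask:
            continue
        conflict_free.append(mask)
        counter = attacked_by(mask)
        fs = 0  # F(S): arguments whose every attacker is counter-attacked
        for i in range(n):
            if attackers[i] & ~counter == 0:
                fs |= 1 << i
        if mask & ~fs == 0:  # S subset of F(S)
            admissible.append(mask)
            if fs == mask:  # and F(S) subset of S
                complete.append(mask)

    grounded = min(complete, key=lambda m: m.bit_count())
    assert all(grounded & ~m == 0 for m in complete), "grounded must be least complete"
    preferred = [m for m in complete if not any(m != o and m & ~o == 0 for o in complete)]

    def out(masks) -> list[frozenset[str]]:
        sets = [members(m) for m in masks]
        sets.sort(key=lambda s: (len(s), tuple(sorted(s))))
        return sets

    return {
        "conflict_free": out(conflict_free),
        "admissible": out(admissible),
        "complete": out(complete),
        "grounded": out([grounded]),
        "preferred": out(preferred),
    }
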