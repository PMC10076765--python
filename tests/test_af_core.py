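"""Unit and property tests for the Dung semantics core."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqrbot.af_core import (
    AcceptanceMode,
    Argument,
    ArgumentationFramework,
    argument_status,
    characteristic_set,
    complete_extensions,
    grounded_extension,
    is_acceptable,
    is_admissible,
    is_conflict_free,
    preferred_extensions,
)
from eqrbot.errors import CapacityError, DomainError
from eqrbot.fixtures import generate_framework
from eqrbot.oracle import enumerate_semantics


def af(ids, attacks=()):
    return ArgumentationFramework(ids, attacks)


MUTUAL = af("ab", [("a", "b"), ("b", "a")])
CHAIN = af("abc", [("a", "b"), ("b", "c")])


class TestConflictFree:
    @pytest.mark.parametrize(
        "framework, s, expected",
        [
            (af("ab", [("a", "b")]), {"a", "b"}, False),
            (af("ab", [("a", "b")]), {"a"}, True),
            (af("ab", [("a", "b")]), set(), True),
            (af("a", [("a", "a")]), {"a"}, False),  # self-attackers excluded
        ],
    )
    def test_examples(self, framework, s, expected):
        assert is_conflict_free(s, framework) is expected

    def test_unknown_id_is_domain_error(self):
        with pytest.raises(DomainError):
            is_conflict_free({"z"}, MUTUAL)


class TestAcceptability:
    @pytest.mark.parametrize(
        "framework, x, s, expected",
        [
            (af("abc", [("b", "a"), ("c", "b")]), "a", {"c"}, True),
            (af("abc", [("b", "a"), ("c", "b")]), "a", set(), False),
            (af("ab"), "a", set(), True),  # unattacked: vacuous defence
        ],
    )
    def test_examples(self, framework, x, s, expected):
        assert is_acceptable(x, s, framework) is expected

    @pytest.mark.parametrize(
        "framework, s, expected",
        [
            (af("ab"), set(), {"a", "b"}),
            (af("ab", [("a", "b")]), set(), {"a"}),
            (MUTUAL, set(), set()),
        ],
    )
    def test_characteristic_set(self, framework, s, expected):
        assert characteristic_set(s, framework) == frozenset(expected)


class TestAdmissible:
    @pytest.mark.parametrize(
        "framework, s, expected",
        [
            (MUTUAL, set(), True),  # the empty set is always admissible
            (MUTUAL, {"a"}, True),
            (CHAIN, {"c"}, False),  # c is undefended against b
        ],
    )
    def test_examples(self, framework, s, expected):
        assert is_admissible(s, framework) is expected


class TestExtensions:
    @pytest.mark.parametrize(
        "framework, expected",
        [
            (af("a"), [set("a")]),
            (MUTUAL, [set(), {"a"}, {"b"}]),
            (CHAIN, [{"a", "c"}]),
        ],
    )
    def test_complete(self, framework, expected):
        got = [set(e.members) for e in complete_extensions(framework)]
        assert got == sorted(expected, key=lambda s: (len(s), tuple(sorted(s))))

    @pytest.mark.parametrize(
        "framework, expected",
        [
            (af("ab"), {"a", "b"}),
            (af("ab", [("a", "b")]), {"a"}),
            (MUTUAL, set()),
        ],
    )
    def test_grounded(self, framework, expected):
        assert grounded_extension(framework).members == frozenset(expected)

    @pytest.mark.parametrize(
        "framework, expected",
        [
            (MUTUAL, [{"a"}, {"b"}]),
            (af("ab"), [{"a", "b"}]),
            (CHAIN, [{"a", "c"}]),
        ],
    )
    def test_preferred(self, framework, expected):
        got = [set(e.members) for e in preferred_extensions(framework)]
        assert got == sorted(expected, key=lambda s: (len(s), tuple(sorted(s))))

    def test_capacity_cap(self):
        big = af([f"x{i}" for i in range(25)])
        with pytest.raises(CapacityError):
            complete_extensions(big)


class TestStatus:
    @pytest.mark.parametrize(
        "mode, expected",
        [
            (AcceptanceMode("preferred", "credulous"), "accepted"),
            (AcceptanceMode("preferred", "skeptical"), "rejected"),
        ],
    )
    def test_mutual_attack(self, mode, expected):
        assert argument_status("a", MUTUAL, mode) == expected

    def test_grounded_unattacked(self):
        assert argument_status("a", af("ab"), AcceptanceMode("grounded")) == "accepted"

    def test_invalid_mode(self):
        with pytest.raises(DomainError):
            AcceptanceMode("stable")


class TestFramework:
    def test_duplicate_and_dangling_rejected(self):
        with pytest.raises(DomainError):
            ArgumentationFramework(["a", "a"])
        with pytest.raises(DomainError):
            ArgumentationFramework(["a"], [("a", "b")])

    def test_payload_does_not_affect_identity(self):
        assert Argument("x", payload=1) == Argument("x", payload=2)

    def test_serialization_round_trip(self, tmp_path):
        path = tmp_path / "af.yaml"
        CHAIN.save(path)
        assert ArgumentationFramework.load(path) == CHAIN


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10_000))
def test_oracle_equivalence_on_random_frameworks(seed):
    """Production grounded/complete/preferred match definition-literal
    exhaustive subset enumeration."""
    framework = generate_framework(seed)
    oracle = enumerate_semantics(framework)
    assert [grounded_extension(framework).members] == oracle["grounded"]
    assert [e.members for e in complete_extensions(framework)] == oracle["complete"]
    assert [e.members for e in preferred_extensions(framework)] == oracle["preferred"]


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10_000), data=st.data())
def test_characteristic_set_is_monotone(seed, data):
    framework = generate_framework(seed)
    ids = list(framework.argument_ids)
    small = data.draw(st.sets(st.sampled_from(ids)))
    extra = data.draw(st.sets(st.sampled_from(ids)))
    large = small | extra
    assert characteristic_set(small, framework) <= characteristic_set(large, framework)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(seed=st.integers(0, 10_000))
def test_lattice_facts(seed):
    framework = generate_framework(seed)
    assert is_admissible(set(), framework)
    grounded = grounded_extension(framework).members
    preferred = preferred_extensions(framework)
    complete = {e.members for e in complete_extensions(framework)}
    assert preferred  # at least one preferred extension exists
    for ext in preferred:
        assert grounded <= ext.members
        assert ext.members in complete
    # grounded terminates within |AR| characteristic-function iterations
    current = frozenset()
    for _ in range(len(framework)):
        current = characteristic_set(current, framework)
    assert current == grounded


def test_attack_free_framework_has_unique_full_extension():
    framework = af([f"n{i}" for i in range(6)])
    everything = frozenset(framework.argument_ids)
    assert grounded_extension(framework).members == everything
    assert [e.members for e in complete_extensions(framework)] == [everything]
    assert [e.members for e in preferred_extensions(framework)] == [everything]
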