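import numpy as np
import pytest

from cgspn.net import Marking, Multiset, Net
from cgspn.semantics import (
    BindingSpaceError,
    FiringError,
    enumerate_bindings,
    evaluate_guard,
    fire,
    match_pattern,
)

from .oracle import brute_force_bindings, count_selections


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestMatchPattern:
    def test_constants_filter_and_variables_bind(self, cell_colorset):
        b = match_pattern('1\'("active", p, l, 4)', ("active", 0, 7, 4), colorset=cell_colorset)
        assert b == {"p": 0, "l": 7}

    def test_constant_mismatch_fails_softly(self, cell_colorset):
        b = match_pattern('1\'("active", p, l, 4)', ("resting", 0, 7, 4), colorset=cell_colorset)
        assert b is None

    def test_whole_tuple_variable_binds_components(self, cell_colorset):
        b = match_pattern("1'(th)", ("resting", 0, 5, 3), colorset=cell_colorset)
        assert b == {"th:1": "resting", "th:2": 0, "th:3": 5, "th:4": 3}

    def test_inconsistent_rebinding_fails(self, cell_colorset):
        partial = {"p": 0, "l": 3}
        b = match_pattern('1\'("active", p, l, 4)', ("active", 0, 7, 4), partial, colorset=cell_colorset)
        assert b is None
        assert partial == {"p": 0, "l": 3}  # input binding untouched

    def test_offset_term_inverts_on_input(self, cell_colorset):
        # matching a token against th:3-1 binds th:3 to life+1
        b = match_pattern(
            "1'(th:1, th:2, th:3-1, th:4)", ("resting", 0, 4, 3), colorset=cell_colorset
        )
        assert b["th:3"] == 5


class TestEvaluateGuard:
    def test_life_zero(self):
        assert evaluate_guard("[th:3 = 0]", {"th:1": "resting", "th:2": 0, "th:3": 0, "th:4": 2})

    def test_receptor_match(self):
        assert evaluate_guard("[b:4 = th:4]", {"b:4": 4, "th:4": 4})
        assert not evaluate_guard("[b:4 = th:4]", {"b:4": 4, "th:4": 5})

    def test_empty_guard_true(self):
        assert evaluate_guard(None, {})


class TestEnumerateBindings:
    def test_death_guard_selects_only_exhausted_token(self, immune_net):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("resting", 0, 0, 2): 1, ("resting", 0, 4, 2): 1})
        elements = enumerate_bindings(immune_net, "die_TH", m)
        assert len(elements) == 1
        assert elements[0].binding["c:3"] == 0
        assert elements[0].weight == 1

    def test_empty_marking_yields_nothing(self, immune_net):
        elements = enumerate_bindings(immune_net, "die_TH", immune_net.initial_marking())
        assert elements == []

    def test_identical_tokens_weighted_combinatorially(self):
        net = Net("pairs")
        net.add_colorset("C", ["a", "b"])
        net.add_place("X", ["C"])
        net.add_transition("take2", "stochastic", rate=1.0)
        net.add_input("X", "take2", "2'(v)")
        m = net.initial_marking()
        m["X"] = Multiset.of({("a",): 3})
        elements = enumerate_bindings(net, "take2", m)
        assert len(elements) == 1
        assert elements[0].weight == count_selections(3, 2) == 3

    def test_source_transition_always_enabled(self, immune_net):
        elements = enumerate_bindings(immune_net, "gen_TH", immune_net.initial_marking())
        assert len(elements) == 1 and elements[0].weight == 1 and elements[0].binding == {}

    def test_does_not_mutate_marking(self, immune_net):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("resting", 0, 0, 2): 1})
        snapshot = m.copy()
        enumerate_bindings(immune_net, "die_TH", m)
        assert m == snapshot

    def test_binding_space_cap(self, immune_net):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("resting", 0, life, r): 1 for life in range(11) for r in range(10)})
        with pytest.raises(BindingSpaceError):
            enumerate_bindings(immune_net, "age_TH", m, cap=10)


class TestOracleEquivalence:
    """Colored enumeration must agree with the executable unfolded net."""

    def interaction_net(self):
        net = Net("interaction")
        net.add_colorset("STATE", ["resting", "active", "presenting"])
        net.add_colorset("LIFE", range(3))
        net.add_colorset("RECEPTOR", range(3))
        net.add_product("CELL", ["STATE", "LIFE", "RECEPTOR"])  # 27 colors
        net.add_place("TH", "CELL")
        net.add_place("B", "CELL")
        net.add_transition(
            "interact",
            "stochastic",
            rate=1.0,
            guard='[th:1 = "active" & b:1 = "presenting" & b:3 = th:3]',
        )
        net.add_input("TH", "interact", "1'(th)")
        net.add_input("B", "interact", "1'(b)")
        net.add_output("interact", "TH", "2'(th:1, 2, th:3)")
        return net

    def as_dict(self, elements):
        return {tuple(sorted(e.binding.items())): e.weight for e in elements}

    def test_two_place_interaction_matches_brute_force(self):
        net = self.interaction_net()
        m = net.initial_marking()
        m["TH"] = Multiset.of(
            {("active", 1, 0): 2, ("active", 2, 1): 1, ("resting", 1, 0): 3}
        )
        m["B"] = Multiset.of(
            {("presenting", 0, 0): 3, ("presenting", 0, 2): 1, ("active", 0, 0): 2}
        )
        got = self.as_dict(enumerate_bindings(net, "interact", m))
        assert got == brute_force_bindings(net, "interact", m)
        # sanity: receptor-0 pairing contributes weight 2 * 3
        assert sum(got.values()) == 2 * 3 + 0

    def test_aging_with_guard_matches_brute_force(self, immune_net):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of(
            {("resting", 0, 0, 1): 2, ("resting", 0, 3, 1): 4, ("active", 0, 5, 2): 1}
        )
        for t in ("age_TH", "die_TH", "gen_TH"):
            got = self.as_dict(enumerate_bindings(immune_net, t, m))
            assert got == brute_force_bindings(immune_net, t, m), t

    def test_multiplicity_demand_matches_brute_force(self):
        net = Net("pairs")
        net.add_colorset("C", ["a", "b"])
        net.add_place("X", ["C"])
        net.add_transition("take2", "stochastic", rate=1.0)
        net.add_input("X", "take2", "2'(v)")
        m = net.initial_marking()
        m["X"] = Multiset.of({("a",): 4, ("b",): 1})
        got = self.as_dict(enumerate_bindings(net, "take2", m))
        assert got == brute_force_bindings(net, "take2", m)
        assert got[(("v", "a"),)] == count_selections(4, 2)


class TestFire:
    def test_th_b_interaction_products(self, immune_net, rng):
        """The central duplication/differentiation event: 2 TH back, a
        memory B cell and a plasma cell, all with renewed life."""
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("active", 0, 7, 4): 1})
        m["B"] = Multiset.of({("presenting", 0, 2, 4): 1})
        (element,) = enumerate_bindings(immune_net, "TH_B_interact", m)
        m2 = fire(immune_net, "TH_B_interact", element.binding, m, rng)
        assert m2["TH"] == Multiset.of({("active", 0, 10, 4): 2})
        assert m2["B"] == Multiset.of({("memory", 0, 10, 4): 1})
        assert m2["PB"] == Multiset.of({("plasma", 0, 10, 4): 1})

    def test_source_burst_draws_random_position_and_receptor(self, immune_net, rng):
        m = immune_net.initial_marking()
        m2 = fire(immune_net, "gen_TH", {}, m, rng)
        assert m2["TH"].total() == 10
        ((value, count),) = m2["TH"].items()
        state, pos, life, receptor = value
        assert (state, life) == ("resting", 10) and count == 10
        assert pos == 0 and 0 <= receptor <= 9
        # receptors vary across firings (uniform draw per firing)
        receptors = {next(iter(fire(immune_net, "gen_TH", {}, m, rng)["TH"]))[3] for _ in range(30)}
        assert len(receptors) > 3

    def test_aging_conserves_tokens_and_decrements_life(self, immune_net, rng):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("resting", 0, 1, 3): 1})
        (element,) = enumerate_bindings(immune_net, "age_TH", m)
        m2 = fire(immune_net, "age_TH", element.binding, m, rng)
        assert m2["TH"] == Multiset.of({("resting", 0, 0, 3): 1})
        assert m2["TH"].total() == m["TH"].total()

    def test_original_marking_untouched(self, immune_net, rng):
        m = immune_net.initial_marking()
        m["TH"] = Multiset.of({("resting", 0, 1, 3): 1})
        snapshot = m.copy()
        (element,) = enumerate_bindings(immune_net, "age_TH", m)
        fire(immune_net, "age_TH", element.binding, m, rng)
        assert m == snapshot

    def test_firing_disabled_binding_is_hard_error(self, immune_net, rng):
        m = immune_net.initial_marking()
        binding = {"c:1": "resting", "c:2": 0, "c:3": 5, "c:4": 1}
        with pytest.raises(FiringError):
            fire(immune_net, "age_TH", binding, m, rng)

    def test_firing_conservation_identity(self, immune_net, rng):
        """m'(p) - m(p) equals produced minus consumed, per place."""
        m = immune_net.initial_marking()
        m["B"] = Multiset.of({("resting", 0, 6, 3): 2})
        m["Bacteria"] = Multiset.of({(0, 10, 3): 5})
        (element,) = enumerate_bindings(immune_net, "B_recognize", m)
        m2 = fire(immune_net, "B_recognize", element.binding, m, rng)
        diff = {
            p: {v: m2[p].get(v, 0) - m[p].get(v, 0) for v in set(m2[p]) | set(m[p])}
            for p in immune_net.places
        }
        assert diff["B"] == {("resting", 0, 6, 3): -1, ("active", 0, 10, 3): 1}
        assert diff["IgM"] == {(0, 10, 3): 5}
        assert all(v == 0 for v in diff["Bacteria"].values())  # bacterium returned
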