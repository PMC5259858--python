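import pytest

from cgspn.fixtures import birth_death, random_walk_2d
from cgspn.net import Net, NetError, unfold_report, validate_net


def small_cell_net():
    net = Net("mini")
    net.add_colorset("STATE", ["resting", "active"])
    net.add_colorset("POSITION", [0])
    net.add_colorset("LIFE", range(11))
    net.add_colorset("RECEPTOR", range(10))
    net.add_product("CELL", ["STATE", "POSITION", "LIFE", "RECEPTOR"])
    net.add_place("TH", "CELL")
    return net


class TestValidation:
    def test_arity_mismatch_is_diagnosed(self):
        net = small_cell_net()
        net.add_transition("die", "stochastic", rate=1.0)
        net.add_input("TH", "die", "1'(a, b, c)")  # 3 terms against 4 components
        diags = validate_net(net)
        assert any("arity mismatch" in d for d in diags)

    def test_wellformed_birth_death_is_clean(self):
        assert validate_net(birth_death()) == []

    def test_default_immune_model_is_clean(self, immune_net):
        assert validate_net(immune_net) == []

    def test_validation_is_idempotent_and_pure(self, immune_net):
        before = len(immune_net.arcs)
        assert validate_net(immune_net) == validate_net(immune_net) == []
        assert len(immune_net.arcs) == before

    def test_strict_mode_raises(self):
        net = small_cell_net()
        net.add_transition("die", "stochastic", rate=1.0)
        net.add_input("TH", "die", "1'(a, b, c)")
        with pytest.raises(NetError):
            validate_net(net, strict=True)

    def test_kind_parameter_discipline(self):
        net = small_cell_net()
        net.add_transition("no_rate", "stochastic")
        net.add_transition("bad_delay", "delayed")
        net.add_transition("bad_sched", "scheduled", schedule=(10.0, None, 5.0))
        diags = validate_net(net)
        assert any("no_rate" in d and "rate" in d for d in diags)
        assert any("bad_delay" in d and "delay" in d for d in diags)
        assert any("bad_sched" in d for d in diags)

    def test_guard_variable_must_be_bound_by_input_arc(self):
        net = small_cell_net()
        net.add_transition("gen", "stochastic", rate=1.0, guard="[c:3 = 0]")
        net.add_output("gen", "TH", "1'(c)")
        diags = validate_net(net)
        assert any("c:3" in d for d in diags)

    def test_guard_constant_type_checks(self):
        net = small_cell_net()
        net.add_transition("bad", "stochastic", rate=1.0)
        net.add_input("TH", "bad", '1\'("zombie", p, l, r)')
        assert any("zombie" in d for d in validate_net(net))

    def test_duplicate_names_rejected(self):
        net = small_cell_net()
        with pytest.raises(NetError):
            net.add_place("TH", "CELL")
        net.add_transition("t", "stochastic", rate=1.0)
        with pytest.raises(NetError):
            net.add_transition("t", "immediate")


class TestUnfoldReport:
    def test_cell_and_mol_place_sizes(self, immune_net):
        report = unfold_report(immune_net)
        assert report["places"]["TH"] == 5 * 1 * 11 * 10 == 550
        assert report["places"]["Bacteria"] == 1 * 11 * 10 == 110

    def test_total_is_product_sum(self, immune_net):
        report = unfold_report(immune_net)
        assert report["total_places"] == 6 * 550 + 3 * 110 == 3630

    def test_transition_enumeration_on_small_net(self):
        net = random_walk_2d(3)
        report = unfold_report(net, enumerate_transitions=True)
        # each move transition unfolds to one low-level copy per grid cell
        assert all(report["transitions"][t] == 9 for t in ("x_inc", "x_dec", "y_inc", "y_dec"))
        assert report["total_transitions"] == 36

    def test_guard_restricts_satisfiable_bindings(self):
        net = small_cell_net()
        net.add_transition("die", "stochastic", rate=1.0, guard="[c:3 = 0]")
        net.add_input("TH", "die", "1'(c)")
        report = unfold_report(net, enumerate_transitions=True)
        # LIFE pinned to 0 leaves STATE x POSITION x RECEPTOR assignments
        assert report["transitions"]["die"] == 2 * 1 * 10

    def test_cap_refuses_oversized_enumeration(self, immune_net):
        report = unfold_report(immune_net, enumerate_transitions=True, cap=100)
        assert report["transitions"]["TH_B_interact"] == "too large; structural counts only"
        assert report["total_transitions"] is None


def test_fixture_nets_are_all_wellformed():
    from cgspn.fixtures import fixture_nets

    nets = fixture_nets()
    assert set(nets) == {
        "birth_death",
        "exponential_race",
        "preemption",
        "immediate_conflict",
        "scheduled_injection",
        "random_walk_2d",
    }
    for name, net in nets.items():
        assert validate_net(net) == [], name
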