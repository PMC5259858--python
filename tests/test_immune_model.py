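import dataclasses

import numpy as np
import pytest

from cgspn.immune import (
    ENTITY_PLACES,
    ImmuneParams,
    Injection,
    build_model,
    default_params,
    model_observables,
)
from cgspn.scheduler import Observable, run

CELL_STATES = {
    "B": {"resting", "active", "presenting", "memory"},
    "PB": {"plasma"},
    "MP": {"resting", "presenting"},
    "TH": {"resting", "active"},
}


class TestStructure:
    def test_nine_places_seven_of_them_entities(self, immune_net):
        assert len(immune_net.places) == 9
        assert set(ENTITY_PLACES) <= set(immune_net.places)
        assert len(ENTITY_PLACES) == 7
        assert set(immune_net.places) - set(ENTITY_PLACES) == {"MP_proc", "B_proc"}

    def test_twenty_seven_transitions(self, immune_net):
        assert len(immune_net.transitions) == 27

    def test_fifty_five_arcs(self, immune_net):
        assert len(immune_net.arcs) == 55

    def test_cellular_and_molecular_typing(self, immune_net):
        for place in ("MP", "TH", "B", "PB", "MP_proc", "B_proc"):
            assert immune_net.places[place].colorset.arity == 4
        for place in ("Bacteria", "IgM", "IgG"):
            assert immune_net.places[place].colorset.arity == 3

    def test_transition_kind_inventory(self, immune_net):
        kinds = {}
        for t in immune_net.transitions.values():
            kinds[t.kind] = kinds.get(t.kind, 0) + 1
        assert kinds == {"stochastic": 23, "scheduled": 2, "delayed": 2}

    def test_optional_igm_kill_extends_inventory(self):
        p = dataclasses.replace(default_params(), igm_kill_rate=1e-5)
        net = build_model(p)
        assert "IgM_kill" in net.transitions and len(net.transitions) == 28


class TestParams:
    def test_default_params_build_cleanly(self):
        build_model(default_params())

    def test_invalid_params_rejected_with_named_diagnostics(self):
        p = dataclasses.replace(default_params(), source_rate=-1.0, igm_burst=0)
        with pytest.raises(ValueError) as err:
            build_model(p)
        assert "source_rate" in str(err.value) and "igm_burst" in str(err.value)

    def test_epitope_outside_receptor_range_rejected(self):
        p = default_params().with_injections([Injection(100.0, ((10, 12),))])
        with pytest.raises(ValueError) as err:
            build_model(p)
        assert "epitope" in str(err.value)


@pytest.fixture(scope="module")
def infected_markings(immune_net):
    return run(immune_net, 130, model_observables([3]), seed=9, record_markings=True)


class TestDynamicsInvariants:
    def test_state_discipline_on_every_recorded_marking(self, infected_markings):
        """Tokens never migrate into a place whose entity type forbids
        their internal state, and every life counter stays within range."""
        for marking in infected_markings.markings:
            for place, allowed in CELL_STATES.items():
                for value in marking[place]:
                    assert value[0] in allowed, (place, value)
                    assert 0 <= value[2] <= 10
            for place in ("Bacteria", "IgM", "IgG"):
                for value in marking[place]:
                    assert 0 <= value[1] <= 10

    def test_specificity_closure_single_epitope(self, infected_markings):
        """With only epitope 3 injected, every IgG and every non-resting
        B/TH token carries receptor 3 (recognition is strict equality)."""
        for marking in infected_markings.markings:
            for value in marking["IgG"]:
                assert value[2] == 3
            for place in ("B", "TH"):
                for value in marking[place]:
                    if value[0] != "resting":
                        assert value[3] == 3, (place, value)

    def test_no_bacteria_before_first_injection(self, infected_markings):
        counts = infected_markings.counts["bacteria_3"]
        assert counts[:100].sum() == 0
        assert counts[100] == 2000

    def test_memory_b_cells_do_not_age(self, immune_net):
        from cgspn.net import Multiset
        from cgspn.semantics import enumerate_bindings

        m = immune_net.initial_marking()
        m["B"] = Multiset.of({("memory", 0, 5, 3): 1, ("active", 0, 5, 3): 1})
        bindings = enumerate_bindings(immune_net, "age_B", m)
        assert len(bindings) == 1
        assert bindings[0].binding["c:1"] == "active"


class TestHomeostasis:
    def test_th_population_stationary_within_burn_in(self, immune_net):
        """Source/death balance settles well before the first injection."""
        traj = run(immune_net, 99, [Observable("TH", "TH")], seed=21)
        th = traj.counts["TH"].astype(float)
        reference = th[60:80]
        late = th[80:]
        assert abs(late.mean() - reference.mean()) < 3 * reference.std(ddof=1)
        assert th[90:].min() > 0
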