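import numpy as np
import pytest

from cgspn.fixtures import (
    birth_death,
    exponential_race,
    immediate_conflict,
    preemption_net,
    random_walk_2d,
    scheduled_injection,
)
from cgspn.net import Multiset, Net
from cgspn.scheduler import (
    LivelockError,
    Observable,
    Simulator,
    run,
    run_replicates,
    sample_stochastic_delay,
)


def source_net(rate=2.0):
    net = Net("pure_source")
    net.add_colorset("U", ["u"])
    net.add_place("X", ["U"])
    net.add_transition("src", "stochastic", rate=rate)
    net.add_output("src", "X", "1'(\"u\")")
    return net


class TestExponentialSampler:
    def test_mean_within_three_standard_errors(self, rng):
        lam = 2.5
        draws = np.array([sample_stochastic_delay(lam, rng) for _ in range(10_000)])
        assert abs(draws.mean() - 1 / lam) < 3 * (1 / lam) / np.sqrt(10_000)

    def test_huge_rate_gives_vanishing_waits(self, rng):
        draws = [sample_stochastic_delay(1e6, rng) for _ in range(101)]
        assert np.median(draws) < 1e-5

    def test_fixed_seed_reproduces_sequence(self):
        a = [sample_stochastic_delay(1.0, np.random.default_rng(7)) for _ in range(5)]
        b = [sample_stochastic_delay(1.0, np.random.default_rng(7)) for _ in range(5)]
        assert a == b

    def test_nonpositive_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_stochastic_delay(0.0, rng)


class TestImmediatePriority:
    def test_immediate_always_beats_stochastic_conflict(self):
        net = immediate_conflict(stochastic_rate=1e6)
        obs = [Observable("imm", "WonImmediate"), Observable("sto", "WonStochastic")]
        wins = sum(run(net, 1, obs, seed=s).final("imm") for s in range(1000))
        assert wins == 1000

    def test_immediate_consumes_no_time(self):
        net = immediate_conflict()
        traj = run(net, 1, [Observable("imm", "WonImmediate")], seed=0, record_events=True)
        (event,) = [e for e in traj.events if e.transition == "imm"]
        assert event.time == 0.0

    def test_immediate_source_livelocks(self):
        net = Net("livelock")
        net.add_colorset("U", ["u"])
        net.add_place("X", ["U"])
        net.add_transition("imm", "immediate")
        net.add_output("imm", "X", "1'(\"u\")")
        with pytest.raises(LivelockError):
            run(net, 1, [Observable("X", "X")], seed=0, max_immediate_chain=50)


class TestDelayed:
    def delayed_only_net(self, delay=5.0):
        net = Net("delayed_only")
        net.add_colorset("U", ["u"])
        net.add_place("X", ["U"])
        net.add_place("Done", ["U"])
        net.add_transition("proc", "delayed", delay=delay)
        net.add_input("X", "proc", "1'(v)")
        net.add_output("proc", "Done", "1'(v)")
        net.set_initial("X", [("u",)])
        return net

    def test_fires_exactly_delay_after_enabling(self):
        traj = run(self.delayed_only_net(5.0), 10, [Observable("Done", "Done")], seed=0, record_events=True)
        (event,) = [e for e in traj.events if e.fired]
        assert event.time == 5.0 and event.transition == "proc"
        assert traj.counts["Done"][4] == 0 and traj.counts["Done"][5] == 1

    def test_preempted_timer_never_fires(self):
        net = preemption_net(delay=5.0, competitor_rate=10.0)
        obs = [Observable("slow", "Slow"), Observable("fast", "Fast")]
        for seed in range(50):
            traj = run(net, 30, obs, seed=seed)
            assert traj.final("slow") == 0 and traj.final("fast") == 1

    def test_identical_tokens_hold_concurrent_timers(self):
        net = self.delayed_only_net(3.0)
        net.set_initial("X", {("u",): 4})
        sim = Simulator(net, seed=0)
        assert len(sim.pending_events()) == 4
        traj = run(net, 10, [Observable("Done", "Done")], seed=0)
        assert traj.counts["Done"][2] == 0 and traj.counts["Done"][3] == 4

    def test_pending_events_visible(self):
        sim = Simulator(self.delayed_only_net(5.0), seed=0)
        (pe,) = sim.pending_events()
        assert pe.due_time == 5.0 and pe.origin == "delayed" and pe.transition == "proc"


class TestScheduled:
    def test_fires_exactly_at_absolute_time(self):
        net = scheduled_injection(start=100.0, count=2000)
        traj = run(net, 101, [Observable("X", "X")], seed=3, record_events=True)
        assert traj.counts["X"][99] == 0 and traj.counts["X"][100] == 2000
        (event,) = traj.events
        assert event.time == 100.0

    def test_periodic_schedule_respects_start_period_end(self):
        net = scheduled_injection(start=2.0, count=1, period=3.0, end=11.0)
        traj = run(net, 15, [Observable("X", "X")], seed=0, record_events=True)
        assert [e.time for e in traj.events] == [2.0, 5.0, 8.0, 11.0]

    def test_disabled_occurrence_is_skipped(self):
        net = Net("sched_consume")
        net.add_colorset("U", ["u"])
        net.add_place("X", ["U"])
        net.add_transition("take", "scheduled", schedule=(3.0, None, None))
        net.add_input("X", "take", "1'(v)")
        traj = run(net, 5, [Observable("X", "X")], seed=0, record_events=True)
        (event,) = traj.events
        assert not event.fired and event.kind == "skipped"


class TestRunStatistics:
    def test_pure_source_is_poisson(self):
        """A constant-rate source to time T yields mean count lam*T."""
        lam, T, n = 2.0, 10, 200
        s = run_replicates(source_net(lam), T, [Observable("X", "X")], n=n, base_seed=10)
        finals = s.counts["X"][:, -1]
        assert abs(finals.mean() - lam * T) < 3 * np.sqrt(lam * T / n)

    def test_birth_death_reaches_mm_infinity_stationarity(self):
        lam, mu, n = 2.0, 0.5, 200
        s = run_replicates(birth_death(lam, mu), 30, [Observable("X", "X")], n=n, base_seed=20)
        finals = s.counts["X"][:, -1]
        mean = lam / mu
        assert abs(finals.mean() - mean) < 3 * np.sqrt(mean / n)

    def test_stationary_sd_is_poisson(self):
        lam, mu = 2.0, 0.5
        s = run_replicates(birth_death(lam, mu), 30, [Observable("X", "X")], n=100, base_seed=30)
        sd = s.counts["X"][:, -1].std(ddof=1)
        assert abs(sd - np.sqrt(lam / mu)) / np.sqrt(lam / mu) < 0.2

    def test_empty_net_gives_zero_trajectory(self):
        net = Net("empty")
        net.add_colorset("U", ["u"])
        net.add_place("X", ["U"])
        traj = run(net, 10, [Observable("X", "X")], seed=0)
        assert traj.counts["X"].sum() == 0

    def test_exponential_race_consumes_single_token_once(self):
        traj = run(exponential_race(1.0, 3.0), 50, [Observable("X", "X")], seed=0, record_events=True)
        assert traj.final("X") == 0
        assert sum(e.fired for e in traj.events) == 1


class TestDeterminismAndClock:
    def test_same_seed_bit_identical(self, immune_net):
        obs = [Observable("TH", "TH"), Observable("B", "B")]
        a = run(immune_net, 50, obs, seed=11)
        b = run(immune_net, 50, obs, seed=11)
        assert all(np.array_equal(a.counts[k], b.counts[k]) for k in a.counts)

    def test_event_recording_does_not_change_the_draws(self):
        net = birth_death(2.0, 0.5)
        a = run(net, 20, [Observable("X", "X")], seed=5)
        b = run(net, 20, [Observable("X", "X")], seed=5, record_events=True)
        assert np.array_equal(a.counts["X"], b.counts["X"])

    def test_replicate_summary_reproducible_and_single_rep_mean(self):
        net = birth_death(1.0, 0.5)
        s1 = run_replicates(net, 10, [Observable("X", "X")], n=5, base_seed=3)
        s2 = run_replicates(net, 10, [Observable("X", "X")], n=5, base_seed=3)
        assert np.array_equal(s1.counts["X"], s2.counts["X"])
        single = run_replicates(net, 10, [Observable("X", "X")], n=1, base_seed=3)
        traj = run(net, 10, [Observable("X", "X")], seed=3)
        assert np.array_equal(single.mean["X"], traj.counts["X"].astype(float))

    def test_mean_within_replicate_envelope(self):
        s = run_replicates(birth_death(2.0, 0.5), 20, [Observable("X", "X")], n=10, base_seed=1)
        x = s.counts["X"]
        assert np.all(s.mean["X"] <= x.max(axis=0)) and np.all(s.mean["X"] >= x.min(axis=0))

    def test_event_times_never_decrease(self):
        traj = run(birth_death(5.0, 1.0), 20, [Observable("X", "X")], seed=2, record_events=True)
        times = [e.time for e in traj.events]
        assert all(t1 <= t2 for t1, t2 in zip(times, times[1:]))


class TestIncrementalPropensityExactness:
    """The incremental indexes must agree with from-scratch enumeration."""

    def test_weights_match_enumeration_mid_infection(self, immune_net):
        sim = Simulator(immune_net, seed=4, record_events=False)
        while sim.step(105.0) is not None:
            pass
        for state in sim.stochastic:
            expected = sum(e.weight for e in state.ct.enumerate(sim.marking))
            assert state.weight == expected, state.ct.name

    def test_delayed_timers_match_enabled_instances(self, immune_net):
        sim = Simulator(immune_net, seed=4, record_events=False)
        while sim.step(105.0) is not None:
            pass
        for ds in sim.delayed:
            expected = sum(e.weight for e in ds.ct.enumerate(sim.marking))
            assert sum(len(v[1]) for v in ds.timers.values()) == expected

    def test_compiled_fire_matches_generic_deltas(self, immune_net, rng):
        sim = Simulator(immune_net, seed=4, record_events=False)
        while sim.step(105.0) is not None:
            pass
        for state in sim.stochastic:
            if state.fast_fire is None or state.weight <= 0:
                continue
            vals = state.sample_values(lambda: 0.37)
            binding = state.binding_of(vals)
            generic, _ = state.ct.fire_deltas(binding, sim.marking, rng)
            agg_fast, agg_gen = {}, {}
            for place, value, dn in state.fast_fire(*vals):
                agg_fast[(place, value)] = agg_fast.get((place, value), 0) + dn
            for place, value, dn in generic:
                agg_gen[(place, value)] = agg_gen.get((place, value), 0) + dn
            agg_gen = {k: v for k, v in agg_gen.items() if v}
            agg_fast = {k: v for k, v in agg_fast.items() if v}
            assert agg_fast == agg_gen, state.ct.name
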