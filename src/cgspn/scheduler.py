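"""Hybrid continuous-time simulation of a colored generalized stochastic net.

Event semantics, in priority order at any instant:

* **immediate** transitions fire first, consuming no time; a binding is
  chosen with probability proportional to its combinatorial weight;
* **scheduled** transitions fire at their fixed absolute times when enabled
  (a disabled occurrence is skipped);
* **delayed** transitions fire exactly ``delay`` after the instant a binding
  became enabled, unless enabling was lost in between (pre-emptive rule);
* **stochastic** transitions race with exponential waiting times; the
  transition is selected proportionally to ``rate * total_weight``
  (Gillespie direct method on the colored net), the binding proportionally
  to its weight.

Propensities are kept exactly synchronized with the marking through
incremental per-transition indexes (a count index for single-input-arc
transitions, a hash-join index over guard equality atoms for two-place
interactions, full re-enumeration as the general fallback).  Weights are
integers, so there is no floating-point drift; the total stochastic rate is
re-summed from the per-transition weights every step.  The indexes use
per-transition compiled token tests (:mod:`cgspn._fastpath`) where the
transition shape allows, and fall back to the generic matcher otherwise.

One simulated time unit corresponds to one model step (8 h in the immune
model); rates are per time unit.  Each replicate owns a single seeded
:class:`numpy.random.Generator`; replicate ``i`` uses ``base_seed + i``,
and identical seeds give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._fastpath import arc_info, compile_fire, compile_key, compile_test
from .expressions import Comp
from .net import Marking, Net
from .semantics import BindingElement, CompiledTransition

__all__ = [
    "Observable",
    "PendingEvent",
    "FiredEvent",
    "Trajectory",
    "ReplicateSummary",
    "Simulator",
    "LivelockError",
    "SchedulerError",
    "sample_stochastic_delay",
    "run",
    "run_replicates",
]

_INF = float("inf")


class SchedulerError(RuntimeError):
    pass


class LivelockError(SchedulerError):
    """Too many consecutive immediate firings without time advancing."""


def sample_stochastic_delay(rate: float, rng) -> float:
    """Exponential waiting time with mean ``1/rate`` (the stochastic-firing pdf)."""
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return float(rng.exponential(1.0 / rate))


# ---------------------------------------------------------------------------
# observables and results


class Observable:
    """A recorded quantity: token count of a place, optionally filtered.

    ``where`` is either a mapping of 0-based component index -> required
    value (e.g. ``{2: 3}`` for "receptor equals 3") or a predicate over the
    whole token value.
    """

    __slots__ = ("name", "place", "where", "_pred")

    def __init__(self, name: str, place: str, where=None):
        self.name = name
        self.place = place
        self.where = where
        if where is None:
            self._pred = None
        elif callable(where):
            self._pred = where
        else:
            items = tuple(where.items())
            self._pred = lambda v: all(v[i] == x for i, x in items)

    def count(self, marking: Marking) -> int:
        ms = marking.get(self.place)
        if not ms:
            return 0
        if self._pred is None:
            return ms.total()
        pred = self._pred
        return sum(k for v, k in ms.items() if pred(v))


@dataclass(frozen=True)
class PendingEvent:
    """A queued deterministic firing (delayed timer or scheduled slot)."""

    due_time: float
    transition: str
    binding: Optional[dict]  # None for scheduled transitions
    origin: str  # "delayed" | "scheduled"


@dataclass(frozen=True)
class FiredEvent:
    time: float
    kind: str  # transition kind, or "cancelled"/"skipped"
    transition: str
    binding: Optional[dict]
    fired: bool = True


#: sentinel returned by :meth:`Simulator.step` when event records are off
_FIRED = FiredEvent(-1.0, "internal", "", None)


@dataclass
class Trajectory:
    """Per-replicate time series of observable counts on the integer grid."""

    replicate: int
    seed: int
    times: np.ndarray
    counts: dict  # observable name -> int array aligned with times
    events: Optional[list] = None
    markings: Optional[list] = None

    def final(self, name: str) -> int:
        return int(self.counts[name][-1])


@dataclass
class ReplicateSummary:
    """Mean/sd trajectories across replicates; raw counts kept for checks."""

    times: np.ndarray
    counts: dict  # name -> array of shape (n_replicates, n_times)
    seeds: list
    mean: dict = field(init=False)
    sd: dict = field(init=False)

    def __post_init__(self):
        self.mean = {k: v.mean(axis=0) for k, v in self.counts.items()}
        ddof = 1 if self.n > 1 else 0
        self.sd = {k: v.std(axis=0, ddof=ddof) for k, v in self.counts.items()}

    @property
    def n(self) -> int:
        return next(iter(self.counts.values())).shape[0] if self.counts else 0


# ---------------------------------------------------------------------------
# per-transition propensity state


def _slow_test(arc, atoms):
    def test(v):
        b = arc.match(v, {})
        if b is None:
            return False
        return all(a.evaluate(b) for a in atoms)

    return test


def _slow_key(arc, keyslots):
    def key(v):
        b = arc.match(v, {})
        return tuple(b[s] for s in keyslots)

    return key


class _Constant:
    """Transition with no input places: always enabled, weight 1."""

    __slots__ = ("ct", "rate", "fast_fire")

    places = ()
    weight = 1

    def __init__(self, ct: CompiledTransition):
        self.ct = ct
        self.rate = ct.obj.rate
        self.fast_fire = None  # sources draw random slots: generic firing

    def on_delta(self, place, value, dn):  # pragma: no cover - never subscribed
        pass

    def refresh(self, marking):
        pass

    def sample_values(self, urand):
        return ()

    def binding_of(self, vals) -> dict:
        return {}


class _Unary:
    """Single input arc, multiplicity 1: weight = matching token count."""

    __slots__ = ("ct", "rate", "place", "places", "arc", "test", "index", "weight", "fast_fire")

    def __init__(self, ct: CompiledTransition):
        self.ct = ct
        self.rate = ct.obj.rate
        arc = ct.inputs[0]
        self.arc = arc
        self.place = arc.place
        self.places = (arc.place,)
        info = arc_info(arc)
        test = compile_test(info, ct.atoms) if info is not None else None
        self.test = test if test is not None else _slow_test(arc, ct.atoms)
        self.fast_fire = compile_fire(ct, ["a"])
        self.index: dict = {}
        self.weight = 0

    def refresh(self, marking):
        self.index.clear()
        self.weight = 0
        test = self.test
        for v, n in marking[self.place].items():
            if test(v):
                self.index[v] = n
                self.weight += n

    def on_delta(self, place, value, dn):
        if not self.test(value):
            return
        n = self.index.get(value, 0) + dn
        if n:
            self.index[value] = n
        else:
            self.index.pop(value, None)
        self.weight += dn

    def sample_values(self, urand):
        return (_weighted_value(self.index, urand() * self.weight),)

    def binding_of(self, vals) -> dict:
        return self.arc.match(vals[0], {})


class _Join2:
    """Two input arcs (mult 1, distinct places) joined on equality atoms.

    Each side keeps ``key -> [total, {value: count}]`` over tokens passing
    its unary conditions; the total weight is ``sum tot1[k] * tot2[k]``,
    maintained incrementally under token deltas.
    """

    __slots__ = ("ct", "rate", "places", "arcs", "tests", "keys", "sides", "weight", "fast_fire")

    @staticmethod
    def plan(ct: CompiledTransition):
        """Return a _Join2 when the transition fits the join shape, else None."""
        if len(ct.inputs) != 2 or ct.atoms is None:
            return None
        a1, a2 = ct.inputs
        if a1.place == a2.place or a1.mult != 1 or a2.mult != 1:
            return None
        s1, s2 = set(a1.slots), set(a2.slots)
        unary: tuple[list, list] = ([], [])
        pairs = [(s, s) for s in sorted(s1 & s2)]
        for atom in ct.atoms:
            slots = atom.slots()
            if slots <= s1:
                unary[0].append(atom)
            elif slots <= s2:
                unary[1].append(atom)
            elif (
                atom.op == "="
                and isinstance(atom.lhs, Comp)
                and isinstance(atom.rhs, Comp)
            ):
                l, r = atom.lhs.slot, atom.rhs.slot
                if l in s1 and r in s2:
                    pairs.append((l, r))
                elif r in s1 and l in s2:
                    pairs.append((r, l))
                else:
                    return None
            else:
                return None
        return _Join2(ct, unary, pairs)

    def __init__(self, ct: CompiledTransition, unary, pairs):
        self.ct = ct
        self.rate = ct.obj.rate
        self.arcs = (ct.inputs[0], ct.inputs[1])
        self.places = (ct.inputs[0].place, ct.inputs[1].place)
        self.tests = []
        self.keys = []
        for side in (0, 1):
            arc = self.arcs[side]
            keyslots = tuple(p[side] for p in pairs)
            info = arc_info(arc)
            test = compile_test(info, unary[side]) if info is not None else None
            key = compile_key(info, keyslots) if info is not None else None
            self.tests.append(test if test is not None else _slow_test(arc, unary[side]))
            self.keys.append(key if key is not None else _slow_key(arc, keyslots))
        self.fast_fire = compile_fire(ct, ["a", "b"])
        self.sides: tuple = ({}, {})
        self.weight = 0

    def refresh(self, marking):
        self.sides = ({}, {})
        for side in (0, 1):
            test, key = self.tests[side], self.keys[side]
            bucket = self.sides[side]
            for v, n in marking[self.places[side]].items():
                if not test(v):
                    continue
                entry = bucket.setdefault(key(v), [0, {}])
                entry[0] += n
                entry[1][v] = entry[1].get(v, 0) + n
        s1, s2 = self.sides
        self.weight = sum(e[0] * s2[k][0] for k, e in s1.items() if k in s2)

    def on_delta(self, place, value, dn):
        side = 0 if place == self.places[0] else 1
        if not self.tests[side](value):
            return
        k = self.keys[side](value)
        other = self.sides[1 - side].get(k)
        if other is not None:
            self.weight += dn * other[0]
        entry = self.sides[side].setdefault(k, [0, {}])
        entry[0] += dn
        n = entry[1].get(value, 0) + dn
        if n:
            entry[1][value] = n
        else:
            del entry[1][value]
            if entry[0] == 0:
                del self.sides[side][k]

    def sample_values(self, urand):
        s1, s2 = self.sides
        r = urand() * self.weight
        acc = 0.0
        e1 = e2 = None
        for k, e in s1.items():
            o = s2.get(k)
            if o is None:
                continue
            acc += e[0] * o[0]
            e1, e2 = e, o
            if r < acc:
                break
        # the weight factorizes over the two sides: draw each independently
        v1 = _weighted_value(e1[1], urand() * e1[0])
        v2 = _weighted_value(e2[1], urand() * e2[0])
        return v1, v2

    def binding_of(self, vals) -> dict:
        b = self.arcs[0].match(vals[0], {})
        return self.arcs[1].match(vals[1], b)


def _weighted_value(counts: dict, r: float):
    acc = 0.0
    chosen = None
    for v, n in counts.items():
        acc += n
        chosen = v
        if r < acc:
            break
    return chosen


class _Generic:
    """Fallback: full re-enumeration when an input place changed."""

    __slots__ = ("ct", "rate", "places", "dirty", "weight", "_elements", "fast_fire")

    def __init__(self, ct: CompiledTransition):
        self.ct = ct
        self.rate = ct.obj.rate
        self.places = tuple({a.place for a in ct.inputs})
        self.dirty = True
        self.weight = 0
        self._elements: list[BindingElement] = []
        self.fast_fire = None

    def on_delta(self, place, value, dn):
        self.dirty = True

    def refresh(self, marking):
        self.dirty = True
        self.ensure(marking)

    def ensure(self, marking):
        if self.dirty:
            self._elements = self.ct.enumerate(marking)
            self.weight = sum(e.weight for e in self._elements)
            self.dirty = False

    def sample_binding(self, marking, urand) -> dict:
        self.ensure(marking)
        r = urand() * self.weight
        acc = 0.0
        chosen = self._elements[0]
        for e in self._elements:
            acc += e.weight
            chosen = e
            if r < acc:
                break
        return chosen.binding


def _make_state(ct: CompiledTransition):
    if ct.obj.rate_function is not None:
        return _Generic(ct)  # marking-dependent rate: keep bindings fresh
    if not ct.inputs:
        return _Constant(ct)
    if ct.atoms is not None and len(ct.inputs) == 1 and ct.inputs[0].mult == 1:
        return _Unary(ct)
    join = _Join2.plan(ct)
    if join is not None:
        return join
    return _Generic(ct)


class _DelayedState:
    """Timer bookkeeping for one delayed transition.

    One timer per enabled *instance*: a binding enabled with weight w holds
    w concurrent timers.  Timers start when the instance becomes enabled
    and are cancelled as soon as enabling is lost (pre-emptive rule);
    enabling is re-verified at the due instant as a final check.
    """

    __slots__ = ("ct", "delay", "places", "timers", "earliest_due", "earliest_keys")

    def __init__(self, ct: CompiledTransition):
        self.ct = ct
        self.delay = ct.obj.delay
        self.places = tuple({a.place for a in ct.inputs})
        self.timers: dict = {}  # key -> [binding, list_of_due_times]
        self.earliest_due = _INF
        self.earliest_keys: list = []

    def sync(self, marking, now: float):
        """Reconcile timers with the currently enabled bindings."""
        current = {}
        for e in self.ct.enumerate(marking):
            key = tuple(sorted(e.binding.items()))
            current[key] = (e.binding, e.weight)
        for key in list(self.timers):
            if key not in current:
                del self.timers[key]
        for key, (binding, w) in current.items():
            entry = self.timers.get(key)
            if entry is None:
                entry = self.timers[key] = [binding, []]
            dues = entry[1]
            while len(dues) < w:
                dues.append(now + self.delay)
            while len(dues) > w:
                dues.pop()  # cancel newest first; oldest timers survive
        self._rescan()

    def _rescan(self):
        best, keys = _INF, []
        for key, (_b, dues) in self.timers.items():
            if not dues:
                continue
            due = dues[0]
            if due < best:
                best, keys = due, [key]
            elif due == best:
                keys.append(key)
        self.earliest_due, self.earliest_keys = best, keys

    def pop(self, key):
        binding, dues = self.timers[key]
        dues.pop(0)
        if not dues:
            del self.timers[key]
        self._rescan()
        return binding

    def pending(self):
        for _key, (binding, dues) in sorted(self.timers.items()):
            for due in dues:
                yield PendingEvent(due, self.ct.name, dict(binding), "delayed")


class _SchedState:
    __slots__ = ("ct", "times", "next_time")

    def __init__(self, ct: CompiledTransition):
        self.ct = ct
        self.times = ct.obj.schedule_times()
        self.next_time = next(self.times, _INF)

    def advance(self):
        self.next_time = next(self.times, _INF)


# ---------------------------------------------------------------------------
# the simulator


class Simulator:
    """Stateful hybrid simulator over a compiled net.

    ``step(max_time)`` fires the next event at or before ``max_time`` and
    returns its :class:`FiredEvent`, or advances the clock to ``max_time``
    and returns ``None`` when no event is due.  The clock never decreases.
    With ``record_events=False`` (the bulk-simulation mode used by
    :func:`run`) successful firings return a shared sentinel instead of a
    fresh event record; the random-number stream is identical either way.
    """

    def __init__(
        self,
        net: Net,
        seed: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        max_immediate_chain: int = 1000,
        record_events: bool = True,
    ):
        self.net = net
        self.compiled = net.compiled()
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.max_immediate_chain = max_immediate_chain
        self.record_events = record_events
        self.marking: Marking = net.initial_marking()
        self.time = 0.0
        self._imm_chain = 0

        self.stochastic: list = []
        self._lazy: list = []  # generic/rate-function states needing ensure()
        self.immediates: list = []
        self.delayed: list[_DelayedState] = []
        self.scheduled: list[_SchedState] = []
        self._by_place: dict[str, list] = {p: [] for p in net.places}
        self._delayed_by_place: dict[str, list] = {p: [] for p in net.places}

        for name, ct in self.compiled.transitions.items():
            kind = ct.obj.kind
            if kind in ("stochastic", "immediate"):
                state = _make_state(ct)
                state.refresh(self.marking)
                for p in state.places:
                    self._by_place[p].append(state)
                if kind == "stochastic":
                    self.stochastic.append(state)
                    if isinstance(state, _Generic):
                        self._lazy.append(state)
                else:
                    self.immediates.append(state)
            elif kind == "delayed":
                ds = _DelayedState(ct)
                ds.sync(self.marking, 0.0)
                for p in ds.places:
                    self._delayed_by_place[p].append(ds)
                self.delayed.append(ds)
            elif kind == "scheduled":
                self.scheduled.append(_SchedState(ct))

        # exponential/uniform draw blocks (amortize numpy call overhead)
        self._exp_block = np.empty(0)
        self._uni_block = np.empty(0)
        self._exp_i = 0
        self._uni_i = 0

    # -- randomness -----------------------------------------------------

    def _exp1(self) -> float:
        if self._exp_i >= len(self._exp_block):
            self._exp_block = self.rng.standard_exponential(4096)
            self._exp_i = 0
        v = self._exp_block[self._exp_i]
        self._exp_i += 1
        return float(v)

    def _u(self) -> float:
        if self._uni_i >= len(self._uni_block):
            self._uni_block = self.rng.random(4096)
            self._uni_i = 0
        v = self._uni_block[self._uni_i]
        self._uni_i += 1
        return float(v)

    # -- state plumbing --------------------------------------------------

    def _apply(self, deltas):
        marking = self.marking
        by_place = self._by_place
        delayed_dirty = None
        for place, value, dn in deltas:
            ms = marking[place]
            if dn < 0:
                ms.subtract(value, -dn)
            else:
                ms.add(value, dn)
            for state in by_place[place]:
                state.on_delta(place, value, dn)
            dl = self._delayed_by_place[place]
            if dl:
                delayed_dirty = dl if delayed_dirty is None else delayed_dirty + dl
        if delayed_dirty:
            now = self.time
            for ds in set(delayed_dirty) if len(delayed_dirty) > 1 else delayed_dirty:
                ds.sync(marking, now)

    def _fire(self, ct: CompiledTransition, binding: dict) -> FiredEvent:
        deltas, full = ct.fire_deltas(binding, self.marking, self.rng)
        self._apply(deltas)
        if not self.record_events:
            return _FIRED
        return FiredEvent(self.time, ct.obj.kind, ct.name, full)

    # -- pending-event introspection -------------------------------------

    def pending_events(self) -> list[PendingEvent]:
        out = []
        for ds in self.delayed:
            out.extend(ds.pending())
        for ss in self.scheduled:
            if ss.next_time < _INF:
                out.append(PendingEvent(ss.next_time, ss.ct.name, None, "scheduled"))
        return sorted(out, key=lambda e: e.due_time)

    # -- the step --------------------------------------------------------

    def step(self, max_time: float = _INF) -> Optional[FiredEvent]:
        if max_time < self.time:
            raise SchedulerError(
                f"clock cannot go backwards: at {self.time}, asked for {max_time}"
            )

        # 1. immediate transitions pre-empt everything, consume no time
        if self.immediates:
            total = 0
            for state in self.immediates:
                if isinstance(state, _Generic):
                    state.ensure(self.marking)
                total += state.weight
            if total > 0:
                self._imm_chain += 1
                if self._imm_chain > self.max_immediate_chain:
                    raise LivelockError(
                        f"more than {self.max_immediate_chain} consecutive "
                        "immediate firings; the net livelocks"
                    )
                r = self._u() * total
                acc = 0
                chosen = None
                for state in self.immediates:
                    if state.weight <= 0:
                        continue
                    acc += state.weight
                    chosen = state
                    if r < acc:
                        break
                if isinstance(chosen, _Generic):
                    binding = chosen.sample_binding(self.marking, self._u)
                else:
                    binding = chosen.binding_of(chosen.sample_values(self._u))
                return self._fire(chosen.ct, binding)
            self._imm_chain = 0

        # 2. total stochastic propensity (exact resummation each step)
        for state in self._lazy:
            state.ensure(self.marking)
        total_rate = 0.0
        for state in self.stochastic:
            if state.ct.obj.rate_function is not None:
                if state.weight > 0:
                    total_rate += float(state.ct.obj.rate_function(self.marking))
            else:
                total_rate += state.rate * state.weight
        t_sto = self.time + self._exp1() / total_rate if total_rate > 0 else _INF

        t_del, del_cands = _INF, None
        for ds in self.delayed:
            due = ds.earliest_due
            if due < t_del:
                t_del, del_cands = due, [(ds, k) for k in ds.earliest_keys]
            elif due == t_del and due < _INF:
                del_cands.extend((ds, k) for k in ds.earliest_keys)

        t_sch, sch_cands = _INF, None
        for ss in self.scheduled:
            if ss.next_time < t_sch:
                t_sch, sch_cands = ss.next_time, [ss]
            elif ss.next_time == t_sch and ss.next_time < _INF:
                sch_cands.append(ss)

        # priority on ties: scheduled > delayed > stochastic
        t_next, cls = min((t_sch, 0), (t_del, 1), (t_sto, 2))
        if t_next > max_time:
            self.time = max_time
            return None
        self.time = t_next

        if cls == 0:  # scheduled
            ss = sch_cands[int(self._u() * len(sch_cands))] if len(sch_cands) > 1 else sch_cands[0]
            ss.advance()
            elements = ss.ct.enumerate(self.marking)
            if not elements:
                return FiredEvent(self.time, "skipped", ss.ct.name, None, fired=False)
            total = sum(e.weight for e in elements)
            r = self._u() * total
            acc = 0
            chosen = elements[0]
            for e in elements:
                acc += e.weight
                chosen = e
                if r < acc:
                    break
            return self._fire(ss.ct, chosen.binding)

        if cls == 1:  # delayed
            ds, key = (
                del_cands[int(self._u() * len(del_cands))]
                if len(del_cands) > 1
                else del_cands[0]
            )
            binding = ds.pop(key)
            if not ds.ct.enabled(binding, self.marking):
                # pre-empted between the last sync and now; cancel
                return FiredEvent(self.time, "cancelled", ds.ct.name, dict(binding), fired=False)
            return self._fire(ds.ct, binding)

        # stochastic: select transition proportional to its rate
        r = self._u() * total_rate
        acc = 0.0
        chosen = None
        for state in self.stochastic:
            w = state.weight
            if w <= 0:
                continue
            if state.ct.obj.rate_function is not None:
                acc += float(state.ct.obj.rate_function(self.marking))
            else:
                acc += state.rate * w
            chosen = state
            if r < acc:
                break
        if chosen is None:  # numerically impossible unless total drifted
            self.time = max_time if max_time < _INF else self.time
            return None

        if isinstance(chosen, _Generic):
            binding = chosen.sample_binding(self.marking, self._u)
            return self._fire(chosen.ct, binding)
        vals = chosen.sample_values(self._u)
        if chosen.fast_fire is not None:
            self._apply(chosen.fast_fire(*vals))
            if not self.record_events:
                return _FIRED
            return FiredEvent(self.time, "stochastic", chosen.ct.name, chosen.binding_of(vals))
        return self._fire(chosen.ct, chosen.binding_of(vals))


# ---------------------------------------------------------------------------
# trajectory drivers


def _as_observables(observables, net: Net) -> list[Observable]:
    out = []
    for obs in observables:
        if isinstance(obs, Observable):
            out.append(obs)
        elif isinstance(obs, str):
            out.append(Observable(obs, obs))
        else:
            out.append(Observable(*obs))
    if not out:
        out = [Observable(p, p) for p in net.places]
    return out


def run(
    net: Net,
    t_end: float,
    observables: Sequence = (),
    seed: int = 0,
    *,
    record_events: bool = False,
    record_markings: bool = False,
    replicate: int = 0,
    max_immediate_chain: int = 1000,
) -> Trajectory:
    """Simulate to ``t_end``, recording observables on the integer grid.

    Events at exactly a grid time are processed before that grid point is
    recorded, so e.g. a scheduled injection at t=100 is visible in the
    t=100 sample.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    obs = _as_observables(observables, net)
    sim = Simulator(
        net,
        seed=seed,
        max_immediate_chain=max_immediate_chain,
        record_events=record_events,
    )
    n = int(t_end) + 1
    times = np.arange(n)
    counts = {o.name: np.zeros(n, dtype=np.int64) for o in obs}
    events = [] if record_events else None
    markings = [] if record_markings else None
    for g in range(n):
        while True:
            ev = sim.step(float(g))
            if ev is None:
                break
            if record_events:
                events.append(ev)
        for o in obs:
            counts[o.name][g] = o.count(sim.marking)
        if record_markings:
            markings.append(sim.marking.copy())
    return Trajectory(replicate, seed, times, counts, events, markings)


def run_replicates(
    net: Net,
    t_end: float,
    observables: Sequence,
    n: int,
    base_seed: int = 0,
    **kw,
) -> ReplicateSummary:
    """``n`` independent replicates with derived seeds ``base_seed + i``."""
    if n < 1:
        raise ValueError("need at least one replicate")
    trajs = [
        run(net, t_end, observables, seed=base_seed + i, replicate=i, **kw)
        for i in range(n)
    ]
    counts = {
        name: np.stack([t.counts[name] for t in trajs])
        for name in trajs[0].counts
    }
    return ReplicateSummary(trajs[0].times, counts, [t.seed for t in trajs])
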