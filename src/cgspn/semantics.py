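"""Execution semantics: binding enumeration, guards, and the firing rule.

A *binding* assigns values to the variable components (``slots``) used by a
transition's arc inscriptions.  A transition is enabled under a binding when
every input place covers the multiset the bound input inscriptions demand
and the guard holds.  The *weight* of a binding counts the distinct ways of
drawing the demanded identical tokens, ``prod C(n_c, k_c)`` over demanded
values ``c``; this makes the colored race statistically identical to
mass-action kinetics on the unfolded low-level net.

Firing is atomic: inputs subtracted, outputs added, never a negative count
in between.  Variables that occur only on output arcs are resolved at fire
time by a uniform draw from their color set, matching the convention that
an unbound position/receptor on a production arc means "random".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .colorsets import ProductColorSet
from .expressions import ArcPattern, Cmp, GuardError, conjuncts, parse_pattern
from .net import Marking, Multiset, Net, NetError, resolve_terms, transition_slots

__all__ = [
    "Binding",
    "BindingElement",
    "FiringError",
    "BindingSpaceError",
    "match_pattern",
    "enumerate_bindings",
    "evaluate_guard",
    "fire",
    "compile_net",
]

Binding = dict  # slot -> value


class FiringError(RuntimeError):
    """Firing attempted with a binding that is not enabled."""


class BindingSpaceError(RuntimeError):
    """Binding enumeration refused: space too large; reduce color sets."""


@dataclass(frozen=True)
class BindingElement:
    """An enabled (transition, binding) pair with its combinatorial weight."""

    transition: str
    binding: Binding
    weight: int


# ---------------------------------------------------------------------------
# compiled structures


class CompiledArc:
    """An arc inscription resolved against its place's color set."""

    __slots__ = ("place", "mult", "terms", "slots", "arity")

    def __init__(self, place: str, pattern: ArcPattern, pcs: ProductColorSet):
        self.place = place
        self.mult = pattern.mult
        self.terms = resolve_terms(pattern, pcs)
        self.arity = pcs.arity
        self.slots = tuple(p[0] for kind, p in self.terms if kind == "slot")

    def match(self, value: tuple, binding: Binding) -> Optional[Binding]:
        """Extend ``binding`` by matching an input token ``value``.

        Constants must equal the token entry; offset terms invert the
        offset (the bound value is the preimage).  Returns the extended
        binding (copy-on-write) or ``None`` on mismatch.
        """
        nb = binding
        fresh = False
        for entry, (kind, payload) in zip(value, self.terms):
            if kind == "const":
                if entry != payload:
                    return None
            else:
                slot, off, cs = payload
                if off:
                    entry = cs.unshift(entry, off)
                    if entry is None:
                        return None
                have = nb.get(slot, _MISSING)
                if have is _MISSING:
                    if not fresh:
                        nb = dict(nb)
                        fresh = True
                    nb[slot] = entry
                elif have != entry:
                    return None
        return nb

    def ground(self, binding: Binding) -> tuple:
        """The concrete token value this arc reads/writes under ``binding``."""
        out = []
        for kind, payload in self.terms:
            if kind == "const":
                out.append(payload)
            else:
                slot, off, cs = payload
                v = binding[slot]
                out.append(cs.shift(v, off) if off else v)
        return tuple(out)


_MISSING = object()


class CompiledTransition:
    __slots__ = (
        "name",
        "obj",
        "inputs",
        "outputs",
        "guard",
        "atoms",
        "atoms_by_depth",
        "tail_atoms",
        "input_slots",
        "random_slots",
    )

    def __init__(self, net: Net, name: str):
        t = net.transitions[name]
        self.name = name
        self.obj = t
        self.inputs = [
            CompiledArc(a.place, a.pattern, net.places[a.place].colorset)
            for a in net.arcs_of(name, "in")
        ]
        self.outputs = [
            CompiledArc(a.place, a.pattern, net.places[a.place].colorset)
            for a in net.arcs_of(name, "out")
        ]
        self.guard = t.guard
        self.input_slots = set()
        for arc in self.inputs:
            self.input_slots.update(arc.slots)

        # conjunction atoms scheduled at the earliest DFS depth where all
        # their slots are bound; non-conjunctive guards evaluate at the end
        atoms = conjuncts(t.guard)
        self.atoms = atoms
        self.atoms_by_depth = [[] for _ in self.inputs]
        self.tail_atoms = []
        if atoms is None:
            if t.guard.slots() - self.input_slots:
                raise NetError(
                    f"guard of {name!r} references output-only variables"
                )
            self.tail_atoms = [t.guard.evaluate]
        else:
            seen_bound: set[str] = set()
            remaining = list(atoms)
            for depth, arc in enumerate(self.inputs):
                seen_bound |= set(arc.slots)
                here, remaining = (
                    [a for a in remaining if a.slots() <= seen_bound],
                    [a for a in remaining if not (a.slots() <= seen_bound)],
                )
                self.atoms_by_depth[depth] = [a.evaluate for a in here]
            if remaining:
                raise NetError(
                    f"guard of {name!r} references output-only variables: "
                    f"{sorted(set().union(*(a.slots() for a in remaining)) - seen_bound)}"
                )

        # output-only slots are resolved by a uniform random draw per firing
        slots = transition_slots(net, name)
        self.random_slots = tuple(
            (slot, slots[slot].values)
            for slot in sorted(slots)
            if slot not in self.input_slots
        )

    # -- enumeration ----------------------------------------------------

    def demand(self, binding: Binding) -> dict:
        """(place, value) -> multiplicity demanded by the input arcs."""
        d: dict[tuple, int] = {}
        for arc in self.inputs:
            key = (arc.place, arc.ground(binding))
            d[key] = d.get(key, 0) + arc.mult
        return d

    def enabled(self, binding: Binding, marking: Marking) -> bool:
        if not all(f(binding) for f in self.tail_atoms):
            return False
        if self.atoms is not None and not all(a.evaluate(binding) for a in self.atoms):
            return False
        for (place, value), k in self.demand(binding).items():
            if marking[place].get(value, 0) < k:
                return False
        return True

    def enumerate(self, marking: Marking, cap: int = 1_000_000) -> list[BindingElement]:
        """All enabled bindings with weights, deterministic (sorted) order."""
        out: list[BindingElement] = []
        n_visited = 0

        def weight_of(binding: Binding) -> int:
            w = 1
            for (place, value), k in self.demand(binding).items():
                n = marking[place].get(value, 0)
                if n < k:
                    return 0
                w *= math.comb(n, k)
            return w

        def rec(depth: int, binding: Binding):
            nonlocal n_visited
            if depth == len(self.inputs):
                if all(f(binding) for f in self.tail_atoms):
                    w = weight_of(binding)
                    if w:
                        out.append(BindingElement(self.name, binding, w))
                return
            arc = self.inputs[depth]
            ms = marking.get(arc.place)
            if not ms:
                return
            atoms = self.atoms_by_depth[depth] if self.atoms is not None else ()
            for value in sorted(ms):
                n_visited += 1
                if n_visited > cap:
                    raise BindingSpaceError(
                        f"binding space of transition {self.name!r} exceeds cap "
                        f"{cap}; reduce color set sizes or raise the cap"
                    )
                nb = arc.match(value, binding)
                if nb is None:
                    continue
                if atoms and not all(f(nb) for f in atoms):
                    continue
                rec(depth + 1, nb)

        if not self.inputs:
            # a transition with no input places is always enabled
            if all(f({}) for f in self.tail_atoms) and (
                self.atoms is None or all(a.evaluate({}) for a in self.atoms)
            ):
                return [BindingElement(self.name, {}, 1)]
            return []
        rec(0, {})
        return out

    # -- firing ---------------------------------------------------------

    def fire_deltas(self, binding: Binding, marking: Marking, rng):
        """Token deltas of one firing; raises :class:`FiringError` if disabled.

        Returns ``(deltas, full_binding)`` where deltas is a list of
        ``(place, value, +/-count)`` with inputs first.
        """
        demand = self.demand(binding)
        for (place, value), k in demand.items():
            if marking[place].get(value, 0) < k:
                raise FiringError(
                    f"transition {self.name!r} fired with disabled binding: "
                    f"needs {k} x {value!r} in {place!r}"
                )
        if self.atoms is not None:
            ok = all(a.evaluate(binding) for a in self.atoms)
        else:
            ok = self.guard.evaluate(binding)
        if not ok:
            raise FiringError(f"guard of {self.name!r} is false for binding {binding!r}")

        full = binding
        if self.random_slots:
            full = dict(binding)
            for slot, values in self.random_slots:
                full[slot] = values[int(rng.integers(0, len(values)))]
        deltas = [(place, value, -k) for (place, value), k in demand.items()]
        produced: dict[tuple, int] = {}
        for arc in self.outputs:
            key = (arc.place, arc.ground(full))
            produced[key] = produced.get(key, 0) + arc.mult
        deltas.extend((place, value, k) for (place, value), k in produced.items())
        return deltas, full


class CompiledNet:
    """Per-transition compiled execution structures for a net."""

    def __init__(self, net: Net):
        from .net import validate_net

        problems = validate_net(net)
        if problems:
            raise NetError(
                "cannot compile an invalid net:\n  " + "\n  ".join(problems)
            )
        self.net = net
        self.transitions = {name: CompiledTransition(net, name) for name in net.transitions}

    def __getitem__(self, name: str) -> CompiledTransition:
        return self.transitions[name]


def compile_net(net: Net) -> CompiledNet:
    return CompiledNet(net)


# ---------------------------------------------------------------------------
# public operations


def match_pattern(
    pattern,
    token: tuple,
    partial: Optional[Binding] = None,
    *,
    colorset: ProductColorSet,
) -> Optional[Binding]:
    """Match an input-arc ``pattern`` against one ``token`` value.

    Returns the (possibly extended) binding, or ``None`` on mismatch —
    failure is a value, not an exception.  ``partial`` is never mutated.
    """
    arc = CompiledArc("_", parse_pattern(pattern), colorset)
    return arc.match(token, dict(partial) if partial else {})


def evaluate_guard(guard, binding: Binding) -> bool:
    """Evaluate a guard under a binding; unbound references are an error."""
    from .expressions import parse_guard

    return parse_guard(guard).evaluate(binding)


def enumerate_bindings(
    net: Net, transition: str, marking: Marking, cap: int = 1_000_000
) -> list[BindingElement]:
    """All enabled binding elements of ``transition`` under ``marking``.

    Does not mutate the marking.  Weights follow the combinatorial
    convention (``C(n, k)`` for k identical tokens from a stock of n).
    """
    return net.compiled()[transition].enumerate(marking, cap=cap)


def fire(net: Net, transition: str, binding: Binding, marking: Marking, rng) -> Marking:
    """One atomic firing; returns the new marking, the original untouched.

    Output-only variables are drawn uniformly at random from their color
    sets using ``rng`` (a :class:`numpy.random.Generator`).  Firing a
    disabled binding raises :class:`FiringError`.
    """
    ct = net.compiled()[transition]
    deltas, _ = ct.fire_deltas(binding, marking, rng)
    new = marking.copy()
    for place, value, k in deltas:
        if k < 0:
            new[place].subtract(value, -k)
        else:
            new[place].add(value, k)
    return new
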