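"""Structural representation of a colored generalized stochastic Petri net.

A net is the classical tuple: color sets, places, transitions, arcs, a color
function typing each place, guards, arc inscriptions and an initial marking.
This module holds the data model plus structural validation and the
unfolding-size report; execution semantics live in :mod:`cgspn.semantics`
and :mod:`cgspn.scheduler`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional, Union

from .colorsets import ColorSet, ProductColorSet
from .expressions import (
    ArcPattern,
    Comp,
    Const,
    Guard,
    TRUE,
    parse_guard,
    parse_pattern,
)

__all__ = [
    "Multiset",
    "Marking",
    "Place",
    "Transition",
    "Arc",
    "Net",
    "NetError",
    "validate_net",
    "unfold_report",
    "TRANSITION_KINDS",
]

TRANSITION_KINDS = ("stochastic", "immediate", "delayed", "scheduled")


class NetError(ValueError):
    """Raised for structurally invalid nets (in strict validation)."""


class MultisetUnderflow(ArithmeticError):
    """Subtraction that would produce a negative multiplicity."""


class Multiset(dict):
    """Token multiset: mapping value -> positive multiplicity.

    Zero-multiplicity entries are never stored, so equality of dicts is
    multiset equality.
    """

    @classmethod
    def of(cls, items) -> "Multiset":
        """Build from an iterable of values, a value->count mapping, or None."""
        ms = cls()
        if items is None:
            return ms
        if isinstance(items, dict):
            for v, k in items.items():
                ms.add(v, k)
        else:
            for v in items:
                ms.add(v)
        return ms

    def add(self, value, k: int = 1) -> None:
        if k < 0:
            raise ValueError("use subtract/discard for removal")
        if k == 0:
            return
        self[value] = self.get(value, 0) + k

    def subtract(self, value, k: int = 1) -> None:
        have = self.get(value, 0)
        if k > have:
            raise MultisetUnderflow(f"cannot remove {k} x {value!r}, only {have} present")
        if k == have:
            if k:
                del self[value]
        else:
            self[value] = have - k

    def total(self) -> int:
        return sum(self.values())

    def copy(self) -> "Multiset":
        return Multiset(self)

    def __add__(self, other: "Multiset") -> "Multiset":
        out = self.copy()
        for v, k in other.items():
            out.add(v, k)
        return out

    def __sub__(self, other: "Multiset") -> "Multiset":
        out = self.copy()
        for v, k in other.items():
            out.subtract(v, k)
        return out

    def __ge__(self, other: "Multiset") -> bool:
        """Componentwise >= : self covers other."""
        return all(self.get(v, 0) >= k for v, k in other.items())

    def __le__(self, other: "Multiset") -> bool:
        return all(other.get(v, 0) >= k for v, k in self.items())


class Marking(dict):
    """Global state: mapping place name -> :class:`Multiset`."""

    def copy(self) -> "Marking":
        return Marking({p: ms.copy() for p, ms in self.items()})

    def count(self, place: str, where: Optional[dict] = None) -> int:
        """Token count in ``place``, optionally filtered by components.

        ``where`` maps 0-based component index -> required value.
        """
        ms = self.get(place)
        if not ms:
            return 0
        if where is None:
            return ms.total()
        items = list(where.items())
        return sum(k for v, k in ms.items() if all(v[i] == x for i, x in items))


@dataclass(frozen=True)
class Place:
    name: str
    colorset: ProductColorSet


@dataclass
class Transition:
    """An event.  Exactly the parameters of its kind are meaningful.

    kind:
        ``stochastic`` — fires after an exponential delay with rate
        ``rate * (sum of binding weights)`` unless ``rate_function``
        overrides the marking-dependent rate entirely;
        ``immediate`` — zero delay, priority over everything else;
        ``delayed`` — fires exactly ``delay`` time units after enabling,
        pre-empted if enabling is lost meanwhile;
        ``scheduled`` — fires at the absolute times
        ``start, start+period, ... <= end`` when enabled.
    """

    name: str
    kind: str = "stochastic"
    guard: Guard = TRUE
    rate: Optional[float] = None
    rate_function: Optional[Callable] = None
    delay: Optional[float] = None
    schedule: Optional[tuple] = None  # (start, period|None, end|None)

    def __post_init__(self):
        self.guard = parse_guard(self.guard)

    def schedule_times(self):
        """Iterate the absolute firing times of a scheduled transition."""
        start, period, end = self.schedule
        if period is None:
            yield start
            return
        t = start
        while end is None or t <= end:
            yield t
            t += period


@dataclass(frozen=True)
class Arc:
    """Directed arc between one place and one transition."""

    place: str
    transition: str
    direction: str  # "in": place -> transition, "out": transition -> place
    pattern: ArcPattern


class Net:
    """A colored generalized stochastic Petri net under construction.

    Built programmatically::

        net = Net("birth_death")
        C = net.add_colorset("C", ["a", "b"])
        X = net.add_place("X", [C])
        net.add_transition("birth", kind="stochastic", rate=1.0)
        net.add_output("birth", "X", "1'(c)")
        net.add_transition("death", kind="stochastic", rate=0.5)
        net.add_input("X", "death", "1'(c)")
    """

    def __init__(self, name: str = "net"):
        self.name = name
        self.colorsets: dict[str, ColorSet] = {}
        self.products: dict[str, ProductColorSet] = {}
        self.places: dict[str, Place] = {}
        self.transitions: dict[str, Transition] = {}
        self.arcs: list[Arc] = []
        self.initial: dict[str, Multiset] = {}
        self._compiled = None  # semantics cache, invalidated on mutation

    # -- construction ---------------------------------------------------

    def _touch(self):
        self._compiled = None

    def add_colorset(self, name, values=None, circular=False) -> ColorSet:
        cs = name if isinstance(name, ColorSet) else ColorSet(name, values, circular)
        if cs.name in self.colorsets:
            raise NetError(f"duplicate color set {cs.name!r}")
        self.colorsets[cs.name] = cs
        self._touch()
        return cs

    def add_product(self, name, components) -> ProductColorSet:
        comps = [self.colorsets[c] if isinstance(c, str) else c for c in components]
        pcs = ProductColorSet(name, comps)
        if name in self.products:
            raise NetError(f"duplicate product color set {name!r}")
        self.products[name] = pcs
        self._touch()
        return pcs

    def add_place(self, name: str, colorset) -> Place:
        if name in self.places:
            raise NetError(f"duplicate place {name!r}")
        if isinstance(colorset, str):
            colorset = self.products[colorset]
        elif isinstance(colorset, (list, tuple)):
            comps = [self.colorsets[c] if isinstance(c, str) else c for c in colorset]
            colorset = ProductColorSet(f"{name}_type", comps)
        place = Place(name, colorset)
        self.places[name] = place
        self._touch()
        return place

    def add_transition(self, name: str, kind: str = "stochastic", **kw) -> Transition:
        if name in self.transitions:
            raise NetError(f"duplicate transition {name!r}")
        if kind not in TRANSITION_KINDS:
            raise NetError(f"unknown transition kind {kind!r}")
        t = Transition(name, kind, **kw)
        self.transitions[name] = t
        self._touch()
        return t

    def add_input(self, place: str, transition: str, pattern) -> Arc:
        arc = Arc(place, transition, "in", parse_pattern(pattern))
        self.arcs.append(arc)
        self._touch()
        return arc

    def add_output(self, transition: str, place: str, pattern) -> Arc:
        arc = Arc(place, transition, "out", parse_pattern(pattern))
        self.arcs.append(arc)
        self._touch()
        return arc

    def set_initial(self, place: str, tokens) -> None:
        self.initial[place] = Multiset.of(tokens)
        self._touch()

    # -- queries --------------------------------------------------------

    def initial_marking(self) -> Marking:
        m = Marking({p: Multiset() for p in self.places})
        for p, ms in self.initial.items():
            m[p] = ms.copy()
        return m

    def arcs_of(self, transition: str, direction: Optional[str] = None):
        return [
            a
            for a in self.arcs
            if a.transition == transition and (direction is None or a.direction == direction)
        ]

    def compiled(self):
        """Compiled execution structures (cached); see :mod:`cgspn.semantics`."""
        if self._compiled is None:
            from .semantics import compile_net

            self._compiled = compile_net(self)
        return self._compiled


# ---------------------------------------------------------------------------
# pattern resolution (shared by validation and semantics)


def resolve_terms(pattern: ArcPattern, pcs: ProductColorSet):
    """Resolve a pattern's terms against a place's product color set.

    Expands a single whole-tuple variable to per-component references and
    returns a list of ``(kind, payload)`` resolved terms where kind is
    ``"const"`` (payload: value) or ``"slot"`` (payload: (slot, offset,
    component ColorSet)).  Raises :class:`NetError` on a type mismatch.
    """
    terms = pattern.terms
    if (
        len(terms) == 1
        and isinstance(terms[0], Comp)
        and terms[0].index is None
        and terms[0].offset == 0
        and pcs.arity > 1
    ):
        # whole-tuple variable: th == (th:1, ..., th:n)
        terms = tuple(Comp(terms[0].var, i + 1) for i in range(pcs.arity))
    if len(terms) != pcs.arity:
        raise NetError(
            f"arity mismatch: pattern {pattern} has {len(terms)} terms "
            f"but color set {pcs.name!r} has {pcs.arity} components"
        )
    resolved = []
    for i, term in enumerate(terms):
        cs = pcs.components[i]
        if isinstance(term, Const):
            if term.value not in cs:
                raise NetError(
                    f"constant {term} not in color set {cs.name!r} (component {i + 1})"
                )
            resolved.append(("const", term.value))
        else:
            if term.offset and not cs.is_integer:
                raise NetError(
                    f"offset on non-integer color set {cs.name!r} in term {term}"
                )
            resolved.append(("slot", (term.slot, term.offset, cs)))
    return resolved


def transition_slots(net: Net, tname: str):
    """Map slot -> component ColorSet over all arcs of a transition.

    Raises :class:`NetError` when the same slot is used with incompatible
    color sets on different arcs.
    """
    slots: dict[str, ColorSet] = {}
    for arc in net.arcs_of(tname):
        pcs = net.places[arc.place].colorset
        for kind, payload in resolve_terms(arc.pattern, pcs):
            if kind != "slot":
                continue
            slot, _off, cs = payload
            prev = slots.get(slot)
            if prev is None:
                slots[slot] = cs
            elif prev is not cs and tuple(prev.values) != tuple(cs.values):
                raise NetError(
                    f"slot {slot!r} of transition {tname!r} used with "
                    f"incompatible color sets {prev.name!r} and {cs.name!r}"
                )
    return slots


# ---------------------------------------------------------------------------
# validation


def validate_net(net: Net, strict: bool = False) -> list[str]:
    """Structural well-formedness diagnostics; empty list means valid.

    Checks that every arc connects an existing place and transition, every
    pattern type-checks against its place's color set, every guard variable
    occurs on an input arc of its transition, and each transition carries
    exactly the parameters its kind requires.  With ``strict=True`` the
    first violation raises :class:`NetError` instead.
    """
    diags: list[str] = []

    def emit(msg: str):
        if strict:
            raise NetError(msg)
        diags.append(msg)

    for arc in net.arcs:
        if arc.place not in net.places:
            emit(f"arc references unknown place {arc.place!r}")
            continue
        if arc.transition not in net.transitions:
            emit(f"arc references unknown transition {arc.transition!r}")
            continue
        try:
            resolve_terms(arc.pattern, net.places[arc.place].colorset)
        except NetError as e:
            emit(f"arc {arc.place}<->{arc.transition}: {e}")

    for name, t in net.transitions.items():
        # kind parameter discipline
        if t.kind == "stochastic":
            if t.rate_function is None and (t.rate is None or t.rate <= 0):
                emit(f"stochastic transition {name!r} needs a positive rate")
        elif t.rate is not None or t.rate_function is not None:
            emit(f"{t.kind} transition {name!r} must not carry a rate")
        if t.kind == "delayed":
            if t.delay is None or t.delay < 0:
                emit(f"delayed transition {name!r} needs delay >= 0")
        elif t.delay is not None:
            emit(f"{t.kind} transition {name!r} must not carry a delay")
        if t.kind == "scheduled":
            if not t.schedule:
                emit(f"scheduled transition {name!r} needs a schedule")
            else:
                start, period, end = t.schedule
                if period is not None and period <= 0:
                    emit(f"scheduled transition {name!r}: period must be > 0")
                if end is not None and end < start:
                    emit(f"scheduled transition {name!r}: start must be <= end")
        elif t.schedule is not None:
            emit(f"{t.kind} transition {name!r} must not carry a schedule")

        try:
            slots = transition_slots(net, name)
        except NetError as e:
            emit(str(e))
            continue
        input_slots = set()
        for arc in net.arcs_of(name, "in"):
            if arc.place not in net.places:
                continue
            try:
                for kind, payload in resolve_terms(arc.pattern, net.places[arc.place].colorset):
                    if kind == "slot":
                        input_slots.add(payload[0])
            except NetError:
                pass
        for slot in t.guard.slots():
            if slot not in slots:
                emit(f"guard of {name!r} references unknown variable {slot!r}")
            elif slot not in input_slots:
                emit(
                    f"guard of {name!r} references {slot!r} which is not bound "
                    "by any input arc"
                )

    for place, ms in net.initial.items():
        if place not in net.places:
            emit(f"initial marking references unknown place {place!r}")
            continue
        pcs = net.places[place].colorset
        for v in ms:
            if v not in pcs:
                emit(f"initial token {v!r} not in color set of place {place!r}")

    return diags


# ---------------------------------------------------------------------------
# unfolding report


def unfold_report(
    net: Net,
    enumerate_transitions: bool = False,
    cap: int = 1_000_000,
) -> dict:
    """Size of the equivalent unfolded low-level (place/transition) net.

    Per-place unfolded place count is the cardinality of the place's
    product color set.  With ``enumerate_transitions=True`` the report also
    counts, per colored transition, the guard-satisfiable variable bindings
    (one low-level transition each) by brute-force enumeration; a
    transition whose binding space exceeds ``cap`` is reported as
    ``"too large; structural counts only"``.
    """
    places = {name: p.colorset.cardinality for name, p in net.places.items()}
    report = {
        "places": places,
        "total_places": sum(places.values()),
        "colored_places": len(net.places),
        "colored_transitions": len(net.transitions),
    }
    if not enumerate_transitions:
        return report

    per_t: dict[str, object] = {}
    total = 0
    complete = True
    for name, t in net.transitions.items():
        slots = transition_slots(net, name)
        names = sorted(slots)
        space = math.prod(len(slots[s]) for s in names) if names else 1
        if space > cap:
            per_t[name] = "too large; structural counts only"
            complete = False
            continue
        guard = t.guard
        if not names:
            per_t[name] = 1 if guard.evaluate({}) else 0
        else:
            count = 0
            domains = [slots[s].values for s in names]
            for combo in product(*domains):
                if guard.evaluate(dict(zip(names, combo))):
                    count += 1
            per_t[name] = count
        total += per_t[name]
    report["transitions"] = per_t
    report["total_transitions"] = total if complete else None
    return report
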