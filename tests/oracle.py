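"""Independent brute-force oracles for the colored-net semantics.

These deliberately avoid the package's binding-enumeration machinery: the
low-level view enumerates *every* full variable assignment over the color
space (one low-level transition per assignment) and checks enablement
directly against the marking, counting identical-token selections by
explicit enumeration of combinations.  Only structural accessors
(``transition_slots``, ``resolve_terms``) are shared, never the DFS
matcher.
"""

from itertools import combinations, product

from cgspn.net import resolve_terms, transition_slots


def _ground(pattern_terms, binding):
    out = []
    for kind, payload in pattern_terms:
        if kind == "const":
            out.append(payload)
        else:
            slot, off, cs = payload
            v = binding[slot]
            out.append(cs.shift(v, off) if off else v)
    return tuple(out)


def count_selections(n: int, k: int) -> int:
    """Number of ways to pick k identical tokens from a stock of n, by
    explicit enumeration (no binomial formula)."""
    return sum(1 for _ in combinations(range(n), k))


def brute_force_bindings(net, tname, marking):
    """All enabled full bindings with weights, via exhaustive enumeration.

    Returns ``{binding_items_tuple: weight}`` restricted to the input-side
    slots (output-only slots are projected away, mirroring what binding
    enumeration reports).
    """
    t = net.transitions[tname]
    slots = transition_slots(net, tname)
    in_arcs = [
        (a, resolve_terms(a.pattern, net.places[a.place].colorset))
        for a in net.arcs_of(tname, "in")
    ]
    input_slots = set()
    for _a, terms in in_arcs:
        for kind, payload in terms:
            if kind == "slot":
                input_slots.add(payload[0])
    names = sorted(input_slots)
    domains = [slots[s].values for s in names]

    result = {}
    for combo in product(*domains) if names else [()]:
        binding = dict(zip(names, combo))
        if not t.guard.evaluate(binding):
            continue
        demand = {}
        for arc, terms in in_arcs:
            key = (arc.place, _ground(terms, binding))
            demand[key] = demand.get(key, 0) + arc.pattern.mult
        weight = 1
        for (place, value), k in demand.items():
            n = marking[place].get(value, 0)
            if n < k:
                weight = 0
                break
            weight *= count_selections(n, k)
        if weight:
            result[tuple(sorted(binding.items()))] = weight
    return result
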