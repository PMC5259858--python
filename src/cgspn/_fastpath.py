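"""Specialized code generation for the simulation hot path.

The generic matching machinery in :mod:`cgspn.semantics` interprets arc
inscriptions term by term; at hundreds of thousands of firings per
replicate that interpretation dominates the run time.  For the common
transition shapes (input arcs without offsets, conjunctive guards) this
module compiles, once per transition:

* a token *test* — ``lambda v: v[0] == "resting" and v[2] > 0`` — used by
  the incremental propensity indexes;
* a *key* extractor for hash-join propensities (guard equality atoms);
* a *fire* function mapping the chosen input token value(s) directly to
  the list of token deltas, with successor/predecessor offsets inlined as
  integer arithmetic and "token returned unchanged" input/output pairs
  cancelled.

Everything compiled here is semantically equivalent to the generic path;
the equivalence is exercised by the test suite (colored engine vs unfolded
low-level simulation, and fast vs generic enumeration).
"""

from __future__ import annotations

from typing import Optional

from .colorsets import ColorSet
from .expressions import Comp, Const

__all__ = ["arc_info", "compile_test", "compile_key", "compile_fire"]


def _range_info(cs: ColorSet):
    """(lo, hi) when the color set is a contiguous integer interval."""
    vals = cs.values
    if not vals or not isinstance(vals[0], int):
        return None
    lo, hi = vals[0], vals[-1]
    if vals != tuple(range(lo, hi + 1)):
        return None
    return lo, hi


def _shift_expr(src: str, off: int, cs: ColorSet) -> Optional[str]:
    if off == 0:
        return src
    info = _range_info(cs)
    if info is None:
        return None
    lo, hi = info
    n = hi - lo + 1
    if cs.circular:
        return f"(({src} + {off - lo}) % {n} + {lo})"
    return f"min(max({src} + {off}, {lo}), {hi})"


class ArcInfo:
    """Index-level view of an input arc without offsets."""

    __slots__ = ("slot_index", "conds")

    def __init__(self, slot_index: dict, conds: list):
        self.slot_index = slot_index  # slot name -> component index
        self.conds = conds  # source snippets over the token variable


def arc_info(arc, var: str = "v") -> Optional[ArcInfo]:
    """Analyze a compiled input arc; None when it has offset terms."""
    slot_index: dict[str, int] = {}
    conds: list[str] = []
    for i, (kind, payload) in enumerate(arc.terms):
        if kind == "const":
            conds.append(f"{var}[{i}] == {payload!r}")
        else:
            slot, off, _cs = payload
            if off:
                return None
            j = slot_index.setdefault(slot, i)
            if j != i:  # repeated variable inside one pattern
                conds.append(f"{var}[{i}] == {var}[{j}]")
    return ArcInfo(slot_index, conds)


_PYOP = {"=": "==", "!=": "!=", "<": "<", "<=": "<=", ">": ">", ">=": ">="}


def _atom_expr(atom, slot_index: dict, var: str) -> Optional[str]:
    def operand(term):
        if isinstance(term, Const):
            return repr(term.value)
        idx = slot_index.get(term.slot)
        return None if idx is None else f"{var}[{idx}]"

    l, r = operand(atom.lhs), operand(atom.rhs)
    if l is None or r is None:
        return None
    return f"{l} {_PYOP[atom.op]} {r}"


def compile_test(info: ArcInfo, atoms, var: str = "v"):
    """Boolean token-acceptance function for one arc plus its unary atoms."""
    conds = list(info.conds)
    for atom in atoms:
        expr = _atom_expr(atom, info.slot_index, var)
        if expr is None:
            return None
        conds.append(expr)
    body = " and ".join(conds) if conds else "True"
    return eval(f"lambda {var}: {body}")


def compile_key(info: ArcInfo, keyslots):
    """Join-key extractor ``v -> tuple of key component values``."""
    idx = []
    for slot in keyslots:
        i = info.slot_index.get(slot)
        if i is None:
            return None
        idx.append(i)
    inner = ", ".join(f"v[{i}]" for i in idx)
    return eval(f"lambda v: ({inner}{',' if len(idx) == 1 else ''})")


def compile_fire(ct, envs: list[str]):
    """Direct delta function ``(token values...) -> [(place, value, dn)]``.

    ``envs`` names one variable per input arc, in arc order.  Returns None
    when any output references an output-only (random) slot, any input arc
    carries an offset, or an offset cannot be inlined.
    """
    slot_src: dict[str, str] = {}
    in_exprs = []  # (place, canonical token expr, mult)
    for arc, env in zip(ct.inputs, envs):
        info = arc_info(arc, env)
        if info is None:
            return None
        for slot, i in info.slot_index.items():
            slot_src.setdefault(slot, f"{env}[{i}]")
        in_exprs.append([arc.place, env, arc.mult])

    out_exprs = []
    for arc in ct.outputs:
        parts = []
        plain_env = None  # whole input token passed through unchanged?
        for i, (kind, payload) in enumerate(arc.terms):
            if kind == "const":
                parts.append(repr(payload))
                plain_env = False if plain_env is None else plain_env
                continue
            slot, off, cs = payload
            src = slot_src.get(slot)
            if src is None:
                return None  # output-only slot: needs an RNG draw
            expr = _shift_expr(src, off, cs)
            if expr is None:
                return None
            parts.append(expr)
            if plain_env is not False and off == 0 and src.endswith(f"[{i}]"):
                env = src[: src.index("[")]
                plain_env = env if (plain_env in (None, env)) else False
            else:
                plain_env = False
        if plain_env and len(parts) == ct.inputs[envs.index(plain_env)].arity:
            token = plain_env
        else:
            token = "(" + ", ".join(parts) + ("," if len(parts) == 1 else "") + ")"
        out_exprs.append([arc.place, token, arc.mult])

    # cancel "token returned unchanged" pairs: no net marking change
    for ie in in_exprs:
        for oe in out_exprs:
            if oe[2] and ie[2] and oe[0] == ie[0] and oe[1] == ie[1] and oe[2] == ie[2]:
                ie[2] = oe[2] = 0
                break

    deltas = [f"({place!r}, {tok}, {-mult})" for place, tok, mult in in_exprs if mult]
    deltas += [f"({place!r}, {tok}, {mult})" for place, tok, mult in out_exprs if mult]
    args = ", ".join(envs)
    return eval(f"lambda {args}: [{', '.join(deltas)}]")
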