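"""Arc-pattern and guard expression language.

Arc inscriptions follow the conventional colored-net notation::

    2'("active", p, l, 4)          # multiplicity 2, constants and variables
    1'(th:1, th:2, th:3-1, th:4)   # component references with a -1 offset
    1'(th)                         # whole-tuple variable (sugar for th:1..th:n)

and guards are boolean combinations of comparisons::

    [th:3 = 0]
    [b:1 = "presenting" & th:1 = "active" & b:4 = th:4]

Component indices are 1-based, as is customary.  The parser also accepts the
typographic quotes/dashes that figures tend to use (curly quotes, en dash,
prime mark).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

__all__ = [
    "Const",
    "Comp",
    "ArcPattern",
    "Cmp",
    "And",
    "Or",
    "Not",
    "TRUE",
    "Guard",
    "GuardError",
    "ExpressionError",
    "parse_pattern",
    "parse_guard",
]


class ExpressionError(ValueError):
    """Raised on malformed pattern or guard text."""


class GuardError(RuntimeError):
    """Raised when a guard references an unbound variable component."""


# ---------------------------------------------------------------------------
# terms


@dataclass(frozen=True)
class Const:
    """A literal value: a quoted symbol or an integer."""

    value: Union[str, int]

    def __str__(self) -> str:
        return f'"{self.value}"' if isinstance(self.value, str) else str(self.value)


@dataclass(frozen=True)
class Comp:
    """A variable reference, optionally a tuple component with an offset.

    ``Comp("p")`` is an atomic variable, ``Comp("th", 3)`` the third
    component of tuple variable ``th`` (1-based) and ``Comp("th", 3, -1)``
    the same component decremented by one.
    """

    var: str
    index: Optional[int] = None
    offset: int = 0

    @property
    def slot(self) -> str:
        """The binding key this reference reads/writes."""
        return self.var if self.index is None else f"{self.var}:{self.index}"

    def __str__(self) -> str:
        s = self.var if self.index is None else f"{self.var}:{self.index}"
        if self.offset > 0:
            s += f"+{self.offset}"
        elif self.offset < 0:
            s += str(self.offset)
        return s


Term = Union[Const, Comp]


@dataclass(frozen=True)
class ArcPattern:
    """A ``k'(term, ...)`` arc inscription."""

    mult: int
    terms: tuple  # tuple[Term, ...]

    def __post_init__(self):
        if self.mult < 1:
            raise ExpressionError(f"multiplicity must be positive, got {self.mult}")

    def __str__(self) -> str:
        inner = ", ".join(str(t) for t in self.terms)
        return f"{self.mult}'({inner})"


# ---------------------------------------------------------------------------
# guards


@dataclass(frozen=True)
class Cmp:
    """Atomic comparison between component references and/or constants."""

    op: str  # one of = != < <= > >=
    lhs: Term
    rhs: Term

    _OPS = {
        "=": lambda a, b: a == b,
        "!=": lambda a, b: a != b,
        "<": lambda a, b: a < b,
        "<=": lambda a, b: a <= b,
        ">": lambda a, b: a > b,
        ">=": lambda a, b: a >= b,
    }

    def __post_init__(self):
        if self.op not in self._OPS:
            raise ExpressionError(f"unknown comparison operator {self.op!r}")

    def _operand(self, term: Term, binding) -> Union[str, int]:
        if isinstance(term, Const):
            return term.value
        try:
            return binding[term.slot]
        except KeyError:
            raise GuardError(f"guard references unbound component {term.slot!r}") from None

    def evaluate(self, binding) -> bool:
        return self._OPS[self.op](self._operand(self.lhs, binding), self._operand(self.rhs, binding))

    def slots(self) -> frozenset:
        return frozenset(t.slot for t in (self.lhs, self.rhs) if isinstance(t, Comp))

    def __str__(self) -> str:
        return f"{self.lhs} {self.op} {self.rhs}"


@dataclass(frozen=True)
class And:
    items: tuple

    def evaluate(self, binding) -> bool:
        return all(x.evaluate(binding) for x in self.items)

    def slots(self) -> frozenset:
        return frozenset().union(*(x.slots() for x in self.items))

    def __str__(self) -> str:
        return " & ".join(_paren(x, (Or,)) for x in self.items)


@dataclass(frozen=True)
class Or:
    items: tuple

    def evaluate(self, binding) -> bool:
        return any(x.evaluate(binding) for x in self.items)

    def slots(self) -> frozenset:
        return frozenset().union(*(x.slots() for x in self.items))

    def __str__(self) -> str:
        return " | ".join(str(x) for x in self.items)


@dataclass(frozen=True)
class Not:
    item: object

    def evaluate(self, binding) -> bool:
        return not self.item.evaluate(binding)

    def slots(self) -> frozenset:
        return self.item.slots()

    def __str__(self) -> str:
        return "!" + _paren(self.item, (And, Or))


class _True:
    """The default (empty) guard."""

    def evaluate(self, binding) -> bool:
        return True

    def slots(self) -> frozenset:
        return frozenset()

    def __str__(self) -> str:
        return "true"

    def __repr__(self) -> str:
        return "TRUE"


TRUE = _True()

Guard = Union[Cmp, And, Or, Not, _True]


def _paren(x, wrap_types) -> str:
    s = str(x)
    return f"({s})" if isinstance(x, wrap_types) else s


def conjuncts(guard: Guard):
    """Flatten a pure conjunction of comparisons to a list of :class:`Cmp`.

    Returns ``None`` when the guard is not a plain conjunction; callers fall
    back to opaque evaluation in that case.
    """
    if guard is TRUE or isinstance(guard, _True):
        return []
    if isinstance(guard, Cmp):
        return [guard]
    if isinstance(guard, And):
        out = []
        for item in guard.items:
            sub = conjuncts(item)
            if sub is None:
                return None
            out.extend(sub)
        return out
    return None


# ---------------------------------------------------------------------------
# parsing

_NORMALIZE = str.maketrans(
    {
        "’": "'",  # right single quote / prime
        "‘": "'",
        "“": '"',
        "”": '"',
        "–": "-",  # en dash
        "−": "-",  # minus sign
        "≠": "!",  # != split below
    }
)

_TOKEN = re.compile(
    r"""\s*(?:
        (?P<str>"[^"]*")
      | (?P<int>\d+)
      | (?P<name>[A-Za-z_]\w*)
      | (?P<op><=|>=|!=|[()\[\],:'=<>+\-&|!])
    )""",
    re.VERBOSE,
)


def _tokenize(text: str):
    text = text.translate(_NORMALIZE).replace("≠", "!=")
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise ExpressionError(f"cannot tokenize {rest[:20]!r}")
        pos = m.end()
        if m.lastgroup == "str":
            out.append(("str", m.group("str")[1:-1]))
        elif m.lastgroup == "int":
            out.append(("int", int(m.group("int"))))
        elif m.lastgroup == "name":
            out.append(("name", m.group("name")))
        else:
            out.append(("op", m.group("op")))
    return out


class _Parser:
    def __init__(self, tokens):
        self.toks = tokens
        self.i = 0

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else ("eof", None)

    def next(self):
        tok = self.peek()
        self.i += 1
        return tok

    def expect(self, kind, value=None):
        k, v = self.next()
        if k != kind or (value is not None and v != value):
            raise ExpressionError(f"expected {value or kind}, got {v!r}")
        return v

    # -- shared term parsing -------------------------------------------
    def term(self, allow_offset=True) -> Term:
        k, v = self.next()
        if k == "str":
            return Const(v)
        if k == "int":
            return Const(v)
        if k == "name":
            index = None
            if self.peek() == ("op", ":"):
                self.next()
                k2, v2 = self.next()
                if k2 != "int":
                    raise ExpressionError(f"component index must be an integer, got {v2!r}")
                if v2 < 1:
                    raise ExpressionError("component indices are 1-based")
                index = v2
            offset = 0
            if allow_offset and self.peek() in (("op", "+"), ("op", "-")):
                sign = 1 if self.next()[1] == "+" else -1
                k3, v3 = self.next()
                if k3 != "int":
                    raise ExpressionError(f"offset must be an integer, got {v3!r}")
                offset = sign * v3
            return Comp(v, index, offset)
        raise ExpressionError(f"unexpected token {v!r} in expression")

    # -- patterns -------------------------------------------------------
    def pattern(self) -> ArcPattern:
        mult = 1
        if self.peek()[0] == "int":
            mult = self.next()[1]
            self.expect("op", "'")
        self.expect("op", "(")
        terms = [self.term()]
        while self.peek() == ("op", ","):
            self.next()
            terms.append(self.term())
        self.expect("op", ")")
        return ArcPattern(mult, tuple(terms))

    # -- guards ---------------------------------------------------------
    def guard(self) -> Guard:
        if self.peek() == ("op", "["):
            self.next()
            g = self.or_expr()
            self.expect("op", "]")
        else:
            g = self.or_expr()
        return g

    def or_expr(self) -> Guard:
        items = [self.and_expr()]
        while self.peek() == ("op", "|"):
            self.next()
            items.append(self.and_expr())
        return items[0] if len(items) == 1 else Or(tuple(items))

    def and_expr(self) -> Guard:
        items = [self.not_expr()]
        while self.peek() == ("op", "&"):
            self.next()
            items.append(self.not_expr())
        return items[0] if len(items) == 1 else And(tuple(items))

    def not_expr(self) -> Guard:
        if self.peek() == ("op", "!"):
            self.next()
            return Not(self.not_expr())
        if self.peek() == ("op", "("):
            self.next()
            g = self.or_expr()
            self.expect("op", ")")
            return g
        return self.atom()

    def atom(self) -> Cmp:
        lhs = self.term(allow_offset=False)
        k, op = self.next()
        if k != "op" or op not in Cmp._OPS:
            raise ExpressionError(f"expected comparison operator, got {op!r}")
        rhs = self.term(allow_offset=False)
        return Cmp(op, lhs, rhs)


def parse_pattern(text: Union[str, ArcPattern]) -> ArcPattern:
    """Parse ``k'(term, ...)`` inscription text into an :class:`ArcPattern`."""
    if isinstance(text, ArcPattern):
        return text
    p = _Parser(_tokenize(text))
    pat = p.pattern()
    if p.peek()[0] != "eof":
        raise ExpressionError(f"trailing input after pattern in {text!r}")
    return pat


def parse_guard(text) -> Guard:
    """Parse ``[...]`` guard text into a guard expression tree."""
    if text is None:
        return TRUE
    if not isinstance(text, str):
        return text
    if text.strip() in ("", "true", "[]"):
        return TRUE
    p = _Parser(_tokenize(text))
    g = p.guard()
    if p.peek()[0] != "eof":
        raise ExpressionError(f"trailing input after guard in {text!r}")
    return g
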