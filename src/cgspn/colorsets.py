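"""Finite color sets and their Cartesian products.

A *color set* is a finite, ordered domain of atomic values (symbols such as
``"resting"`` or integers such as a life counter).  Token values are tuples
drawn from a *product color set*, one entry per component.  Integer color
sets support successor/predecessor arithmetic which either saturates at the
interval boundaries (the default, appropriate for e.g. a life counter that
must never wrap below zero) or wraps around toroidally when the ``circular``
flag is set (appropriate for positions on a periodic grid).
"""

from __future__ import annotations

import itertools
from typing import Iterator, Sequence

__all__ = ["ColorSet", "ProductColorSet", "integer_range"]


class ColorSet:
    """A named, finite, ordered domain of atomic values.

    Parameters
    ----------
    name:
        Identifier, unique within a net.
    values:
        Non-empty sequence of distinct symbols (str) or integers.
    circular:
        If true, successor/predecessor arithmetic wraps around; only
        allowed when all values are integers.
    """

    __slots__ = ("name", "values", "circular", "_index")

    def __init__(self, name: str, values: Sequence, circular: bool = False):
        values = tuple(values)
        if not name:
            raise ValueError("color set needs a name")
        if not values:
            raise ValueError(f"color set {name!r} must be non-empty")
        if len(set(values)) != len(values):
            raise ValueError(f"color set {name!r} has duplicate values")
        if circular and not all(isinstance(v, int) for v in values):
            raise ValueError(f"color set {name!r}: circular requires integer values")
        self.name = name
        self.values = values
        self.circular = bool(circular)
        self._index = {v: i for i, v in enumerate(values)}

    @property
    def is_integer(self) -> bool:
        return all(isinstance(v, int) for v in self.values)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator:
        return iter(self.values)

    def __contains__(self, value) -> bool:
        return value in self._index

    def shift(self, value, offset: int):
        """Apply a successor (+) / predecessor (-) offset to ``value``.

        Saturates at the boundary unless the color set is circular, in
        which case it wraps.
        """
        if offset == 0:
            return value
        if not self.is_integer:
            raise TypeError(f"offset arithmetic needs integer color set, not {self.name!r}")
        i = self._index[value] + offset
        n = len(self.values)
        if self.circular:
            i %= n
        else:
            i = min(max(i, 0), n - 1)
        return self.values[i]

    def unshift(self, value, offset: int):
        """Exact preimage of ``value`` under :meth:`shift` by ``offset``.

        Returns ``None`` when no in-range preimage exists.  At a saturating
        boundary only the exact arithmetic preimage is accepted.
        """
        if offset == 0:
            return value
        if not self.is_integer:
            raise TypeError(f"offset arithmetic needs integer color set, not {self.name!r}")
        i = self._index[value] - offset
        n = len(self.values)
        if self.circular:
            return self.values[i % n]
        if 0 <= i < n:
            return self.values[i]
        return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tail = ", circular" if self.circular else ""
        return f"ColorSet({self.name!r}, {list(self.values)!r}{tail})"


def integer_range(name: str, lo: int, hi: int, circular: bool = False) -> ColorSet:
    """Closed integer interval ``[lo, hi]`` as a color set."""
    if hi < lo:
        raise ValueError(f"empty range [{lo}, {hi}]")
    return ColorSet(name, range(lo, hi + 1), circular=circular)


class ProductColorSet:
    """Ordered Cartesian product of component color sets.

    The type of whole token values: a token of this product is a tuple with
    one entry per component, each drawn from the matching component domain.
    """

    __slots__ = ("name", "components")

    def __init__(self, name: str, components: Sequence[ColorSet]):
        components = tuple(components)
        if not components:
            raise ValueError(f"product color set {name!r} needs >= 1 component")
        self.name = name
        self.components = components

    @property
    def arity(self) -> int:
        return len(self.components)

    @property
    def cardinality(self) -> int:
        n = 1
        for c in self.components:
            n *= len(c)
        return n

    def __iter__(self) -> Iterator[tuple]:
        """Exhaustive enumeration of all token values, lexicographic."""
        return itertools.product(*(c.values for c in self.components))

    def __contains__(self, value) -> bool:
        return (
            isinstance(value, tuple)
            and len(value) == len(self.components)
            and all(v in c for v, c in zip(value, self.components))
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ProductColorSet({self.name!r}, {[c.name for c in self.components]})"
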