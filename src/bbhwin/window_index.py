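"""Augmented ordered index over candidate window starts.

During the sliding-window enumeration, every gene of the counterpart genome H
that shares a family with the current query window is a candidate *start* of
an r-window in H.  :class:`WindowIndex` stores those candidate starts keyed
by position and maintains, for the window ``[key, key + r]`` anchored at each
key, its shared gene count ``s`` — the number of stored keys falling inside
that window.

Inserting (or deleting) a position changes ``s`` for every window whose span
covers it, i.e. for all keys in ``[position - r, position]``.  Rather than
touching those windows one by one, the structure applies the increment to the
roots of O(lg |T|) subtrees that exactly cover the affected key range — the
canonical-decomposition trick of segment trees — and resolves the pending
adjustment (``Δ_s``) lazily on traversal.  Each node is augmented with

* ``s``      — shared gene count of the window starting at this key,
* ``max_s``  — maximum effective ``s`` in the subtree,
* ``min_p, max_p`` — smallest/largest key in the subtree,
* ``lazy``   — pending ``Δ_s`` for the node's children,
* ``size``   — number of keys in the subtree (used to initialise a freshly
  inserted window's count by range-counting).

The balancing scheme is a treap with a fixed-seed priority stream, which
keeps the expected height logarithmic while making every run reproducible.
Split/merge rotations recompute the augmented attributes in constant time
per node.
"""

from __future__ import annotations

import random
from typing import Iterator, Optional

__all__ = ["WindowIndex"]

_DEFAULT_SEED = 0x5EEDB0B5


class _Node:
    __slots__ = ("key", "prio", "left", "right", "s", "max_s", "min_p", "max_p", "lazy", "size")

    def __init__(self, key: float, prio: float, s: int) -> None:
        self.key = key
        self.prio = prio
        self.left: Optional[_Node] = None
        self.right: Optional[_Node] = None
        self.s = s
        self.max_s = s
        self.min_p = key
        self.max_p = key
        self.lazy = 0
        self.size = 1


def _push(t: _Node) -> None:
    if t.lazy:
        for c in (t.left, t.right):
            if c is not None:
                c.s += t.lazy
                c.max_s += t.lazy
                c.lazy += t.lazy
        t.lazy = 0


def _pull(t: _Node) -> None:
    t.max_s = t.s
    t.min_p = t.max_p = t.key
    t.size = 1
    if t.left is not None:
        t.max_s = max(t.max_s, t.left.max_s)
        t.min_p = t.left.min_p
        t.size += t.left.size
    if t.right is not None:
        t.max_s = max(t.max_s, t.right.max_s)
        t.max_p = t.right.max_p
        t.size += t.right.size


def _split(t: Optional[_Node], key: float, inclusive: bool) -> tuple[Optional[_Node], Optional[_Node]]:
    """Split into (keys <= key, rest) when inclusive, else (keys < key, rest)."""
    if t is None:
        return None, None
    _push(t)
    goes_left = t.key <= key if inclusive else t.key < key
    if goes_left:
        left, right = _split(t.right, key, inclusive)
        t.right = left
        _pull(t)
        return t, right
    left, right = _split(t.left, key, inclusive)
    t.left = right
    _pull(t)
    return left, t


def _merge(a: Optional[_Node], b: Optional[_Node]) -> Optional[_Node]:
    if a is None:
        return b
    if b is None:
        return a
    if a.prio > b.prio:
        _push(a)
        a.right = _merge(a.right, b)
        _pull(a)
        return a
    _push(b)
    b.left = _merge(a, b.left)
    _pull(b)
    return b


def _add(t: Optional[_Node], delta: int) -> None:
    if t is not None and delta:
        t.s += delta
        t.max_s += delta
        t.lazy += delta


class WindowIndex:
    """Candidate H-window starts with range-updatable shared gene counts.

    Parameters
    ----------
    r : maximum window length (positional span); the window anchored at key
        ``k`` is ``[k, k + r]``.
    seed : seed for the treap priority stream (fixed default for
        reproducibility).
    """

    def __init__(self, r: float, *, seed: int = _DEFAULT_SEED) -> None:
        if r < 0:
            raise ValueError(f"maximum window length r must be >= 0, got {r}")
        self.r = r
        self._root: Optional[_Node] = None
        self._rng = random.Random(seed)

    # -- basic queries -------------------------------------------------------
    def __len__(self) -> int:
        return self._root.size if self._root is not None else 0

    def __contains__(self, position: float) -> bool:
        t = self._root
        while t is not None:
            if position == t.key:
                return True
            t = t.left if position < t.key else t.right
        return False

    def __bool__(self) -> bool:
        return self._root is not None

    # -- mutation ------------------------------------------------------------
    def insert(self, position: float) -> None:
        """Insert a candidate window start.

        The new window's count is initialised to 1 plus the number of existing
        keys in ``(position, position + r]``; every existing window covering
        the position (keys in ``[position - r, position)``) is incremented.
        """
        if position in self:
            raise KeyError(f"position {position!r} already present")
        below, rest = _split(self._root, position, True)
        inside, above = _split(rest, position + self.r, True)
        s0 = 1 + (inside.size if inside is not None else 0)
        lo, covering = _split(below, position - self.r, False)
        _add(covering, 1)
        node = _Node(position, self._rng.random(), s0)
        self._root = _merge(_merge(lo, covering), _merge(node, _merge(inside, above)))

    def delete(self, position: float) -> None:
        """Remove a key, decrementing every window that covered it."""
        below, rest = _split(self._root, position, False)
        target, above = _split(rest, position, True)
        if target is None:
            raise KeyError(f"position {position!r} not present")
        lo, covering = _split(below, position - self.r, False)
        _add(covering, -1)
        self._root = _merge(_merge(lo, covering), above)

    # -- window queries ------------------------------------------------------
    def best_window(self) -> Optional[tuple[list[float], int]]:
        """All keys whose window attains the maximum shared gene count.

        Returns ``(keys, max_s)`` with keys in increasing order, or ``None``
        when the index is empty.  Only subtrees whose ``max_s`` equals the
        global maximum are visited.  Tie-breaking between the returned keys
        (shortest window, then smallest start) is the caller's concern.
        """
        if self._root is None:
            return None
        target = self._root.max_s
        found: list[float] = []

        def visit(t: _Node) -> None:
            _push(t)
            if t.left is not None and t.left.max_s == target:
                visit(t.left)
            if t.s == target:
                found.append(t.key)
            if t.right is not None and t.right.max_s == target:
                visit(t.right)

        visit(self._root)
        return found, target

    def last_key_at_most(self, bound: float) -> Optional[float]:
        """Largest key <= bound, or None."""
        t = self._root
        best: Optional[float] = None
        while t is not None:
            if t.key <= bound:
                best = t.key
                t = t.right
            else:
                t = t.left
        return best

    # -- introspection (tests, debugging) -------------------------------------
    def items(self) -> Iterator[tuple[float, int]]:
        """Yield ``(key, effective s)`` in increasing key order."""

        def walk(t: Optional[_Node], pending: int) -> Iterator[tuple[float, int]]:
            # `pending` = sum of ancestors' lazy not yet pushed down to t;
            # t.s itself is current relative to its ancestors' pushed state.
            if t is None:
                return
            yield from walk(t.left, pending + t.lazy)
            yield t.key, t.s + pending
            yield from walk(t.right, pending + t.lazy)

        yield from walk(self._root, 0)

    def height(self) -> int:
        def h(t: Optional[_Node]) -> int:
            return 0 if t is None else 1 + max(h(t.left), h(t.right))

        return h(self._root)
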