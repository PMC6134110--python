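"""A small atom-selection language.

Grammar (case-sensitive keywords, whitespace-separated tokens)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | primary
    primary  := "(" expr ")" | term
    term     := "all" | "none"
              | ("name" | "resname" | "segment" | "chain") VALUE+
              | "resid" RANGE+        where RANGE := INT | INT-INT (inclusive)

Multiple values after a keyword are a union, e.g. ``name P O1`` matches either
atom name.  ``segment`` and ``chain`` are synonyms (PDB chain id / GRO segment
id both land in the topology's segid field).

Examples
--------
``segment A and resid 27-631`` — monomer-A extracellular lobe.
``name P`` — all phosphate marker atoms.
``not (resname LIP or name CPA)`` — everything except lipids and CPA markers.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import AtomSelection, Topology

__all__ = ["select_atoms", "SelectionSyntaxError"]

_KEYWORDS = {"name", "resname", "segment", "chain", "resid",
             "and", "or", "not", "all", "none", "(", ")"}


class SelectionSyntaxError(ValueError):
    """Selection expression failed to parse; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"at position {position}: {message}")
        self.position = position


class _Tokens:
    def __init__(self, expression: str):
        self.toks: list[tuple[str, int]] = []
        pos = 0
        for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
            found = expression.find(raw if raw not in "()" else raw, pos)
            self.toks.append((raw, max(found, pos)))
            pos = (found if found >= 0 else pos) + len(raw)
        self.i = 0

    def peek(self) -> str | None:
        return self.toks[self.i][0] if self.i < len(self.toks) else None

    def pos(self) -> int:
        return self.toks[self.i][1] if self.i < len(self.toks) else (
            self.toks[-1][1] + len(self.toks[-1][0]) if self.toks else 0
        )

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", self.pos())
        self.i += 1
        return tok


def _parse_values(ts: _Tokens) -> list[str]:
    vals = []
    while ts.peek() is not None and ts.peek() not in _KEYWORDS:
        vals.append(ts.next())
    if not vals:
        raise SelectionSyntaxError("keyword needs at least one value", ts.pos())
    return vals


def _term(ts: _Tokens, topo: Topology) -> np.ndarray:
    tok = ts.next()
    n = topo.n_atoms
    if tok == "all":
        return np.ones(n, dtype=bool)
    if tok == "none":
        return np.zeros(n, dtype=bool)
    if tok in ("name", "resname", "segment", "chain"):
        vals = _parse_values(ts)
        col = {"name": topo.names, "resname": topo.resnames,
               "segment": topo.segids, "chain": topo.segids}[tok]
        return np.isin(col, vals)
    if tok == "resid":
        pos = ts.pos()
        vals = _parse_values(ts)
        mask = np.zeros(n, dtype=bool)
        for v in vals:
            try:
                if "-" in v.lstrip("-"):
                    head, tail = v.rsplit("-", 1)
                    lo, hi = int(head), int(tail)
                else:
                    lo = hi = int(v)
            except ValueError:
                raise SelectionSyntaxError(
                    f"bad resid value {v!r}", pos) from None
            mask |= (topo.resids >= lo) & (topo.resids <= hi)
        return mask
    raise SelectionSyntaxError(f"unexpected token {tok!r}", ts.pos())


def _not_expr(ts: _Tokens, topo: Topology) -> np.ndarray:
    if ts.peek() == "not":
        ts.next()
        return ~_not_expr(ts, topo)
    if ts.peek() == "(":
        ts.next()
        mask = _or_expr(ts, topo)
        if ts.peek() != ")":
            raise SelectionSyntaxError("missing closing parenthesis", ts.pos())
        ts.next()
        return mask
    return _term(ts, topo)


def _and_expr(ts: _Tokens, topo: Topology) -> np.ndarray:
    mask = _not_expr(ts, topo)
    while ts.peek() == "and":
        ts.next()
        mask = mask & _not_expr(ts, topo)
    return mask


def _or_expr(ts: _Tokens, topo: Topology) -> np.ndarray:
    mask = _and_expr(ts, topo)
    while ts.peek() == "or":
        ts.next()
        mask = mask | _and_expr(ts, topo)
    return mask


def select_atoms(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a selection expression to an :class:`AtomSelection`.

    The result is deterministic (indices in ascending order).  An empty
    selection is legal but emits a warning.
    """
    ts = _Tokens(expression)
    if ts.peek() is None:
        raise SelectionSyntaxError("empty expression", 0)
    mask = _or_expr(ts, topology)
    if ts.peek() is not None:
        raise SelectionSyntaxError(
            f"trailing token {ts.peek()!r}", ts.pos())
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomSelection(name=expression, indices=indices)
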