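"""Label-based atom selection with a small expression grammar.

Supported predicates::

    chain A          chain id (one or more values)
    resid 2-9        residue index, single values and inclusive ranges
    resname NAG      residue name (PDB convention: GCS, NAG, HOH)
    name O6          atom name
    element O        chemical element

combined with ``and``, ``or``, ``not`` and parentheses. ``all`` and
``none`` are also accepted. Keywords take one or more whitespace-separated
values. Selections return atom indices in file order, so repeated selection
of the same expression on the same frame is stable.
"""

from __future__ import annotations

import numpy as np

_KEYWORDS = {"chain", "resid", "resname", "name", "element"}
_OPS = {"and", "or", "not", "(", ")", "all", "none"}


class SelectionError(ValueError):
    """Raised when a selection expression cannot be parsed."""


def _tokenize(expression: str) -> list[str]:
    out: list[str] = []
    for raw in expression.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _Parser:
    """Recursive-descent parser; precedence: not > and > or."""

    def __init__(self, frame, tokens: list[str]):
        self.frame = frame
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def fail(self, msg: str):
        raise SelectionError(f"{msg} at token {self.pos} "
                             f"({' '.join(self.tokens)!r})")

    def parse(self) -> np.ndarray:
        mask = self.parse_or()
        if self.peek() is not None:
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def parse_or(self) -> np.ndarray:
        left = self.parse_and()
        while self.peek() == "or":
            self.take()
            left = left | self.parse_and()
        return left

    def parse_and(self) -> np.ndarray:
        left = self.parse_not()
        while self.peek() == "and":
            self.take()
            left = left & self.parse_not()
        return left

    def parse_not(self) -> np.ndarray:
        if self.peek() == "not":
            self.take()
            return ~self.parse_not()
        return self.parse_atom()

    def parse_atom(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            self.fail("unexpected end of expression")
        if tok == "(":
            self.take()
            mask = self.parse_or()
            if self.take() != ")":
                self.fail("missing closing parenthesis")
            return mask
        if tok == "all":
            self.take()
            return np.ones(self.frame.n_atoms, bool)
        if tok == "none":
            self.take()
            return np.zeros(self.frame.n_atoms, bool)
        if tok in _KEYWORDS:
            return self.parse_predicate(self.take())
        self.fail(f"expected a predicate, got {tok!r}")

    def parse_predicate(self, keyword: str) -> np.ndarray:
        values = []
        while self.peek() is not None and self.peek() not in _OPS \
                and self.peek() not in _KEYWORDS:
            values.append(self.take())
        if not values:
            self.fail(f"keyword {keyword!r} needs at least one value")
        f = self.frame
        if keyword == "resid":
            mask = np.zeros(f.n_atoms, bool)
            for v in values:
                if "-" in v[1:]:
                    lo_s, hi_s = v.rsplit("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        self.fail(f"bad resid range {v!r}")
                    mask |= (f.resids >= lo) & (f.resids <= hi)
                else:
                    try:
                        mask |= f.resids == int(v)
                    except ValueError:
                        self.fail(f"bad resid {v!r}")
            return mask
        column = {"chain": f.chains, "resname": f.resnames,
                  "name": f.names, "element": f.elements}[keyword]
        return np.isin(column, values)


def select(frame, expression: str) -> np.ndarray:
    """Atom indices (file order) of atoms matching the expression."""
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(frame, tokens).parse()
    return np.flatnonzero(mask)
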