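"""Small selection mini-language over atom annotations.

Grammar (case-insensitive keywords, whitespace separated)::

    expr     := or_term
    or_term  := and_term ("or" and_term)*
    and_term := unary ("and" unary)*
    unary    := "not" unary | "(" expr ")" | predicate
    predicate:= "all" | "none"
               | "chain"   ID[,ID...]
               | "name"    NAME[,NAME...]
               | "resname" NAME[,NAME...]
               | "element" SYM[,SYM...]
               | "resid"   A | A-B         (inclusive residue-index range)

``and`` binds tighter than ``or``.  Matching is exact (no wildcards).
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["SelectionError", "evaluate_query"]


class SelectionError(ValueError):
    """Raised for syntactically invalid selection expressions."""


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(query: str) -> list[str]:
    tokens = _TOKEN.findall(query)
    if not tokens:
        raise SelectionError("empty selection expression")
    return tokens


class _Parser:
    def __init__(self, structure, tokens: list[str]):
        self.s = structure
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_term()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens after expression: {self.tokens[self.pos:]}")
        return mask

    def or_term(self) -> np.ndarray:
        mask = self.and_term()
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            mask = mask | self.and_term()
        return mask

    def and_term(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.or_term()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.predicate()

    def _values(self) -> list[str]:
        tok = self.take()
        return tok.split(",")

    def predicate(self) -> np.ndarray:
        n = len(self.s)
        keyword = self.take().lower()
        if keyword == "all":
            return np.ones(n, dtype=bool)
        if keyword == "none":
            return np.zeros(n, dtype=bool)
        if keyword == "chain":
            return np.isin(self.s.chain_id.astype(str), self._values())
        if keyword == "name":
            return np.isin(self.s.name.astype(str), self._values())
        if keyword == "resname":
            return np.isin(self.s.res_name.astype(str), self._values())
        if keyword == "element":
            wanted = [v.capitalize() for v in self._values()]
            return np.isin([e.capitalize() for e in self.s.element], wanted)
        if keyword == "resid":
            spec = self.take()
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", spec)
            if m is None:
                raise SelectionError(f"invalid resid range {spec!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise SelectionError(f"resid range {spec!r} is reversed")
            return (self.s.res_id >= lo) & (self.s.res_id <= hi)
        raise SelectionError(f"unknown selection keyword {keyword!r}")


def evaluate_query(structure, query: str) -> np.ndarray:
    """Boolean mask over atoms of ``structure`` for the query string."""
    if not isinstance(query, str):
        raise SelectionError(f"selection query must be a string, got {type(query)}")
    return _Parser(structure, _tokenize(query)).parse()
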