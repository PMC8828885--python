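"""Boolean expression language shared by marker gating and pixel-area analysis.

Two atom styles are supported over the same grammar:

* *gate* atoms compare a marker to a threshold: ``CD4 >= 0.1``
* *mask* atoms name a binary mask: ``IgA``

Atoms combine with ``&`` (AND), ``|`` (OR), ``!`` (NOT) and parentheses; the
word forms ``and`` / ``or`` / ``not`` are accepted as synonyms.  Evaluation is
vectorised over numpy arrays or pandas columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ExpressionError

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_\-]*)"
    r"|(?P<cmp><=|>=|<|>)"
    r"|(?P<op>[&|!()]))"
)

_WORD_OPS = {"and": "&", "or": "|", "not": "!"}


@dataclass(frozen=True)
class Atom:
    name: str
    comparator: str | None = None  # one of > >= < <=, or None for mask atoms
    threshold: float | None = None

    def evaluate(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        if self.name not in env:
            raise ExpressionError(f"unknown name {self.name!r}")
        values = np.asarray(env[self.name])
        if self.comparator is None:
            return values.astype(bool)
        if self.comparator == ">":
            return values > self.threshold
        if self.comparator == ">=":
            return values >= self.threshold
        if self.comparator == "<":
            return values < self.threshold
        return values <= self.threshold


@dataclass(frozen=True)
class Node:
    op: str  # "&", "|", "!"
    children: tuple

    def evaluate(self, env: Mapping[str, np.ndarray]) -> np.ndarray:
        parts = [c.evaluate(env) for c in self.children]
        if self.op == "&":
            out = parts[0]
            for p in parts[1:]:
                out = out & p
            return out
        if self.op == "|":
            out = parts[0]
            for p in parts[1:]:
                out = out | p
            return out
        return ~parts[0]


def tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ExpressionError(f"unexpected character {text[pos]!r}", pos)
        if m.group("num") is not None:
            tokens.append(("num", m.group("num"), m.start("num")))
        elif m.group("name") is not None:
            word = m.group("name")
            if word.lower() in _WORD_OPS:
                tokens.append(("op", _WORD_OPS[word.lower()], m.start("name")))
            else:
                tokens.append(("name", word, m.start("name")))
        elif m.group("cmp") is not None:
            tokens.append(("cmp", m.group("cmp"), m.start("cmp")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens, mode: str, text: str):
        self.tokens = tokens
        self.mode = mode
        self.text = text
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self):
        node = self.parse_or()
        if self.peek() is not None:
            kind, value, pos = self.peek()
            raise ExpressionError(f"unexpected token {value!r}", pos)
        return node

    def parse_or(self):
        children = [self.parse_and()]
        while self.peek() is not None and self.peek()[:2] == ("op", "|"):
            self.next()
            children.append(self.parse_and())
        return children[0] if len(children) == 1 else Node("|", tuple(children))

    def parse_and(self):
        children = [self.parse_unary()]
        while self.peek() is not None and self.peek()[:2] == ("op", "&"):
            self.next()
            children.append(self.parse_unary())
        return children[0] if len(children) == 1 else Node("&", tuple(children))

    def parse_unary(self):
        kind, value, pos = self.next()
        if kind == "op" and value == "!":
            return Node("!", (self.parse_unary(),))
        if kind == "op" and value == "(":
            node = self.parse_or()
            tok = self.next()
            if tok[:2] != ("op", ")"):
                raise ExpressionError("expected ')'", tok[2])
            return node
        if kind == "name":
            if self.mode == "mask":
                return Atom(value)
            tok = self.next()
            if tok[0] != "cmp":
                raise ExpressionError(
                    f"expected comparator after {value!r}, got {tok[1]!r}", tok[2]
                )
            comparator = tok[1]
            num = self.next()
            if num[0] != "num":
                raise ExpressionError(f"expected number, got {num[1]!r}", num[2])
            return Atom(value, comparator, float(num[1]))
        raise ExpressionError(f"unexpected token {value!r}", pos)


def parse_gate_expression(text: str):
    """Parse a marker-threshold expression such as ``CD8 >= 0.01 & PD1 >= 0.005``."""
    return _Parser(tokenize(text), "gate", text).parse()


def parse_mask_expression(text: str):
    """Parse a mask-combination expression such as ``IgA & !Epithelium``."""
    return _Parser(tokenize(text), "mask", text).parse()


def referenced_names(node) -> set[str]:
    """All atom names referenced by a parsed expression."""
    if isinstance(node, Atom):
        return {node.name}
    out: set[str] = set()
    for child in node.children:
        out |= referenced_names(child)
    return out
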