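"""Boolean expression trees over binary features.

A tree is the genetic-programming individual: internal nodes are drawn from
the function set {AND, OR, NOT} (arities 2, 2, 1) and leaves are feature
indices into the columns of a binary patient-by-gene matrix.  Trees are
stored as immutable nested tuples, e.g. ``("OR", 3, ("AND", 1, 2))``; the
:class:`BoolTree` wrapper adds evaluation, structural queries and the Lisp
s-expression serialization used to persist evolved solutions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

import numpy as np

FUNCTIONS = {"AND": 2, "OR": 2, "NOT": 1}

Expr = object  # int leaf or ("OP", child[, child]) tuple


class ParseError(ValueError):
    """Raised on malformed s-expression input; carries the offending position."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at position {pos})")
        self.pos = pos


def _validate(expr: Expr) -> None:
    if isinstance(expr, (int, np.integer)):
        if expr < 0:
            raise ValueError(f"negative terminal index {expr}")
        return
    if not isinstance(expr, tuple) or not expr:
        raise ValueError(f"malformed node {expr!r}")
    op, *children = expr
    if op not in FUNCTIONS:
        raise ValueError(f"unknown function {op!r}")
    if len(children) != FUNCTIONS[op]:
        raise ValueError(f"{op} expects {FUNCTIONS[op]} children, got {len(children)}")
    for c in children:
        _validate(c)


def _depth(expr: Expr) -> int:
    if isinstance(expr, (int, np.integer)):
        return 0
    return 1 + max(_depth(c) for c in expr[1:])


def _n_nodes(expr: Expr) -> int:
    if isinstance(expr, (int, np.integer)):
        return 1
    return 1 + sum(_n_nodes(c) for c in expr[1:])


def _terminals(expr: Expr, out: set) -> None:
    if isinstance(expr, (int, np.integer)):
        out.add(int(expr))
    else:
        for c in expr[1:]:
            _terminals(c, out)


def _paths(expr: Expr, prefix: tuple = ()) -> Iterator[tuple]:
    """Yield the path (tuple of child positions) of every node, root first."""
    yield prefix
    if not isinstance(expr, (int, np.integer)):
        for i, c in enumerate(expr[1:]):
            yield from _paths(c, prefix + (i,))


def _get(expr: Expr, path: tuple) -> Expr:
    for i in path:
        expr = expr[1 + i]
    return expr


def _replace(expr: Expr, path: tuple, sub: Expr) -> Expr:
    if not path:
        return sub
    i, rest = path[0], path[1:]
    children = list(expr[1:])
    children[i] = _replace(children[i], rest, sub)
    return (expr[0],) + tuple(children)


def _evaluate(expr: Expr, X: np.ndarray) -> np.ndarray:
    if isinstance(expr, (int, np.integer)):
        return X[:, expr].astype(bool)
    op = expr[0]
    if op == "NOT":
        return ~_evaluate(expr[1], X)
    a = _evaluate(expr[1], X)
    b = _evaluate(expr[2], X)
    return (a & b) if op == "AND" else (a | b)


def _to_sexpr(expr: Expr) -> str:
    if isinstance(expr, (int, np.integer)):
        return f"X{int(expr)}"
    return "(" + " ".join([expr[0]] + [_to_sexpr(c) for c in expr[1:]]) + ")"


_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ParseError(f"unexpected character {text[pos]!r}", pos)
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def _parse_tokens(tokens: list[tuple[str, int]], i: int) -> tuple[Expr, int]:
    if i >= len(tokens):
        raise ParseError("unexpected end of input", -1)
    tok, pos = tokens[i]
    if tok == "(":
        if i + 1 >= len(tokens):
            raise ParseError("unexpected end of input after '('", pos)
        op, op_pos = tokens[i + 1]
        if op not in FUNCTIONS:
            raise ParseError(f"unknown function {op!r}", op_pos)
        i += 2
        children = []
        while i < len(tokens) and tokens[i][0] != ")":
            child, i = _parse_tokens(tokens, i)
            children.append(child)
        if i >= len(tokens):
            raise ParseError(f"missing ')' for {op}", pos)
        if len(children) != FUNCTIONS[op]:
            raise ParseError(
                f"{op} expects {FUNCTIONS[op]} arguments, got {len(children)}", op_pos
            )
        return (op,) + tuple(children), i + 1
    if tok == ")":
        raise ParseError("unexpected ')'", pos)
    m = re.fullmatch(r"[Xx](\d+)", tok)
    if m is None:
        raise ParseError(f"expected terminal X<k>, got {tok!r}", pos)
    return int(m.group(1)), i + 1


@dataclass(frozen=True)
class BoolTree:
    """A boolean syntax tree over terminal feature indices.

    Parameters
    ----------
    expr
        Nested-tuple expression: an ``int`` leaf (feature index) or a tuple
        ``("AND", a, b)``, ``("OR", a, b)`` or ``("NOT", a)``.
    """

    expr: Expr

    def __post_init__(self):
        _validate(self.expr)

    @property
    def depth(self) -> int:
        """Depth of the tree; a lone terminal has depth 0."""
        return _depth(self.expr)

    @property
    def n_nodes(self) -> int:
        return _n_nodes(self.expr)

    @property
    def terminals(self) -> frozenset[int]:
        """Set of distinct feature indices used by the tree."""
        out: set = set()
        _terminals(self.expr, out)
        return frozenset(out)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Row-wise boolean evaluation against a binary feature matrix.

        Returns a length-n vector in {0,1}.  Raises ``IndexError`` if any
        terminal index exceeds the number of columns (the applicability
        error used during external validation).
        """
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        hi = max(self.terminals)
        if hi >= X.shape[1]:
            raise IndexError(
                f"tree uses terminal X{hi} but matrix has only {X.shape[1]} columns"
            )
        return _evaluate(self.expr, X).astype(np.int8)

    def remap(self, mapping: dict[int, int]) -> "BoolTree":
        """Return a copy with every terminal index translated via *mapping*."""

        def go(e: Expr) -> Expr:
            if isinstance(e, (int, np.integer)):
                return mapping[int(e)]
            return (e[0],) + tuple(go(c) for c in e[1:])

        return BoolTree(go(self.expr))

    def to_sexpr(self) -> str:
        """Lisp representation, e.g. ``(OR X3 (AND X1 X2))``."""
        return _to_sexpr(self.expr)

    @classmethod
    def parse(cls, text: str) -> "BoolTree":
        """Parse a Lisp s-expression; malformed input raises :class:`ParseError`."""
        tokens = _tokenize(text)
        if not tokens:
            raise ParseError("empty input", 0)
        expr, i = _parse_tokens(tokens, 0)
        if i != len(tokens):
            raise ParseError(f"trailing input {tokens[i][0]!r}", tokens[i][1])
        return cls(expr)

    def __str__(self) -> str:
        return self.to_sexpr()

    # -- structural helpers used by the genetic operators ------------------

    def paths(self) -> list[tuple]:
        return list(_paths(self.expr))

    def subtree_at(self, path: tuple) -> Expr:
        return _get(self.expr, path)

    def with_subtree(self, path: tuple, sub: Expr) -> "BoolTree":
        return BoolTree(_replace(self.expr, path, sub))

    def depth_of(self, path: tuple) -> int:
        return len(path)


def random_tree(
    rng: np.random.Generator, n_features: int, max_depth: int, method: str = "grow"
) -> BoolTree:
    """Generate a random tree by the Koza ``grow`` or ``full`` method.

    ``full`` places functions at every node above *max_depth* so all leaves
    sit exactly at *max_depth*; ``grow`` chooses uniformly between the
    function and terminal sets at each interior point, so trees vary in
    shape.  Terminal indices are sampled uniformly over ``0..n_features-1``.
    """
    if method not in ("grow", "full"):
        raise ValueError(f"unknown init method {method!r}")
    funcs = list(FUNCTIONS)

    def build(depth: int) -> Expr:
        if depth >= max_depth:
            return int(rng.integers(n_features))
        if method == "grow" and depth > 0:
            # uniform over combined primitive set: 3 functions + n terminals
            if rng.random() < n_features / (n_features + len(funcs)):
                return int(rng.integers(n_features))
        op = funcs[rng.integers(len(funcs))]
        return (op,) + tuple(build(depth + 1) for _ in range(FUNCTIONS[op]))

    if max_depth == 0:
        return BoolTree(int(rng.integers(n_features)))
    return BoolTree(build(0))
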