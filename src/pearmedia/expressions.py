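"""Expression trees over media factors, with protected (total) operators.

Symbolic-regression models are represented as finite expression trees whose
leaves are factor symbols (A..F) or numeric constants and whose internal
nodes come from a fixed function table.  Every operator is *protected*: it
returns a finite real for every finite real input, so any tree can be
evaluated anywhere in the factor box.  This is essential both for evolving
trees (arbitrary compositions arise) and for evaluating the published media
models, whose printed forms contain sub-expressions (square roots of
negative quantities, logarithms near zero) that leave the real domain inside
the experimental ranges.

Protection conventions (configurable via :class:`Convention`):

* ``sqrt(x) = |x| ** 0.5`` (alternatives: clamp-to-zero, sign-preserving);
* odd-order roots are sign-preserving, even-order roots act on ``|x|``;
* ``ln(x) = log(max(|x|, eps))``;
* division and ``inverse`` clamp the denominator to ``+-eps``;
* ``exp`` clips its argument to ``+-50``;
* every operator output is clipped to ``+-1e100`` so that chained powers and
  products cannot overflow to infinity.

All operators accept scalars or numpy arrays, so a tree can be evaluated on
a whole design matrix in one pass.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np

EPS = 1e-9
#: hard output bound guaranteeing totality under overflow
VALUE_BOUND = 1e100
EXP_ARG_BOUND = 50.0


@dataclass(frozen=True)
class Convention:
    """Protected-operator conventions for out-of-domain arguments.

    ``sqrt_mode``: "abs" (sqrt of |x|), "zero" (0 for negative x) or "sign"
    (sign-preserving).  The "abs" default is the convention under which the
    published media equations reproduce the printed data.
    """

    sqrt_mode: str = "abs"
    eps: float = EPS

    def __post_init__(self) -> None:
        if self.sqrt_mode not in ("abs", "zero", "sign"):
            raise ValueError(f"unknown sqrt_mode {self.sqrt_mode!r}")


DEFAULT_CONVENTION = Convention()


def _bound(x):
    return np.clip(x, -VALUE_BOUND, VALUE_BOUND)


def _safe_den(x, eps):
    x = np.asarray(x, dtype=float)
    tiny = np.abs(x) < eps
    if np.any(tiny):
        x = np.where(tiny, np.where(x < 0, -eps, eps), x)
    return x


def _make_ops(conv: Convention) -> dict[str, tuple[int, Callable]]:
    eps = conv.eps

    def add(a, b):
        return _bound(a + b)

    def sub(a, b):
        return _bound(a - b)

    def mul(a, b):
        return _bound(a * b)

    def div(a, b):
        return _bound(a / _safe_den(b, eps))

    def inv(a):
        return _bound(1.0 / _safe_den(a, eps))

    def sqrt(a):
        a = np.asarray(a, dtype=float)
        if conv.sqrt_mode == "abs":
            return np.sqrt(np.abs(a))
        if conv.sqrt_mode == "zero":
            return np.sqrt(np.maximum(a, 0.0))
        return np.copysign(np.sqrt(np.abs(a)), a)

    def nthroot(n: int) -> Callable:
        def f(a):
            a = np.asarray(a, dtype=float)
            if n % 2 == 1:
                return np.copysign(np.abs(a) ** (1.0 / n), a)
            return np.abs(a) ** (1.0 / n)

        return f

    def exp(a):
        return np.exp(np.clip(a, -EXP_ARG_BOUND, EXP_ARG_BOUND))

    def ln(a):
        return np.log(np.maximum(np.abs(a), eps))

    def sq(a):
        a = _bound(a)
        return _bound(a * a)

    def cube(a):
        a = np.clip(a, -1e67, 1e67)
        return a * a * a

    def avg2(a, b):
        return _bound((a + b) / 2.0)

    def neg(a):
        return -np.asarray(a, dtype=float)

    return {
        "+": (2, add),
        "-": (2, sub),
        "*": (2, mul),
        "/": (2, div),
        "neg": (1, neg),
        "sqrt": (1, sqrt),
        "cbrt": (1, nthroot(3)),
        "root4": (1, nthroot(4)),
        "root6": (1, nthroot(6)),
        "root9": (1, nthroot(9)),
        "sin": (1, np.sin),
        "cos": (1, np.cos),
        "atan": (1, np.arctan),
        "sq": (1, sq),
        "cube": (1, cube),
        "exp": (1, exp),
        "ln": (1, ln),
        "inv": (1, inv),
        "tanh": (1, np.tanh),
        "avg2": (2, avg2),
    }


class FunctionTable:
    """Symbol -> (arity, protected rule) for every operator the package uses."""

    def __init__(self, convention: Convention = DEFAULT_CONVENTION,
                 symbols: Sequence[str] | None = None):
        self.convention = convention
        ops = _make_ops(convention)
        if symbols is not None:
            unknown = set(symbols) - set(ops)
            if unknown:
                raise KeyError(f"unknown function symbols {sorted(unknown)}")
            ops = {s: ops[s] for s in symbols}
        self._ops = ops

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._ops

    def __iter__(self) -> Iterator[str]:
        return iter(self._ops)

    def arity(self, symbol: str) -> int:
        return self._ops[symbol][0]

    def rule(self, symbol: str) -> Callable:
        return self._ops[symbol][1]

    @property
    def max_arity(self) -> int:
        return max(a for a, _ in self._ops.values())


DEFAULT_TABLE = FunctionTable()

_TERMINAL_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class Node:
    """One expression-tree node: operator, terminal symbol, or constant leaf."""

    symbol: str
    children: tuple["Node", ...] = ()
    value: float | None = None  # set iff symbol == "const"

    @property
    def arity(self) -> int:
        return len(self.children)

    def __iter__(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c

    def size(self) -> int:
        return sum(1 for _ in self)


ExpressionTree = Node  # domain alias


def const(v: float) -> Node:
    return Node("const", value=float(v))


def term(symbol: str) -> Node:
    if not _TERMINAL_RE.match(symbol):
        raise ValueError(f"invalid terminal symbol {symbol!r}")
    return Node(symbol)


def op(symbol: str, *children: Node, table: FunctionTable = DEFAULT_TABLE) -> Node:
    if symbol not in table:
        raise KeyError(f"unknown function symbol {symbol!r}")
    if len(children) != table.arity(symbol):
        raise ValueError(
            f"{symbol!r} takes {table.arity(symbol)} children, got {len(children)}"
        )
    return Node(symbol, tuple(children))


def validate_tree(tree: Node, table: FunctionTable = DEFAULT_TABLE) -> None:
    """Check every operator node's arity against the function table."""
    for node in tree:
        if node.symbol == "const":
            if node.value is None or not np.isfinite(node.value):
                raise ValueError("constant leaf without a finite value")
        elif node.symbol in table:
            if node.arity != table.arity(node.symbol):
                raise ValueError(
                    f"arity mismatch at {node.symbol!r}: "
                    f"expected {table.arity(node.symbol)}, got {node.arity}"
                )
        elif node.arity != 0:
            raise KeyError(f"unknown function symbol {node.symbol!r}")


def evaluate_tree(tree: Node, x: Mapping[str, float | np.ndarray],
                  table: FunctionTable = DEFAULT_TABLE):
    """Evaluate a tree at terminal values ``x`` (scalars or aligned arrays).

    Pure function of ``(tree, x)``; returns a float for scalar inputs and an
    ndarray for array inputs.  Raises ``KeyError`` for an unknown symbol and
    ``ValueError`` on arity mismatch.
    """
    sym = tree.symbol
    if sym == "const":
        out = tree.value
    elif tree.arity == 0:
        try:
            out = x[sym]
        except KeyError:
            raise KeyError(f"unknown terminal symbol {sym!r}") from None
    else:
        if sym not in table:
            raise KeyError(f"unknown function symbol {sym!r}")
        if table.arity(sym) != tree.arity:
            raise ValueError(
                f"arity mismatch at {sym!r}: expected {table.arity(sym)}, got {tree.arity}"
            )
        args = [evaluate_tree(c, x, table) for c in tree.children]
        out = table.rule(sym)(*args)
    if np.ndim(out) == 0:
        return float(out)
    return np.asarray(out, dtype=float)


# --------------------------------------------------------------------------
# infix rendering and parsing

def to_formula_string(tree: Node) -> str:
    """Parenthesized infix rendering; parse -> evaluate round-trips exactly."""
    sym = tree.symbol
    if sym == "const":
        return repr(tree.value)
    if tree.arity == 0:
        return sym
    args = [to_formula_string(c) for c in tree.children]
    if sym in ("+", "-", "*", "/"):
        return f"({args[0]}{sym}{args[1]})"
    if sym == "neg":
        return f"(-{args[0]})"
    if sym == "avg2":
        return f"(({args[0]}+{args[1]})/2)"
    return f"{sym}({', '.join(args)})"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/(),]))"
)


def _tokenize(s: str) -> list[tuple[str, str]]:
    tokens, pos = [], 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or m.end() == pos:
            raise ValueError(f"cannot tokenize formula at: {s[pos:pos + 20]!r}")
        pos = m.end()
        for kind in ("num", "name", "op"):
            if m.group(kind) is not None:
                tokens.append((kind, m.group(kind)))
                break
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], table: FunctionTable):
        self.tokens = tokens
        self.pos = 0
        self.table = table

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.pos]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, text: str) -> None:
        kind, val = self.next()
        if val != text:
            raise ValueError(f"expected {text!r}, got {val!r}")

    def parse_expr(self) -> Node:
        node = self.parse_term()
        while self.peek()[1] in ("+", "-"):
            sym = self.next()[1]
            node = Node(sym, (node, self.parse_term()))
        return node

    def parse_term(self) -> Node:
        node = self.parse_unary()
        while self.peek()[1] in ("*", "/"):
            sym = self.next()[1]
            node = Node(sym, (node, self.parse_unary()))
        return node

    def parse_unary(self) -> Node:
        if self.peek()[1] == "-":
            self.next()
            return Node("neg", (self.parse_unary(),))
        return self.parse_atom()

    def parse_atom(self) -> Node:
        kind, val = self.next()
        if kind == "num":
            return const(float(val))
        if kind == "name":
            if self.peek()[1] == "(":
                if val not in self.table:
                    raise KeyError(f"unknown function symbol {val!r}")
                self.next()
                args = [self.parse_expr()]
                while self.peek()[1] == ",":
                    self.next()
                    args.append(self.parse_expr())
                self.expect(")")
                if len(args) != self.table.arity(val):
                    raise ValueError(
                        f"{val!r} takes {self.table.arity(val)} arguments, got {len(args)}"
                    )
                return Node(val, tuple(args))
            return term(val)
        if val == "(":
            node = self.parse_expr()
            self.expect(")")
            return node
        raise ValueError(f"unexpected token {val!r}")


def parse_formula(s: str, table: FunctionTable = DEFAULT_TABLE) -> Node:
    """Parse an infix formula string into an expression tree."""
    parser = _Parser(_tokenize(s), table)
    tree = parser.parse_expr()
    if parser.peek()[0] != "end":
        raise ValueError(f"trailing input after formula: {parser.peek()[1]!r}")
    return tree
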