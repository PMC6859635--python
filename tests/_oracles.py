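"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own evaluation/decoding code paths:
the evaluator is plain-`math` recursion, the decoder is a FIFO-queue
algorithm (the package builds level lists instead).
"""
import math
from collections import deque

from pearmedia.expressions import DEFAULT_TABLE, EPS, Node, const, term
from pearmedia.gep import CONSTANT_SLOT


def oracle_eval(node, env):
    """Direct-recursion scalar evaluation with the protected conventions."""
    s = node.symbol
    if s == "const":
        return node.value
    if not node.children:
        return env[s]
    a = [oracle_eval(c, env) for c in node.children]
    clip = lambda v: max(-1e100, min(1e100, v))
    den = lambda v: v if abs(v) >= EPS else (EPS if v >= 0 else -EPS)
    table = {
        "+": lambda: clip(a[0] + a[1]),
        "-": lambda: clip(a[0] - a[1]),
        "*": lambda: clip(a[0] * a[1]),
        "/": lambda: clip(a[0] / den(a[1])),
        "sqrt": lambda: math.sqrt(abs(a[0])),
        "cbrt": lambda: math.copysign(abs(a[0]) ** (1 / 3), a[0]),
        "ln": lambda: math.log(max(abs(a[0]), EPS)),
        "exp": lambda: math.exp(max(-50.0, min(50.0, a[0]))),
        "inv": lambda: clip(1.0 / den(a[0])),
        "avg2": lambda: clip((a[0] + a[1]) / 2.0),
        "sq": lambda: clip(clip(a[0]) ** 2),
        "tanh": lambda: math.tanh(a[0]),
        "sin": lambda: math.sin(a[0]),
        "cos": lambda: math.cos(a[0]),
        "atan": lambda: math.atan(a[0]),
    }
    return table[s]()


def oracle_decode(gene):
    """FIFO-queue Karva decoding (breadth-first ORF), independent algorithm."""

    class N:
        def __init__(self, sym, pos):
            self.sym, self.pos, self.kids = sym, pos, []

    arity = lambda s: DEFAULT_TABLE.arity(s) if s in DEFAULT_TABLE else 0
    root = N(gene.symbols[0], 0)
    queue = deque([root] if arity(root.sym) else [])
    i = 1
    while queue:
        parent = queue[0]
        node = N(gene.symbols[i], i)
        i += 1
        parent.kids.append(node)
        if arity(node.sym):
            queue.append(node)
        if len(parent.kids) == arity(parent.sym):
            queue.popleft()

    def build(n):
        if arity(n.sym) == 0:
            if n.sym == CONSTANT_SLOT:
                return const(gene.constants[n.pos])
            return term(n.sym)
        return Node(n.sym, tuple(build(k) for k in n.kids))

    return build(root)
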