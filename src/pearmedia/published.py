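"""The ten published media-response equations, transcribed verbatim.

Each model predicts one growth response (PR, SL, STN, Vitri, QI) for one
rootstock (Pyrodwarf or OHF) as a sum of three sub-expressions (the three
genes of the multigenic chromosome that evolved it, linked by addition).
Terminals follow the experimental tables' column order:

    A = KNO3, B = NH4NO3, C = mesos, D = minors, E = BAP, F = IBA

(the source table's footnote transposes A and B; evaluating both mappings
against the experimental data shows the column-order mapping is the correct
one).  Constants are kept at full printed precision.  Evaluation uses the
protected operators of :mod:`pearmedia.expressions`, so the models are total
on the whole factor box even where the printed forms leave the real domain.
"""
from __future__ import annotations

from functools import lru_cache
from typing import Mapping

import numpy as np

from .expressions import (
    DEFAULT_TABLE,
    FunctionTable,
    Node,
    evaluate_tree,
    parse_formula,
)
from .factors import FACTOR_SYMBOLS, FactorVector, canonical_rootstock

# Three gene sub-expressions per model, linked by addition.
_FORMULAS: dict[tuple[str, str], tuple[str, str, str]] = {
    ("Pyrodwarf", "PR"): (
        "exp((F-B)*C) - D",
        "inv(ln((sqrt((E-2.1016)/2) + E)/2)) + D",
        "sq(cbrt(3.1775-C)) + cbrt(exp(A)/(C+0.11065))",
    ),
    ("Pyrodwarf", "SL"): (
        "cbrt(ln(cube(D))) + (F*(((C+A)/2)*E))",
        "2.4011*sq(((((E+1.7251)/2)*2.7057) + (1.7251-B))/2 - E)",
        "cbrt(2.3488*((inv(E)-7.0907) + (E-D)))",
    ),
    ("Pyrodwarf", "STN"): (
        "(D + (sqrt(C)*(F-E)))/2 + exp(A-C)",
        "(B - ((6.1753/E)+E)/2) + ((9.3446*A)*ln(B))",
        "(((ln(F) + 11.3038/A) - E + 1.0814) + 15.0404*sq(A))/2",
    ),
    ("Pyrodwarf", "Vitri"): (
        "((exp(B)*B)*inv(C))/2 - (D-B) - 1.5069",
        "((exp(2.988-D) + (A-9.0917)/2)/2) * (2*B - (B*D))",
        "(((((E+B)/2)+B)/2 + F + 8.8145)/2) * ((A+B)/2 + 2*B)",
    ),
    ("Pyrodwarf", "QI"): (
        "root9((D*A)/(sqrt(C)*B))",
        "cbrt(inv(((E/30.7869)+B)/2) + (0.9692-A-B))",
        "root6((exp(C)*(10.3785+F)) + inv(F) - A)",
    ),
    ("OHF", "PR"): (
        "sqrt((0.0894*D*B) + inv(A+E))",
        "cbrt((-8.5762/A) - 6.8234) * inv(3.2661-E)",
        "(((C+0.1838)/2 + 6.8196)/2) + inv(C) + ((B*F) - B)",
    ),
    ("OHF", "SL"): (
        "(ln((B+4.8333)/2) + ((D+4.7651)/2 - (A+B)))/2",
        "C + exp((-2.8335*A) * (((D-6.4679) + (9.3060*C))/2))",
        "exp((((3.8362*F)-A) + ((E+3.1237)/2))/2 - inv(3.4882-E))",
    ),
    ("OHF", "STN"): (
        "sq(B) - cbrt(((C/E)+8.1303)/ln(A))",
        "exp(A) + cube(C) - C",
        "F + (D + (sq(-4.4380/C) - 6.1907/B))/2",
    ),
    ("OHF", "Vitri"): (
        "E * (A + (((E-0.8805)/2)*B)/(F+A))",
        "(A - (cbrt(A)-6.8169)) / sq(D)",
        "((A + 2*D - 6.8579)/2) * ((sq(D) + B/A)/2)",
    ),
    ("OHF", "QI"): (
        "sqrt(cube(root4(((inv(E)+8.3712)/2)*(C-F))))",
        "inv(((C-5.1079)*sqrt(D)) * ((C*A)-5.0292))",
        "(inv(B) + ln(ln(C/0.3661)*(D+F)))/2",
    ),
}

#: responses whose printed optimum row is attributed to a different model
#: family in the source's prose (kept for reporting metadata)
AMBIGUOUS_PROVENANCE: frozenset[str] = frozenset({"QI"})


def model_keys() -> list[tuple[str, str]]:
    """All (rootstock, response) pairs with a published model."""
    return sorted(_FORMULAS)


def _resolve(rootstock: str, response: str) -> tuple[str, str]:
    rs = canonical_rootstock(rootstock)
    for (r, resp) in _FORMULAS:
        if r == rs and resp.lower() == response.lower():
            return (r, resp)
    raise KeyError(
        f"no published model for ({rootstock!r}, {response!r}); "
        f"valid keys: {model_keys()}"
    )


def published_terms(rootstock: str, response: str) -> tuple[str, str, str]:
    """The three addition-linked sub-expression strings of one model."""
    return _FORMULAS[_resolve(rootstock, response)]


@lru_cache(maxsize=None)
def published_model(rootstock: str, response: str) -> Node:
    """The full expression tree (sum of three sub-trees) of one model."""
    terms = published_terms(rootstock, response)
    subtrees = [parse_formula(t) for t in terms]
    tree = subtrees[0]
    for sub in subtrees[1:]:
        tree = Node("+", (tree, sub))
    return tree


def published_subtrees(rootstock: str, response: str) -> list[Node]:
    """The three addition-linked gene sub-trees of one model."""
    return [parse_formula(t) for t in published_terms(rootstock, response)]


def predict(rootstock: str, response: str,
            x: FactorVector | Mapping[str, float | np.ndarray],
            table: FunctionTable = DEFAULT_TABLE):
    """Evaluate a published model at composition(s) ``x``.

    ``x`` may be a :class:`FactorVector`, a mapping keyed by factor names or
    by symbols A..F, with scalar or aligned-array values.
    """
    tree = published_model(rootstock, response)
    if isinstance(x, FactorVector):
        env = x.as_symbols()
    elif all(s in x for s in FACTOR_SYMBOLS):
        env = {s: x[s] for s in FACTOR_SYMBOLS}
    else:
        from .factors import NAME_TO_SYMBOL

        env = {NAME_TO_SYMBOL[k]: v for k, v in x.items() if k in NAME_TO_SYMBOL}
    return evaluate_tree(tree, env, table)
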