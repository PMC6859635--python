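"""Gene expression programming: symbolic regression on linear genomes.

Individuals are fixed-length linear chromosomes of one or more genes.  Each
gene has a *head* (functions or terminals) and a *tail* (terminals only) of
length ``t = h*(a_max - 1) + 1``, which guarantees that the breadth-first
open-reading-frame (Karva) decoding of any gene is a complete expression
tree.  A chromosome's phenotype is the fold of its per-gene trees under a
linking operator (addition here).  Evolution uses roulette-wheel selection
with elitism and the classical operator suite — per-symbol mutation, head
inversion, one-/two-point and whole-gene recombination, and gene
transposition — at the published rates.  Fitness is the root relative
squared error (RRSE) of the decoded model on the training records; roulette
weights use the strictly decreasing transform ``1000 / (1 + RRSE)``.

Ephemeral numeric constants: the terminal alphabet may include the slot
``"?"``; each gene carries one constant per position, drawn uniformly from
a configurable range at creation and perturbed by jitter mutation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .expressions import (
    DEFAULT_TABLE,
    FunctionTable,
    Node,
    const,
    evaluate_tree,
    term,
)
from .factors import FACTOR_SYMBOLS, SYMBOL_TO_NAME

CONSTANT_SLOT = "?"

#: default function set: the published runs' operator alphabet
DEFAULT_FUNCTIONS: tuple[str, ...] = (
    "+", "-", "*", "/", "sqrt", "cbrt", "sin", "cos", "atan",
    "sq", "cube", "exp", "ln", "inv", "tanh", "avg2",
)


def tail_length(head_length: int, max_arity: int) -> int:
    """Tail length t = h*(a - 1) + 1 guaranteeing complete decoding."""
    if head_length < 1 or max_arity < 1:
        raise ValueError("head_length and max_arity must be >= 1")
    return head_length * (max_arity - 1) + 1


@dataclass(frozen=True)
class GEPConfig:
    """Run configuration; operator rates default to the published settings."""

    population_size: int = 50
    head_length: int = 8
    n_genes: int = 3
    linking: str = "+"
    function_set: tuple[str, ...] = DEFAULT_FUNCTIONS
    terminal_set: tuple[str, ...] = FACTOR_SYMBOLS
    use_constants: bool = True
    constant_range: tuple[float, float] = (-10.0, 10.0)
    mutation_rate: float = 0.044
    inversion_rate: float = 0.1
    one_point_recomb: float = 0.1
    two_point_recomb: float = 0.3
    gene_recomb: float = 0.1
    gene_transposition: float = 0.1
    generations: int = 500
    elitism: int = 1
    target_rrse: float = 1e-6
    stall_window: int = 50
    stall_delta: float = 1e-6
    reseed_stall: int = 0   # >0: refresh non-elites after this many stalled generations
    selection_pressure: float = 1.0  # exponent on the roulette weight
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.mutation_rate, self.inversion_rate, self.one_point_recomb,
                 self.two_point_recomb, self.gene_recomb, self.gene_transposition)
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("operator rates must be in [0, 1]")
        if self.head_length < 1 or self.n_genes < 1:
            raise ValueError("head_length and n_genes must be >= 1")
        if self.elitism < 1:
            raise ValueError("elitism must be >= 1")

    @property
    def terminals_with_const(self) -> tuple[str, ...]:
        if self.use_constants:
            return (*self.terminal_set, CONSTANT_SLOT)
        return self.terminal_set

    def gene_length(self, table: FunctionTable = DEFAULT_TABLE) -> int:
        a = max(table.arity(s) for s in self.function_set)
        return self.head_length + tail_length(self.head_length, a)


@dataclass(frozen=True)
class Gene:
    """Fixed-length symbol string with per-position ephemeral constants."""

    symbols: tuple[str, ...]
    head_length: int
    constants: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.constants) != len(self.symbols):
            raise ValueError("one constant per symbol position required")

    def validate(self, config: GEPConfig, table: FunctionTable) -> None:
        terminals = set(config.terminals_with_const)
        for i, s in enumerate(self.symbols):
            if i < self.head_length:
                if s not in terminals and s not in config.function_set:
                    raise ValueError(f"invalid head symbol {s!r}")
            elif s not in terminals:
                raise ValueError(f"function {s!r} in tail position {i}")


@dataclass
class Chromosome:
    """A list of genes plus cached phenotype/fitness."""

    genes: list[Gene]
    _tree: Node | None = field(default=None, repr=False, compare=False)
    _rrse: float | None = field(default=None, repr=False, compare=False)

    @property
    def fitness(self) -> float | None:
        return self._rrse

    def copy(self) -> "Chromosome":
        c = Chromosome(list(self.genes))
        c._tree, c._rrse = self._tree, self._rrse
        return c


def karva_decode(gene: Gene, table: FunctionTable = DEFAULT_TABLE) -> Node:
    """Breadth-first open-reading-frame decoding of one gene."""
    def make(i: int) -> tuple[str, int]:
        s = gene.symbols[i]
        if s in table:
            return s, table.arity(s)
        return s, 0

    sym0, arity0 = make(0)
    idx = 1
    # build level by level; children resolved bottom-up afterwards
    levels: list[list[tuple[str, int, int]]] = [[(sym0, arity0, 0)]]
    while any(a > 0 for _, a, _ in levels[-1]):
        nxt = []
        for _, a, _ in levels[-1]:
            for _ in range(a):
                s, ar = make(idx)
                nxt.append((s, ar, idx))
                idx += 1
        levels.append(nxt)

    def leaf(s: str, pos: int) -> Node:
        if s == CONSTANT_SLOT:
            return const(gene.constants[pos])
        return term(s)

    built: list[list[Node]] = [[] for _ in levels]
    for li in range(len(levels) - 1, -1, -1):
        child_iter = iter(built[li + 1]) if li + 1 < len(levels) else iter(())
        for s, a, pos in levels[li]:
            if a == 0:
                built[li].append(leaf(s, pos))
            else:
                built[li].append(Node(s, tuple(next(child_iter) for _ in range(a))))
    return built[0][0]


def express(chromosome: Chromosome, config: GEPConfig,
            table: FunctionTable = DEFAULT_TABLE) -> Node:
    """Decode a chromosome to its phenotype tree (linking-operator fold)."""
    if chromosome._tree is None:
        trees = [karva_decode(g, table) for g in chromosome.genes]
        tree = trees[0]
        for t in trees[1:]:
            tree = Node(config.linking, (tree, t))
        chromosome._tree = tree
    return chromosome._tree


def fitness_rrse(predicted, observed) -> float:
    """Root relative squared error: sqrt(SS_err / SS_tot).  Lower is better."""
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("predicted/observed must be equal-length 1-D, n >= 2")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant; RRSE undefined")
    return float(np.sqrt(np.sum((p - o) ** 2) / ss_tot))


def selection_weight(rrse: float, pressure: float = 1.0) -> float:
    """Roulette weight: (1000 / (1 + RRSE)) ** pressure (maximized, positive)."""
    return (1000.0 / (1.0 + rrse)) ** pressure


# --------------------------------------------------------------------------
# genome construction and variation

def random_gene(config: GEPConfig, rng: np.random.Generator,
                table: FunctionTable = DEFAULT_TABLE) -> Gene:
    h = config.head_length
    t = tail_length(h, max(table.arity(s) for s in config.function_set))
    head_alphabet = (*config.function_set, *config.terminals_with_const)
    tail_alphabet = config.terminals_with_const
    symbols = [head_alphabet[rng.integers(len(head_alphabet))] for _ in range(h)]
    symbols += [tail_alphabet[rng.integers(len(tail_alphabet))] for _ in range(t)]
    lo, hi = config.constant_range
    constants = tuple(float(v) for v in rng.uniform(lo, hi, size=h + t))
    return Gene(tuple(symbols), h, constants)


def random_chromosome(config: GEPConfig, rng: np.random.Generator,
                      table: FunctionTable = DEFAULT_TABLE) -> Chromosome:
    return Chromosome([random_gene(config, rng, table) for _ in range(config.n_genes)])


def _mutate_gene(gene: Gene, config: GEPConfig, rng: np.random.Generator,
                 table: FunctionTable) -> Gene:
    head_alphabet = (*config.function_set, *config.terminals_with_const)
    tail_alphabet = config.terminals_with_const
    symbols = list(gene.symbols)
    constants = list(gene.constants)
    hits = np.nonzero(rng.random(len(symbols)) < config.mutation_rate)[0]
    for i in hits:
        alphabet = head_alphabet if i < gene.head_length else tail_alphabet
        symbols[i] = alphabet[rng.integers(len(alphabet))]
        if symbols[i] == CONSTANT_SLOT:
            lo, hi = config.constant_range
            constants[i] = float(rng.uniform(lo, hi))
    if config.use_constants and rng.random() < config.mutation_rate:
        # constant jitter: perturb one ephemeral constant
        j = int(rng.integers(len(constants)))
        lo, hi = config.constant_range
        constants[j] = float(np.clip(constants[j] + rng.normal(0.0, 1.0), lo, hi))
    return Gene(tuple(symbols), gene.head_length, tuple(constants))


def _invert_head(gene: Gene, rng: np.random.Generator) -> Gene:
    h = gene.head_length
    if h < 2:
        return gene
    i, j = sorted(rng.choice(h, size=2, replace=False))
    symbols = list(gene.symbols)
    constants = list(gene.constants)
    symbols[i:j + 1] = symbols[i:j + 1][::-1]
    constants[i:j + 1] = constants[i:j + 1][::-1]
    return Gene(tuple(symbols), h, tuple(constants))


def _flat(ch: Chromosome) -> tuple[list[str], list[float]]:
    syms, cons = [], []
    for g in ch.genes:
        syms.extend(g.symbols)
        cons.extend(g.constants)
    return syms, cons


def _unflat(syms: Sequence[str], cons: Sequence[float],
            template: Chromosome) -> Chromosome:
    genes, pos = [], 0
    for g in template.genes:
        n = len(g.symbols)
        genes.append(Gene(tuple(syms[pos:pos + n]), g.head_length,
                          tuple(cons[pos:pos + n])))
        pos += n
    return Chromosome(genes)


def _recombine(a: Chromosome, b: Chromosome, rng: np.random.Generator,
               points: int) -> tuple[Chromosome, Chromosome]:
    sa, ca = _flat(a)
    sb, cb = _flat(b)
    L = len(sa)
    cut = sorted(rng.choice(np.arange(1, L), size=points, replace=False))
    lo, hi = (cut[0], cut[1]) if points == 2 else (cut[0], L)
    sa2 = sa[:lo] + sb[lo:hi] + sa[hi:]
    sb2 = sb[:lo] + sa[lo:hi] + sb[hi:]
    ca2 = ca[:lo] + cb[lo:hi] + ca[hi:]
    cb2 = cb[:lo] + ca[lo:hi] + cb[hi:]
    return _unflat(sa2, ca2, a), _unflat(sb2, cb2, b)


def _gene_recombine(a: Chromosome, b: Chromosome,
                    rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    g = int(rng.integers(len(a.genes)))
    ga, gb = list(a.genes), list(b.genes)
    ga[g], gb[g] = gb[g], ga[g]
    return Chromosome(ga), Chromosome(gb)


def _gene_transpose(ch: Chromosome, rng: np.random.Generator) -> Chromosome:
    if len(ch.genes) < 2:
        return ch
    g = int(rng.integers(1, len(ch.genes)))
    genes = list(ch.genes)
    moved = genes.pop(g)
    genes.insert(0, moved)
    return Chromosome(genes)


def apply_operators(population: list[Chromosome], config: GEPConfig,
                    rng: np.random.Generator,
                    table: FunctionTable = DEFAULT_TABLE) -> list[Chromosome]:
    """One round of variation; the best ``config.elitism`` pass unchanged.

    Chromosomes are ranked by cached RRSE (unevaluated ones rank last, ties
    broken by position); non-elite members undergo mutation, inversion,
    recombination and transposition at their configured rates, in place of
    their position.  With all rates zero the population is returned
    unchanged.
    """
    n = len(population)
    order = sorted(range(n), key=lambda i: (
        population[i].fitness if population[i].fitness is not None else np.inf, i))
    elite = set(order[:config.elitism])
    out: list[Chromosome] = list(population)
    workers = [i for i in range(n) if i not in elite]
    # per-symbol mutation, inversion, transposition
    for i in workers:
        ch = out[i]
        genes = [_mutate_gene(g, config, rng, table) for g in ch.genes]
        ch = Chromosome(genes)
        if rng.random() < config.inversion_rate:
            g = int(rng.integers(len(ch.genes)))
            gs = list(ch.genes)
            gs[g] = _invert_head(gs[g], rng)
            ch = Chromosome(gs)
        if rng.random() < config.gene_transposition:
            ch = _gene_transpose(ch, rng)
        out[i] = ch
    # pairwise recombinations
    for k in range(0, len(workers) - 1, 2):
        i, j = workers[k], workers[k + 1]
        if rng.random() < config.one_point_recomb:
            out[i], out[j] = _recombine(out[i], out[j], rng, points=1)
        if rng.random() < config.two_point_recomb:
            out[i], out[j] = _recombine(out[i], out[j], rng, points=2)
        if rng.random() < config.gene_recomb and config.n_genes > 1:
            out[i], out[j] = _gene_recombine(out[i], out[j], rng)
    return out


# --------------------------------------------------------------------------
# the generational loop

def _resolve_env(train: pd.DataFrame, terminal_set: Sequence[str]) -> dict[str, np.ndarray]:
    env = {}
    for t in terminal_set:
        if t == CONSTANT_SLOT:
            continue
        if t in train.columns:
            env[t] = train[t].to_numpy(float)
        elif t in SYMBOL_TO_NAME and SYMBOL_TO_NAME[t] in train.columns:
            env[t] = train[SYMBOL_TO_NAME[t]].to_numpy(float)
        else:
            raise KeyError(f"no data column for terminal {t!r}")
    return env


def _evaluate(ch: Chromosome, env, y, config, table) -> float:
    if ch._rrse is None:
        tree = express(ch, config, table)
        pred = evaluate_tree(tree, env, table)
        pred = np.broadcast_to(np.asarray(pred, float), y.shape)
        with np.errstate(over="ignore"):
            ch._rrse = fitness_rrse(pred, y)
        if not np.isfinite(ch._rrse):
            ch._rrse = float(np.finfo(float).max / 1e10)
    return ch._rrse


def evolve(train: pd.DataFrame, response: str, config: GEPConfig,
           table: FunctionTable = DEFAULT_TABLE) -> tuple[Chromosome, pd.DataFrame]:
    """Run the generational loop; returns (best chromosome, history).

    History has one row per generation with the best and mean RRSE.
    Reproducible from ``config.seed``.
    """
    if len(train) < 10:
        raise ValueError("need at least 10 training records")
    y = train[response].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError(f"response {response!r} is constant")
    env = _resolve_env(train, config.terminal_set)
    rng = np.random.default_rng(config.seed)
    pop = [random_chromosome(config, rng, table) for _ in range(config.population_size)]
    best: Chromosome | None = None
    hist: list[dict] = []
    stalled = 0
    for gen in range(config.generations):
        fits = np.array([_evaluate(c, env, y, config, table) for c in pop])
        i_best = int(np.argmin(fits))
        if best is None or fits[i_best] < best._rrse:
            if best is not None and best._rrse - fits[i_best] > config.stall_delta:
                stalled = 0
            best = pop[i_best].copy()
        else:
            stalled += 1
        hist.append({"generation": gen, "best_rrse": float(best._rrse),
                     "mean_rrse": float(np.mean(np.minimum(fits, 1e12)))})
        if best._rrse < config.target_rrse:
            break
        if config.reseed_stall and stalled >= config.reseed_stall:
            # diversity refresh on stagnation: keep the elites, reseed the rest
            order = sorted(range(len(pop)), key=lambda i: (fits[i], i))
            pop = [pop[i].copy() for i in order[:config.elitism]] + [
                random_chromosome(config, rng)
                for _ in range(config.population_size - config.elitism)
            ]
            stalled = 0
            continue
        w = len(hist) - 1 - config.stall_window
        if w >= 0 and hist[w]["best_rrse"] - best._rrse < config.stall_delta:
            break
        # roulette selection of the non-elite slots
        weights = np.array([selection_weight(f, config.selection_pressure)
                            for f in fits])
        if weights.sum() <= 0 or not np.isfinite(weights.sum()):
            weights = np.ones_like(weights)
        probs = weights / weights.sum()
        order = sorted(range(len(pop)), key=lambda i: (fits[i], i))
        elites = [pop[i].copy() for i in order[:config.elitism]]
        n_rest = config.population_size - config.elitism
        chosen = rng.choice(len(pop), size=n_rest, p=probs)
        rest = [pop[i].copy() for i in chosen]
        pop = apply_operators(elites + rest, config, rng, table)
    return best, pd.DataFrame(hist)


def chromosome_formula(ch: Chromosome, config: GEPConfig,
                       table: FunctionTable = DEFAULT_TABLE) -> str:
    from .expressions import to_formula_string

    return to_formula_string(express(ch, config, table))
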