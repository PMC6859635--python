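"""Gene-expression-programming engine: decoding, operators, evolution."""
import numpy as np
import pytest

from _oracles import oracle_decode
from pearmedia.bbd import load_paper_design
from pearmedia.expressions import DEFAULT_TABLE, Node, const, evaluate_tree, term
from pearmedia.gep import (
    CONSTANT_SLOT,
    Chromosome,
    Gene,
    GEPConfig,
    apply_operators,
    chromosome_formula,
    evolve,
    express,
    fitness_rrse,
    karva_decode,
    random_chromosome,
    random_gene,
    tail_length,
)


def _gene(symbols, head, constants=None):
    constants = constants or tuple(0.0 for _ in symbols)
    return Gene(tuple(symbols), head, tuple(constants))


# ----------------------------------------------------------------- structure

@pytest.mark.parametrize("h,a,t", [(8, 2, 9), (1, 1, 1), (8, 1, 1), (5, 3, 11)])
def test_tail_length_rule(h, a, t):
    assert tail_length(h, a) == t


def test_gene_length_from_config():
    cfg = GEPConfig(head_length=8, function_set=("+", "-", "*", "/"))
    assert cfg.gene_length() == 17  # head 8 + tail 9 for binary operators


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        GEPConfig(mutation_rate=1.5)
    with pytest.raises(ValueError):
        GEPConfig(elitism=0)
    with pytest.raises(ValueError):
        GEPConfig(head_length=0)


# ------------------------------------------------------------------ decoding

def test_karva_decode_classic_example():
    # K-expression * + - a b c d  decodes to (a+b)*(c-d)
    g = _gene("*+-abcdaaaaaaaaaa", 8)
    tree = karva_decode(g)
    assert evaluate_tree(tree, dict(a=1, b=2, c=5, d=3)) == 6.0


def test_karva_decode_single_terminal_orf():
    g = _gene("a" * 17, 8)
    tree = karva_decode(g)
    assert tree.symbol == "a" and tree.arity == 0


def test_karva_decode_constant_slot_uses_position_constant():
    g = _gene("+?a" + "a" * 14, 8, constants=(0.0, 2.5) + (0.0,) * 15)
    tree = karva_decode(g)
    assert evaluate_tree(tree, {"a": 1.0}) == 3.5


def test_decoder_matches_independent_queue_oracle(rng):
    """1,000 random genes decode identically under a second decoder."""
    cfg = GEPConfig(head_length=8,
                    function_set=("+", "-", "*", "/", "sqrt", "ln", "avg2"),
                    terminal_set=("a", "b", "c", "d"))
    env = {k: rng.uniform(-2, 2, size=7) for k in "abcd"}
    for _ in range(1000):
        g = random_gene(cfg, rng)
        ours = evaluate_tree(karva_decode(g), env)
        oracle = evaluate_tree(oracle_decode(g), env)
        np.testing.assert_allclose(ours, oracle, rtol=1e-14)


# ------------------------------------------------------------------- fitness

def test_rrse_closed_forms():
    o = np.array([1.0, 2.0, 3.0])
    assert fitness_rrse(o, o) == 0.0
    assert fitness_rrse(np.full(3, o.mean()), o) == pytest.approx(1.0)
    assert fitness_rrse([1, 2, 4], o) == pytest.approx(np.sqrt(0.5))


def test_rrse_rejects_constant_observations():
    with pytest.raises(ValueError):
        fitness_rrse([1.0, 2.0], [5.0, 5.0])


# ----------------------------------------------------------------- operators

def _tail_ok(ch, cfg):
    terminals = set(cfg.terminals_with_const)
    for g in ch.genes:
        for i, s in enumerate(g.symbols):
            if i >= g.head_length and s not in terminals:
                return False
    return True


def test_operators_preserve_structure_under_fuzz(rng):
    """10,000 variation rounds never break gene length or the tail invariant."""
    cfg = GEPConfig(population_size=10, mutation_rate=0.3, inversion_rate=0.5,
                    one_point_recomb=0.5, two_point_recomb=0.5, gene_recomb=0.5,
                    gene_transposition=0.5, terminal_set=("A", "B", "C", "D"),
                    function_set=("+", "-", "*", "/", "sqrt"))
    pop = [random_chromosome(cfg, rng) for _ in range(10)]
    L = cfg.gene_length()
    for _ in range(1000):  # 1000 rounds x 10 chromosomes
        pop = apply_operators(pop, cfg, rng)
        for ch in pop:
            assert len(ch.genes) == cfg.n_genes
            assert all(len(g.symbols) == L for g in ch.genes)
            assert _tail_ok(ch, cfg)


def test_zero_rates_full_elitism_is_identity(rng):
    cfg = GEPConfig(population_size=6, mutation_rate=0.0, inversion_rate=0.0,
                    one_point_recomb=0.0, two_point_recomb=0.0, gene_recomb=0.0,
                    gene_transposition=0.0, elitism=6)
    pop = [random_chromosome(cfg, rng) for _ in range(6)]
    out = apply_operators(pop, cfg, rng)
    assert all(a.genes == b.genes for a, b in zip(pop, out))


def test_mutation_hit_rate_matches_binomial_mean(rng):
    """Observed symbol changes match rate x positions x (1 - resample-same)."""
    cfg = GEPConfig(population_size=2, mutation_rate=0.044, inversion_rate=0.0,
                    one_point_recomb=0.0, two_point_recomb=0.0, gene_recomb=0.0,
                    gene_transposition=0.0, use_constants=False,
                    function_set=("+", "-", "*", "/"),
                    terminal_set=("A", "B", "C", "D", "E", "F"))
    L, h = cfg.gene_length(), cfg.head_length
    n_head, n_tail = 3 * h, 3 * (L - h)
    p_head = cfg.mutation_rate * (1 - 1 / 10)  # head alphabet: 4 fns + 6 terms
    p_tail = cfg.mutation_rate * (1 - 1 / 6)
    expect = n_head * p_head + n_tail * p_tail  # ~2.0 changes per chromosome
    trials, changes = 4000, 0
    base = random_chromosome(cfg, rng)
    for _ in range(trials):
        out = apply_operators([base.copy(), base.copy()], cfg, rng)
        mutated = out[1]  # index 0 is the elite copy
        changes += sum(sa != sb for ga, gb in zip(base.genes, mutated.genes)
                       for sa, sb in zip(ga.symbols, gb.symbols))
    mean = changes / trials
    var = n_head * p_head * (1 - p_head) + n_tail * p_tail * (1 - p_tail)
    assert abs(mean - expect) < 4 * np.sqrt(var / trials)


# ------------------------------------------------------------------ evolve

def _target_frame():
    df = load_paper_design()
    df["y"] = (df["KNO3"] + df["NH4NO3"]) * (df["mesos"] - df["minors"])
    return df


def test_evolution_is_seed_deterministic():
    df = _target_frame()
    cfg = GEPConfig(population_size=40, generations=15, seed=5,
                    function_set=("+", "-", "*"), terminal_set=("A", "B", "C", "D"),
                    use_constants=False, n_genes=1)
    b1, h1 = evolve(df, "y", cfg)
    b2, h2 = evolve(df, "y", cfg)
    assert chromosome_formula(b1, cfg) == chromosome_formula(b2, cfg)
    assert h1.equals(h2)


def test_best_rrse_is_monotone_under_elitism():
    df = _target_frame()
    cfg = GEPConfig(population_size=60, generations=40, seed=2,
                    function_set=("+", "-", "*"), terminal_set=("A", "B", "C", "D"),
                    use_constants=False, n_genes=1)
    _, hist = evolve(df, "y", cfg)
    best = hist["best_rrse"].to_numpy()
    assert (np.diff(best) <= 1e-15).all()


def test_recovers_expressible_target_smoke():
    """Noiseless (A+B)(C-D) on the 48-run design is found quickly."""
    df = _target_frame()
    cfg = GEPConfig(population_size=300, generations=200, seed=1,
                    function_set=("+", "-", "*"), terminal_set=("A", "B", "C", "D"),
                    use_constants=False, n_genes=1, target_rrse=0.005,
                    mutation_rate=0.1, reseed_stall=15, selection_pressure=4.0,
                    stall_window=10 ** 9)
    best, _ = evolve(df, "y", cfg)
    assert best.fitness < 0.01


def test_constant_response_rejected():
    df = _target_frame()
    df["y"] = 1.0
    with pytest.raises(ValueError):
        evolve(df, "y", GEPConfig())


def test_gene_validation():
    cfg = GEPConfig(function_set=("+", "-"), terminal_set=("A", "B"))
    bad = _gene("+AB+AAAA" + "+AAAAAAAA", 8)  # function in tail position
    with pytest.raises(ValueError, match="tail"):
        bad.validate(cfg, DEFAULT_TABLE)
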