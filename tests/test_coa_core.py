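import numpy as np
import pytest

from coasel import (BinaryMask, COAConfig, FitnessValue, fitness, make_mask,
                    opposite, run_coa)
from coasel.coa_core import (initialize_population, opposition_step,
                             select_leader, switching_probability,
                             territorial_move)
from coasel.synthetic import TabularSpec, generate_tabular


class StubRNG:
    """Cycles through a fixed sequence of 'uniform' draws."""

    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def random(self, size=None):
        if size is not None:
            raise NotImplementedError
        v = self.values[self.i % len(self.values)]
        self.i += 1
        return v


def fv(value):
    return FitnessValue(value=value, accuracy=1.0 - value, n_selected=1)


def test_config_validation():
    for kwargs in [dict(N=1), dict(T=0), dict(p=0.0), dict(p=1.0),
                   dict(early_stop_eps=-1), dict(early_stop_window=0)]:
        with pytest.raises(ValueError):
            COAConfig(**kwargs)


def test_initialize_population_respects_p():
    cfg = COAConfig(N=2, T=1, p=1 - 1e-12, seed=0)
    pop = initialize_population(cfg, 8, np.random.default_rng(0))
    assert all(m.bits == (1,) * 8 for m in pop)


def test_initialize_population_binomial_fraction():
    cfg = COAConfig(N=1000, T=1, p=0.5, seed=5)
    pop = initialize_population(cfg, 1, np.random.default_rng(5))
    frac = np.mean([m.bits[0] for m in pop])
    se = 0.5 / np.sqrt(1000)
    assert abs(frac - 0.5) < 5 * se


def test_initialize_population_deterministic():
    cfg = COAConfig(N=10, T=1, seed=3)
    a = initialize_population(cfg, 12, np.random.default_rng(3))
    b = initialize_population(cfg, 12, np.random.default_rng(3))
    assert [m.bits for m in a] == [m.bits for m in b]


@pytest.mark.parametrize("values, expected", [
    ([0.0, 0.2, 0.4], 0),
    ([0.3, 0.1, 0.1], 1),
    ([0.7], 0),
])
def test_select_leader(values, expected):
    assert select_leader([fv(v) for v in values]) == expected


def test_select_leader_empty():
    with pytest.raises(ValueError):
        select_leader([])


@pytest.mark.parametrize("bit, r1, r2, expected", [
    (0, 0.6, 0.3, 0.6),
    (1, 0.6, 0.5, 0.3),
    (1, 0.25, 0.0, 0.25),
])
def test_switching_probability(bit, r1, r2, expected):
    assert switching_probability(bit, r1, r2) == pytest.approx(expected)


def test_territorial_move_noop_when_equal():
    m = BinaryMask((1, 0, 1, 1))
    out = territorial_move(m, m, np.random.default_rng(0))
    assert out.bits == m.bits


def test_territorial_move_forced_adoption():
    # r1 > 0 and u = 0 every bit: u < S always, leader adopted wholesale
    coati, leader = BinaryMask((0, 0, 0, 0)), BinaryMask((1, 0, 1, 1))
    out = territorial_move(coati, leader, StubRNG([0.9, 0.9, 0.0]))
    assert out.bits == leader.bits


def test_territorial_move_forced_retention():
    # r1 = 0 every bit: S = 0 and u >= 0 is never below it
    coati, leader = BinaryMask((0, 1, 0, 1)), BinaryMask((1, 0, 1, 0))
    out = territorial_move(coati, leader, StubRNG([0.0, 0.5, 0.5]))
    assert out.bits == coati.bits


def test_territorial_move_length_mismatch():
    with pytest.raises(ValueError):
        territorial_move(BinaryMask((1, 0)), BinaryMask((1, 0, 1)),
                         np.random.default_rng(0))


def test_opposition_step_strictly_better_accepted():
    table = {(1, 0): 0.1, (0, 1): 0.4}
    coati = BinaryMask((0, 1))
    out, out_fv = opposition_step(coati, fv(0.4),
                                  lambda m: fv(table[m.bits]))
    assert out.bits == (1, 0) and out_fv.value == 0.1


def test_opposition_step_equal_keeps_original():
    coati = BinaryMask((0, 1))
    out, out_fv = opposition_step(coati, fv(0.3), lambda m: fv(0.3))
    assert out.bits == coati.bits


def test_opposition_step_penalty_interaction(demo):
    # opposite of all-ones is the empty mask (fitness 1.0): original kept
    coati = make_mask(set(range(6)), 6)
    base = fitness(demo, coati)
    out, out_fv = opposition_step(coati, base, lambda m: fitness(demo, m))
    assert out.bits == coati.bits and out_fv == base


def test_run_coa_finds_worked_example_optimum(demo):
    # seed 34 puts [1,0,1,0,1,0] in the initial N=3 population
    res = run_coa(demo, COAConfig(N=3, T=50, seed=34))
    assert res.best_fitness.value == 0.0
    assert set(res.best_mask.indices) == {0, 2, 4}


def test_run_coa_trace_non_increasing_and_elitist(demo):
    for seed in range(5):
        res = run_coa(demo, COAConfig(N=4, T=20, seed=seed))
        assert all(a >= b for a, b in zip(res.trace, res.trace[1:]))
        assert res.best_fitness.value == res.trace[-1]


def test_run_coa_seed_determinism():
    F, _ = generate_tabular(TabularSpec(n=40, d=10, k_informative=2, seed=9))
    a = run_coa(F, COAConfig(N=6, T=10, seed=11))
    b = run_coa(F, COAConfig(N=6, T=10, seed=11))
    assert a.best_mask.bits == b.best_mask.bits
    assert a.trace == b.trace
    assert a.n_evaluations == b.n_evaluations


def test_run_coa_population_shape_constant(demo):
    seen = []
    res = run_coa(demo, COAConfig(N=5, T=5, seed=2,
                                  early_stop_window=100),
                  callback=lambda t, best, n: seen.append((t, best)))
    assert res.n_iterations == 5
    assert [t for t, _ in seen] == [1, 2, 3, 4, 5]
    assert res.best_mask.d == demo.d


def test_run_coa_early_stopping(demo):
    # fitness 0 is found at initialization (seed 34), so the best cannot
    # improve and the run stops after exactly one stall window
    res = run_coa(demo, COAConfig(N=3, T=50, seed=34, early_stop_window=10))
    assert res.stopped_early
    assert res.n_iterations == 10
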