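"""Unit tests for the core fitness algebra."""

import numpy as np
import pytest

from germsoma import (
    GERM,
    SOMA,
    Genotype,
    ModelParams,
    ParameterError,
    carrying_capacity,
    cell_fitness_components,
    colony_components,
    colony_survival_prob,
    founder_fitness,
    monomorphic_colony_components,
    suppression_cost,
)
from germsoma.simulate import Cell


class TestCellFitness:
    def test_zero_suppression_reduces_to_major_model(self, params):
        # with g = s = 0 both roles give exactly the unregulated components
        for x, y in [(0.3, 0.8), (0.5, 0.5), (0.9, 0.1)]:
            f_expect = x ** params.alpha * (1 - y) ** params.beta
            v_expect = y ** params.alpha * (1 - x) ** params.beta
            for role in (GERM, SOMA):
                fc = cell_fitness_components(Genotype(x, y, 0, 0), role,
                                             params)
                assert fc.fertility == f_expect
                assert fc.viability == v_expect

    def test_no_tradeoff_decouples_components(self):
        p = ModelParams(beta=0.0)
        base = cell_fitness_components(Genotype(0.6, 0.2, 0, 0.5), SOMA, p)
        # with beta = 0 fertility ignores the viability gene entirely
        for y in (0.0, 0.4, 0.99):
            fc = cell_fitness_components(Genotype(0.6, y, 0, 0.5), SOMA, p)
            assert fc.fertility == base.fertility
        for x in (0.0, 0.3, 0.9):
            fc = cell_fitness_components(Genotype(x, 0.2, 0, 0.5), SOMA, p)
            assert fc.viability == base.viability

    def test_complete_differentiation_corner(self, params):
        full = Genotype(1, 1, 1, 1)
        soma = cell_fitness_components(full, SOMA, params)
        germ = cell_fitness_components(full, GERM, params)
        assert soma.fertility == 0.0      # soma cannot reproduce
        assert germ.viability == 0.0      # germ cannot survive alone
        assert soma.viability > 0.9 * suppression_cost(1.0, params)
        assert germ.fertility == pytest.approx(
            suppression_cost(1.0, params))

    @pytest.mark.parametrize("role", [GERM, SOMA])
    def test_components_within_unit_interval(self, role, rng, params):
        geno = rng.uniform(size=(200, 4))
        for row in geno:
            fc = cell_fitness_components(Genotype(*row), role, params)
            assert 0.0 <= fc.fertility <= 1.0
            assert 0.0 <= fc.viability <= 1.0

    def test_symmetry_under_role_and_gene_swap(self, rng):
        # p = 1/2: swapping (x<->y, g<->s, germ<->soma) swaps f and v exactly
        p = ModelParams(p=0.5)
        for _ in range(50):
            x, y, g, s = rng.uniform(size=4)
            a = cell_fitness_components(Genotype(x, y, g, s), GERM, p)
            b = cell_fitness_components(Genotype(y, x, s, g), SOMA, p)
            assert a.fertility == b.viability
            assert a.viability == b.fertility

    def test_invalid_inputs(self, params):
        with pytest.raises(ParameterError):
            cell_fitness_components(Genotype(1.2, 0.5), GERM, params)
        with pytest.raises(ParameterError):
            cell_fitness_components(Genotype(0.5, 0.5), "stem", params)


class TestSuppressionCost:
    def test_zero_effect_is_free(self, params):
        assert suppression_cost(0.0, params) == 1.0

    def test_strictly_decreasing_in_effect(self, params):
        effects = np.linspace(0, 1, 25)
        costs = suppression_cost(effects, params)
        assert np.all(np.diff(costs) < 0)
        assert np.all((costs > 0) & (costs <= 1))

    def test_larger_scale_means_smaller_costs(self, params):
        cheap = params.with_(cost_scale=2 * params.cost_scale)
        for e in (0.2, 0.5, 1.0):
            assert suppression_cost(e, cheap) > suppression_cost(e, params)

    def test_derivative_vanishes_at_zero(self, params):
        # Gaussian cost has zero slope at zero suppression, so costs do not
        # contribute to first-order selection on a rare suppressor
        h = 1e-7
        slope = (suppression_cost(h, params) - 1.0) / h
        assert abs(slope) < 1e-6


class TestColonyAggregation:
    def test_identical_cells(self, params):
        cells = [Cell(Genotype(0.4, 0.6), GERM, _params=params)
                 for _ in range(8)]
        V, F = colony_components(cells, params)
        assert V == pytest.approx(cells[0].fitness.viability)
        assert F == pytest.approx(cells[0].fitness.fertility)

    def test_half_and_half(self, params):
        half = [Cell(Genotype(0, 1), GERM, _params=params),
                Cell(Genotype(1, 1, 1, 1), GERM, _params=params)]
        # first cell: y=1, x=0 -> v = 1; second: suppressed to v = 0
        V, _ = colony_components(half, params)
        assert V == pytest.approx(0.5)

    def test_random_colony_against_bruteforce_mean(self, rng, params):
        cells = [
            Cell(Genotype(*rng.uniform(size=4)),
                 GERM if rng.random() < 0.5 else SOMA, _params=params)
            for _ in range(16)
        ]
        V, F = colony_components(cells, params)
        # independent brute-force oracle
        v_sum = f_sum = 0.0
        for c in cells:
            f_sum += c.fitness.fertility
            v_sum += c.fitness.viability
        assert V == pytest.approx(v_sum / 16, rel=1e-12)
        assert F == pytest.approx(f_sum / 16, rel=1e-12)

    def test_empty_colony_rejected(self, params):
        with pytest.raises(ParameterError):
            colony_components([], params)

    def test_monomorphic_decomposition_matches_cells(self, params):
        x, y, g, s = 0.7, 0.6, 0.3, 0.2
        F, V = monomorphic_colony_components(x, y, g, s, params)
        k = params.n_germ
        cells = [Cell(Genotype(x, y, g, s), GERM, _params=params)] * k + \
                [Cell(Genotype(x, y, g, s), SOMA, _params=params)] \
                * (params.S - k)
        Vc, Fc = colony_components(cells, params)
        assert V == pytest.approx(Vc)
        assert F == pytest.approx(Fc)


class TestDemography:
    def test_zero_viability_never_survives(self, params):
        for N in (0, 1, 100, 10_000):
            assert colony_survival_prob(0.0, N, params) == 0.0

    def test_survival_decreases_with_crowding(self, params):
        probs = colony_survival_prob(0.6, np.arange(0, 5000, 100), params)
        assert np.all(np.diff(probs) < 0)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_negative_N_rejected(self, params):
        with pytest.raises(ParameterError):
            colony_survival_prob(0.5, -1, params)

    def test_founder_fitness_unity_at_carrying_capacity(self, params):
        for f, v in [(0.3, 0.5), (0.8, 0.2), (0.15, 0.9)]:
            K = carrying_capacity(f, v, params)
            assert K > 0
            assert founder_fitness(f, v, K, params) == pytest.approx(1.0)
        assert founder_fitness(0.0, 0.9, 10, params) == 0.0
        # monotone in fertility
        w = [founder_fitness(f, 0.5, 200, params)
             for f in (0.1, 0.2, 0.4, 0.8)]
        assert np.all(np.diff(w) > 0)

    def test_carrying_capacity_monotone_and_nonnegative(self, params):
        fgrid = np.linspace(0.1, 0.9, 9)
        assert np.all(np.diff(carrying_capacity(fgrid, 0.5, params)) > 0)
        assert np.all(np.diff(carrying_capacity(0.5, fgrid, params)) > 0)
        assert carrying_capacity(1.0 / params.S, 0.5, params) == 0.0

    def test_recursion_converges_monotonically_to_K(self, rng):
        # the deterministic survival/founding recursion approaches K from
        # any positive start, and its fixed point matches the formula
        for _ in range(20):
            alpha = rng.uniform(0.5, 3)
            p = ModelParams(
                alpha=alpha, beta=rng.uniform(0, 1) * alpha,
                b=rng.uniform(1.2, 5), K0=rng.uniform(100, 2000),
                n_divisions=int(rng.integers(2, 7)))
            f, v = rng.uniform(0.05, 1.0, size=2)
            K = carrying_capacity(f, v, p)
            for N0 in (1.0, max(1.0, 3 * K)):
                N = N0
                path = [N]
                for _ in range(10_000):
                    N = N * founder_fitness(f, v, N, p)
                    path.append(N)
                    if abs(path[-1] - path[-2]) <= 1e-13 * max(1.0, K):
                        break
                if K == 0.0:
                    assert N < 1e-6
                else:
                    diffs = np.diff(path[:50])
                    # monotone approach (within floating tolerance)
                    assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)
                    assert N == pytest.approx(K, rel=1e-9)

    def test_large_colony_limit_of_K(self):
        f, v = 0.4, 0.6
        for n in (14, 18, 22):
            p = ModelParams(n_divisions=n)
            approx = p.K0 * p.S * f * v / (p.b - 1.0)
            assert carrying_capacity(f, v, p) / approx == \
                pytest.approx(1.0, abs=2.0 / (p.S * f))


class TestParams:
    def test_alpha_beta_constraint_warns_not_errors(self):
        with pytest.warns(UserWarning, match="beta"):
            p = ModelParams(alpha=1.0, beta=1.5)
        assert p.beta == 1.5

    @pytest.mark.parametrize("field,value", [
        ("alpha", 0.0), ("beta", -0.1), ("cost_scale", 0.0), ("p", 0.0),
        ("p", 1.0), ("n_divisions", 0), ("mu", 1.5), ("sigma_m", -1e-9),
        ("K0", 0.0), ("b", 1.0),
    ])
    def test_out_of_range_params_rejected(self, field, value):
        with pytest.raises(ParameterError, match=field):
            ModelParams(**{field: value})

    def test_colony_size_is_power_of_two(self):
        assert ModelParams(n_divisions=5).S == 32
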