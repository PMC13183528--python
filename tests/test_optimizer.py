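"""Grey wolf optimizer: movement equations, regeneration, convergence."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igwoderm.optimizer import (EliteTriple, IgwoConfig, ObjectiveError,
                                Population, SearchSpace, gwo_coefficients,
                                gwo_step, igwo_regenerate, init_population,
                                optimize)
from igwoderm.synthetic import benchmark_function


def box(dim, lo=-5.0, hi=5.0, integer=False):
    return SearchSpace(lower=np.full(dim, lo), upper=np.full(dim, hi),
                       integer_mask=np.full(dim, integer))


class TestSearchSpace:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=[1.0], upper=[0.0])

    def test_rejects_fractional_integer_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=[0.5], upper=[10.0], integer_mask=[True])

    def test_quantize_rounds_only_masked_dims(self):
        sp = SearchSpace(lower=[0, 0.0], upper=[10, 1.0],
                         integer_mask=[True, False])
        out = sp.quantize(np.array([3.6, 0.37]))
        assert out[0] == 4.0 and out[1] == 0.37


class TestInitPopulation:
    def test_positions_inside_box(self):
        sp = box(2, 0.0, 1.0)
        pop = init_population(sp, IgwoConfig(pop_size=30), np.random.default_rng(0))
        assert pop.positions.shape == (30, 2)
        assert (pop.positions >= 0).all() and (pop.positions <= 1).all()

    def test_integer_dimension_yields_integers(self):
        sp = SearchSpace(lower=[16], upper=[256], integer_mask=[True])
        pop = init_population(sp, IgwoConfig(pop_size=50), np.random.default_rng(1))
        vals = pop.positions[:, 0]
        assert np.array_equal(vals, np.round(vals))
        assert vals.min() >= 16 and vals.max() <= 256

    def test_same_seed_reproduces_population(self):
        sp = box(3)
        cfg = IgwoConfig(pop_size=10)
        a = init_population(sp, cfg, np.random.default_rng(7))
        b = init_population(sp, cfg, np.random.default_rng(7))
        assert np.array_equal(a.positions, b.positions)


class TestGwoStep:
    def test_stationary_at_coincident_optimum(self):
        sp = box(3)
        pop = Population(np.zeros((5, 3)), np.zeros(5))
        z = np.zeros(3)
        elites = EliteTriple(z, z.copy(), z.copy(), 0.0, 0.0, 0.0)
        out = gwo_step(pop, elites, 0, 10, np.random.default_rng(0), sp)
        assert np.array_equal(out.positions, np.zeros((5, 3)))

    def test_control_scalar_endpoints(self):
        rng = np.random.default_rng(0)
        assert gwo_coefficients(0, 200, rng, (1,)).a == 2.0
        assert gwo_coefficients(200, 200, rng, (1,)).a == 0.0

    def test_iteration_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gwo_coefficients(11, 10, np.random.default_rng(0), (1,))

    def test_matches_hand_rolled_equations(self):
        """One agent, dim 2: position must equal a loop transcription of the
        elite-pull equations computed with the identical random draws."""
        sp = box(2, -10.0, 10.0)
        x = np.array([[1.5, -2.0]])
        elites = EliteTriple(np.array([0.5, 0.25]), np.array([-1.0, 2.0]),
                             np.array([2.0, 0.0]), 1.0, 2.0, 3.0)
        pop = Population(x.copy(), np.array([5.0]))
        t, T = 3, 10
        out = gwo_step(pop, elites, t, T, np.random.default_rng(42), sp)

        # independent transcription with the same generator stream: one
        # (r1, r2) pair per agent/dimension shared by the three elite pulls
        rng = np.random.default_rng(42)
        a = 2.0 * (1.0 - t / T)
        r1 = rng.random((1, 2))[0]
        r2 = rng.random((1, 2))[0]
        A = 2.0 * a * r1 - a
        C = 2.0 * r2
        acc = np.zeros(2)
        for e in (elites.alpha, elites.beta, elites.delta):
            D = np.array([abs(C[j] * e[j] - x[0, j]) for j in range(2)])
            acc += np.array([e[j] - A[j] * D[j] for j in range(2)])
        expected = np.clip(acc / 3.0, -10, 10)
        np.testing.assert_allclose(out.positions[0], expected, rtol=1e-12)


class TestRegeneration:
    def _pop(self, n=30, dim=4, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-5, 5, (n, dim))
        fit = (pos ** 2).sum(axis=1)
        pop = Population(pos, fit)
        order = np.argsort(fit)
        elites = EliteTriple(pos[order[0]].copy(), pos[order[1]].copy(),
                             pos[order[2]].copy(), fit[order[0]],
                             fit[order[1]], fit[order[2]])
        return pop, elites

    def test_replacement_count_is_floor_r_n(self):
        pop, elites = self._pop()
        cfg = IgwoConfig(pop_size=30, elim_fraction=0.3)
        out = igwo_regenerate(pop, elites, cfg, 0, np.random.default_rng(0), box(4))
        changed = (out.positions != pop.positions).any(axis=1)
        assert changed.sum() == 9  # floor(0.3 * 30)

    def test_count_capped_so_elites_survive(self):
        pop, elites = self._pop(n=5)
        cfg = IgwoConfig(pop_size=5, elim_fraction=1.0)
        out = igwo_regenerate(pop, elites, cfg, 0, np.random.default_rng(0), box(4))
        changed = (out.positions != pop.positions).any(axis=1)
        assert changed.sum() <= 2  # N - 3
        order = np.argsort(pop.fitness)
        assert not changed[order[:3]].any()

    def test_all_elite_copies_when_p_is_one(self):
        pop, elites = self._pop()
        cfg = IgwoConfig(pop_size=30, elim_fraction=0.3, elite_prob=1.0)
        out = igwo_regenerate(pop, elites, cfg, 5, np.random.default_rng(3), box(4))
        changed = np.nonzero((out.positions != pop.positions).any(axis=1))[0]
        assert len(changed) > 0
        elite_rows = np.stack([elites.alpha, elites.beta, elites.delta])
        for i in changed:
            assert any(np.array_equal(out.positions[i], e) for e in elite_rows)

    def test_sigma_decays_harmonically(self):
        # p=0: every replacement is alpha + sigma*g; recover sigma from spread
        pop, elites = self._pop(n=200, dim=50, seed=1)
        cfg = IgwoConfig(pop_size=200, elim_fraction=0.3, elite_prob=0.0)
        sp = box(50, -1e6, 1e6)
        est = []
        for t in (0, 4, 9):
            out = igwo_regenerate(pop, elites, cfg, t, np.random.default_rng(9), sp)
            changed = (out.positions != pop.positions).any(axis=1)
            dev = out.positions[changed] - elites.alpha
            est.append(dev.std())
        np.testing.assert_allclose(est, [1.0, 1 / 5, 1 / 10], rtol=0.1)

    def test_requires_evaluated_fitness(self):
        pop, elites = self._pop()
        pop.fitness[0] = np.nan
        with pytest.raises(ValueError):
            igwo_regenerate(pop, elites, IgwoConfig(), 0,
                            np.random.default_rng(0), box(4))


class TestOptimize:
    def test_sphere_converges(self):
        b = benchmark_function("sphere", 5)
        res = optimize(b.fn, box(5), IgwoConfig(seed=1), variant="igwo",
                       vectorized=True)
        assert res.best_fitness < 1e-3

    def test_constant_objective_flat_history(self):
        res = optimize(lambda x: 4.25, box(3),
                       IgwoConfig(pop_size=8, max_iter=20, seed=0))
        assert res.best_fitness == 4.25
        assert np.all(res.history == 4.25)

    def test_integer_line_search_finds_optimum(self):
        sp = SearchSpace(lower=[0], upper=[10], integer_mask=[True])
        res = optimize(lambda x: (x[0] - 7) ** 2, sp,
                       IgwoConfig(pop_size=10, max_iter=30, seed=0))
        assert res.best_position[0] == 7 and res.best_fitness == 0.0

    def test_greedy_history_non_increasing(self):
        b = benchmark_function("rastrigin", 4)
        res = optimize(b.fn, box(4), IgwoConfig(pop_size=10, max_iter=50, seed=2),
                       variant="igwo", vectorized=True)
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness == res.history.min()

    def test_seed_reproducibility(self):
        b = benchmark_function("ackley", 3)
        cfg = IgwoConfig(pop_size=12, max_iter=40, seed=11)
        r1 = optimize(b.fn, box(3), cfg, variant="igwo", vectorized=True)
        r2 = optimize(b.fn, box(3), cfg, variant="igwo", vectorized=True)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.history, r2.history)
        assert r1.n_evaluations == r2.n_evaluations

    def test_non_finite_objective_reported_with_position(self):
        def bad(x):
            return np.inf if x[0] > 0 else x[0]
        with pytest.raises(ObjectiveError, match="position"):
            optimize(bad, box(1), IgwoConfig(pop_size=8, max_iter=5, seed=0))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            optimize(lambda x: 0.0, box(1), IgwoConfig(pop_size=4), variant="pso")

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000), dim=st.integers(1, 6))
    def test_box_invariance_property(self, seed, dim):
        b = benchmark_function("rastrigin", dim)
        sp = box(dim, -2.0, 3.0)
        res = optimize(b.fn, sp, IgwoConfig(pop_size=8, max_iter=15, seed=seed),
                       variant="igwo", vectorized=True)
        assert (res.best_position >= -2.0).all()
        assert (res.best_position <= 3.0).all()

    def test_trace_csv_roundtrip(self, tmp_path):
        res = optimize(lambda x: float((x ** 2).sum()), box(2),
                       IgwoConfig(pop_size=6, max_iter=10, seed=0))
        path = tmp_path / "trace.csv"
        res.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness"
        assert len(lines) == len(res.history) + 1


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"pop_size": 3},
        {"elim_fraction": 0.0},
        {"elim_fraction": 1.2},
        {"elite_prob": -0.1},
        {"elite_weights": (1.0, 2.0)},
        {"max_iter": 0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IgwoConfig(**kwargs)
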