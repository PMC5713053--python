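"""Firefly-algorithm feature selection with learning-automata gamma control."""

import numpy as np
import pytest

from mifala.fa_la import (
    FaLaConfig,
    TransitionMatrix,
    activate_features,
    attractiveness,
    evaluate_fitness,
    init_population,
    move_firefly,
    run_fa_la,
    select_gamma,
    stratified_split,
    update_transition_row,
)
from mifala.signals import generate_synthetic_features


class FixedUniform:
    """Stub RNG whose uniform() returns preset values (for roulette/moves)."""

    def __init__(self, values):
        self.values = list(values)

    def uniform(self, low=0.0, high=1.0, size=None):
        v = self.values.pop(0)
        if size is None:
            return low + (high - low) * v
        return np.full(size, low + (high - low) * v)


class TestInitPopulation:
    def test_seed_reproducible(self):
        a = init_population(10, 30, seed=5)
        b = init_population(10, 30, seed=5)
        assert np.array_equal(a.positions, b.positions)

    def test_shape_and_range(self):
        swarm = init_population(50, 304, seed=0)
        assert swarm.positions.shape == (50, 304)
        assert swarm.positions.min() >= 0.0 and swarm.positions.max() <= 1.0

    def test_uniform_mean(self):
        swarm = init_population(100, 500, seed=1)
        n = swarm.positions.size
        sigma = np.sqrt(1.0 / 12.0 / n)
        assert abs(swarm.positions.mean() - 0.5) < 3 * sigma


class TestActivation:
    def test_all_above_half(self):
        assert activate_features(np.full(6, 0.6)).all()

    def test_exactly_half_is_inactive(self):
        mask = activate_features(np.array([0.5, 0.7]))
        assert not mask[0] and mask[1]

    def test_mixed_vector(self):
        mask = activate_features(np.array([0.2, 0.9, 0.5, 0.7]))
        assert mask.tolist() == [False, True, False, True]

    def test_empty_activation_falls_back_to_argmax(self):
        mask = activate_features(np.array([0.1, 0.4, 0.3]))
        assert mask.tolist() == [False, True, False]


@pytest.fixture(scope="module")
def split_data():
    x, y = generate_synthetic_features(n_per_class=100, seed=21)
    rng = np.random.default_rng(0)
    tr, va = stratified_split(y, 0.25, rng)
    return x[tr], y[tr], x[va], y[va]


class TestFitness:
    def test_fitness_is_inverse_accuracy(self, split_data):
        tr_x, tr_y, va_x, va_y = split_data
        theta = np.zeros(30)
        theta[:6] = 0.9  # exactly the informative features
        fit = evaluate_fitness(theta, tr_x, tr_y, va_x, va_y)
        assert fit >= 1.0
        # CAv for the planted-informative mask is high -> fitness near 1
        assert fit < 1.5

    def test_informative_mask_beats_all_features(self):
        wins = 0
        for seed in range(10):
            x, y = generate_synthetic_features(n_per_class=100, seed=300 + seed)
            tr, va = stratified_split(y, 0.25, np.random.default_rng(seed))
            good = np.zeros(30)
            good[:6] = 1.0
            f_good = evaluate_fitness(good, x[tr], y[tr], x[va], y[va])
            f_all = evaluate_fitness(np.ones(30), x[tr], y[tr], x[va], y[va])
            wins += f_good <= f_all
        assert wins >= 8

    def test_missing_class_in_split_rejected(self, split_data):
        tr_x, tr_y, va_x, va_y = split_data
        keep = tr_y != 0
        with pytest.raises(ValueError):
            evaluate_fitness(np.ones(30), tr_x[keep], tr_y[keep], va_x, va_y)


class TestRoulette:
    def test_degenerate_row_always_chosen(self, rng):
        row = np.zeros(20)
        row[7] = 1.0
        for _ in range(20):
            j, gamma = select_gamma(row, rng)
            assert j == 7
            assert gamma == pytest.approx(0.4)

    def test_cumulative_rule_on_uniform_row(self):
        # r = 0.03 falls in the first cumulative slot of a uniform row
        stub = FixedUniform([0.97])  # r = 1 - 0.97 = 0.03
        j, gamma = select_gamma(np.full(20, 0.05), stub)
        assert j == 0
        assert gamma == pytest.approx(0.05)

    def test_empirical_frequencies_multinomial(self, rng):
        row = np.full(20, 0.05)
        n = 100_000
        counts = np.zeros(20)
        for _ in range(n):
            j, _ = select_gamma(row, rng)
            counts[j] += 1
        freqs = counts / n
        sigma = np.sqrt(0.05 * 0.95 / n)
        assert np.max(np.abs(freqs - 0.05)) < 3 * sigma

    def test_malformed_row_rejected(self, rng):
        with pytest.raises(ValueError, match="probability"):
            select_gamma(np.full(20, 0.06), rng)


class TestReinforcement:
    def test_reward_from_uniform_row(self):
        row = update_transition_row(np.full(20, 0.05), 3, improved=True)
        assert row[3] == pytest.approx(0.145)
        others = np.delete(row, 3)
        assert np.allclose(others, 0.045)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_punish_from_uniform_row(self):
        row = update_transition_row(np.full(20, 0.05), 3, improved=False)
        assert row[3] == pytest.approx(0.045)
        assert np.allclose(np.delete(row, 3), 0.1 / 19 + 0.045)
        assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_learning_rates_leave_row_unchanged(self, rng):
        row = rng.dirichlet(np.ones(20))
        assert np.allclose(update_transition_row(row, 5, True, a=0.0), row)
        assert np.allclose(update_transition_row(row, 5, False, b=0.0), row)

    def test_row_stochastic_after_many_random_updates(self, rng):
        row = np.full(20, 0.05)
        for _ in range(10_000):
            j = int(rng.integers(20))
            row = update_transition_row(row, j, bool(rng.integers(2)))
            assert abs(row.sum() - 1.0) < 1e-12
            assert row.min() >= 0.0

    def test_reinforcement_direction(self, rng):
        row = rng.dirichlet(np.ones(20))
        j = int(np.argmin(row))
        assert update_transition_row(row, j, True)[j] > row[j]
        assert update_transition_row(row, j, False)[j] < row[j]


class TestAttractiveness:
    def test_zero_distance_gives_beta0(self):
        assert attractiveness(0.0, gamma=0.7) == pytest.approx(1.0)

    def test_infinite_distance_asymptote(self):
        assert attractiveness(1e6, gamma=0.7) == pytest.approx(0.3)

    def test_direct_evaluation(self):
        expected = 0.3 + 0.7 * np.exp(-0.5)
        assert attractiveness(1.0, gamma=0.5) == pytest.approx(expected)

    def test_monotone_non_increasing(self):
        rs = np.linspace(0, 5, 50)
        betas = [attractiveness(r, 0.4) for r in rs]
        assert np.all(np.diff(betas) <= 0)


class TestMove:
    def test_fixed_point_without_noise(self, rng):
        theta = rng.uniform(0, 1, 10)
        out = move_firefly(theta, theta, gamma_i=0.5, alpha=0.0, rng=rng)
        assert np.allclose(out, theta)

    def test_full_attraction_limit(self):
        # beta == 1 at zero "effective" gamma distance: use beta_min=1
        theta = np.zeros(5)
        target = np.full(5, 0.8)
        out = move_firefly(
            theta, target, gamma_i=0.5, alpha=0.0,
            rng=np.random.default_rng(0), beta_min=1.0, beta0=1.0,
        )
        assert np.allclose(out, target)

    def test_clamped_to_unit_cube(self, rng):
        for _ in range(10_000 // 50):
            theta = rng.uniform(0, 1, 50)
            target = rng.uniform(0, 1, 50)
            out = move_firefly(theta, target, 0.3, alpha=1.0, rng=rng)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestRun:
    def test_history_non_increasing_and_shapes(self):
        x, y = generate_synthetic_features(n_per_class=40, seed=2)
        cfg = FaLaConfig(pop_size=50, generations=5, seed=0)
        res = run_fa_la(x, y, cfg)
        hist = np.array(res.best_fitness_history)
        assert np.all(np.diff(hist) <= 0)
        assert res.transition.c.shape == (50, 20)
        assert res.mask.shape == (30,)
        assert res.selected_count == res.mask.sum()

    def test_uniform_initial_transition_matrix(self):
        tm = TransitionMatrix.uniform(50, 20)
        assert tm.c.shape == (50, 20)
        assert np.all(tm.c == 0.05)
        assert np.allclose(tm.levels, np.arange(1, 21) / 20)

    def test_pure_function_of_seed(self):
        x, y = generate_synthetic_features(n_per_class=30, seed=4)
        cfg = FaLaConfig(pop_size=10, generations=4, seed=9)
        r1 = run_fa_la(x, y, cfg)
        r2 = run_fa_la(x, y, cfg)
        assert np.array_equal(r1.mask, r2.mask)
        assert r1.best_fitness_history == r2.best_fitness_history

    def test_recovers_planted_informative_features(self):
        hits, acc_ok = 0, 0
        for seed in range(10):
            x, y = generate_synthetic_features(n_per_class=100, seed=1000 + seed)
            res = run_fa_la(x, y, FaLaConfig(pop_size=20, generations=30, seed=seed))
            hits += int(res.mask[:6].sum()) >= 5
            # compare with the all-features validation accuracy
            rng = np.random.default_rng(seed)
            tr, va = stratified_split(y, 0.25, rng)
            full = 1.0 / evaluate_fitness(np.ones(30), x[tr], y[tr], x[va], y[va])
            acc_ok += res.best_accuracy >= full
        assert hits >= 8
        assert acc_ok >= 8

    def test_la_not_worse_than_fixed_gamma_ablation(self):
        la_acc, fa_acc = [], []
        for seed in range(10):
            x, y = generate_synthetic_features(n_per_class=100, seed=2000 + seed)
            base = dict(pop_size=20, generations=30, seed=seed)
            la_acc.append(run_fa_la(x, y, FaLaConfig(**base)).best_accuracy)
            fa_acc.append(
                run_fa_la(x, y, FaLaConfig(**base, fixed_gamma=1.0)).best_accuracy
            )
        assert np.mean(la_acc) >= np.mean(fa_acc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            run_fa_la(np.random.default_rng(0).normal(size=(20, 5)), np.zeros(20))
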