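"""Swarm selector: schedule laws, update equations, mask decoding, wrapped
fitness, full-run behaviour, and the Relief baseline."""

import numpy as np
import pytest

from eegfsel import (
    InertiaSchedule,
    PSOConfig,
    decode_mask,
    inertia_weight,
    relief_select,
    select_features,
)
from eegfsel.pso import (
    FitnessEvaluator,
    Particle,
    relief_weights,
    update_position,
    update_velocity,
)

from conftest import make_planted


class TestSchedule:
    @pytest.mark.parametrize(
        "strategy,t,expected",
        [
            ("w6", 0, 0.9),
            ("w6", 25, 0.5),     # on the plateau (t1=20 < t <= t2=30)
            ("w6", 50, 0.4),
            ("w2", 25, 0.8),     # w2 plateau value
            ("w1", 20, 0.8),     # plateau region of w1 (t1=10, t2=40)
            ("w0", 50, 0.4),     # LDW endpoint
            ("w0", 0, 0.9),
        ],
    )
    def test_strategy_values(self, strategy, t, expected):
        sched = InertiaSchedule.strategy(strategy)
        assert inertia_weight(sched, t) == pytest.approx(expected)

    @pytest.mark.parametrize("name", ["w1", "w2", "w3", "w4", "w5", "w6"])
    def test_continuity_at_stage_boundaries(self, name):
        s = InertiaSchedule.strategy(name)
        eps = 1e-9
        assert inertia_weight(s, s.t1) == pytest.approx(
            inertia_weight(s, s.t1 + eps), abs=1e-6
        )
        assert inertia_weight(s, s.t2) == pytest.approx(
            inertia_weight(s, s.t2 + eps), abs=1e-6
        )
        # plateau equals wm exactly from both sides
        assert inertia_weight(s, s.t1) == pytest.approx(s.wm)
        assert inertia_weight(s, s.t2) == pytest.approx(s.wm)

    def test_multistage_degenerates_toward_ldw(self):
        """With the plateau at the linear midpoint and vanishing stage width,
        the three-stage law approaches the plain linear descent."""
        ldw = InertiaSchedule.strategy("w0")
        mid = inertia_weight(ldw, 25)
        tight = InertiaSchedule(kind="mldw", wm=mid, t1=24, t2=26, tmax=50)
        grid = np.linspace(0, 50, 101)
        dev = max(
            abs(inertia_weight(tight, t) - inertia_weight(ldw, t)) for t in grid
        )
        assert dev < 0.02

    def test_out_of_range_iteration_rejected(self):
        s = InertiaSchedule.strategy("w6")
        with pytest.raises(ValueError):
            inertia_weight(s, -1)
        with pytest.raises(ValueError):
            inertia_weight(s, 51)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            InertiaSchedule(kind="mldw", wm=0.95, t1=10, t2=40)  # wm > ws
        with pytest.raises(ValueError):
            InertiaSchedule(kind="mldw", wm=0.5, t1=30, t2=20)


class _OnesRng:
    """Stand-in RNG forcing R1 = R2 = 1 in the velocity update."""

    def uniform(self, size=None):
        return np.ones(size)


class TestUpdates:
    def test_attraction_fixed_point(self):
        x = np.array([0.5, 0.2])
        p = Particle(x.copy(), np.array([0.1, -0.1]), x.copy())
        v = update_velocity(p, x, w=0.7, c1=2, c2=2, rng=np.random.default_rng(0))
        np.testing.assert_allclose(v, 0.7 * np.array([0.1, -0.1]), atol=1e-12)

    def test_hand_evaluated_velocity(self):
        """w=0, R1=R2=1, C1=C2=2, X=0, pbest=gbest=v  ->  velocity 4v."""
        target = np.array([0.05, -0.02])
        p = Particle(np.zeros(2), np.zeros(2), target.copy())
        v = update_velocity(p, target, w=0.0, c1=2, c2=2, rng=_OnesRng())
        np.testing.assert_allclose(v, 4 * target, atol=1e-12)

    def test_velocity_clamped(self):
        p = Particle(np.zeros(1), np.array([10.0]), np.zeros(1))
        v = update_velocity(
            p, np.zeros(1), w=1.0, c1=2, c2=2,
            rng=np.random.default_rng(0), velocity_clamp=0.4,
        )
        assert v[0] == pytest.approx(0.4)

    def test_position_update_is_addition(self):
        p = Particle(np.array([0.5]), np.array([0.2]), np.array([0.5]))
        assert update_position(p)[0] == pytest.approx(0.7)
        p.velocity = np.zeros(1)
        assert update_position(p)[0] == pytest.approx(0.5)
        assert update_position(p)[0] == pytest.approx(0.5)  # idempotent at V=0


class TestDecodeMask:
    def test_strict_threshold(self):
        mask = decode_mask(np.array([0.9, 0.8, 0.81]), 0.8)
        assert mask.tolist() == [True, False, True]

    def test_all_below_selects_argmax(self):
        mask = decode_mask(np.array([0.1, 0.5, 0.3]), 0.8)
        assert mask.tolist() == [False, True, False]

    def test_zero_threshold_selects_all_positive(self):
        assert decode_mask(np.array([0.2, 0.4]), 0.0).all()


class TestFitness:
    def test_separable_informative_mask_zero_error(self):
        X, y = make_planted(n_per_class=15, n_features=10, shift=6.0, seed=0)
        fit = FitnessEvaluator(X, y, seed=0)
        mask = np.zeros(10, dtype=bool)
        mask[:5] = True
        assert fit(mask) == 0.0

    def test_permutation_null_error_near_half(self):
        """With labels shuffled, cross-validated error hovers at chance."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 10))
        errs = []
        for rep in range(200):
            y = np.r_[np.ones(50), -np.ones(50)].astype(int)
            rng.shuffle(y)
            fit = FitnessEvaluator(X, y, seed=rep)
            errs.append(fit(np.ones(10, dtype=bool)))
        assert np.mean(errs) == pytest.approx(0.5, abs=0.05)

    def test_noise_mask_worse_than_informative(self):
        X, y = make_planted(n_per_class=20, n_features=20, shift=2.0, seed=1)
        fit = FitnessEvaluator(X, y, seed=0)
        informative = np.zeros(20, dtype=bool)
        informative[:5] = True
        assert fit(~informative) > fit(informative)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            FitnessEvaluator(np.zeros((10, 2)), np.ones(10))

    def test_empty_mask_rejected(self):
        X, y = make_planted(n_per_class=5, n_features=4, seed=2)
        fit = FitnessEvaluator(X, y, seed=0)
        with pytest.raises(ValueError):
            fit(np.zeros(4, dtype=bool))


@pytest.fixture(scope="module")
def run(planted):
    X, y = planted
    cfg = PSOConfig(n_particles=8, tmax=12, schedule="w0", seed=3)
    return select_features(X, y, cfg), X, y, cfg


class TestSelectFeatures:

    def test_gbest_history_non_increasing(self, run):
        res = run[0]
        fits = [h["gbest_fitness"] for h in res.history]
        assert all(a >= b for a, b in zip(fits, fits[1:]))

    def test_seed_determinism_bitwise(self, run):
        res, X, y, cfg = run
        res2 = select_features(X, y, cfg)
        assert np.array_equal(res.mask, res2.mask)
        assert np.array_equal(res.positions, res2.positions)
        assert np.array_equal(res.velocities, res2.velocities)
        assert res.history == res2.history

    def test_mask_matches_gbest_decode(self, run):
        res, _, _, cfg = run
        assert np.array_equal(res.mask, decode_mask(res.gbest_position, cfg.theta))

    def test_matches_hand_rolled_update_equations(self):
        """Straight-line re-implementation of the two update equations with
        the same random stream reproduces the swarm state at F=4, K=2."""
        F, K, tmax = 4, 2, 2
        theta = 0.8
        fitness = lambda mask: 1.0 - mask.sum() / F  # deterministic surrogate

        cfg = PSOConfig(
            n_particles=K, tmax=tmax, schedule="constant", seed=17, theta=theta
        )
        res = select_features(np.zeros((2, F)), np.array([1, -1]), cfg, fitness=fitness)

        rng = np.random.default_rng(17)
        pos = rng.uniform(0.0, 1.0, (K, F))
        vel = rng.uniform(-0.1, 0.1, (K, F))
        pbest = pos.copy()
        pbest_fit = np.full(K, np.inf)
        gbest = pos[0].copy()
        gbest_fit = np.inf
        for t in range(1, tmax + 1):
            for i in range(K):
                m = pos[i] > theta
                if not m.any():
                    m = np.zeros(F, dtype=bool)
                    m[np.argmax(pos[i])] = True
                f = fitness(m)
                if f < pbest_fit[i]:
                    pbest_fit[i] = f
                    pbest[i] = pos[i].copy()
                if f < gbest_fit:
                    gbest_fit = f
                    gbest = pos[i].copy()
            w = 0.9
            for i in range(K):
                r1 = rng.uniform(size=F)
                r2 = rng.uniform(size=F)
                v = w * vel[i] + 2 * r1 * (pbest[i] - pos[i]) + 2 * r2 * (gbest - pos[i])
                vel[i] = np.clip(v, -0.4, 0.4)
                pos[i] = pos[i] + vel[i]
        np.testing.assert_allclose(res.positions, pos, atol=1e-12)
        np.testing.assert_allclose(res.velocities, vel, atol=1e-12)
        assert res.gbest_fitness == pytest.approx(gbest_fit)

    def test_recovers_informative_columns_better_than_chance(self):
        """Planted-informative recall of the selected mask beats a
        size-matched random mask across seeds."""
        wins = 0
        for seed in range(3):
            X, y = make_planted(n_per_class=20, n_features=60, shift=1.5, seed=seed)
            cfg = PSOConfig(n_particles=10, tmax=15, schedule="w0", seed=seed)
            res = select_features(X, y, cfg)
            recall = res.mask[:5].mean()
            rng = np.random.default_rng(100 + seed)
            rand = np.zeros(60, dtype=bool)
            rand[rng.choice(60, res.n_selected, replace=False)] = True
            if recall > rand[:5].mean():
                wins += 1
        assert wins >= 2


class TestRelief:
    def test_half_selection_count(self):
        X, y = make_planted(n_per_class=10, n_features=748, seed=4)
        mask = relief_select(X, y, 0.5)
        assert mask.sum() == 374

    def test_informative_column_ranks_first(self):
        """Brute-force Relief definition agrees: a single well-separated
        column among noise gets the top weight."""
        rng = np.random.default_rng(5)
        n = 40
        X = rng.standard_normal((n, 20)) * 0.5
        y = np.r_[np.ones(20), -np.ones(20)].astype(int)
        X[:20, 7] += 5.0
        w = relief_weights(X, y)
        assert np.argmax(w) == 7

        # brute-force re-derivation from the definition
        span = X.max(0) - X.min(0)
        Z = (X - X.min(0)) / span
        w_ref = np.zeros(20)
        for i in range(n):
            d = np.sqrt(((Z - Z[i]) ** 2).sum(1))
            d[i] = np.inf
            hit = np.where(y == y[i], d, np.inf).argmin()
            miss = np.where(y != y[i], d, np.inf).argmin()
            w_ref += np.abs(Z[i] - Z[miss]) - np.abs(Z[i] - Z[hit])
        np.testing.assert_allclose(w, w_ref / n, atol=1e-10)

    def test_keep_everything(self):
        X, y = make_planted(n_per_class=5, n_features=12, seed=6)
        assert relief_select(X, y, 1.0).all()

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            relief_select(np.zeros((2, 3)), np.array([1, -1]))

    def test_bad_fraction_rejected(self):
        X, y = make_planted(n_per_class=5, n_features=6, seed=7)
        with pytest.raises(ValueError):
            relief_select(X, y, 0.0)
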