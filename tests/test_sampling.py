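"""Samplers: Metropolis Monte Carlo, conjugate gradients, discrete enumeration."""

import numpy as np
import pytest

import assemblage as asm
from assemblage.sampling import (
    BallMove,
    RigidBodyMove,
    Schedule,
    SwapMove,
    brute_force_enumerate,
    domino_sample,
    metropolis_accept,
    monte_carlo,
    refine_rigid_bodies,
)
from conftest import make_state_space


class TestMetropolis:
    def test_zero_delta_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(0.0, 1.0, rng) for _ in range(100))

    def test_zero_temperature_rejects_uphill(self):
        rng = np.random.default_rng(0)
        assert not any(metropolis_accept(1e-6, 0.0, rng) for _ in range(100))

    def test_delta_equal_temperature_acceptance_is_inverse_e(self):
        rng = np.random.default_rng(123)
        n = 10_000
        freq = sum(metropolis_accept(1.0, 1.0, rng) for _ in range(n)) / n
        assert freq == pytest.approx(np.exp(-1), abs=0.02)


class TestMonteCarlo:
    @pytest.fixture
    def mc_setup(self, two_particle_model):
        sf = asm.ScoringFunction([asm.HarmonicDistanceRestraint("a", "b", d0=4.0, k=1.0)])
        moves = [BallMove(max_translation=1.5)]
        return two_particle_model, sf, moves

    def test_fixed_seed_reproducible(self, mc_setup):
        model, sf, moves = mc_setup
        start = model.snapshot()
        monte_carlo(model, sf, moves, Schedule(2.0, 0.1, 300), seed=5)
        first = model.coords().copy()
        model.restore(start)
        monte_carlo(model, sf, moves, Schedule(2.0, 0.1, 300), seed=5)
        assert np.array_equal(model.coords(), first)

    def test_best_non_increasing_with_nested_runs(self, mc_setup):
        model, sf, moves = mc_setup
        start = model.snapshot()
        bests = []
        for n in (100, 400):
            model.restore(start)
            result = monte_carlo(model, sf, moves, Schedule(2.0, 2.0, n), seed=9)
            bests.append(result.best.total)
        assert bests[1] <= bests[0]

    def test_recorded_scores_match_re_evaluation(self, mc_setup):
        model, sf, moves = mc_setup
        result = monte_carlo(model, sf, moves, Schedule(2.0, 0.1, 200), seed=2)
        for sc in result.ensemble:
            model.restore(sc.configuration)
            assert sf.evaluate(model) == pytest.approx(sc.total, abs=1e-9)

    def test_model_left_at_best(self, mc_setup):
        model, sf, moves = mc_setup
        result = monte_carlo(model, sf, moves, Schedule(2.0, 0.1, 200), seed=2)
        assert sf.evaluate(model) == pytest.approx(result.best.total, abs=1e-9)

    def test_swap_move_exchanges_centroids(self, toy_assembly):
        from assemblage.synthetic import _copy_model

        model = _copy_model(toy_assembly.model)
        bodies = list(model.rigid_bodies)
        before = {
            b: model.coords(model.rigid_bodies[b].member_ids).mean(axis=0) for b in bodies
        }
        rng = np.random.default_rng(0)
        SwapMove(targets=bodies[:2]).propose(model, rng)
        after = {
            b: model.coords(model.rigid_bodies[b].member_ids).mean(axis=0) for b in bodies
        }
        a, b = bodies[:2]
        assert np.allclose(after[a], before[b], atol=1e-9)
        assert np.allclose(after[b], before[a], atol=1e-9)


class TestConjugateGradients:
    def test_two_particle_harmonic_reaches_minimum(self, two_particle_model):
        sf = asm.ScoringFunction([asm.HarmonicDistanceRestraint("a", "b", d0=5.0, k=1.0)])
        asm.conjugate_gradients(two_particle_model, sf)
        d = np.linalg.norm(
            two_particle_model.particles["a"].xyz - two_particle_model.particles["b"].xyz
        )
        assert abs(d - 5.0) < 1e-3

    def test_stationary_start_unchanged(self, two_particle_model):
        sf = asm.ScoringFunction([asm.HarmonicDistanceRestraint("a", "b", d0=8.0, k=1.0)])
        before = two_particle_model.coords().copy()
        result = asm.conjugate_gradients(two_particle_model, sf)
        assert result.ensemble[0].total == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(two_particle_model.coords(), before, atol=1e-6)

    def test_final_never_exceeds_initial(self, small_model):
        sf = asm.ScoringFunction(
            [
                asm.ExcludedVolumeRestraint(k=1.0),
                asm.ConnectivityRestraint(small_model.ids, k=1.0),
            ]
        )
        initial = sf.evaluate(small_model)
        result = asm.conjugate_gradients(small_model, sf, max_steps=50)
        assert result.ensemble[0].total <= initial + 1e-12

    def test_convex_quadratic_reaches_tolerance(self):
        m = asm.Model()
        rng = np.random.default_rng(4)
        for i in range(6):
            m.create_particle(f"p{i}", rng.uniform(-10, 10, 3), 1.0, 1.0)
        terms = [
            asm.HarmonicDistanceRestraint(f"p{i}", f"p{j}", d0=0.0, k=1.0, name=f"q{i}{j}")
            for i in range(6)
            for j in range(i + 1, 6)
        ]
        sf = asm.ScoringFunction(terms)
        result = asm.conjugate_gradients(m, sf, max_steps=500, gtol=1e-8)
        assert result.ensemble[0].total == pytest.approx(0.0, abs=1e-10)

    def test_rigid_bodies_rejected(self, toy_assembly):
        sf = asm.ScoringFunction([asm.ExcludedVolumeRestraint(k=1.0)])
        with pytest.raises(ValueError, match="rigid"):
            asm.conjugate_gradients(toy_assembly.model, sf)


class TestRefineRigidBodies:
    def test_descends_and_preserves_rigidity(self, toy_assembly):
        from assemblage.synthetic import _copy_model, perturb_configuration

        model = perturb_configuration(toy_assembly, 5.0, 30.0, seed=1)
        hier = model.hierarchy
        labels = list(hier)
        terms = [asm.ExcludedVolumeRestraint(1.0)]
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                pa, pb = hier[a][0], hier[b][0]
                d = float(
                    np.linalg.norm(
                        toy_assembly.model.particles[pa].xyz
                        - toy_assembly.model.particles[pb].xyz
                    )
                )
                terms.append(asm.HarmonicDistanceRestraint(pa, pb, d, k=0.5, name=f"{a}{b}"))
        sf = asm.ScoringFunction(terms)
        before = sf.evaluate(model)
        internal = {
            b: np.linalg.norm(
                model.coords(hier[b])[:, None] - model.coords(hier[b])[None, :], axis=-1
            )
            for b in labels
        }
        final = refine_rigid_bodies(model, sf, max_iters=100)
        assert final < before
        for b in labels:
            now = np.linalg.norm(
                model.coords(hier[b])[:, None] - model.coords(hier[b])[None, :], axis=-1
            )
            assert np.allclose(now, internal[b], atol=1e-9)


class TestDiscreteEnumeration:
    def test_pairwise_example_matches_oracle(self):
        model = asm.Model()
        model.create_particle("x.p", (0, 0, 0), 1.0, 1.0, subunit="x")
        model.create_particle("y.p", (0, 0, 0), 1.0, 1.0, subunit="y")
        states = {
            "x": [{"x.p": np.array([0.0, 0, 0])}, {"x.p": np.array([10.0, 0, 0])}],
            "y": [{"y.p": np.array([1.0, 0, 0])}, {"y.p": np.array([11.0, 0, 0])}],
        }
        space = asm.DiscreteStateSpace(model, states)
        # satisfied iff |d - 1| small: (0,0) d=1 and (1,1) d=1 pass; cross terms d=9/11 fail
        sf = asm.ScoringFunction(
            [asm.HarmonicDistanceRestraint("x.p", "y.p", d0=1.0, k=1.0, threshold=0.5)]
        )
        expected = [(0, 0), (1, 1)]
        assert brute_force_enumerate(space, sf) == expected
        assert domino_sample(space, sf) == expected

    def test_no_restraints_returns_full_product(self):
        rng = np.random.default_rng(0)
        space, _ = make_state_space(rng, n_components=3, n_states=3)
        sf = asm.ScoringFunction([])
        assert len(domino_sample(space, sf)) == 27
        assert domino_sample(space, sf) == brute_force_enumerate(space, sf)

    def test_unreachable_thresholds_give_empty_set(self):
        rng = np.random.default_rng(1)
        space, sf = make_state_space(rng, n_components=3, n_states=3)
        impossible = {t.name: -1.0 for t in sf.terms}
        # thresholds below zero can never be met by nonnegative scores
        for t in sf.terms:
            t.threshold = 0.0
        tight = asm.ScoringFunction(
            [
                asm.HarmonicDistanceRestraint(
                    t.p1, t.p2, d0=t.d0, k=t.k, name=t.name, threshold=1e-12
                )
                for t in sf.terms
            ]
        )
        result = domino_sample(space, tight)
        assert result == brute_force_enumerate(space, tight)

    @pytest.mark.parametrize("seed", range(60))
    def test_domino_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        space, sf = make_state_space(rng)
        assert domino_sample(space, sf) == brute_force_enumerate(space, sf)

    def test_brute_force_guard(self):
        rng = np.random.default_rng(2)
        space, sf = make_state_space(rng, n_components=4, n_states=6)
        with pytest.raises(ValueError, match="exceeds"):
            brute_force_enumerate(space, sf, max_product=10)

    def test_single_component_unary_filtering(self):
        model = asm.Model()
        model.create_particle("x.p", (0, 0, 0), 1.0, 1.0, subunit="x")
        model.create_particle("anchor", (0, 0, 0), 1.0, 1.0, subunit="fixed")
        states = {"x": [{"x.p": np.array([float(v), 0, 0])} for v in (1, 5, 20)]}
        space = asm.DiscreteStateSpace(model, states)
        sf = asm.ScoringFunction(
            [asm.HarmonicDistanceRestraint("x.p", "anchor", d0=0.0, k=1.0, kind="upper",
                                           threshold=20.0)]
        )
        # scores: 0.5*d^2 <= 20 -> d <= 6.3: states 0 and 1 pass
        assert brute_force_enumerate(space, sf) == [(0,), (1,)]
        assert domino_sample(space, sf) == [(0,), (1,)]


class TestSchedule:
    def test_geometric_endpoints(self):
        s = Schedule(10.0, 0.1, 5)
        assert s.temperature(0) == pytest.approx(10.0)
        assert s.temperature(4) == pytest.approx(0.1)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            Schedule(1.0, 2.0, 10)
        with pytest.raises(ValueError):
            Schedule(1.0, 0.0, 10)
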