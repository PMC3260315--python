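"""Restraint terms: values, gradients, invariances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import assemblage as asm
from assemblage.density import grid_spec_for, simulate_density
from assemblage.restraints import harmonic_distance_score


def finite_difference(scoring, model, h=1e-5):
    """Central finite differences of the total score over all coordinates."""
    ids = model.ids
    out = np.zeros((len(ids), 3))
    for i, pid in enumerate(ids):
        base = model.particles[pid].xyz.copy()
        for k in range(3):
            model.particles[pid].xyz = base + np.eye(3)[k] * h
            plus = scoring.evaluate(model)
            model.particles[pid].xyz = base - np.eye(3)[k] * h
            minus = scoring.evaluate(model)
            out[i, k] = (plus - minus) / (2 * h)
        model.particles[pid].xyz = base
    return out


def apply_rigid_motion(model, seed=0):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng)
    t = rng.uniform(-30, 30, 3)
    for p in model.particles.values():
        p.xyz = rot.apply(p.xyz) + t


class TestHarmonicDistance:
    def test_zero_at_equilibrium(self, two_particle_model):
        term = asm.HarmonicDistanceRestraint("a", "b", d0=8.0, k=3.0)
        assert term.evaluate(two_particle_model) == pytest.approx(0.0)

    def test_direct_formula(self, two_particle_model):
        # d = 8, d0 = 7, k = 2 -> 0.5 * 2 * 1^2 = 1.0
        term = asm.HarmonicDistanceRestraint("a", "b", d0=7.0, k=2.0)
        assert term.evaluate(two_particle_model) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kind,d0,expected",
        [("upper", 10.0, 0.0), ("lower", 5.0, 0.0), ("upper", 5.0, 4.5), ("lower", 10.0, 2.0)],
    )
    def test_one_sided_variants(self, two_particle_model, kind, d0, expected):
        term = asm.HarmonicDistanceRestraint("a", "b", d0=d0, k=1.0, kind=kind)
        assert term.evaluate(two_particle_model) == pytest.approx(expected)

    def test_identical_particles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            asm.HarmonicDistanceRestraint("a", "a", d0=1.0, k=1.0)

    def test_scalar_helper(self):
        assert harmonic_distance_score(3.0, 1.0, 2.0) == pytest.approx(4.0)
        assert harmonic_distance_score(0.5, 1.0, 2.0, kind="upper") == 0.0


class TestExcludedVolume:
    def test_zero_without_overlap(self, two_particle_model):
        term = asm.ExcludedVolumeRestraint(k=1.0)
        assert term.evaluate(two_particle_model) == 0.0

    def test_hand_computed_overlap(self):
        m = asm.Model()
        m.create_particle("a", (0, 0, 0), radius=2.0, mass=1.0)
        m.create_particle("b", (3, 0, 0), radius=2.0, mass=1.0)
        # overlap = 2 + 2 - 3 = 1 -> 0.5 * 1 * 1^2 = 0.5
        assert asm.excluded_volume_score(m, k=1.0) == pytest.approx(0.5)

    def test_same_rigid_body_pairs_skipped(self):
        m = asm.Model()
        m.create_particle("a", (0, 0, 0), radius=3.0, mass=1.0)
        m.create_particle("b", (2, 0, 0), radius=3.0, mass=1.0)
        m.create_rigid_body("AB", ["a", "b"])
        assert asm.ExcludedVolumeRestraint(k=1.0).evaluate(m) == 0.0

    def test_rigid_motion_invariance(self, small_model):
        term = asm.ExcludedVolumeRestraint(k=2.0)
        before = term.evaluate(small_model)
        apply_rigid_motion(small_model, seed=5)
        assert term.evaluate(small_model) == pytest.approx(before, rel=1e-9)


class TestConnectivity:
    def test_zero_when_all_touching(self):
        m = asm.Model()
        for i, x in enumerate((0.0, 2.0, 4.0)):
            m.create_particle(f"p{i}", (x, 0, 0), radius=1.0, mass=1.0)
        assert asm.connectivity_score(m, m.ids, k=1.0) == 0.0

    def test_collinear_hand_case(self):
        # beads r=1 at x = 0, 2, 5: MST gaps {0, 1} -> 0.5 * 1 * 1^2 = 0.5
        m = asm.Model()
        for i, x in enumerate((0.0, 2.0, 5.0)):
            m.create_particle(f"p{i}", (x, 0, 0), radius=1.0, mass=1.0)
        assert asm.connectivity_score(m, m.ids, k=1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_adding_interior_particle_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        m = asm.Model()
        coords = rng.uniform(-10, 10, (5, 3))
        for i, c in enumerate(coords):
            m.create_particle(f"p{i}", c, radius=1.0, mass=1.0)
        before = asm.connectivity_score(m, m.ids, k=1.0)
        m.create_particle("mid", coords.mean(axis=0), radius=1.0, mass=1.0)
        after = asm.connectivity_score(m, m.ids, k=1.0)
        assert after <= before + 1e-9

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            asm.ConnectivityRestraint(["only"], k=1.0)


class TestScoringFunction:
    def test_empty_sum_is_zero(self, small_model):
        assert asm.ScoringFunction([]).evaluate(small_model) == 0.0

    def test_weighted_linearity(self, two_particle_model):
        term = asm.HarmonicDistanceRestraint("a", "b", d0=7.0, k=3.0, weight=2.0)
        sf = asm.ScoringFunction([term])
        assert sf.evaluate(two_particle_model) == pytest.approx(2.0 * term.evaluate(two_particle_model))

    def test_missing_particle_rejected(self, two_particle_model):
        sf = asm.ScoringFunction([asm.HarmonicDistanceRestraint("a", "zz", d0=1.0, k=1.0)])
        with pytest.raises(KeyError, match="zz"):
            sf.evaluate(two_particle_model)

    @pytest.mark.parametrize("seed", range(5))
    def test_analytic_gradients_match_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        m = asm.Model()
        for i in range(5):
            m.create_particle(f"p{i}", rng.uniform(-8, 8, 3), float(rng.uniform(1, 4)), 10.0)
        sf = asm.ScoringFunction(
            [
                asm.HarmonicDistanceRestraint("p0", "p1", d0=5.0, k=1.5),
                asm.HarmonicDistanceRestraint("p2", "p3", d0=3.0, k=0.7, kind="upper"),
                asm.ExcludedVolumeRestraint(k=1.0),
                asm.ConnectivityRestraint(m.ids, k=0.5, slack=0.5),
            ]
        )
        _, grad = sf.evaluate(m, want_gradient=True)
        fd = finite_difference(sf, m)
        scale = max(np.abs(fd).max(), 1e-8)
        assert np.abs(grad - fd).max() / scale < 1e-4

    def test_is_good_scoring_uses_raw_per_term_thresholds(self, two_particle_model):
        ok = asm.HarmonicDistanceRestraint("a", "b", d0=8.0, k=1.0, threshold=0.1, weight=100.0)
        sf = asm.ScoringFunction([ok])
        assert sf.is_good_scoring(two_particle_model)
        bad = asm.HarmonicDistanceRestraint("a", "b", d0=3.0, k=1.0, threshold=0.1, name="bad")
        sf.add(bad)
        assert not sf.is_good_scoring(two_particle_model)


class TestRigidMotionBehaviour:
    def test_non_em_terms_invariant_em_term_not(self, small_model):
        ps = list(small_model.particles.values())
        spec = grid_spec_for(ps, spacing=2.0, resolution=10.0)
        grid = simulate_density(ps, 10.0, spec)
        em = asm.EMFitRestraint(grid, 10.0)
        others = [
            asm.HarmonicDistanceRestraint("P.1", "P.2", d0=4.0, k=1.0),
            asm.ExcludedVolumeRestraint(k=1.0),
            asm.ConnectivityRestraint(small_model.ids, k=1.0),
        ]
        before = [t.evaluate(small_model) for t in others]
        em_before = em.evaluate(small_model)
        apply_rigid_motion(small_model, seed=9)
        after = [t.evaluate(small_model) for t in others]
        assert np.allclose(before, after, rtol=1e-9, atol=1e-12)
        assert abs(em.evaluate(small_model) - em_before) > 1e-3

    def test_em_gradient_matches_finite_differences(self, small_model):
        ps = list(small_model.particles.values())
        spec = grid_spec_for(ps, spacing=2.0, resolution=10.0)
        grid = simulate_density(ps, 10.0, spec)
        em = asm.EMFitRestraint(grid, 10.0)
        rng = np.random.default_rng(1)
        for p in small_model.particles.values():
            p.xyz = p.xyz + rng.normal(0, 2, 3)
        sf = asm.ScoringFunction([em])
        _, grad = sf.evaluate(small_model, want_gradient=True)
        fd = finite_difference(sf, small_model, h=1e-4)
        assert np.abs(grad - fd).max() / np.abs(fd).max() < 1e-4
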