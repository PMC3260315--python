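"""Superposition, placement scores, clustering, localization, satisfaction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import assemblage as asm
from assemblage.analysis import (
    Transform,
    align_ensemble,
    cluster_ensemble,
    kabsch_superpose,
    localization_density,
    placement_score,
    rmsd,
    satisfaction_report,
)
from assemblage.density import GridSpec, simulate_density
from assemblage.sampling import ScoredConfiguration


def brute_force_min_rmsd(ref, mov, n_grid=24):
    """Independent superposition oracle: dense grid over rotation space."""
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    cref, cmov = ref.mean(axis=0), mov.mean(axis=0)
    best = np.inf
    angles = np.linspace(0, 2 * np.pi, n_grid, endpoint=False)
    half = np.linspace(0, np.pi, n_grid // 2 + 1)
    for a in angles:
        for b in half:
            for c in angles:
                rot = Rotation.from_euler("zyz", [a, b, c])
                best = min(best, rmsd(ref - cref, rot.apply(mov - cmov)))
    return best


def scored(model, ids, coords, total):
    xyz = {pid: np.asarray(c, float) for pid, c in zip(ids, coords)}
    return ScoredConfiguration(asm.Configuration(xyz=xyz, frames={}), total, {})


@pytest.fixture
def point_cloud():
    rng = np.random.default_rng(8)
    return rng.uniform(-10, 10, (7, 3))


class TestKabsch:
    def test_identical_sets_give_zero(self, point_cloud):
        transform, value = kabsch_superpose(point_cloud, point_cloud)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert transform.angle_degrees == pytest.approx(0.0, abs=1e-6)

    def test_rotated_translated_copy_recovered(self, point_cloud):
        rng = np.random.default_rng(1)
        rot = Rotation.random(rng=rng)
        moved = rot.apply(point_cloud) + [12.0, -3.0, 44.0]
        transform, value = kabsch_superpose(point_cloud, moved)
        assert value < 1e-6
        assert np.allclose(transform.apply(moved), point_cloud, atol=1e-6)

    def test_matches_rotation_grid_oracle_on_distorted_square(self):
        # unit square with one corner pulled 1 unit outward along the diagonal
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        distorted = square.copy()
        distorted[2] += np.array([1, 1, 0]) / np.sqrt(2)
        _, value = kabsch_superpose(square, distorted)
        oracle = brute_force_min_rmsd(square, distorted)
        assert value <= oracle + 1e-9
        assert value == pytest.approx(oracle, abs=0.02)

    def test_superposed_never_worse_than_raw(self, point_cloud):
        rng = np.random.default_rng(3)
        noisy = point_cloud + rng.normal(0, 2, point_cloud.shape)
        _, fitted = kabsch_superpose(point_cloud, noisy)
        assert fitted <= rmsd(point_cloud, noisy) + 1e-12

    def test_collinear_input_flagged_translation_only(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 0, 0]], float)
        transform, _ = kabsch_superpose(line, line + [0, 3, 0])
        assert transform.degenerate
        assert transform.angle_degrees == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestTransform:
    def test_inverse_composes_to_identity(self):
        rng = np.random.default_rng(5)
        rot = Rotation.random(rng=rng)
        from assemblage.core import rotation_to_quaternion

        t = Transform(rotation_to_quaternion(rot), rng.uniform(-5, 5, 3))
        combo = t.compose(t.inverse())
        pts = rng.uniform(-10, 10, (4, 3))
        assert np.allclose(combo.apply(pts), pts, atol=1e-9)


class TestPlacementScore:
    def test_identity_placement(self, point_cloud):
        assert placement_score(point_cloud, point_cloud) == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_pure_translation(self, point_cloud):
        d, angle = placement_score(point_cloud, point_cloud + [3.0, 4.0, 0.0])
        assert d == pytest.approx(5.0)
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_half_turn_about_centroid(self, point_cloud):
        centroid = point_cloud.mean(axis=0)
        rot = Rotation.from_euler("z", 180, degrees=True)
        moved = rot.apply(point_cloud - centroid) + centroid
        d, angle = placement_score(point_cloud, moved)
        assert d == pytest.approx(0.0, abs=1e-9)
        assert angle == pytest.approx(180.0, abs=1e-6)


class TestClustering:
    @pytest.fixture
    def blob_ensemble(self):
        """Two groups of configurations with different internal shapes
        (rigid pre-alignment cannot merge them); jitter 0.5 Å."""
        rng = np.random.default_rng(2)
        ids = [f"p{i}" for i in range(4)]
        shape_a = rng.uniform(-5, 5, (4, 3))
        shape_b = shape_a.copy()
        shape_b[0] += np.array([50.0, 0.0, 0.0])  # one point pulled far out
        members, labels = [], []
        for g, base in enumerate((shape_a, shape_b)):
            for j in range(5):
                coords = base + rng.normal(0, 0.5, (4, 3))
                members.append(scored(None, ids, coords, total=float(g * 10 + j)))
                labels.append(g)
        return members, labels, ids

    def test_kmeans_recovers_separated_blobs(self, blob_ensemble):
        members, labels, ids = blob_ensemble
        clusters = cluster_ensemble(members, ids, method="kmeans", k=2, seed=0)
        got = clusters.assignment
        agreement = [g == l for g, l in zip(got, labels)]
        assert all(agreement) or not any(agreement)  # label permutation allowed

    def test_k_equal_one_single_cluster(self, blob_ensemble):
        members, _, ids = blob_ensemble
        clusters = cluster_ensemble(members, ids, method="kmeans", k=1, seed=0)
        assert clusters.n_clusters == 1

    def test_k_exceeding_ensemble_rejected(self, blob_ensemble):
        members, _, ids = blob_ensemble
        with pytest.raises(ValueError):
            cluster_ensemble(members[:3], ids, method="kmeans", k=5, seed=0)

    def test_binning_limit_cases(self, blob_ensemble):
        members, _, ids = blob_ensemble
        one = cluster_ensemble(members, ids, method="binning", rmsd_cutoff=1e6)
        assert one.n_clusters == 1
        # tiny cutoff: one cluster per distinct configuration
        many = cluster_ensemble(members, ids, method="binning", rmsd_cutoff=1e-9)
        assert many.n_clusters == len(members)

    def test_binning_members_within_cutoff_of_representative(self, blob_ensemble):
        members, _, ids = blob_ensemble
        cutoff = 5.0
        clusters = cluster_ensemble(members, ids, method="binning", rmsd_cutoff=cutoff)
        aligned = align_ensemble(members, ids)
        for i, lab in enumerate(clusters.assignment):
            rep = clusters.representatives[lab]
            assert rmsd(aligned[rep], aligned[i]) <= cutoff + 1e-9

    def test_binning_representative_is_lowest_score(self, blob_ensemble):
        members, _, ids = blob_ensemble
        clusters = cluster_ensemble(members, ids, method="binning", rmsd_cutoff=5.0)
        for lab, rep in clusters.representatives.items():
            in_cluster = [i for i, l in enumerate(clusters.assignment) if l == lab]
            assert members[rep].total == min(members[i].total for i in in_cluster)


class TestLocalizationDensity:
    def test_single_member_equals_member_density(self, small_model):
        spec = GridSpec((-40.0, -40.0, -40.0), 2.5, (33, 33, 33))
        member = scored(None, small_model.ids, small_model.coords(), 0.0)
        loc = localization_density([member], small_model, "P", spec, resolution=12.0)
        direct = simulate_density(
            list(small_model.particles.values()), 12.0, spec
        )
        assert np.array_equal(loc.values, direct.values)

    def test_symmetric_pair_gives_symmetric_map(self):
        m = asm.Model()
        m.create_particle("S.1", (10.0, 0, 0), 3.0, 200.0, subunit="S")
        spec = GridSpec((-40.0, -40.0, -40.0), 2.0, (41, 41, 41))
        a = scored(None, ["S.1"], [[10.0, 0, 0]], 0.0)
        b = scored(None, ["S.1"], [[-10.0, 0, 0]], 0.0)
        loc = localization_density([a, b], m, "S", spec, resolution=10.0)
        assert np.allclose(loc.values, loc.values[::-1, :, :], atol=1e-9)

    def test_integral_matches_subunit_mass(self, small_model):
        rng = np.random.default_rng(0)
        spec = GridSpec((-60.0, -60.0, -60.0), 2.5, (49, 49, 49))
        members = [
            scored(None, small_model.ids, small_model.coords() + rng.normal(0, 3, (5, 3)), float(i))
            for i in range(4)
        ]
        loc = localization_density(members, small_model, "P", spec, resolution=12.0)
        mass = small_model.masses().sum()
        assert loc.integral() == pytest.approx(mass, rel=0.01)

    def test_unknown_subunit_rejected(self, small_model):
        spec = GridSpec((-40.0, -40.0, -40.0), 2.0, (41, 41, 41))
        with pytest.raises(KeyError):
            localization_density(
                [scored(None, small_model.ids, small_model.coords(), 0.0)],
                small_model,
                "missing",
                spec,
                12.0,
            )


class TestSatisfaction:
    def test_noise_free_truth_satisfies_everything(self, two_particle_model):
        sf = asm.ScoringFunction(
            [
                asm.HarmonicDistanceRestraint("a", "b", d0=8.0, k=1.0, threshold=0.1),
                asm.ExcludedVolumeRestraint(k=1.0, threshold=0.1),
            ]
        )
        member = scored(None, two_particle_model.ids, two_particle_model.coords(), 0.0)
        report = satisfaction_report([member], two_particle_model, sf)
        assert not report.inconsistent
        assert report.models_all_satisfied.all()

    def test_contradictory_restraints_flag_inconsistency(self, two_particle_model):
        sf = asm.ScoringFunction(
            [
                asm.HarmonicDistanceRestraint("a", "b", d0=5.0, k=1.0, threshold=0.5, name="near"),
                asm.HarmonicDistanceRestraint("a", "b", d0=50.0, k=1.0, threshold=0.5, name="far"),
            ]
        )
        rng = np.random.default_rng(0)
        members = [
            scored(None, two_particle_model.ids,
                   [[0, 0, 0], [float(d), 0, 0]], float(i))
            for i, d in enumerate(rng.uniform(1, 60, 8))
        ]
        report = satisfaction_report(members, two_particle_model, sf)
        assert report.inconsistent
        assert not report.models_all_satisfied.any()

    def test_fractions_monotone_in_threshold(self, two_particle_model):
        members = [
            scored(None, two_particle_model.ids, [[0, 0, 0], [float(d), 0, 0]], float(i))
            for i, d in enumerate((6.0, 8.0, 10.0, 14.0))
        ]
        fracs = []
        for threshold in (10.0, 1.0, 0.1):
            sf = asm.ScoringFunction(
                [asm.HarmonicDistanceRestraint("a", "b", d0=8.0, k=1.0, threshold=threshold)]
            )
            report = satisfaction_report(members, two_particle_model, sf)
            frac = report.fraction_satisfied["dist:a-b"]
            assert 0.0 <= frac <= 1.0
            fracs.append(frac)
        assert fracs == sorted(fracs, reverse=True)
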