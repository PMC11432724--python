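"""Tests for superposition, RMSD, TM-score, classification and densities."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import alloscan as al


def random_cloud(n, seed):
    return np.random.default_rng(seed).normal(scale=4.0, size=(n, 3))


def rigid_copy(coords, seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    return coords @ rot.T + rng.normal(scale=10.0, size=3)


def brute_force_min_rmsd(mobile, reference, n_starts=200, seed=0):
    """Independent oracle: global search over rotations + local refinement.

    The optimal translation for any fixed rotation aligns the centroids, so
    the search space is SO(3), parametrized by rotation vectors.
    """
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((x @ r.T - y) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    starts = Rotation.random(n_starts, rng=rng).as_rotvec()
    best = np.inf
    for s in sorted(starts, key=cost)[:5]:
        res = minimize(cost, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_rigid_copy_recovers_zero_rmsd(self):
        ref = random_cloud(30, 1)
        sup = al.superpose(rigid_copy(ref, 2), ref)
        assert sup.rmsd < 1e-6
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_identity_input(self):
        ref = random_cloud(12, 3)
        sup = al.superpose(ref, ref)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(sup.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_global_search_oracle(self, seed):
        mobile = random_cloud(10, seed + 100)
        reference = random_cloud(10, seed + 200)
        ours = al.superpose(mobile, reference).rmsd
        oracle = brute_force_min_rmsd(mobile, reference, seed=seed)
        assert ours == pytest.approx(oracle, abs=1e-4)
        assert ours <= oracle + 1e-9  # ours is the true optimum

    def test_too_few_or_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            al.superpose(line, line)
        two = random_cloud(2, 0)
        with pytest.raises(ValueError, match="at least 3"):
            al.superpose(two, two)


class TestRmsdProfile:
    def test_copies_of_reference_give_zero(self, small_refs):
        ref = small_refs["active"]
        copies = al.ConformationalEnsemble(
            ref.residue_ids, np.repeat(ref.coords[:1], 5, axis=0)
        )
        assert al.rmsd_profile(copies, ref) == pytest.approx(np.zeros(5), abs=1e-9)

    def test_symmetry_after_mutual_superposition(self):
        a, b = random_cloud(25, 4), random_cloud(25, 5)
        assert al.rmsd(a, b) == pytest.approx(al.rmsd(b, a), abs=1e-9)

    def test_loop_restricted_rmsd_exceeds_whole_chain(self):
        states = al.generate_reference_states(
            n_residues=80, loop_span=(30, 45), n_models=3, noise_sd=0.0, seed=6
        )
        active, i2 = states["active"].ensemble, states["I2"].ensemble
        whole = al.rmsd_profile(i2, active)
        loop = al.rmsd_profile(i2, active, report_residues=(30, 45))
        assert np.all(loop >= whole)

    def test_empty_report_interval_rejected(self, small_refs):
        with pytest.raises(ValueError, match="no residues"):
            al.rmsd_profile(small_refs["I1"], small_refs["active"], report_residues=(900, 950))


class TestTMScore:
    def test_identical_structures_score_one(self):
        coords = al.helix_backbone(60)[1]
        score, same_fold = al.tm_score(coords, coords)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert same_fold

    def test_small_perturbation_scores_high_and_matches_formula(self):
        coords = al.helix_backbone(80)[1]
        noisy = coords + np.random.default_rng(7).normal(0, 0.1, coords.shape)
        score, _ = al.tm_score(noisy, coords)
        assert score > 0.99
        # direct formula evaluated at the whole-chain least-squares fit is a
        # lower bound on the optimized score
        sup = al.superpose(noisy, coords)
        d = np.linalg.norm(sup.apply(noisy) - coords, axis=1)
        d0 = max(0.5, 1.24 * np.cbrt(80 - 15) - 1.8)
        direct = np.mean(1.0 / (1.0 + (d / d0) ** 2))
        assert score >= direct - 1e-9
        assert score == pytest.approx(direct, abs=1e-3)

    def test_rigid_invariance(self):
        coords = al.helix_backbone(50)[1]
        other = coords + np.random.default_rng(8).normal(0, 1.5, coords.shape)
        s1, _ = al.tm_score(other, coords)
        s2, _ = al.tm_score(rigid_copy(other, 9), coords)
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_score_in_unit_interval(self):
        a = random_cloud(30, 10) * 3
        b = random_cloud(30, 11) * 3
        score, _ = al.tm_score(a, b)
        assert 0.0 < score <= 1.0


class TestClassification:
    def test_reference_copy_maps_to_its_state(self, small_refs):
        model = al.ConformationalEnsemble(
            small_refs["active"].residue_ids, small_refs["active"].coords[:1]
        )
        cls = al.classify_states(model, small_refs)
        assert cls.labels == ["active"]
        assert cls.rmsd_table.loc[0, "active"] == pytest.approx(0.0, abs=1e-9)

    def test_threshold_zero_leaves_all_unassigned(self, small_refs, small_states):
        spec = al.MixtureSpec(populations={"active": 1.0}, n_models=8, noise_sd=0.3, seed=1)
        mix, _ = al.generate_mixture_ensemble(spec, small_states)
        cls = al.classify_states(mix, small_refs, rmsd_threshold=0.0)
        assert cls.labels == ["unassigned"] * 8

    def test_populations_sum_to_one(self, small_refs, small_states):
        spec = al.MixtureSpec(
            populations={"I2": 0.5, "I1": 0.3, "active": 0.2}, n_models=60, seed=2
        )
        mix, _ = al.generate_mixture_ensemble(spec, small_states)
        cls = al.classify_states(mix, small_refs)
        assert sum(cls.populations.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mixture_fraction_recovery(self, small_refs, small_states):
        pops = {"I2": 0.82, "I1": 0.10, "active": 0.08}
        spec = al.MixtureSpec(populations=pops, n_models=500, noise_sd=0.3, seed=13)
        mix, truth = al.generate_mixture_ensemble(spec, small_states)
        cls = al.classify_states(mix, small_refs)
        assert cls.labels == truth  # separation >> noise: perfect recovery

    def test_missing_reference_rejected(self, small_refs):
        with pytest.raises(ValueError, match="no reference"):
            al.classify_states(small_refs["active"], {})


class TestDensitySummary:
    def test_standard_normal_density_at_zero(self):
        x = np.random.default_rng(123).normal(size=10000)
        grid, dens = al.density_summary(x)
        assert dens[np.argmin(np.abs(grid))] == pytest.approx(0.3989, abs=0.05)

    def test_integrates_to_one(self):
        x = np.random.default_rng(5).gamma(3.0, size=2000)
        grid, dens = al.density_summary(x)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_two_modes_recovered_at_planted_locations(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-2, 0.3, 4000), rng.normal(2, 0.3, 4000)])
        grid, dens = al.density_summary(x)
        local_max = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])) + 1
        modes = grid[local_max[np.argsort(dens[local_max])[-2:]]]
        assert sorted(np.round(modes, 1)) == pytest.approx([-2.0, 2.0], abs=0.1)

    def test_degenerate_sample_gives_delta_like_output(self):
        grid, dens = al.density_summary(np.full(10, 3.5))
        assert dens.max() > 0
        assert grid[np.argmax(dens)] == pytest.approx(3.5, abs=0.02)
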