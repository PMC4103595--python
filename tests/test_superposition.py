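import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexbench import kabsch, rmsf_profile, superpose_ensemble
from flexbench.structures import Conformer, Ensemble, ResidueKey

from conftest import random_points


def horn_quaternion_rotation(mobile, target, weights=None):
    """Independent oracle: optimal proper rotation via Horn's quaternion
    eigenvalue method (largest eigenvector of the 4x4 Davenport matrix)."""
    n = mobile.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    cm = (w[:, None] * mobile).sum(0) / w.sum()
    ct = (w[:, None] * target).sum(0) / w.sum()
    A = mobile - cm
    B = target - ct
    S = (w[:, None] * A).T @ B
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    evals, evecs = np.linalg.eigh(K)
    qw, qx, qy, qz = evecs[:, -1]
    return Rotation.from_quat([qx, qy, qz, qw]).as_matrix()


def residual(transform, mobile, target, weights=None):
    d = transform.apply(mobile) - target
    w = np.ones(len(mobile)) if weights is None else weights
    return float(np.sum(w * np.sum(d * d, axis=1)))


class TestKabsch:
    def test_identity_on_equal_point_sets(self):
        pts = random_points(6, seed=1)
        T = kabsch(pts, pts)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-10)

    def test_recovers_known_rotation_and_translation(self):
        pts = random_points(8, seed=2)
        R_true = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = pts @ R_true.T + np.array([1.0, 2.0, 3.0])
        T = kabsch(pts, target)
        np.testing.assert_allclose(T.rotation, R_true, atol=1e-8)
        np.testing.assert_allclose(T.translation, [1, 2, 3], atol=1e-8)
        assert residual(T, pts, target) < 1e-16

    @pytest.mark.parametrize("n,seed", [(4, 3), (6, 4), (8, 5)])
    def test_matches_quaternion_oracle_on_noisy_pairs(self, n, seed):
        rng = np.random.default_rng(seed)
        mobile = random_points(n, seed=seed)
        R_true = Rotation.random(random_state=seed).as_matrix()
        target = mobile @ R_true.T + rng.normal(scale=0.5, size=(n, 3))
        T = kabsch(mobile, target)
        R_oracle = horn_quaternion_rotation(mobile, target)
        np.testing.assert_allclose(T.rotation, R_oracle, atol=1e-8)

    def test_weighted_fit_matches_weighted_oracle(self):
        rng = np.random.default_rng(11)
        mobile = random_points(7, seed=11)
        target = mobile @ Rotation.random(random_state=1).as_matrix().T
        target += rng.normal(scale=1.0, size=(7, 3))
        w = rng.uniform(0.1, 2.0, size=7)
        T = kabsch(mobile, target, weights=w)
        R_oracle = horn_quaternion_rotation(mobile, target, weights=w)
        np.testing.assert_allclose(T.rotation, R_oracle, atol=1e-8)

    def test_mirror_image_yields_proper_rotation(self):
        pts = random_points(8, seed=6)
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        T = kabsch(pts, mirrored)
        assert T.is_proper()
        res = residual(T, pts, mirrored)
        assert res > 1e-3
        # no sampled proper rotation may beat the returned one
        best = np.inf
        for R in Rotation.random(4000, random_state=0).as_matrix():
            rot = pts @ R.T
            t = mirrored.mean(0) - rot.mean(0)
            best = min(best, float(np.sum((rot + t - mirrored) ** 2)))
        assert res <= best + 1e-9

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="underdetermined"):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line)
        pts = random_points(5, seed=7)
        with pytest.raises(ValueError):
            kabsch(pts, pts, weights=np.zeros(5))


def _rigid_copies(n_models, n_res, seed):
    rng = np.random.default_rng(seed)
    base = random_points(n_res, seed=seed)
    residues = tuple(ResidueKey("A", i + 1, "", "ALA") for i in range(n_res))
    confs = []
    for j in range(n_models):
        R = Rotation.random(random_state=seed + j).as_matrix()
        t = rng.uniform(-20, 20, 3)
        confs.append(Conformer(j + 1, base @ R.T + t, residues))
    return Ensemble(confs)


class TestSuperposeEnsemble:
    def test_rigid_motion_only_ensemble_collapses(self):
        res = superpose_ensemble(_rigid_copies(6, 25, seed=9), mode="uniform")
        X = res.ensemble.coords_array()
        for j in range(1, X.shape[0]):
            rmsd = np.sqrt(np.mean(np.sum((X[j] - X[0]) ** 2, axis=1)))
            assert rmsd < 1e-6

    def test_two_model_mean_is_midpoint(self):
        rng = np.random.default_rng(10)
        base = random_points(12, seed=10)
        residues = tuple(ResidueKey("A", i + 1, "", "ALA") for i in range(12))
        other = base + rng.normal(scale=0.5, size=base.shape)
        ens = Ensemble([Conformer(1, base, residues), Conformer(2, other, residues)])
        res = superpose_ensemble(ens, mode="uniform")
        X = res.ensemble.coords_array()
        np.testing.assert_allclose(res.mean_structure, X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            res.mean_structure, 0.5 * (X[0] + X[1]), atol=1e-12
        )

    def test_uniform_residual_history_non_increasing(self, helix_ensemble):
        ensemble, _ = helix_ensemble
        res = superpose_ensemble(ensemble, mode="uniform")
        hist = res.residual_history
        assert len(hist) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_global_rigid_transform_leaves_rmsf_invariant(self, helix_ensemble):
        ensemble, _ = helix_ensemble
        prof0 = rmsf_profile(superpose_ensemble(ensemble))
        R = Rotation.from_euler("xyz", [30, -60, 45], degrees=True).as_matrix()
        t = np.array([5.0, -8.0, 2.5])
        moved = Ensemble(
            [
                Conformer(c.model_id, c.coords @ R.T + t, c.residues)
                for c in ensemble.conformers
            ]
        )
        prof1 = rmsf_profile(superpose_ensemble(moved))
        np.testing.assert_allclose(prof0.rmsf, prof1.rmsf, atol=1e-6)

    def test_inverse_variance_recovers_oracle_under_jitter(self, helix_ensemble):
        ensemble, oracle = helix_ensemble
        prof = rmsf_profile(superpose_ensemble(ensemble, mode="inverse_variance"))
        interior = slice(5, -5)
        ratio = prof.rmsf[interior] / oracle.rmsf[interior]
        assert np.all(np.abs(ratio - 1.0) < 0.12)

    def test_single_model_is_an_error(self):
        ens = _rigid_copies(1, 10, seed=3)
        with pytest.raises(ValueError, match="nothing to superpose"):
            superpose_ensemble(ens)

    def test_weights_are_normalized(self, helix_ensemble):
        ensemble, _ = helix_ensemble
        res = superpose_ensemble(ensemble, mode="inverse_variance")
        assert res.weights.sum() == pytest.approx(ensemble.n_residues)
        assert np.all(res.weights >= 0)
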