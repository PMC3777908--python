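"""PCA, projections, PLS-FMA fitting and mode algebra."""

import numpy as np
import pytest

import tqcoupling as tq
from tqcoupling.errors import ConfigError, DataError


class TestPCA:
    def test_two_frames_give_one_nonzero_eigenvalue(self):
        x = np.array([[0.0, 0, 0, 0, 0, 0], [1.0, 1, 0, 0, 0, 0]])
        res = tq.pca(x)
        nz = np.sum(res.eigenvalues > 1e-12 * res.eigenvalues[0])
        assert nz == 1

    def test_eigenvalues_sum_to_total_variance(self, ensemble_system):
        res = ensemble_system["pca"]
        x = ensemble_system["qfit"].flat
        total = ((x - x.mean(axis=0)) ** 2).sum() / (x.shape[0] - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-9)
        assert res.explained_fraction.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_eigenvectors_orthonormal(self, ensemble_system):
        v = ensemble_system["pca"].eigenvectors[:20]
        assert np.abs(v @ v.T - np.eye(20)).max() < 1e-8

    def test_recovers_planted_quaternary_mode(self, ensemble_system):
        cq = ensemble_system["cq"]
        planted = ensemble_system["truths"][0].quaternary_mode_direction
        assert abs(cq.vector @ planted) >= 0.99

    def test_single_frame_raises(self):
        with pytest.raises(DataError):
            tq.pca(np.zeros((1, 6)))


class TestProjection:
    def test_origin_projects_to_zero_and_offsets_scale(self, small_system):
        ref = small_system["ref"]
        vec = np.zeros(3 * ref.n_atoms)
        vec[2] = 1.0
        mode = tq.CollectiveMode(vec, origin=ref.flat)
        assert tq.project(ref, mode).values[0] == pytest.approx(0.0, abs=1e-12)
        shifted = ref.with_coords((ref.flat + 0.5 * mode.vector).reshape(-1, 3))
        assert tq.project(shifted, mode).values[0] == pytest.approx(0.5, abs=1e-12)

    def test_projection_is_linear(self, small_system):
        traj = small_system["traj"]
        ref = small_system["ref"]
        rng = np.random.default_rng(0)
        mode = tq.CollectiveMode(rng.normal(size=3 * ref.n_atoms), origin=ref.flat)
        a = traj.coords
        b = traj.coords[::-1]
        mid = tq.Trajectory(coords=(a + b) / 2, atoms=traj.atoms, partition=traj.partition)
        pa = tq.project(traj, mode).values
        pb = tq.project(
            tq.Trajectory(coords=b, atoms=traj.atoms, partition=traj.partition), mode
        ).values
        pm = tq.project(mid, mode).values
        assert np.abs(pm - (pa + pb) / 2).max() < 1e-9

    def test_dimension_mismatch_raises(self, small_system):
        mode = tq.CollectiveMode(np.ones(9))
        with pytest.raises(DataError):
            tq.project(small_system["traj"], mode)


class TestPearsonAndOverlap:
    @pytest.mark.parametrize(
        "a,b,expect",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
        ],
    )
    def test_exact_linear_series(self, a, b, expect):
        assert tq.pearson(a, b) == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DataError):
            tq.pearson([1, 1, 1], [1, 2, 3])

    def test_overlap_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        m1 = tq.CollectiveMode(rng.normal(size=30))
        m2 = tq.CollectiveMode(rng.normal(size=30))
        assert tq.mode_overlap(m1, m2) == tq.mode_overlap(m2, m1)
        assert 0 <= tq.mode_overlap(m1, m2) <= 1
        assert tq.mode_overlap(m1, m1) == pytest.approx(1.0, abs=1e-12)
        e1 = tq.CollectiveMode(np.eye(30)[0])
        e2 = tq.CollectiveMode(np.eye(30)[1])
        assert tq.mode_overlap(e1, e2) == 0.0


class TestPLSFMA:
    def test_exact_linear_target_recovered_with_one_component(self):
        # target = exact projection on a covariance eigendirection: a single
        # latent vector reproduces it perfectly
        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 30)) * np.linspace(2.0, 0.5, 30)
        xt = x[:150]  # model half: the latent vector is fit on these frames
        direction = np.linalg.svd(xt - xt.mean(axis=0), full_matrices=False)[2][0]
        y = x @ direction
        model = tq.pls_fma(x, y, n_components=1)
        assert model.fit_r == pytest.approx(1.0, abs=1e-9)
        assert abs(model.mode_cT.vector @ direction) >= 0.999

    def test_exact_linear_target_recovered_at_full_rank(self):
        # generic direction: with enough latent vectors the fit converges to
        # the exact least-squares solution
        rng = np.random.default_rng(1)
        x = rng.normal(size=(300, 20))
        direction = rng.normal(size=20)
        direction /= np.linalg.norm(direction)
        y = x @ direction
        model = tq.pls_fma(x, y, n_components=20)
        assert model.fit_r == pytest.approx(1.0, abs=1e-9)
        assert abs(model.mode_cT.vector @ direction) >= 0.999

    def test_permuted_target_has_no_predictive_power(self, ensemble_system):
        tert = ensemble_system["dec"].tertiary
        y = ensemble_system["target"].values
        rng = np.random.default_rng(42)
        cvs = [
            tq.pls_fma(tert, rng.permutation(y), n_components=3).cv_r
            for _ in range(5)
        ]
        assert np.max(np.abs(cvs)) < 0.2

    def test_planted_coupling_recovery(self, ensemble_system):
        model = ensemble_system["model"]
        planted = ensemble_system["truths"][0].tertiary_mode_direction
        assert model.cv_r >= 0.9
        assert abs(model.mode_cT.vector @ planted) >= 0.95

    def test_training_correlation_nondecreasing_in_components(self, ensemble_system):
        tert = ensemble_system["dec"].tertiary
        y = ensemble_system["target"]
        fits = [tq.pls_fma(tert, y, k).fit_r for k in range(1, 6)]
        assert np.all(np.diff(fits) >= -1e-9)

    def test_ct_lies_in_tertiary_subspace(self, ensemble_system):
        basis = tq.chain_rigid_basis(ensemble_system["ref"])
        ct = ensemble_system["model"].mode_cT
        assert np.abs(basis @ ct.vector).max() < 1e-6

    def test_constant_target_raises(self, small_system):
        with pytest.raises(DataError):
            tq.pls_fma(small_system["traj"], np.ones(small_system["traj"].n_frames), 1)

    def test_too_many_components_raises(self):
        x = np.random.default_rng(0).normal(size=(10, 6))
        with pytest.raises(ConfigError):
            tq.pls_fma(x, x[:, 0], n_components=5)  # 5 > 10*0.5 - 1


class TestSelectComponents:
    def test_recovers_planted_dimensionality(self):
        # three predictive internal modes + nuisance variance + noise
        rng = np.random.default_rng(3)
        n, p = 2000, 40
        modes = np.linalg.qr(rng.normal(size=(p, 8)))[0].T
        amps = rng.normal(size=(n, 8))
        x = amps @ modes + 0.05 * rng.normal(size=(n, p))
        y = amps[:, :3] @ [1.0, 0.8, 0.6] + 0.1 * rng.normal(size=n)
        k_best, curve = tq.select_components(x, y, k_max=8)
        assert len(curve) == 8
        assert k_best <= 5  # 3 planted + tolerance 2

    def test_pure_noise_target_never_validates(self, ensemble_system):
        tert = ensemble_system["dec"].tertiary
        rng = np.random.default_rng(7)
        y = rng.permutation(ensemble_system["target"].values)
        _, curve = tq.select_components(tert, y, k_max=6)
        assert np.max(np.abs(curve)) < 0.3


class TestEnsembleWeight:
    def test_single_latent_vector_equals_ct(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 20))
        y = x @ rng.normal(size=20)
        model = tq.pls_fma(x, y, n_components=1)
        ctew = tq.ensemble_weight(model)
        assert tq.mode_overlap(ctew, model.mode_cT) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_scores_leave_direction_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(500, 12))
        y = x @ rng.normal(size=12)
        model = tq.pls_fma(x, y, n_components=3)
        # force equal variances: the reweighted sum is then proportional to
        # the plain coefficient combination, i.e. cT
        model.score_variances = np.ones_like(model.score_variances)
        ctew = tq.ensemble_weight(model)
        assert tq.mode_overlap(ctew, model.mode_cT) == pytest.approx(1.0, abs=1e-9)

    def test_ctew_projection_correlates_with_target(self, ensemble_system):
        ctew = ensemble_system["model"].mode_cTew
        tert = ensemble_system["dec"].tertiary
        proj = tq.project(tert, ctew).values
        y = ensemble_system["target"].values
        assert tq.pearson(proj, y) > 0
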