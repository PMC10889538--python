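"""Cartesian PCA, projections, porcupine vectors, cross-correlation."""

import numpy as np
import pytest

from dynasome.core import Ensemble
from dynasome.motions import (
    PCAModel,
    _fit_to_average,
    cross_correlation,
    mode_displacements,
    pca,
    project,
    residue_correlation_profile,
)

from conftest import point_topology


def _rank1_ensemble(n_frames=50, n_atoms=12, seed=0):
    """Frames displaced along a single fixed direction."""
    rng = np.random.default_rng(seed)
    topo = point_topology(n_atoms)
    base = rng.normal(0, 5, (n_atoms, 3))
    direction = rng.normal(0, 1, (n_atoms, 3))
    direction /= np.linalg.norm(direction)
    amps = rng.normal(0, 2.0, n_frames)
    coords = base[None] + amps[:, None, None] * direction[None]
    return Ensemble(topo, coords)


class TestPCA:
    def test_rank1_data_pc1_explains_everything(self):
        """Pre-fitted frames displaced along one fixed direction are
        exactly rank 1."""
        model = pca(_rank1_ensemble(), fit=False)
        assert model.explained_variance[0] >= 1 - 1e-8

    def test_rank1_data_dominant_after_fitting(self):
        model = pca(_rank1_ensemble())
        assert model.explained_variance[0] >= 0.999

    def test_eigenvalue_sum_equals_total_fitted_variance(self, random_ensemble):
        """Trace identity: Σ λ_k equals the total fluctuation variance
        Σ_i RMSF_i² on the same fitted coordinates (both with the
        F−1 sampling convention)."""
        model = pca(random_ensemble)
        fitted, mean = _fit_to_average(random_ensemble.coordinates)
        n = len(fitted)
        rmsf_sq = np.sum((fitted - mean) ** 2, axis=(0, 2)) / (n - 1)
        assert model.eigenvalues.sum() == pytest.approx(
            rmsf_sq.sum(), rel=1e-6
        )

    def test_matches_dense_eigensolver(self):
        """SVD route against an explicit covariance-matrix
        eigendecomposition on a 30-atom, 200-frame toy."""
        rng = np.random.default_rng(1)
        topo = point_topology(30)
        base = rng.normal(0, 5, (30, 3))
        coords = base[None] + rng.normal(0, 0.5, (200, 30, 3))
        ens = Ensemble(topo, coords)
        model = pca(ens)
        fitted, mean = _fit_to_average(ens.coordinates)
        X = (fitted - mean[None]).reshape(200, -1)
        cov = X.T @ X / (200 - 1)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            model.eigenvalues, ev[: model.n_modes], rtol=1e-8, atol=1e-10
        )

    def test_modes_orthonormal(self, random_ensemble):
        model = pca(random_ensemble)
        gram = model.modes @ model.modes.T
        np.testing.assert_allclose(gram, np.eye(model.n_modes), atol=1e-8)

    def test_explained_variance_invariant_under_rigid_rotation(self):
        from scipy.spatial.transform import Rotation

        ens = _rank1_ensemble(seed=2)
        R = Rotation.from_euler("zyx", [15, 40, 70], degrees=True).as_matrix()
        rotated = Ensemble(ens.topology, ens.coordinates @ R.T)
        m1, m2 = pca(ens), pca(rotated)
        np.testing.assert_allclose(
            m1.explained_variance[:5], m2.explained_variance[:5], atol=1e-8
        )

    def test_reconstruction_with_all_modes(self, random_ensemble):
        model = pca(random_ensemble)
        fitted, mean = _fit_to_average(random_ensemble.coordinates)
        X = (fitted - mean[None]).reshape(len(fitted), -1)
        coeff = X @ model.modes.T
        back = coeff @ model.modes
        np.testing.assert_allclose(back, X, atol=1e-6)

    def test_too_few_frames_rejected(self):
        topo = point_topology(5)
        ens = Ensemble(topo, np.zeros((1, 5, 3)))
        with pytest.raises(ValueError):
            pca(ens)


class TestProjection:
    def test_mean_structure_projects_to_zero(self, random_ensemble):
        model = pca(random_ensemble)
        mean_ens = Ensemble(random_ensemble.topology, model.mean[None].repeat(2, 0))
        proj = project(mean_ens, model)
        np.testing.assert_allclose(proj, 0.0, atol=1e-8)

    def test_pc1_projection_variance_equals_eigenvalue(self, random_ensemble):
        model = pca(random_ensemble)
        proj = project(random_ensemble, model, n_modes=1)
        assert np.var(proj[:, 0], ddof=1) == pytest.approx(
            model.eigenvalues[0], rel=1e-8
        )

    def test_source_labels_recoverable(self):
        ens = _rank1_ensemble(n_frames=20, seed=3)
        labels = ["WT"] * 10 + ["A41S"] * 10
        ens2 = Ensemble(ens.topology, ens.coordinates, source_labels=labels)
        model = pca(ens2)
        proj = project(ens2, model)
        assert proj.shape[0] == 20
        assert np.sum(ens2.source_labels == "WT") == 10


class TestModeDisplacements:
    def test_unit_mode_arrow_length_is_sqrt_eigenvalue(self):
        """Hand-built model: mode e_x on atom 0 with λ = 9 gives a
        single 3 Å arrow."""
        n_atoms = 8
        mode = np.zeros(3 * n_atoms)
        mode[0] = 1.0
        model = PCAModel(
            selection=np.arange(n_atoms),
            mean=np.zeros((n_atoms, 3)),
            modes=mode[None],
            eigenvalues=np.array([9.0]),
            explained_variance=np.array([1.0]),
            cumulative_variance=np.array([1.0]),
        )
        arrows, amplitudes, exported = mode_displacements(model, 0, 2.0)
        assert list(exported) == [0]
        assert amplitudes[0] == pytest.approx(3.0, abs=1e-9)

    def test_zero_threshold_exports_all(self, random_ensemble):
        model = pca(random_ensemble)
        _, _, exported = mode_displacements(model, 0, 0.0)
        assert len(exported) == random_ensemble.n_atoms

    def test_unreachable_threshold_exports_none(self, random_ensemble):
        model = pca(random_ensemble)
        _, amps, exported = mode_displacements(model, 0, amps_max := 1e9)
        assert len(exported) == 0

    def test_invalid_mode_rejected(self, random_ensemble):
        model = pca(random_ensemble)
        with pytest.raises(ValueError):
            mode_displacements(model, model.n_modes + 5)


class TestCrossCorrelation:
    def test_unit_diagonal(self, random_ensemble):
        corr = cross_correlation(
            random_ensemble, np.arange(random_ensemble.n_atoms), fit=False
        )
        np.testing.assert_allclose(np.diag(corr.values), 1.0, atol=1e-12)

    def test_identical_and_mirrored_displacements(self):
        rng = np.random.default_rng(5)
        topo = point_topology(4)
        base = rng.normal(0, 20, (4, 3))
        disp = rng.normal(0, 1, (60, 3))
        coords = np.repeat(base[None], 60, axis=0)
        coords[:, 0] += disp
        coords[:, 1] += disp  # identical motion
        coords[:, 2] -= disp  # mirrored motion
        ens = Ensemble(topo, coords)
        corr = cross_correlation(ens, np.arange(4), fit=False)
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-8)
        assert corr.values[0, 2] == pytest.approx(-1.0, abs=1e-8)

    def test_independent_jitter_near_zero(self):
        rng = np.random.default_rng(6)
        topo = point_topology(20)
        coords = rng.normal(0, 1, (10_000, 20, 3)) + rng.normal(
            0, 30, (20, 3)
        )
        ens = Ensemble(topo, coords)
        corr = cross_correlation(ens, np.arange(20), fit=False)
        off = corr.values[~np.eye(20, dtype=bool)]
        assert np.mean(np.abs(off) <= 0.05) >= 0.99

    def test_positive_semidefinite(self, random_ensemble):
        corr = cross_correlation(random_ensemble, np.arange(20), fit=False)
        ev = np.linalg.eigvalsh(corr.values)
        assert ev.min() >= -1e-8

    def test_zero_variance_atom_handled(self):
        rng = np.random.default_rng(7)
        topo = point_topology(5)
        coords = np.repeat(rng.normal(0, 5, (5, 3))[None], 30, axis=0)
        coords[:, :4] += rng.normal(0, 0.5, (30, 4, 3))  # atom 4 frozen
        ens = Ensemble(topo, coords)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = cross_correlation(ens, np.arange(5), fit=False)
        assert corr.values[4, 4] == 1.0
        np.testing.assert_allclose(corr.values[4, :4], 0.0, atol=1e-12)


class TestResidueProfile:
    def test_row_extraction_and_self_correlation(self, random_ensemble):
        corr = cross_correlation(random_ensemble, np.arange(20), fit=False)
        row = residue_correlation_profile(corr, residue=3)
        np.testing.assert_array_equal(row, corr.values[2])
        assert row[2] == 1.0

    def test_rigid_block_profile_near_one(self):
        rng = np.random.default_rng(8)
        topo = point_topology(6)
        base = rng.normal(0, 10, (6, 3))
        disp = rng.normal(0, 1, (80, 3))
        coords = np.repeat(base[None], 80, axis=0)
        coords[:, :3] += disp[:, None, :]  # rigid sub-block
        coords[:, 3:] += rng.normal(0, 1, (80, 3, 3))
        ens = Ensemble(topo, coords)
        corr = cross_correlation(ens, np.arange(6), fit=False)
        row = residue_correlation_profile(corr, residue=1)
        np.testing.assert_allclose(row[:3], 1.0, atol=1e-8)

    def test_out_of_range_rejected(self, random_ensemble):
        corr = cross_correlation(random_ensemble, np.arange(20), fit=False)
        with pytest.raises(ValueError):
            residue_correlation_profile(corr, residue=99)
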