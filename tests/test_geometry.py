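"""Superposition, RMSD/RMSF/Rg and density profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dynasome.core import Conformation, Ensemble, Topology
from dynasome.geometry import (
    density_profile,
    extend_axis_for_display,
    fit_ensemble,
    helix_axis_drift,
    radius_of_gyration,
    rmsd_series,
    rmsd_value,
    rmsf,
    superpose,
)
from dynasome.synthetic import build_ideal_helix

from conftest import grid_search_rmsd, point_topology


def _conf(topo, xyz):
    return Conformation(topo, xyz)


class TestSuperpose:
    def test_identity(self):
        topo = point_topology(6)
        xyz = np.random.default_rng(0).normal(0, 3, (6, 3))
        res, fitted = superpose(_conf(topo, xyz), _conf(topo, xyz))
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_translation_invariance(self):
        topo = point_topology(6)
        xyz = np.random.default_rng(1).normal(0, 3, (6, 3))
        res, _ = superpose(_conf(topo, xyz), _conf(topo, xyz + [5.0, 0, 0]))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        topo = point_topology(5)
        a = rng.normal(0, 3, (5, 3))
        b = rng.normal(0, 3, (5, 3))
        res, _ = superpose(_conf(topo, a), _conf(topo, b))
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-8)

    def test_matches_rotation_grid_oracle(self):
        """The analytic fit must agree with a brute-force rotation-grid
        search on small random structures."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            topo = point_topology(n)
            ref = rng.normal(0, 3, (n, 3))
            R = Rotation.random(random_state=int(rng.integers(1 << 16))).as_matrix()
            mob = ref @ R.T + rng.normal(0, 0.3, (n, 3))
            res, _ = superpose(_conf(topo, mob), _conf(topo, ref))
            oracle = grid_search_rmsd(mob, ref)
            assert res.rmsd <= oracle + 1e-9  # analytic is the true minimum
            assert abs(res.rmsd - oracle) <= 1e-2

    def test_too_few_atoms_rejected(self):
        topo = point_topology(2)
        xyz = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            superpose(_conf(topo, xyz), _conf(topo, xyz))

    def test_collinear_selection_rejected(self):
        topo = point_topology(4)
        xyz = np.array([[float(i), 0, 0] for i in range(4)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(_conf(topo, xyz), _conf(topo, xyz))

    def test_fitted_rmsd_never_exceeds_unfitted(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(0, 3, (8, 3))
            b = rng.normal(0, 3, (8, 3))
            assert rmsd_value(a, b, fit=True) <= rmsd_value(a, b, fit=False) + 1e-12


class TestRMSDSeries:
    def test_reference_frame_is_zero(self, random_ensemble):
        vals = rmsd_series(random_ensemble, random_ensemble.frame(4))
        assert vals[4] == pytest.approx(0.0, abs=1e-10)

    def test_random_rotations_all_zero(self):
        rng = np.random.default_rng(5)
        topo = point_topology(10)
        base = rng.normal(0, 4, (10, 3))
        frames = np.stack(
            [
                base @ Rotation.random(random_state=k).as_matrix().T + rng.normal(0, 9, 3)
                for k in range(8)
            ]
        )
        ens = Ensemble(topo, frames)
        vals = rmsd_series(ens, Conformation(topo, base))
        np.testing.assert_allclose(vals, 0.0, atol=1e-8)

    def test_two_well_bimodality(self):
        rng = np.random.default_rng(6)
        topo = point_topology(30)
        base = rng.normal(0, 5, (30, 3))
        shifted = base + np.array([6.0, 0, 0])  # uniform 6 Å translation
        frames = np.stack([base + rng.normal(0, 0.05, (30, 3)) for _ in range(40)]
                          + [shifted + rng.normal(0, 0.05, (30, 3)) for _ in range(40)])
        ens = Ensemble(topo, frames)
        # no-fit distance to base separates the wells at 0 and 6 Å
        d = np.array([rmsd_value(f, base, fit=False) for f in frames])
        assert np.all(d[:40] < 1.0) and np.all(np.abs(d[40:] - 6.0) < 1.0)

    def test_pseudometric_on_random_triples(self):
        rng = np.random.default_rng(8)
        for _ in range(15):
            a, b, c = rng.normal(0, 3, (3, 7, 3))
            dab = rmsd_value(a, b)
            dba = rmsd_value(b, a)
            assert dab == pytest.approx(dba, abs=1e-8)
            assert dab <= rmsd_value(a, c) + rmsd_value(c, b) + 1e-8


class TestRMSF:
    def test_static_ensemble_zero(self):
        topo = point_topology(5)
        xyz = np.random.default_rng(0).normal(0, 3, (5, 3))
        ens = Ensemble(topo, np.repeat(xyz[None], 10, axis=0))
        np.testing.assert_allclose(rmsf(ens), 0.0, atol=1e-12)

    def test_single_frame_warns_and_zeros(self):
        topo = point_topology(4)
        ens = Ensemble(topo, np.random.default_rng(1).normal(size=(1, 4, 3)))
        with pytest.warns(UserWarning):
            vals = rmsf(ens)
        np.testing.assert_array_equal(vals, 0.0)

    def test_isotropic_jitter_closed_form(self):
        """One atom jittered with per-coordinate σ = 0.5 Å has
        RMSF → σ√3 ≈ 0.866 Å."""
        rng = np.random.default_rng(9)
        n_frames = 5000
        topo = point_topology(10)
        base = rng.normal(0, 10, (10, 3))
        coords = np.repeat(base[None], n_frames, axis=0)
        coords[:, 0, :] += rng.normal(0, 0.5, (n_frames, 3))
        ens = Ensemble(topo, coords)
        vals = rmsf(ens, fit=False)
        assert vals[0] == pytest.approx(0.5 * np.sqrt(3), rel=0.05)
        np.testing.assert_allclose(vals[1:], 0.0, atol=1e-9)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        topo = point_topology(1)
        conf = Conformation(topo, np.array([[1.0, 2.0, 3.0]]))
        assert radius_of_gyration(conf, selection=np.array([0])) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_equal_masses(self):
        topo = point_topology(2)
        conf = Conformation(topo, np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(conf) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_definition(self):
        """Direct evaluation of Rg = sqrt(Σ m_i r_i² / Σ m_i) with an
        explicit loop over atoms."""
        rng = np.random.default_rng(10)
        topo = point_topology(50)
        xyz = rng.normal(0, 6, (50, 3))
        conf = Conformation(topo, xyz)
        m = topo.masses
        com = np.zeros(3)
        for i in range(50):
            com += m[i] * xyz[i]
        com /= m.sum()
        num = sum(m[i] * np.sum((xyz[i] - com) ** 2) for i in range(50))
        expected = np.sqrt(num / m.sum())
        assert radius_of_gyration(conf) == pytest.approx(expected, abs=1e-10)

    def test_empty_selection_rejected(self):
        topo = point_topology(3)
        conf = Conformation(topo, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            radius_of_gyration(conf, selection=np.array([], dtype=int))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        topo = point_topology(12)
        xyz = rng.normal(0, 5, (12, 3))
        R = Rotation.random(random_state=seed).as_matrix()
        moved = xyz @ R.T + rng.normal(0, 20, 3)
        rg0 = radius_of_gyration(Conformation(topo, xyz))
        rg1 = radius_of_gyration(Conformation(topo, moved))
        assert rg1 == pytest.approx(rg0, rel=1e-10)


class TestHelixAxis:
    def test_static_helix_direction(self):
        helix = build_ideal_helix(15, "alpha")
        topo = helix.topology
        ca = helix.coordinates[topo.select(names=["CA"])]
        # rotate the helix so its end-to-end axis lies along z
        v = ca[-1] - ca[0]
        R, _ = Rotation.align_vectors(np.array([[0.0, 0, 1]]), v[None] / np.linalg.norm(v))
        xyz = helix.coordinates @ R.as_matrix().T
        ens = Ensemble(topo, np.repeat(xyz[None], 4, axis=0))
        axes = helix_axis_drift(ens, (1, 15))
        for ax in axes:
            np.testing.assert_allclose(ax.direction, [0, 0, 1], atol=1e-6)

    def test_helix_rotated_against_fixed_anchor_drifts_90_degrees(self):
        """Fit on a stationary anchor, rotate the helix 90° about an
        axis perpendicular to its own: the axis angle between frames
        must be exactly 90°."""
        helix = build_ideal_helix(15, "alpha")
        htopo = helix.topology
        rng = np.random.default_rng(4)
        anchors = rng.normal(0, 5, (4, 3)) + np.array([60.0, 0, 0])
        topo = Topology(
            names=list(htopo.names) + ["CA"] * 4,
            elements=list(htopo.elements) + ["C"] * 4,
            resids=list(htopo.resids) + [16, 17, 18, 19],
            resnames=list(htopo.resnames) + ["ALA"] * 4,
        )
        frame0 = np.vstack([helix.coordinates, anchors])
        ca = htopo.select(names=["CA"])
        v0 = helix.coordinates[ca[-1]] - helix.coordinates[ca[0]]
        u = np.cross(v0, [0.0, 0.0, 1.0])
        u /= np.linalg.norm(u)
        R = Rotation.from_rotvec(np.pi / 2 * u).as_matrix()
        center = helix.coordinates.mean(axis=0)
        frame1 = frame0.copy()
        frame1[: len(helix.coordinates)] = (
            helix.coordinates - center
        ) @ R.T + center
        ens = Ensemble(topo, np.stack([frame0, frame1]))
        anchor_idx = np.arange(len(helix.coordinates), topo.n_atoms)
        axes = helix_axis_drift(ens, (1, 15), fit_selection=anchor_idx)
        cosang = float(axes[0].direction @ axes[1].direction)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(
            90.0, abs=1e-6
        )

    def test_display_extension_is_fifty_percent(self):
        helix = build_ideal_helix(10, "alpha")
        ens = Ensemble(helix.topology, helix.coordinates[None])
        (axis,) = helix_axis_drift(ens, (1, 10))
        s, e = extend_axis_for_display(axis)
        orig = np.linalg.norm(axis.end_point - axis.start_point)
        assert np.linalg.norm(e - s) == pytest.approx(1.5 * orig, rel=1e-9)


class TestDensityProfile:
    def test_constant_sample_single_spike(self):
        centers, dens = density_profile(np.full(50, 2.5), bin_width=0.1)
        assert np.sum(dens * 0.1) == pytest.approx(1.0, abs=1e-6)
        assert np.count_nonzero(dens) == 1

    def test_integrates_to_one(self):
        rng = np.random.default_rng(11)
        centers, dens = density_profile(rng.normal(5, 1, 2000), bin_width=0.1)
        assert np.sum(dens * 0.1) == pytest.approx(1.0, abs=1e-6)

    def test_gaussian_sample_matches_pdf(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 100_000)
        centers, dens = density_profile(x, grid_min=-4, grid_max=4, bin_width=0.1)
        pdf = np.exp(-(centers**2) / 2) / np.sqrt(2 * np.pi)
        assert np.max(np.abs(dens - pdf)) <= 0.02

    def test_bimodal_modes_at_planted_locations(self):
        rng = np.random.default_rng(13)
        x = np.concatenate([rng.normal(0, 0.3, 5000), rng.normal(4, 0.3, 5000)])
        centers, dens = density_profile(x, bin_width=0.1)
        # local maxima
        peaks = centers[1:-1][(dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])]
        assert np.any(np.abs(peaks - 0.0) <= 0.1)
        assert np.any(np.abs(peaks - 4.0) <= 0.1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            density_profile(np.array([1.0]))
        with pytest.raises(ValueError):
            density_profile(np.array([1.0, 2.0]), bin_width=0.0)
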