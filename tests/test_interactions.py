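"""H-bond, hydrophobic and salt-bridge detection."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynasome.core import Conformation, Ensemble, Topology
from dynasome.interactions import (
    annotate_salt_bridges,
    detect_hbonds,
    detect_hydrophobic_contacts,
    hbond_occurrence,
    strength_scale,
)


def _donor_acceptor_topology():
    """Residue 1 donates (N with H); residue 3 accepts (O)."""
    return Topology(
        names=["N", "H", "O"],
        elements=["N", "H", "O"],
        resids=[1, 1, 3],
        resnames=["GLY", "GLY", "GLY"],
    )


def _geometry(acceptor_xyz):
    """Donor N at origin, H at (1, 0, 0), acceptor wherever asked."""
    return np.array([[0.0, 0, 0], [1.0, 0, 0], list(acceptor_xyz)])


class TestHBondCriteria:
    def test_boundary_distance_accepted(self):
        """D⋯A exactly 3.60 Å with a linear geometry is a bond
        (inclusive boundary)."""
        topo = _donor_acceptor_topology()
        conf = Conformation(topo, _geometry([3.6, 0, 0]))  # angle at H = 180°
        recs = detect_hbonds(conf)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.6, abs=1e-12)
        assert recs[0].angle == pytest.approx(180.0, abs=1e-9)

    def test_beyond_distance_rejected(self):
        topo = _donor_acceptor_topology()
        conf = Conformation(topo, _geometry([3.7, 0, 0]))
        assert detect_hbonds(conf) == []

    def test_right_angle_rejected(self):
        """Angle exactly 90° at the hydrogen fails the strict
        inequality even at a short distance."""
        topo = _donor_acceptor_topology()
        # H->A perpendicular to H->D; D..A = sqrt(1+9) ≈ 3.16 ≤ 3.6
        conf = Conformation(topo, _geometry([1.0, 3.0, 0]))
        assert detect_hbonds(conf) == []

    def test_obtuse_angle_accepted(self):
        topo = _donor_acceptor_topology()
        conf = Conformation(topo, _geometry([3.0, 1.0, 0]))
        recs = detect_hbonds(conf)
        assert len(recs) == 1
        assert 90.0 < recs[0].angle <= 180.0

    def test_donor_without_hydrogen_skipped(self):
        topo = Topology(
            names=["N", "O"], elements=["N", "O"], resids=[1, 3],
            resnames=["GLY", "GLY"],
        )
        conf = Conformation(topo, np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        assert detect_hbonds(conf) == []

    def test_rigid_motion_invariance(self):
        topo = _donor_acceptor_topology()
        xyz = _geometry([3.2, 0.8, 0])
        R = Rotation.from_euler("xyz", [30, 60, 10], degrees=True).as_matrix()
        moved = xyz @ R.T + np.array([12.0, -7.0, 3.0])
        r1 = detect_hbonds(Conformation(topo, xyz))
        r2 = detect_hbonds(Conformation(topo, moved))
        assert len(r1) == len(r2) == 1
        assert r1[0].distance == pytest.approx(r2[0].distance, abs=1e-9)
        assert r1[0].angle == pytest.approx(r2[0].angle, abs=1e-9)


class TestOccurrence:
    def _ensemble(self, n_on, n_off):
        topo = _donor_acceptor_topology()
        on = _geometry([3.0, 0, 0])
        off = _geometry([5.0, 0, 0])
        frames = [on] * n_on + [off] * n_off
        return Ensemble(topo, np.stack(frames))

    def test_permanent_bond_frequency_one(self):
        series = hbond_occurrence(self._ensemble(8, 0))
        assert len(series) == 1
        assert series[0].frequency == 1.0

    def test_exact_threshold_retention(self):
        """A bond present in exactly 60 % of frames survives the 0.6
        threshold but not 0.61 — checked in exact rational arithmetic."""
        ens = self._ensemble(6, 4)
        kept = hbond_occurrence(ens, min_frequency=0.6)
        assert len(kept) == 1
        assert Fraction(int(np.sum(kept[0].present)), ens.n_frames) == Fraction(3, 5)
        assert hbond_occurrence(ens, min_frequency=0.61) == []

    def test_frequency_is_mean_of_presence(self):
        series = hbond_occurrence(self._ensemble(7, 3), min_frequency=0.5)
        s = series[0]
        assert s.frequency == pytest.approx(np.mean(s.present), abs=0)


class TestStrengthScale:
    def test_scale_endpoints(self):
        assert strength_scale(2.6) == 0.0  # strongest end of the scale
        assert strength_scale(3.6) == 1.0  # weakest end
        assert strength_scale(2.0) == 0.0
        assert strength_scale(3.1) == pytest.approx(0.5)


class TestHydrophobicContacts:
    def _two_leu(self, cb_gap):
        # residues 1 and 3 (|i-j| = 2, allowed); CB atoms cb_gap apart
        return (
            Topology(
                names=["CA", "CB", "CA", "CB"],
                elements=["C", "C", "C", "C"],
                resids=[1, 1, 3, 3],
                resnames=["LEU", "LEU", "LEU", "LEU"],
            ),
            np.array(
                [[0.0, 0, 0], [1.5, 0, 0], [20.0, 0, 0], [1.5 + cb_gap, 0, 0]]
            ),
        )

    def test_within_cutoff_is_contact(self):
        topo, xyz = self._two_leu(3.9)
        recs = detect_hydrophobic_contacts(Conformation(topo, xyz))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(3.9, abs=1e-12)

    def test_beyond_cutoff_is_not(self):
        topo, xyz = self._two_leu(4.1)
        assert detect_hydrophobic_contacts(Conformation(topo, xyz)) == []

    def test_backbone_proximity_does_not_count(self):
        """Only side-chain carbons qualify: close CA atoms with distant
        CB atoms give no contact."""
        topo = Topology(
            names=["CA", "CB", "CA", "CB"],
            elements=["C"] * 4,
            resids=[1, 1, 3, 3],
            resnames=["LEU"] * 4,
        )
        xyz = np.array([[0.0, 0, 0], [0, 10, 0], [2.5, 0, 0], [2.5, -10, 0]])
        assert detect_hydrophobic_contacts(Conformation(topo, xyz)) == []

    def test_sequence_adjacent_excluded(self):
        topo = Topology(
            names=["CA", "CB", "CA", "CB"],
            elements=["C"] * 4,
            resids=[1, 1, 2, 2],
            resnames=["LEU"] * 4,
        )
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [5.0, 0, 0], [3.0, 0, 0]])
        assert detect_hydrophobic_contacts(Conformation(topo, xyz)) == []

    def test_glycine_never_qualifies(self):
        topo = Topology(
            names=["CA", "CA"],
            elements=["C", "C"],
            resids=[1, 3],
            resnames=["GLY", "GLY"],
        )
        xyz = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert detect_hydrophobic_contacts(Conformation(topo, xyz)) == []

    def test_polar_residues_excluded(self):
        topo = Topology(
            names=["CA", "CB", "CA", "CB"],
            elements=["C"] * 4,
            resids=[1, 1, 3, 3],
            resnames=["SER", "SER", "SER", "SER"],
        )
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [6.0, 0, 0], [4.5, 0, 0]])
        assert detect_hydrophobic_contacts(Conformation(topo, xyz)) == []


class TestSaltBridges:
    def _record_for(self, donor_res, donor_name, acc_res, acc_name):
        topo = Topology(
            names=[donor_name, "H", acc_name],
            elements=[donor_name[0], "H", acc_name[0]],
            resids=[1, 1, 5],
            resnames=[donor_res, donor_res, acc_res],
        )
        conf = Conformation(topo, _geometry([3.0, 0.5, 0]))
        recs = detect_hbonds(conf)
        assert len(recs) == 1
        return annotate_salt_bridges(recs, topo)[0]

    def test_arg_to_asp_is_salt_bridge(self):
        rec = self._record_for("ARG", "NH1", "ASP", "OD1")
        assert rec.kind == "salt_bridge"

    def test_backbone_bond_unchanged(self):
        rec = self._record_for("ALA", "N", "ALA", "O")
        assert rec.kind == "hbond"

    def test_ser_to_glu_stays_hbond(self):
        """A hydroxyl donor to a carboxylate is a plain H-bond: the
        donor side is not a basic side chain."""
        rec = self._record_for("SER", "OG", "GLU", "OE1")
        assert rec.kind == "hbond"

    def test_lys_to_glu_is_salt_bridge(self):
        rec = self._record_for("LYS", "NZ", "GLU", "OE2")
        assert rec.kind == "salt_bridge"
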