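"""Non-covalent interaction detection.

Hydrogen bonds use the geometric criterion D⋯A ≤ 3.6 Å (inclusive) with
pseudo-valent angle at the hydrogen ∠D–H⋯A > 90° (strict), donors and
acceptors being nitrogen and oxygen heavy atoms only.  Hydrophobic
contacts are side-chain carbon pairs of hydrophobic residues within
4 Å.  Salt bridges are the subset of H-bonds joining a basic side-chain
nitrogen to a carboxylate oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Conformation, Ensemble, Topology

HBOND_DISTANCE_MAX = 3.6  # Å, D⋯A inclusive
HBOND_ANGLE_MIN = 90.0  # degrees, strict
HBOND_STRENGTH_MIN = 2.6  # Å, strongest end of the display scale
HYDROPHOBIC_CUTOFF = 4.0  # Å, side-chain C–C
COVALENT_CUTOFF = 1.8  # Å, pairs closer than this are bonded
H_BOND_TO_DONOR = 1.25  # Å, H considered attached to a heavy atom

HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}
BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_SIDECHAIN_O = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
BACKBONE_SET = {"N", "CA", "C", "O", "H", "OXT"}


@dataclass
class ContactRecord:
    kind: str  # hbond | salt_bridge | hydrophobic
    donor_atom: int  # atom index (residue index for hydrophobic)
    acceptor_atom: int
    donor_label: str
    acceptor_label: str
    distance: float  # Å (D⋯A, or closest C–C)
    angle: float | None = None  # degrees at H, H-bonds only
    hydrogen_atom: int | None = None
    frame_time: float = 0.0

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")
        if self.kind in ("hbond", "salt_bridge") and self.angle is not None:
            if not (HBOND_ANGLE_MIN < self.angle <= 180.0):
                raise ValueError("H-bond angle must lie in (90°, 180°]")


@dataclass
class ContactTimeSeries:
    pair: tuple[int, int]  # donor, acceptor atom indices
    label: str
    present: np.ndarray  # bool per frame
    distance: np.ndarray  # Å per frame (nan when absent)
    kind: str = "hbond"

    @property
    def frequency(self) -> float:
        return float(np.mean(self.present))


def _atom_label(topology: Topology, i: int) -> str:
    return (
        f"{topology.resnames[i]}{topology.resids[i]}:{topology.names[i]}"
    )


def strength_scale(distance: float) -> float:
    """Position of a D⋯A distance on the 2.6–3.6 Å display scale.

    0 at ≤ 2.6 Å (strongest) up to 1 at ≥ 3.6 Å (weakest).
    """
    d = np.clip(distance, HBOND_STRENGTH_MIN, HBOND_DISTANCE_MAX)
    return float((d - HBOND_STRENGTH_MIN) / (HBOND_DISTANCE_MAX - HBOND_STRENGTH_MIN))


def _donor_hydrogens(topology: Topology, coords: np.ndarray) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of covalently attached hydrogens."""
    h_idx = np.nonzero(topology.elements == "H")[0]
    heavy = np.nonzero(np.isin(topology.elements, ["N", "O"]))[0]
    out: dict[int, list[int]] = {}
    if len(h_idx) == 0 or len(heavy) == 0:
        return out
    tree = cKDTree(coords[heavy])
    for h in h_idx:
        dist, j = tree.query(coords[h], k=1)
        if dist <= H_BOND_TO_DONOR:
            out.setdefault(int(heavy[j]), []).append(int(h))
    return out


def detect_hbonds(
    conformation: Conformation, topology: Topology | None = None
) -> list[ContactRecord]:
    """All (D, H, A) hydrogen bonds of one conformation.

    Donors are N/O heavy atoms bearing an explicit hydrogen; acceptors
    are N/O heavy atoms.  Covalently bound D–A pairs (closer than
    1.8 Å) and D = A are excluded.  A donor without a resolvable H
    cannot form bonds (no distance-only fallback).
    """
    topo = topology if topology is not None else conformation.topology
    xyz = conformation.coordinates
    donors_h = _donor_hydrogens(topo, xyz)
    acceptors = np.nonzero(np.isin(topo.elements, ["N", "O"]))[0]
    if not donors_h or len(acceptors) == 0:
        return []
    acc_tree = cKDTree(xyz[acceptors])
    records: list[ContactRecord] = []
    for d, hydrogens in sorted(donors_h.items()):
        near = acc_tree.query_ball_point(xyz[d], HBOND_DISTANCE_MAX + 1e-12)
        for j in near:
            a = int(acceptors[j])
            if a == d:
                continue
            da = float(np.linalg.norm(xyz[a] - xyz[d]))
            if da > HBOND_DISTANCE_MAX or da < COVALENT_CUTOFF:
                continue
            for h in hydrogens:
                hd = xyz[d] - xyz[h]
                ha = xyz[a] - xyz[h]
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom == 0:
                    continue
                cosang = np.clip(np.dot(hd, ha) / denom, -1.0, 1.0)
                ang = float(np.degrees(np.arccos(cosang)))
                if ang > HBOND_ANGLE_MIN:
                    records.append(
                        ContactRecord(
                            kind="hbond",
                            donor_atom=d,
                            acceptor_atom=a,
                            donor_label=_atom_label(topo, d),
                            acceptor_label=_atom_label(topo, a),
                            distance=da,
                            angle=ang,
                            hydrogen_atom=h,
                            frame_time=conformation.time,
                        )
                    )
    return records


def hbond_occurrence(
    ensemble: Ensemble, min_frequency: float = 0.6
) -> list[ContactTimeSeries]:
    """Per-(donor, acceptor) H-bond time series over an ensemble.

    Events are aggregated over all hydrogens of a donor; pairs observed
    in at least ``min_frequency`` of the frames are retained, sorted by
    decreasing frequency.  Per-frame distances feed the 2.6–3.6 Å
    strength scale (see :func:`strength_scale`).
    """
    n = ensemble.n_frames
    presence: dict[tuple[int, int], np.ndarray] = {}
    distances: dict[tuple[int, int], np.ndarray] = {}
    for i, frame in enumerate(ensemble):
        for rec in detect_hbonds(frame):
            key = (rec.donor_atom, rec.acceptor_atom)
            if key not in presence:
                presence[key] = np.zeros(n, dtype=bool)
                distances[key] = np.full(n, np.nan)
            presence[key][i] = True
            d = distances[key][i]
            if np.isnan(d) or rec.distance < d:
                distances[key][i] = rec.distance
    topo = ensemble.topology
    series = [
        ContactTimeSeries(
            pair=key,
            label=f"{_atom_label(topo, key[0])}->{_atom_label(topo, key[1])}",
            present=presence[key],
            distance=distances[key],
        )
        for key in presence
    ]
    kept = [s for s in series if s.frequency >= min_frequency]
    kept.sort(key=lambda s: (-s.frequency, s.pair))
    return kept


def _sidechain_carbons(topology: Topology) -> dict[int, np.ndarray]:
    """Residue id -> indices of side-chain carbon atoms (CB and beyond)."""
    mask = (topology.elements == "C") & ~np.isin(
        topology.names, ["C", "CA"]
    )
    out: dict[int, np.ndarray] = {}
    for rid in topology.residue_ids:
        idx = np.nonzero(mask & (topology.resids == rid))[0]
        if len(idx):
            out[int(rid)] = idx
    return out


def detect_hydrophobic_contacts(
    conformation: Conformation,
    topology: Topology | None = None,
    cutoff: float = HYDROPHOBIC_CUTOFF,
    min_sequence_separation: int = 2,
    residue_set: set[str] | None = None,
) -> list[ContactRecord]:
    """Hydrophobic residue pairs with side-chain carbons within 4 Å.

    Only side-chain carbons count (glycine never qualifies); pairs
    closer than ``min_sequence_separation`` in sequence are excluded.
    Donor/acceptor fields hold the two residue indices.
    """
    topo = topology if topology is not None else conformation.topology
    resset = HYDROPHOBIC_RESIDUES if residue_set is None else residue_set
    xyz = conformation.coordinates
    sc = _sidechain_carbons(topo)
    rid_name = {
        int(r): str(topo.resnames[np.nonzero(topo.resids == r)[0][0]])
        for r in topo.residue_ids
    }
    hydrophobic = [r for r in sc if rid_name[r] in resset]
    records: list[ContactRecord] = []
    for ii, r1 in enumerate(hydrophobic):
        for r2 in hydrophobic[ii + 1 :]:
            if abs(r2 - r1) < min_sequence_separation:
                continue
            d = np.sqrt(
                np.min(
                    np.sum(
                        (xyz[sc[r1]][:, None, :] - xyz[sc[r2]][None, :, :]) ** 2,
                        axis=2,
                    )
                )
            )
            if d <= cutoff:
                records.append(
                    ContactRecord(
                        kind="hydrophobic",
                        donor_atom=r1,
                        acceptor_atom=r2,
                        donor_label=f"{rid_name[r1]}{r1}",
                        acceptor_label=f"{rid_name[r2]}{r2}",
                        distance=float(d),
                        frame_time=conformation.time,
                    )
                )
    return records


def annotate_salt_bridges(
    hbonds: list[ContactRecord], topology: Topology
) -> list[ContactRecord]:
    """Relabel H-bonds between basic side-chain N and carboxylate O as
    salt bridges (either direction); all other records pass unchanged."""

    def _is_basic_n(i: int) -> bool:
        return str(topology.names[i]) in BASIC_SIDECHAIN_N.get(
            str(topology.resnames[i]), set()
        )

    def _is_acidic_o(i: int) -> bool:
        return str(topology.names[i]) in ACIDIC_SIDECHAIN_O.get(
            str(topology.resnames[i]), set()
        )

    out: list[ContactRecord] = []
    for rec in hbonds:
        d, a = rec.donor_atom, rec.acceptor_atom
        if (_is_basic_n(d) and _is_acidic_o(a)) or (
            _is_acidic_o(d) and _is_basic_n(a)
        ):
            rec = ContactRecord(
                kind="salt_bridge",
                donor_atom=d,
                acceptor_atom=a,
                donor_label=rec.donor_label,
                acceptor_label=rec.acceptor_label,
                distance=rec.distance,
                angle=rec.angle,
                hydrogen_atom=rec.hydrogen_atom,
                frame_time=rec.frame_time,
            )
        out.append(rec)
    return out
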