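"""Ground-truth synthetic ensembles.

This module fabricates the statistical structure the analyses assume —
ideal helices with known (φ, ψ), a two-domain toy protein (stable
helical bundle + disordered loop), multi-well Cartesian mixtures with
known populations, and spherical shells enclosing a cavity of known
volume — so that every downstream stage can be tested against planted
truth.  No physics is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Conformation, Ensemble, Topology

# canonical backbone dihedrals (degrees)
HELIX_DIHEDRALS = {
    "alpha": (-57.0, -47.0),
    "three_ten": (-49.0, -26.0),
    "pi": (-57.0, -70.0),
}

# idealised backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.01, 1.53
_A_CA_C_N, _A_C_N_CA, _A_N_CA_C, _A_CA_C_O = 116.2, 121.7, 111.2, 120.5


@dataclass
class WellSpec:
    """One conformational well of a Cartesian mixture."""

    center: np.ndarray  # (n_atoms, 3) Å
    population: float  # fraction in [0, 1]
    spread: float  # Å, isotropic σ per coordinate


@dataclass
class SyntheticGroundTruth:
    """What was planted, for oracle-based testing."""

    frame_labels: np.ndarray  # well index per frame
    planted_hbonds: list = field(default_factory=list)
    planted_cavity: dict | None = None  # {"center": [...], "radius": r, "volume": V}
    helix_truth: list | None = None  # per-residue intended reduced SS letter

    def to_json(self, path) -> None:
        payload = {
            "frame_labels": np.asarray(self.frame_labels).tolist(),
            "planted_hbonds": self.planted_hbonds,
            "planted_cavity": self.planted_cavity,
            "helix_truth": self.helix_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF: position of atom D given A-B-C, |CD|, ∠BCD and dihedral ABCD."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang, dih = np.radians(angle), np.radians(dihedral)
    d = bond * (
        -np.cos(ang) * bc + np.sin(ang) * (np.cos(dih) * m + np.sin(dih) * n)
    )
    return c + d


def _backbone_chain(
    phi_psi: Sequence[tuple[float, float]],
    resnames: Sequence[str],
    start_resid: int = 1,
    omega: float = 180.0,
    with_cb: bool = True,
) -> tuple[Topology, np.ndarray]:
    """Build an N/H/CA/C/O(/CB) backbone from per-residue (φ, ψ)."""
    n_res = len(phi_psi)
    if len(resnames) != n_res:
        raise ValueError("one residue name per (φ, ψ) pair required")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed triad in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        phi_prev_psi = phi_psi[i - 1][1]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, phi_prev_psi)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, omega)
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi_psi[i][0])

    names: list[str] = []
    elements: list[str] = []
    resids: list[int] = []
    rnames: list[str] = []
    coords: list[np.ndarray] = []

    def add(name: str, element: str, i: int, xyz: np.ndarray) -> None:
        names.append(name)
        elements.append(element)
        resids.append(start_resid + i)
        rnames.append(resnames[i])
        coords.append(xyz)

    for i in range(n_res):
        add("N", "N", i, N[i])
        if i > 0:  # amide H anti-bisecting C(prev)–N–Cα
            u = N[i] - C[i - 1]
            v = N[i] - CA[i]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            h_dir = h_dir / np.linalg.norm(h_dir)
            add("H", "H", i, N[i] + _B_N_H * h_dir)
        add("CA", "C", i, CA[i])
        if with_cb and resnames[i] != "GLY":
            nh = N[i] - CA[i]
            nh /= np.linalg.norm(nh)
            ch = C[i] - CA[i]
            ch /= np.linalg.norm(ch)
            bis = nh + ch
            bis /= np.linalg.norm(bis)
            perp = np.cross(ch, nh)
            perp /= np.linalg.norm(perp)
            cb_dir = -0.58 * bis + 0.8146 * perp
            add("CB", "C", i, CA[i] + _B_CA_CB * cb_dir / np.linalg.norm(cb_dir))
        add("C", "C", i, C[i])
        # carbonyl O in the peptide plane, trans to the next N
        psi = phi_psi[i][1]
        add("O", "O", i, _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0))

    topo = Topology(names=names, elements=elements, resids=resids, resnames=rnames)
    return topo, np.asarray(coords)


def build_ideal_helix(
    n_residues: int,
    helix_type: str = "alpha",
    resnames: Sequence[str] | None = None,
    start_resid: int = 1,
    with_cb: bool = True,
) -> Conformation:
    """Ideal helix of the requested type from canonical (φ, ψ).

    Canonical dihedrals: α (−57°, −47°), 3₁₀ (−49°, −26°), π (−57°, −70°).
    Backbone atoms N, H, Cα, (Cβ), C, O are generated explicitly so that
    hydrogen-bond geometry is computable.
    """
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    if helix_type not in HELIX_DIHEDRALS:
        raise ValueError(f"unknown helix type {helix_type!r}")
    phi, psi = HELIX_DIHEDRALS[helix_type]
    if resnames is None:
        resnames = ["ALA"] * n_residues
    topo, coords = _backbone_chain(
        [(phi, psi)] * n_residues, resnames, start_resid=start_resid, with_cb=with_cb
    )
    return Conformation(topo, coords)


def build_coil(
    n_residues: int,
    resnames: Sequence[str] | None = None,
    start_resid: int = 1,
    seed: int | None = None,
) -> Conformation:
    """Irregular extended coil (no helical H-bond pattern)."""
    rng = np.random.default_rng(0 if seed is None else seed)
    phi_psi = [
        (-80.0 + rng.uniform(-15, 15), 135.0 + rng.uniform(-15, 15))
        for _ in range(n_residues)
    ]
    if resnames is None:
        resnames = ["SER"] * n_residues
    topo, coords = _backbone_chain(phi_psi, resnames, start_resid=start_resid)
    return Conformation(topo, coords)


def _merge_chains(parts: list[tuple[Topology, np.ndarray]],
                  regions: dict[str, tuple[int, int]],
                  helix_definitions: dict[str, tuple[int, int]] | None = None,
                  ) -> tuple[Topology, np.ndarray]:
    names, elements, resids, resnames, coords = [], [], [], [], []
    for topo, xyz in parts:
        names.extend(topo.names)
        elements.extend(topo.elements)
        resids.extend(topo.resids)
        resnames.extend(topo.resnames)
        coords.append(xyz)
    merged = Topology(
        names=names,
        elements=elements,
        resids=resids,
        resnames=resnames,
        regions=regions,
        helix_definitions=helix_definitions,
    )
    return merged, np.vstack(coords)


def build_two_domain_toy(
    stable_helices: int = 4,
    loop_length: int = 45,
    helix_length: int = 18,
    seed: int = 0,
) -> tuple[Topology, Conformation]:
    """Toy protein: a bundle of ideal α-helices (the stable domain) plus
    an attached disordered loop.

    Regions ``TM1``..``TMn`` and ``L-loop`` are registered in the
    topology; residue numbering is continuous across the chain.
    """
    if stable_helices < 1:
        raise ValueError("need at least one stable helix")
    if loop_length < 10:
        raise ValueError("loop must have at least 10 residues")
    parts: list[tuple[Topology, np.ndarray]] = []
    regions: dict[str, tuple[int, int]] = {}
    resid = 1
    bundle_radius = 8.0
    hydrophobic = ["LEU", "ALA", "VAL", "ILE"]
    for h in range(stable_helices):
        resnames = [hydrophobic[(h + i) % 4] for i in range(helix_length)]
        helix = build_ideal_helix(
            helix_length, "alpha", resnames=resnames, start_resid=resid
        )
        # orient along z, place on a circle, alternate up/down
        xyz = helix.coordinates - helix.coordinates.mean(axis=0)
        # the ideal helix grows roughly along its first principal axis
        _, _, vt = np.linalg.svd(xyz - xyz.mean(axis=0))
        axis = vt[0]
        rot = _rotation_onto(axis, np.array([0.0, 0.0, 1.0 if h % 2 == 0 else -1.0]))
        xyz = xyz @ rot.T
        theta = 2 * np.pi * h / max(stable_helices, 2)
        xyz += np.array(
            [bundle_radius * np.cos(theta), bundle_radius * np.sin(theta), 0.0]
        )
        regions[f"TM{h + 1}"] = (resid, resid + helix_length - 1)
        parts.append((helix.topology, xyz))
        resid += helix_length
    loop = build_coil(loop_length, start_resid=resid, seed=seed)
    loop_xyz = loop.coordinates - loop.coordinates.mean(axis=0)
    z_top = max(p[1].max(axis=0)[2] for p in parts)
    loop_xyz += np.array([0.0, 0.0, z_top + 8.0])
    regions["L-loop"] = (resid, resid + loop_length - 1)
    parts.append((loop.topology, loop_xyz))
    topo, coords = _merge_chains(parts, regions)
    return topo, Conformation(topo, coords)


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180°: rotate about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        v = np.cross(a, perp)
        v /= np.linalg.norm(v)
        return 2 * np.outer(v, v) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1 / (1 + c))


def sample_mixture_ensemble(
    base: Conformation,
    wells: Sequence[WellSpec],
    n_frames: int,
    seed: int,
    perturb_selection: np.ndarray | None = None,
    stride: float = 100.0,
    source_label: str = "WT",
) -> tuple[Ensemble, SyntheticGroundTruth]:
    """Draw frames i.i.d. from a Cartesian mixture of conformational wells.

    Each frame picks a well with the stated population, then adds
    isotropic Gaussian noise of the well's spread to the perturbed
    selection (all atoms when ``None``); unperturbed atoms stay at the
    well centre, mimicking quasi-independent domain dynamics.
    """
    wells = list(wells)
    if n_frames < len(wells):
        raise ValueError("need at least one frame per well")
    pops = np.array([w.population for w in wells], dtype=float)
    if abs(pops.sum() - 1.0) > 1e-9:
        raise ValueError(f"well populations must sum to 1 (got {pops.sum()})")
    if any(w.spread < 0 for w in wells):
        raise ValueError("well spread must be non-negative")
    n_atoms = base.topology.n_atoms
    sel = (
        np.arange(n_atoms)
        if perturb_selection is None
        else np.asarray(perturb_selection, dtype=int)
    )
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(wells), size=n_frames, p=pops)
    coords = np.empty((n_frames, n_atoms, 3))
    for i, lab in enumerate(labels):
        w = wells[lab]
        center = np.asarray(w.center, dtype=float)
        if center.shape != (n_atoms, 3):
            raise ValueError("well centre shape must match the base topology")
        frame = center.copy()
        if w.spread > 0:
            frame[sel] += rng.normal(0.0, w.spread, size=(len(sel), 3))
        coords[i] = frame
    ens = Ensemble(
        base.topology,
        coords,
        times=np.arange(n_frames) * stride,
        source_labels=source_label,
        stride=stride,
    )
    return ens, SyntheticGroundTruth(frame_labels=labels)


VDW_CARBON = 1.70
PROBE_RADIUS = 1.4


def plant_cavity_shell(
    radius: float,
    shell_atoms: int = 300,
    center: np.ndarray | None = None,
    probe_radius: float = PROBE_RADIUS,
) -> tuple[Conformation, SyntheticGroundTruth]:
    """Spherical carbon shell enclosing an empty cavity of known volume.

    Atoms sit at ``radius + vdW(C) + probe_radius`` from the centre so
    the probe-accessible interior has exactly the requested radius; the
    analytic interior volume 4/3·π·r³ is recorded in the ground truth.
    """
    if radius < probe_radius / 2:
        raise ValueError("cavity radius too small to resolve")
    if radius <= 0:
        raise ValueError("cavity radius must be positive")
    shell_r = radius + VDW_CARBON + probe_radius
    # mean inter-atom spacing on the sphere; a probe leaks through gaps
    # wider than twice the blocking radius
    spacing = np.sqrt(4 * np.pi * shell_r**2 / shell_atoms)
    if spacing > VDW_CARBON + probe_radius:
        raise ValueError(
            f"shell too sparse to enclose: spacing {spacing:.2f} Å exceeds "
            f"blocking radius {VDW_CARBON + probe_radius:.2f} Å; "
            f"increase shell_atoms"
        )
    # Fibonacci sphere: deterministic quasi-uniform coverage
    i = np.arange(shell_atoms)
    golden = (1 + 5**0.5) / 2
    z = 1 - 2 * (i + 0.5) / shell_atoms
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pts = shell_r * np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    if center is not None:
        pts += np.asarray(center, dtype=float)
    topo = Topology(
        names=["CB"] * shell_atoms,
        elements=["C"] * shell_atoms,
        resids=np.arange(1, shell_atoms + 1),
        resnames=["ALA"] * shell_atoms,
    )
    truth = SyntheticGroundTruth(
        frame_labels=np.zeros(1, dtype=int),
        planted_cavity={
            "center": (np.zeros(3) if center is None else np.asarray(center)).tolist(),
            "radius": radius,
            "volume": 4.0 / 3.0 * np.pi * radius**3,
        },
    )
    return Conformation(topo, pts), truth


def solid_blob(n_atoms: int = 20, spacing: float = 2.0) -> Conformation:
    """Convex solid cluster of carbons — encloses nothing."""
    side = int(np.ceil(n_atoms ** (1 / 3)))
    pts = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                if len(pts) < n_atoms:
                    pts.append([ix * spacing, iy * spacing, iz * spacing])
    topo = Topology(
        names=["CB"] * n_atoms,
        elements=["C"] * n_atoms,
        resids=np.arange(1, n_atoms + 1),
        resnames=["ALA"] * n_atoms,
    )
    return Conformation(topo, np.asarray(pts, dtype=float))
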