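"""Grid-based cavity detection and ensemble pocket tracking.

A node of a regular grid is cavity when (a) a spherical probe centred
there overlaps no atom (distance to every atom exceeds its van der
Waals radius plus the probe radius) and (b) it is buried: of M evenly
spread rays cast from the node, at least N strike protein within a
fixed horizon.  Tracking a pocket across an ensemble uses the per-node
occupancy frequency thresholded at an isovalue; connected components
(26-neighbour) become pockets P1, P2, … ordered by mean volume.

This detector is deliberately analytic-testable: a planted spherical
shell of interior radius r must return a volume near 4/3·π·r³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Conformation, Ensemble

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4  # Å, water-sized probe
GRID_SPACING = 0.5  # Å
BURIAL_RAYS = 14  # 6 axial + 8 diagonal directions
BURIAL_MIN_HITS = 9
BURIAL_HORIZON = 15.0  # Å
MAX_GRID_NODES = 4_000_000

# deterministic, evenly spread ray directions: face + corner directions
_AXES = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)
_DIAG = np.array(
    [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
    dtype=float,
) / np.sqrt(3.0)
RAY_DIRECTIONS = np.vstack([_AXES, _DIAG])


@dataclass
class Grid:
    origin: np.ndarray  # Å, centre of node (0,0,0)
    spacing: float  # Å
    shape: tuple[int, int, int]

    def node_coords(self, nodes: np.ndarray) -> np.ndarray:
        """Cartesian coordinates of (m, 3) integer node indices."""
        return self.origin + np.asarray(nodes, dtype=float) * self.spacing

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def node_volume(self) -> float:
        return self.spacing**3


@dataclass
class PocketMap:
    grid: Grid
    frequency: np.ndarray  # per-node occupancy fraction in [0, 1]
    isovalue: float
    components: list[np.ndarray]  # node indices per pocket, P1 first
    mean_volumes: np.ndarray  # Å³ per pocket
    cavity_stack: np.ndarray | None = None  # (F, *shape) per-frame cavity

    @property
    def labels(self) -> list[str]:
        return [f"P{i + 1}" for i in range(len(self.components))]


@dataclass
class PocketSeries:
    label: str
    volumes: np.ndarray  # Å³ per frame
    lining_residues: list[list[int]] = field(default_factory=list)
    arginine_counts: np.ndarray | None = None
    hydrophobicity: np.ndarray | None = None


def _atom_radii(conformation: Conformation) -> np.ndarray:
    return np.array(
        [VDW_RADII.get(str(e), DEFAULT_VDW) for e in conformation.topology.elements]
    )


def make_grid(
    coords: np.ndarray, spacing: float = GRID_SPACING, margin: float = 4.0
) -> Grid:
    lo = coords.reshape(-1, 3).min(axis=0) - margin
    hi = coords.reshape(-1, 3).max(axis=0) + margin
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
    n = int(np.prod(shape))
    while n > MAX_GRID_NODES:
        spacing *= 2.0
        warnings.warn(f"grid too large; coarsening spacing to {spacing} Å")
        shape = tuple(int(np.ceil((hi[d] - lo[d]) / spacing)) + 1 for d in range(3))
        n = int(np.prod(shape))
    return Grid(origin=lo, spacing=spacing, shape=shape)


def _blocked_mask(
    grid: Grid, coords: np.ndarray, radii: np.ndarray, extra: float
) -> np.ndarray:
    """Boolean grid: node within (vdW + extra) of any atom."""
    nx, ny, nz = grid.shape
    blocked = np.zeros(grid.shape, dtype=bool)
    axes = [grid.origin[d] + np.arange(grid.shape[d]) * grid.spacing for d in range(3)]
    for r in np.unique(radii):
        cut = r + extra
        atoms = coords[radii == r]
        tree = cKDTree(atoms)
        # query nodes in slabs to bound memory
        nodes = np.stack(
            np.meshgrid(axes[0], axes[1], axes[2], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        hits = tree.query_ball_point(nodes, cut, return_length=True)
        blocked |= (hits > 0).reshape(grid.shape)
    return blocked


def _buried_mask(
    grid: Grid,
    occupied: np.ndarray,
    candidates: np.ndarray,
    min_hits: int = BURIAL_MIN_HITS,
    horizon: float = BURIAL_HORIZON,
) -> np.ndarray:
    """For candidate nodes (m, 3 indices): ≥ min_hits of the ray
    directions strike occupied space within the horizon."""
    if len(candidates) == 0:
        return np.zeros(0, dtype=bool)
    steps = np.arange(1, int(np.ceil(horizon / grid.spacing)) + 1)
    hits = np.zeros(len(candidates), dtype=int)
    shape = np.array(grid.shape)
    for direction in RAY_DIRECTIONS:
        hit_dir = np.zeros(len(candidates), dtype=bool)
        for s in steps:
            offset = direction * s  # in node units (spacing cancels)
            probe = np.rint(candidates + offset).astype(int)
            inside = np.all((probe >= 0) & (probe < shape), axis=1)
            idx = probe[inside]
            vals = np.zeros(len(candidates), dtype=bool)
            vals[inside] = occupied[idx[:, 0], idx[:, 1], idx[:, 2]]
            hit_dir |= vals
            if hit_dir.all():
                break
        hits += hit_dir
    return hits >= min_hits


def cavity_map(
    conformation: Conformation,
    grid: Grid | None = None,
    grid_spacing: float = GRID_SPACING,
    probe_radius: float = PROBE_RADIUS,
    min_hits: int = BURIAL_MIN_HITS,
    horizon: float = BURIAL_HORIZON,
) -> tuple[np.ndarray, Grid]:
    """Boolean cavity grid for one conformation.

    Returns (cavity mask over the grid, the grid).  Pass a shared grid
    when mapping the frames of a superposed ensemble.
    """
    coords = conformation.coordinates
    if len(coords) == 0:
        raise ValueError("empty structure")
    radii = _atom_radii(conformation)
    if grid is None:
        grid = make_grid(coords, spacing=grid_spacing)
    blocked = _blocked_mask(grid, coords, radii, extra=probe_radius)
    occupied = _blocked_mask(grid, coords, radii, extra=0.0)
    free_nodes = np.argwhere(~blocked)
    buried = _buried_mask(grid, occupied, free_nodes, min_hits=min_hits, horizon=horizon)
    cavity = np.zeros(grid.shape, dtype=bool)
    kept = free_nodes[buried]
    cavity[kept[:, 0], kept[:, 1], kept[:, 2]] = True
    return cavity, grid


def cavity_volume(cavity: np.ndarray, grid: Grid) -> float:
    return float(cavity.sum()) * grid.node_volume


def pocket_frequency_map(
    ensemble: Ensemble,
    isovalue: float = 0.5,
    grid_spacing: float = GRID_SPACING,
    probe_radius: float = PROBE_RADIUS,
    min_hits: int = BURIAL_MIN_HITS,
    keep_stack: bool = True,
) -> PocketMap:
    """Ensemble-frequency cavity map with pockets at an isovalue.

    Frames must be superposed to a common reference beforehand so the
    shared grid is comparable across frames.  Components of the
    frequency ≥ isovalue set (26-neighbour connectivity) are labelled
    P1, P2, … by decreasing mean per-frame volume.
    """
    grid = make_grid(ensemble.coordinates, spacing=grid_spacing)
    stack = np.zeros((ensemble.n_frames, *grid.shape), dtype=bool)
    for i, frame in enumerate(ensemble):
        stack[i], _ = cavity_map(
            frame, grid=grid, probe_radius=probe_radius, min_hits=min_hits
        )
    frequency = stack.mean(axis=0)
    above = frequency >= isovalue
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labelled, n_comp = ndimage.label(above, structure=structure)
    components: list[np.ndarray] = []
    mean_volumes = []
    for c in range(1, n_comp + 1):
        nodes = np.argwhere(labelled == c)
        mask = labelled == c
        per_frame = stack[:, mask].sum(axis=1) * grid.node_volume
        components.append(nodes)
        mean_volumes.append(float(per_frame.mean()))
    order = np.argsort(-np.asarray(mean_volumes), kind="stable")
    components = [components[i] for i in order]
    mean_volumes = np.asarray(mean_volumes)[order]
    return PocketMap(
        grid=grid,
        frequency=frequency,
        isovalue=isovalue,
        components=components,
        mean_volumes=mean_volumes,
        cavity_stack=stack if keep_stack else None,
    )


def pocket_volume_series(
    ensemble: Ensemble, pocket_map: PocketMap, component: int = 0
) -> PocketSeries:
    """Per-frame cavity volume inside one pocket's region (Å³); zero
    frames are legitimate for transient (cryptic) pockets."""
    if component >= len(pocket_map.components):
        raise ValueError(f"pocket component {component} not present")
    if pocket_map.cavity_stack is None:
        raise ValueError("pocket map was built without the per-frame stack")
    nodes = pocket_map.components[component]
    mask = np.zeros(pocket_map.grid.shape, dtype=bool)
    mask[nodes[:, 0], nodes[:, 1], nodes[:, 2]] = True
    volumes = (
        pocket_map.cavity_stack[:, mask].sum(axis=1) * pocket_map.grid.node_volume
    )
    return PocketSeries(label=f"P{component + 1}", volumes=volumes)


def lining_residues(
    conformation: Conformation,
    pocket_node_coords: np.ndarray,
    cutoff: float = 4.0,
) -> dict:
    """Residues with a heavy atom within ``cutoff`` of a pocket node.

    Reports the arginine count and, per arginine, whether the side
    chain points into the pocket: inward iff the Cα→Cζ vector has a
    positive projection on Cα→(pocket centroid).
    """
    nodes = np.asarray(pocket_node_coords, dtype=float)
    if len(nodes) == 0:
        return {"residues": [], "arginine_count": 0, "arginine_orientation": {}}
    topo = conformation.topology
    heavy = topo.select(heavy=True)
    tree = cKDTree(nodes)
    near = (
        tree.query_ball_point(conformation.coordinates[heavy], cutoff, return_length=True)
        > 0
    )
    residues = sorted({int(topo.resids[a]) for a in heavy[near]})
    centroid = nodes.mean(axis=0)
    orientation: dict[int, str] = {}
    arg_count = 0
    for rid in residues:
        ridx = np.nonzero(topo.resids == rid)[0]
        if str(topo.resnames[ridx[0]]) != "ARG":
            continue
        arg_count += 1
        ca = ridx[topo.names[ridx] == "CA"]
        cz = ridx[topo.names[ridx] == "CZ"]
        if len(ca) and len(cz):
            v_side = conformation.coordinates[cz[0]] - conformation.coordinates[ca[0]]
            v_pocket = centroid - conformation.coordinates[ca[0]]
            orientation[rid] = (
                "inward" if float(np.dot(v_side, v_pocket)) > 0 else "outward"
            )
    return {
        "residues": residues,
        "arginine_count": arg_count,
        "arginine_orientation": orientation,
    }


# Kyte–Doolittle hydropathy, shipped as the fixed residue scale
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}


def hydrophobicity_score(resnames: list[str]) -> float | None:
    """Mean Kyte–Doolittle hydropathy of the lining residues; ``None``
    (missing, not 0) for an empty lining."""
    if not resnames:
        return None
    return float(np.mean([KYTE_DOOLITTLE.get(str(r).upper(), 0.0) for r in resnames]))
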