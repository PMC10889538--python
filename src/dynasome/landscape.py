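"""Free-energy landscape on PCA reaction coordinates.

The relative Gibbs free energy over the two leading principal
components is Boltzmann-inverted from the sampled probability:

    ΔG(R1, R2) = −k_B·T · ln( P(R1, R2) / P_max )

with P estimated by a k-nearest-neighbour density on a regular grid.
At the default simulation temperature T = 310 K, k_B·T = 0.6160
kcal/mol (k_B = 1.9872·10⁻³ kcal/(mol·K)).  Wells are local minima of
the gridded surface with steepest-descent basins; shallow minima are
merged into their neighbour when the separating barrier is below a
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

KB_KCAL = 1.9872e-3  # kcal/(mol·K)
DEFAULT_TEMPERATURE = 310.0  # K


@dataclass
class FESurface:
    grid_x: np.ndarray  # node centres along R1
    grid_y: np.ndarray  # node centres along R2
    probability: np.ndarray  # (nx, ny), sums to 1 over nodes
    delta_g: np.ndarray  # kcal/mol; inf marks unreachable nodes
    temperature: float
    kB: float = KB_KCAL

    @property
    def kBT(self) -> float:
        return self.kB * self.temperature


@dataclass
class Well:
    label: str  # W1, W2, … ordered by increasing minimum ΔG
    minimum_node: tuple[int, int]
    minimum_coords: tuple[float, float]
    depth: float  # ΔG at the minimum relative to the global one (W1: 0)
    basin_nodes: np.ndarray  # (m, 2) node indices
    member_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    composition: dict[str, float] = field(default_factory=dict)


def knn_density(
    points: np.ndarray,
    k: int | None = None,
    eval_points: np.ndarray | None = None,
    min_distance: float | None = None,
) -> np.ndarray:
    """k-nearest-neighbour density estimate in 2D.

    density(x) ∝ k / (n · π · d_k(x)²) with d_k the distance to the
    k-th neighbour; the returned values are normalised to sum to 1 over
    the evaluation points (the sample points themselves by default).
    Duplicated points that would give d_k = 0 are floored at
    ``min_distance``.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k is None:
        k = int(np.ceil(np.sqrt(n)))
    if n <= k:
        raise ValueError(f"need more than k={k} points (got {n})")
    tree = cKDTree(pts)
    if eval_points is None:
        # self is its own nearest neighbour: ask for k+1
        d, _ = tree.query(pts, k=k + 1)
        dk = d[:, -1]
    else:
        d, _ = tree.query(np.asarray(eval_points, dtype=float), k=k)
        dk = d[:, -1] if k > 1 else d
    if min_distance is not None and np.any(dk < min_distance):
        warnings.warn("duplicate/near-duplicate points: flooring d_k")
        dk = np.maximum(dk, min_distance)
    if np.any(dk == 0):
        positive = dk[dk > 0]
        floor = positive.min() / 10 if len(positive) else 1e-12
        warnings.warn("coincident evaluation points: flooring d_k")
        dk = np.maximum(dk, floor)
    dens = k / (n * np.pi * dk**2)
    return dens / dens.sum()


def free_energy_landscape(
    projections: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    k: int | None = None,
    grid_size: int = 100,
    margin: float = 0.05,
) -> FESurface:
    """Boltzmann inversion of the kNN density on a regular grid.

    The grid spans the projection range plus a 5 % margin with
    ``grid_size`` nodes per axis; the landscape minimum is exactly 0.
    """
    pts = np.asarray(projections, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("projections must be (n, 2)")
    if len(pts) == 0:
        raise ValueError("empty projections")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    pts = pts[:, :2]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - margin * span
    hi = hi + margin * span
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    nodes = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    spacing = min(gx[1] - gx[0], gy[1] - gy[0])
    P = knn_density(pts, k=k, eval_points=nodes, min_distance=spacing / 10)
    P = P.reshape(grid_size, grid_size)
    kBT = KB_KCAL * temperature
    with np.errstate(divide="ignore"):
        dg = np.where(P > 0, -kBT * np.log(P / P.max()), np.inf)
    dg[np.isfinite(dg)] -= dg[np.isfinite(dg)].min()  # exact zero minimum
    return FESurface(
        grid_x=gx, grid_y=gy, probability=P, delta_g=dg, temperature=temperature
    )


_NEIGHBOURS = [
    (dx, dy)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    if not (dx == 0 and dy == 0)
]


def detect_wells(surface: FESurface, min_barrier: float = 0.5) -> list[Well]:
    """Local minima of the gridded ΔG with steepest-descent basins.

    Adjacent basins whose separating barrier (saddle minus the
    shallower minimum) is below ``min_barrier`` are merged.  Wells are
    labelled W1, W2, … by increasing minimum ΔG; W1 has depth 0.
    """
    dg = surface.delta_g
    nx, ny = dg.shape
    finite = np.isfinite(dg)

    # steepest-descent flow: each node points to its lowest neighbour
    basin = -np.ones((nx, ny), dtype=int)
    order = np.argsort(dg, axis=None, kind="stable")
    minima: list[tuple[int, int]] = []
    flat_offset = {}
    for flat in order:
        i, j = divmod(int(flat), ny)
        if not finite[i, j]:
            continue
        best = None
        for dx, dy in _NEIGHBOURS:
            a, b = i + dx, j + dy
            if 0 <= a < nx and 0 <= b < ny and finite[a, b]:
                if dg[a, b] < dg[i, j] or (
                    dg[a, b] == dg[i, j] and basin[a, b] >= 0
                ):
                    if best is None or dg[a, b] < dg[best]:
                        best = (a, b)
        if best is None or dg[best] > dg[i, j]:
            basin[i, j] = len(minima)
            minima.append((i, j))
        else:
            basin[i, j] = basin[best]

    if not minima:
        return []

    # merge shallow minima across low barriers
    def merge_pass() -> bool:
        n_min = len(set(basin[basin >= 0].tolist()))
        active = sorted(set(basin[basin >= 0].tolist()))
        if len(active) < 2:
            return False
        # saddle height between each adjacent basin pair
        saddle: dict[tuple[int, int], float] = {}
        for i in range(nx):
            for j in range(ny):
                if basin[i, j] < 0:
                    continue
                for dx, dy in _NEIGHBOURS:
                    a, b = i + dx, j + dy
                    if 0 <= a < nx and 0 <= b < ny and basin[a, b] >= 0:
                        p, q = basin[i, j], basin[a, b]
                        if p < q:
                            h = max(dg[i, j], dg[a, b])
                            key = (p, q)
                            if key not in saddle or h < saddle[key]:
                                saddle[key] = h
        merged = False
        for (p, q), h in sorted(saddle.items(), key=lambda kv: kv[1]):
            dp = dg[minima[p]]
            dq = dg[minima[q]]
            shallow, deep = (p, q) if dp >= dq else (q, p)
            if h - dg[minima[shallow]] < min_barrier:
                basin[basin == shallow] = deep
                merged = True
                break  # recompute saddles after each merge
        return merged

    while merge_pass():
        pass

    active = sorted(set(basin[basin >= 0].tolist()))
    # order wells by their minimum ΔG
    active.sort(key=lambda m: dg[minima[m]])
    wells: list[Well] = []
    g0 = dg[minima[active[0]]]
    for rank, m in enumerate(active):
        nodes = np.argwhere(basin == m)
        i, j = minima[m]
        wells.append(
            Well(
                label=f"W{rank + 1}",
                minimum_node=(i, j),
                minimum_coords=(float(surface.grid_x[i]), float(surface.grid_y[j])),
                depth=float(dg[i, j] - g0),
                basin_nodes=nodes,
            )
        )
    return wells


def assign_frames_to_wells(
    wells: list[Well],
    surface: FESurface,
    projections: np.ndarray,
) -> None:
    """Attach each projection point to the well owning its grid node."""
    pts = np.asarray(projections, dtype=float)[:, :2]
    gx, gy = surface.grid_x, surface.grid_y
    ix = np.clip(np.searchsorted(gx, pts[:, 0]) - 0, 0, len(gx) - 1)
    # snap to the nearest node centre
    ix = np.clip(np.abs(pts[:, 0][:, None] - gx[None]).argmin(axis=1), 0, len(gx) - 1)
    iy = np.clip(np.abs(pts[:, 1][:, None] - gy[None]).argmin(axis=1), 0, len(gy) - 1)
    node_owner = -np.ones((len(gx), len(gy)), dtype=int)
    for w_idx, well in enumerate(wells):
        node_owner[well.basin_nodes[:, 0], well.basin_nodes[:, 1]] = w_idx
    owners = node_owner[ix, iy]
    for w_idx, well in enumerate(wells):
        well.member_frames = np.nonzero(owners == w_idx)[0]


def well_composition(
    wells: list[Well],
    source_labels: np.ndarray,
) -> dict[str, dict[str, float]]:
    """Per-well percentage of member frames contributed by each source.

    Percentages are relative to the total well population and sum to
    100 per well; empty wells are omitted with a warning.
    """
    labels = np.asarray(source_labels).astype(str)
    out: dict[str, dict[str, float]] = {}
    for well in wells:
        if len(well.member_frames) == 0:
            warnings.warn(f"{well.label} has no member frames; omitted")
            continue
        members = labels[well.member_frames]
        comp: dict[str, float] = {}
        for src in np.unique(members):
            comp[str(src)] = 100.0 * float(np.mean(members == src))
        well.composition = comp
        out[well.label] = comp
    return out
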