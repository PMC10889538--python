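"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynasome.core import Conformation, Ensemble, Topology


def dihedral(p0, p1, p2, p3) -> float:
    """Standard signed dihedral (degrees), independent of the builder."""
    b0 = -(np.asarray(p1) - np.asarray(p0))
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(
        np.degrees(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))
    )


def point_topology(n: int, name: str = "CA", resname: str = "ALA") -> Topology:
    """Minimal n-atom topology of identical pseudo-atoms."""
    return Topology(
        names=[name] * n,
        elements=["C"] * n,
        resids=np.arange(1, n + 1),
        resnames=[resname] * n,
    )


def grid_search_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Brute-force rotation-grid RMSD oracle.

    Coarse 10° Euler grid, then local refinement of the best basins
    down to 0.05°; translation is handled exactly by centroid
    alignment.  Independent of the analytic Kabsch path.
    """
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)

    def rms_on(grid: np.ndarray) -> np.ndarray:
        R = Rotation.from_euler("zyx", grid, degrees=True).as_matrix()
        fit = np.einsum("gij,nj->gni", R, mc)
        return np.sqrt(np.mean(np.sum((fit - rc) ** 2, axis=2), axis=1))

    coarse = (
        np.array(
            np.meshgrid(
                np.arange(0, 360, 10), np.arange(-90, 91, 10), np.arange(0, 360, 10)
            )
        )
        .reshape(3, -1)
        .T
    )
    rms = rms_on(coarse)
    best = np.inf
    for seed in coarse[np.argsort(rms)[:32]]:
        a, b, c = seed
        r = None
        for step in (5.0, 1.0, 0.2, 0.05):
            local = (
                np.array(
                    np.meshgrid(
                        a + np.arange(-2 * step, 2 * step + 1e-9, step),
                        b + np.arange(-2 * step, 2 * step + 1e-9, step),
                        c + np.arange(-2 * step, 2 * step + 1e-9, step),
                    )
                )
                .reshape(3, -1)
                .T
            )
            lr = rms_on(local)
            k = int(np.argmin(lr))
            (a, b, c), r = local[k], float(lr[k])
        best = min(best, r)
    return best


@pytest.fixture(scope="session")
def alpha_helix():
    from dynasome.synthetic import build_ideal_helix

    return build_ideal_helix(12, "alpha")


@pytest.fixture(scope="session")
def two_domain_toy():
    from dynasome.synthetic import build_two_domain_toy

    return build_two_domain_toy(4, 45, seed=0)


@pytest.fixture()
def random_ensemble():
    """30 jittered frames around a random 20-atom structure."""
    rng = np.random.default_rng(7)
    topo = point_topology(20)
    base = rng.normal(0, 5, (20, 3))
    coords = base[None] + rng.normal(0, 0.3, (30, 20, 3))
    return Ensemble(topo, coords)
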