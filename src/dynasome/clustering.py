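"""Ensemble-based RMSD clustering of conformations.

The reference-picking procedure: (i) a random remaining frame becomes a
reference and every frame within the cutoff r (RMSD on the selection)
is removed, repeated until the ensemble is exhausted — references end
up pairwise more than r apart; (ii) every frame is assigned to its
nearest reference, frames farther than r from all references stay
unassigned (coverage < 1).  Clusters are renamed C1, C2, … by
decreasing population.

RMSD here is computed in the shared frame of the pre-fitted ensemble
(fit the ensemble on the stable domain first, then cluster the mobile
region), mirroring how disordered-loop conformations are compared after
removing rigid-body motion of the scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Ensemble


@dataclass
class ClusterResult:
    cutoff: float  # Å
    references: list[int]  # frame indices, in pick order
    labels: np.ndarray  # per-frame cluster id (0 = C1); -1 unassigned
    populations: np.ndarray  # fraction per cluster (of all frames)
    medoids: list[int]  # frame index per cluster
    coverage: float  # fraction of frames assigned

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def _pairwise_rmsd_to(
    coords: np.ndarray, ref: np.ndarray
) -> np.ndarray:
    """RMSD of each frame (F, n, 3) to one reference (n, 3), no refit."""
    diff = coords - ref[None, :, :]
    return np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))


def reference_cluster(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    cutoff: float = 4.0,
    seed: int = 0,
) -> ClusterResult:
    """Reference-based RMSD clustering at a fixed cutoff (Å).

    The ensemble must already be superposed onto a common frame (e.g.
    fitted on the stable domain); the random reference choice is made
    reproducible through ``seed``.  Equidistant frames break ties
    toward the earlier-picked reference.
    """
    if ensemble.n_frames == 0:
        raise ValueError("cannot cluster an empty ensemble")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    coords = ensemble.coordinates[:, sel, :]
    n = ensemble.n_frames
    rng = np.random.default_rng(seed)

    # phase (i): random references, removal within cutoff
    remaining = np.arange(n)
    references: list[int] = []
    while len(remaining):
        pick = int(remaining[rng.integers(len(remaining))])
        references.append(pick)
        d = _pairwise_rmsd_to(coords[remaining], coords[pick])
        remaining = remaining[d > cutoff]

    # phase (ii): nearest-reference assignment
    dists = np.stack([_pairwise_rmsd_to(coords, coords[r]) for r in references])
    nearest = np.argmin(dists, axis=0)  # argmin → earliest reference on ties
    mindist = dists[nearest, np.arange(n)]
    labels_ref = np.where(mindist <= cutoff, nearest, -1)

    # rename clusters by population
    assigned = labels_ref >= 0
    counts = np.bincount(labels_ref[assigned], minlength=len(references))
    order = np.argsort(-counts, kind="stable")
    keep = [int(o) for o in order if counts[o] > 0]
    remap = {old: new for new, old in enumerate(keep)}
    labels = np.array(
        [remap[int(l)] if l >= 0 and int(l) in remap else -1 for l in labels_ref]
    )
    populations = counts[keep] / n
    medoids = [
        medoid(ensemble, np.nonzero(labels == c)[0], sel) for c in range(len(keep))
    ]
    return ClusterResult(
        cutoff=float(cutoff),
        references=[references[k] for k in keep],
        labels=labels,
        populations=populations,
        medoids=medoids,
        coverage=float(np.mean(assigned)),
    )


def cutoff_sweep(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    r_min: float = 2.4,
    r_max: float = 7.0,
    step: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster at every cutoff in [r_min, r_max] (default 2.4–7.0 Å in
    0.2 Å steps) and tabulate cluster count and coverage; the 4.0 Å
    operating point is flagged."""
    if r_min >= r_max:
        raise ValueError("r_min must be below r_max")
    cutoffs = np.round(np.arange(r_min, r_max + 1e-9, step), 10)
    rows = []
    for r in cutoffs:
        res = reference_cluster(ensemble, selection, cutoff=float(r), seed=seed)
        rows.append(
            {
                "cutoff": float(r),
                "n_clusters": res.n_clusters,
                "coverage": res.coverage,
                "largest_population": float(res.populations[0]),
                "operating_point": bool(abs(r - 4.0) < 1e-9),
            }
        )
    return pd.DataFrame(rows)


def medoid(
    ensemble: Ensemble,
    members: np.ndarray,
    selection: np.ndarray | None = None,
    max_exhaustive: int = 2000,
    seed: int = 0,
) -> int:
    """Frame minimising mean RMSD to the other members of its cluster.

    Exhaustive for ≤ ``max_exhaustive`` members; above that the mean is
    estimated on a random subsample of the members.  Ties break to the
    lowest frame index.
    """
    members = np.asarray(members, dtype=int)
    if len(members) == 0:
        raise ValueError("medoid of an empty member set")
    if len(members) == 1:
        return int(members[0])
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    coords = ensemble.coordinates[:, sel, :]
    if len(members) > max_exhaustive:
        rng = np.random.default_rng(seed)
        targets = rng.choice(members, size=max_exhaustive, replace=False)
    else:
        targets = members
    target_xyz = coords[targets]
    best_idx, best_mean = int(members[0]), np.inf
    for m in members:
        d = _pairwise_rmsd_to(target_xyz, coords[m])
        mean = float(np.mean(d))
        if mean < best_mean - 1e-12:
            best_mean, best_idx = mean, int(m)
    return best_idx
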