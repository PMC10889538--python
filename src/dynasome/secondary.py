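"""Secondary-structure assignment and folding-pattern clustering.

Assignment reimplements the DSSP scheme: backbone H-bonds are scored
with the Kabsch–Sander electrostatic energy

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  [kcal/mol]

with a bond when E < −0.5 kcal/mol, and helices/strands are derived
from the i→i+3/4/5 turn and bridge patterns.  The 8-letter alphabet is
reduced to {none, α-helix, 3₁₀-helix, π-helix, strand} for ensemble
clustering, which uses the Jaccard distance between (residue, letter)
sets, complete-linkage trees pruned over a fixed distance sweep, and
silhouette-based cut selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .core import Conformation, Ensemble, Topology

KS_COUPLING = 0.084 * 332.0  # kcal/mol·Å, Kabsch–Sander prefactor
KS_BOND_ENERGY = -0.5  # kcal/mol
CHAIN_BREAK_CN = 2.5  # Å, peptide C–N beyond this is a break
N_H_BOND_LENGTH = 1.01  # Å, reconstructed amide H

FULL_ALPHABET = ("H", "G", "I", "E", "B", "T", "S", "C")
REDUCED_OF_FULL = {
    "H": "alpha",
    "G": "three_ten",
    "I": "pi",
    "E": "strand",
    "B": "none",
    "T": "none",
    "S": "none",
    "C": "none",
}
HELICAL_REDUCED = {"alpha", "three_ten", "pi"}


@dataclass
class SSAssignment:
    """Per-residue secondary structure of one conformation."""

    residue_ids: np.ndarray
    full: np.ndarray  # letters from FULL_ALPHABET
    reduced: np.ndarray  # letters from {none, alpha, three_ten, pi, strand}

    def __post_init__(self) -> None:
        if len(self.full) != len(self.residue_ids) or len(self.reduced) != len(
            self.residue_ids
        ):
            raise ValueError("assignment arrays must share the residue count")

    @property
    def full_string(self) -> str:
        return "".join(self.full)


@dataclass
class SSClusterResult:
    labels: np.ndarray  # per-frame cluster id, 0-based by size
    pruning_distance: float
    silhouette_by_distance: dict[float, float | None]
    silhouette: float | None
    consensus: dict[int, list[str]]  # cluster -> per-residue reduced letters


def _backbone_arrays(
    conformation: Conformation, topology: Topology
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Per-residue N/CA/C/O/H coordinate arrays (nan where missing)."""
    res_ids = topology.residue_ids
    pos = {k: np.full((len(res_ids), 3), np.nan) for k in ("N", "CA", "C", "O", "H")}
    index_of = {int(r): i for i, r in enumerate(res_ids)}
    for i in range(topology.n_atoms):
        name = str(topology.names[i])
        if name in pos:
            pos[name][index_of[int(topology.resids[i])]] = conformation.coordinates[i]
    has_h = ~np.isnan(pos["H"][:, 0])
    # reconstruct missing amide H: 1.01 Å from N, anti-bisecting C(prev)–N–Cα
    for i in range(1, len(res_ids)):
        if has_h[i]:
            continue
        if np.isnan(pos["N"][i, 0]) or np.isnan(pos["C"][i - 1, 0]) or np.isnan(
            pos["CA"][i, 0]
        ):
            continue
        if np.linalg.norm(pos["N"][i] - pos["C"][i - 1]) > CHAIN_BREAK_CN:
            continue
        u = pos["N"][i] - pos["C"][i - 1]
        v = pos["N"][i] - pos["CA"][i]
        d = u / np.linalg.norm(u) + v / np.linalg.norm(v)
        pos["H"][i] = pos["N"][i] + N_H_BOND_LENGTH * d / np.linalg.norm(d)
    return res_ids, pos, has_h


def _chain_breaks(pos: dict[str, np.ndarray]) -> np.ndarray:
    """break[i] is True when the peptide bond i -> i+1 is absent."""
    n = len(pos["N"])
    breaks = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        c, nn = pos["C"][i], pos["N"][i + 1]
        if np.any(np.isnan(c)) or np.any(np.isnan(nn)):
            breaks[i] = True
        elif np.linalg.norm(nn - c) > CHAIN_BREAK_CN:
            breaks[i] = True
    return breaks


def kabsch_sander_hbonds(
    conformation: Conformation, topology: Topology | None = None
) -> np.ndarray:
    """Boolean matrix: hbond[i, j] — CO of residue i accepts the NH of
    residue j with Kabsch–Sander energy below −0.5 kcal/mol."""
    topo = topology if topology is not None else conformation.topology
    res_ids, pos, _ = _backbone_arrays(conformation, topo)
    n = len(res_ids)
    breaks = _chain_breaks(pos)
    hb = np.zeros((n, n), dtype=bool)
    for i in range(n):  # acceptor CO
        C, O = pos["C"][i], pos["O"][i]
        if np.any(np.isnan(C)) or np.any(np.isnan(O)):
            continue
        for j in range(n):  # donor NH
            if j == i or j == i + 1:  # self and the covalently linked NH
                continue
            N, H = pos["N"][j], pos["H"][j]
            if np.any(np.isnan(N)) or np.any(np.isnan(H)):
                continue
            r_on = np.linalg.norm(O - N)
            if r_on > 7.0:  # beyond any plausible bond; skip the rest
                continue
            r_ch = np.linalg.norm(C - H)
            r_oh = np.linalg.norm(O - H)
            r_cn = np.linalg.norm(C - N)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            energy = KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < KS_BOND_ENERGY:
                hb[i, j] = True
    # no turn patterns across chain breaks are formed downstream; bonds
    # themselves may span chains (sheets)
    return hb


def assign_secondary_structure(
    conformation: Conformation, topology: Topology | None = None
) -> SSAssignment:
    """DSSP-style assignment over the 8-letter alphabet, reduced to the
    5-letter ensemble alphabet."""
    topo = topology if topology is not None else conformation.topology
    res_ids, pos, _ = _backbone_arrays(conformation, topo)
    n = len(res_ids)
    hb = kabsch_sander_hbonds(conformation, topo)
    breaks = _chain_breaks(pos)

    def contiguous(i: int, j: int) -> bool:
        """No chain break between residues i..j (inclusive)."""
        if i < 0 or j > n - 1:
            return False
        return not np.any(breaks[i:j])

    turn = {m: np.zeros(n, dtype=bool) for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if hb[i, i + m] and contiguous(i, i + m):
                turn[m][i] = True

    letters = np.full(n, "C", dtype="U1")

    def mark_helix(m: int, letter: str) -> None:
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i]:
                for k in range(i, i + m):
                    if letters[k] == "C" or letters[k] in ("T", "S"):
                        letters[k] = letter

    # bridges / ladders
    bridge = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para or anti:
                bridge[i, j] = bridge[j, i] = True

    is_bridge = bridge.any(axis=1)
    # priority: H, then ladders (E), then G, I, then T, S
    mark_helix(4, "H")
    for i in range(n):
        if is_bridge[i] and letters[i] == "C":
            # part of a ladder when an adjacent residue also bridges
            if (i > 0 and is_bridge[i - 1]) or (i < n - 1 and is_bridge[i + 1]):
                letters[i] = "E"
            else:
                letters[i] = "B"
    mark_helix(3, "G")
    mark_helix(5, "I")
    # turns: interior residues of any n-turn
    for m in (3, 4, 5):
        for i in range(n - m):
            if turn[m][i]:
                for k in range(i + 1, i + m):
                    if letters[k] == "C":
                        letters[k] = "T"
    # bends: backbone curvature above 70 degrees
    ca = pos["CA"]
    for i in range(2, n - 2):
        if letters[i] != "C":
            continue
        if not contiguous(i - 2, i + 2):
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        if np.any(np.isnan(u)) or np.any(np.isnan(v)):
            continue
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            letters[i] = "S"

    reduced = np.array([REDUCED_OF_FULL[let] for let in letters], dtype="U9")
    return SSAssignment(residue_ids=res_ids, full=letters, reduced=reduced)


def reduce_alphabet(full_letters: np.ndarray | str) -> np.ndarray:
    """Map 8-letter DSSP symbols onto the 5-letter ensemble alphabet."""
    arr = np.array(list(full_letters), dtype="U1")
    out = np.empty(len(arr), dtype="U9")
    for i, let in enumerate(arr):
        if let not in REDUCED_OF_FULL:
            raise ValueError(f"unknown DSSP letter {let!r}")
        out[i] = REDUCED_OF_FULL[let]
    return out


def helical_content(
    assignment: SSAssignment, region: tuple[int, int] | None = None
) -> float:
    """Percentage of residues in the region assigned any helix type."""
    mask = np.ones(len(assignment.residue_ids), dtype=bool)
    if region is not None:
        a, b = region
        mask = (assignment.residue_ids >= a) & (assignment.residue_ids <= b)
    if not np.any(mask):
        raise ValueError("empty region for helical content")
    helical = np.isin(assignment.reduced[mask], list(HELICAL_REDUCED))
    return 100.0 * float(np.mean(helical))


def ss_distance(a: SSAssignment, b: SSAssignment) -> float:
    """Jaccard distance between the structured (residue, letter) sets.

    Both sets empty (fully unstructured pair) gives distance 0.
    """
    if len(a.residue_ids) != len(b.residue_ids):
        raise ValueError("assignments must cover the same residues")
    sa = {
        (int(r), str(let))
        for r, let in zip(a.residue_ids, a.reduced)
        if let != "none"
    }
    sb = {
        (int(r), str(let))
        for r, let in zip(b.residue_ids, b.reduced)
        if let != "none"
    }
    union = sa | sb
    if not union:
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def assign_ensemble(ensemble: Ensemble) -> list[SSAssignment]:
    return [assign_secondary_structure(f, ensemble.topology) for f in ensemble]


def cluster_by_ss(
    assignments: list[SSAssignment],
    distances: np.ndarray | None = None,
    sweep: np.ndarray | None = None,
) -> SSClusterResult:
    """Complete-linkage clustering of conformations by folding pattern.

    The tree is pruned at every distance in {0.05, 0.10, …, 1.00}; the
    cut maximising the silhouette score (ties → smaller distance) is
    returned.  Identical assignments collapse to one cluster with an
    undefined silhouette.
    """
    n = len(assignments)
    if n < 3:
        raise ValueError("need at least 3 conformations to cluster")
    if distances is None:
        distances = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                distances[i, j] = distances[j, i] = ss_distance(
                    assignments[i], assignments[j]
                )
    if sweep is None:
        sweep = np.round(np.arange(0.05, 1.0 + 1e-9, 0.05), 2)
    condensed = squareform(distances, checks=False)
    if np.all(condensed == 0):
        consensus = {0: _consensus(assignments, np.zeros(n, dtype=int), 0)}
        return SSClusterResult(
            labels=np.zeros(n, dtype=int),
            pruning_distance=float(sweep[0]),
            silhouette_by_distance={float(d): None for d in sweep},
            silhouette=None,
            consensus=consensus,
        )
    tree = linkage(condensed, method="complete")
    scores: dict[float, float | None] = {}
    best_d, best_s, best_labels = None, -np.inf, None
    for d in sweep:
        raw = fcluster(tree, t=d, criterion="distance")
        k = len(np.unique(raw))
        if 2 <= k <= n - 1:
            s = float(silhouette_score(distances, raw, metric="precomputed"))
        else:
            s = None
        scores[float(d)] = s
        if s is not None and s > best_s:
            best_d, best_s, best_labels = float(d), s, raw
    if best_labels is None:  # every cut degenerate: single cluster
        labels = np.zeros(n, dtype=int)
        consensus = {0: _consensus(assignments, labels, 0)}
        return SSClusterResult(
            labels=labels,
            pruning_distance=float(sweep[-1]),
            silhouette_by_distance=scores,
            silhouette=None,
            consensus=consensus,
        )
    labels = _relabel_by_size(best_labels)
    consensus = {
        c: _consensus(assignments, labels, c) for c in np.unique(labels)
    }
    return SSClusterResult(
        labels=labels,
        pruning_distance=best_d,
        silhouette_by_distance=scores,
        silhouette=best_s,
        consensus=consensus,
    )


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(r)] for r in raw], dtype=int)


def _consensus(
    assignments: list[SSAssignment], labels: np.ndarray, cluster: int
) -> list[str]:
    members = [a for a, l in zip(assignments, labels) if l == cluster]
    n_res = len(members[0].residue_ids)
    out = []
    for pos in range(n_res):
        letters, counts = np.unique(
            [str(m.reduced[pos]) for m in members], return_counts=True
        )
        out.append(str(letters[np.argmax(counts)]))
    return out
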