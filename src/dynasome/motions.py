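"""Collective motions: Cartesian PCA and cross-correlation maps.

PCA is computed by SVD of the centred frame × coordinate matrix after
an iterative least-squares fit of all frames to their average structure
(fit, re-average, repeat until the average is stable).  Eigenvalue k is
s_k²/(F−1) in Å²; mode vectors are orthonormal 3N-component directions.
Two selection presets mirror common practice: full backbone
(N, H, Cα, C, O) for single-protein analyses and Cα-only for
cross-protein merges, where mutants share only the backbone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Conformation, Ensemble
from .geometry import _kabsch, fit_ensemble

BACKBONE_PRESET = ("N", "H", "CA", "C", "O")
CA_PRESET = ("CA",)


@dataclass
class PCAModel:
    selection: np.ndarray  # atom indices the model was built on
    mean: np.ndarray  # (n_sel, 3) Å, converged average structure
    modes: np.ndarray  # (n_modes, 3·n_sel), orthonormal rows
    eigenvalues: np.ndarray  # Å², non-increasing
    explained_variance: np.ndarray  # fractions summing to 1
    cumulative_variance: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # (n, n) in [-1, 1], unit diagonal
    residue_ids: np.ndarray


def _fit_to_average(
    coords: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively superpose frames onto their mean until it is stable.

    Returns (fitted coordinates, converged mean)."""
    fitted = coords.copy()
    ref = fitted[0]
    for _ in range(max_iter):
        for i in range(len(fitted)):
            R, t = _kabsch(fitted[i], ref)
            fitted[i] = fitted[i] @ R.T + t
        mean = fitted.mean(axis=0)
        if np.max(np.linalg.norm(mean - ref, axis=1)) <= tol:
            ref = mean
            break
        ref = mean
    return fitted, ref


def pca(
    ensemble: Ensemble, selection: np.ndarray | None = None, fit: bool = True
) -> PCAModel:
    """Cartesian PCA of the selected atoms.

    Frames are fitted to the converged average conformation (skip with
    ``fit=False`` for pre-fitted coordinates); the SVD of the centred
    (F × 3N) matrix yields modes and eigenvalues λ_k = s_k²/(F−1).
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    if ensemble.n_frames < len(sel) / 3:
        warnings.warn(
            f"only {ensemble.n_frames} frames for {len(sel)} atoms; "
            "the mode spectrum will be rank-deficient"
        )
    coords = ensemble.coordinates[:, sel, :]
    if fit:
        fitted, mean = _fit_to_average(coords)
    else:
        fitted, mean = coords, coords.mean(axis=0)
    X = (fitted - mean[None]).reshape(len(fitted), -1)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigenvalues = s**2 / (len(fitted) - 1)
    total = eigenvalues.sum()
    explained = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return PCAModel(
        selection=sel,
        mean=mean,
        modes=vt,
        eigenvalues=eigenvalues,
        explained_variance=explained,
        cumulative_variance=np.cumsum(explained),
    )


def project(
    ensemble: Ensemble, model: PCAModel, n_modes: int = 3, fit: bool = True
) -> np.ndarray:
    """Per-frame coordinates along the leading modes (frames are fitted
    to the model mean first).  Shape (F, n_modes); source labels stay on
    the ensemble."""
    sel = model.selection
    if ensemble.n_atoms <= int(sel.max()):
        raise ValueError("ensemble does not contain the model's selection")
    coords = ensemble.coordinates[:, sel, :]
    if coords.shape[1] != model.mean.shape[0]:
        raise ValueError("selection size differs from the PCA model")
    n_modes = min(n_modes, model.n_modes)
    out = np.empty((len(coords), n_modes))
    for i in range(len(coords)):
        if fit:
            R, t = _kabsch(coords[i], model.mean)
            dx = (coords[i] @ R.T + t - model.mean).ravel()
        else:
            dx = (coords[i] - model.mean).ravel()
        out[i] = model.modes[:n_modes] @ dx
    return out


def mode_displacements(
    model: PCAModel, mode: int, amplitude_threshold: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-atom displacement arrows for one mode (porcupine data).

    The arrow for atom i is the mode direction scaled by √λ (one
    standard deviation of the collective motion).  Returns
    (arrows for all atoms, amplitudes, indices with amplitude ≥
    threshold) — the export filter keeps all atoms internally.
    """
    if not (0 <= mode < model.n_modes):
        raise ValueError(f"mode {mode} outside 0..{model.n_modes - 1}")
    arrows = model.modes[mode].reshape(-1, 3) * np.sqrt(model.eigenvalues[mode])
    amplitudes = np.linalg.norm(arrows, axis=1)
    exported = np.nonzero(amplitudes >= amplitude_threshold)[0]
    return arrows, amplitudes, exported


def cross_correlation(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> CorrelationMatrix:
    """Dynamic cross-correlation of atomic displacements.

        C_ij = ⟨Δr_i · Δr_j⟩ / sqrt(⟨Δr_i²⟩ ⟨Δr_j²⟩)

    computed after fitting the ensemble to its first frame on the
    selection (default: Cα atoms).  Zero-variance atoms get zero rows
    with a unit diagonal.
    """
    topo = ensemble.topology
    sel = topo.select(names=["CA"]) if selection is None else np.asarray(selection)
    work = fit_ensemble(ensemble, selection=sel) if fit else ensemble
    xyz = work.coordinates[:, sel, :]
    dx = xyz - xyz.mean(axis=0)
    inner = np.einsum("fik,fjk->ij", dx, dx) / len(dx)
    var = np.diag(inner).copy()
    zero = var <= 1e-14
    if np.any(zero):
        warnings.warn(f"{zero.sum()} zero-variance atoms in correlation matrix")
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = inner / denom
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(values=C, residue_ids=topo.resids[sel])


def residue_correlation_profile(
    matrix: CorrelationMatrix, residue: int
) -> np.ndarray:
    """The correlation row of one residue against all others."""
    pos = np.nonzero(matrix.residue_ids == residue)[0]
    if len(pos) == 0:
        raise ValueError(f"residue {residue} not in the correlation matrix")
    return matrix.values[pos[0]]
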