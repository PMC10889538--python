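"""Rigid-body superposition and basic structural descriptors.

All fits are unweighted least squares on a stated atom selection
(Kabsch).  RMSD, RMSF and the radius of gyration follow the standard MD
definitions; the radius of gyration is mass-weighted over non-hydrogen
atoms by default:

    Rg = sqrt( sum_i m_i |r_i - r_com|^2 / sum_i m_i )
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Conformation, Ensemble


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation, Å
    rmsd: float  # Å, on the fitted selection


@dataclass
class HelixAxis:
    start_point: np.ndarray  # Cα of first helix residue, Å
    end_point: np.ndarray  # Cα of last helix residue, Å
    direction: np.ndarray  # unit vector end - start
    time: float = 0.0


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimising |R·x + t − ref|²."""
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    return R, t


def superpose(
    mobile: Conformation,
    reference: Conformation,
    selection: np.ndarray | None = None,
) -> tuple[SuperpositionResult, Conformation]:
    """Least-squares fit of ``mobile`` onto ``reference``.

    The fit is computed on the selection (all atoms when ``None``) and
    applied to the whole conformation.  The returned RMSD is the global
    minimum over rigid motions for the selection.
    """
    sel = (
        np.arange(mobile.topology.n_atoms) if selection is None else np.asarray(selection)
    )
    if len(sel) < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    x = mobile.coordinates[sel]
    y = reference.coordinates[sel]
    if x.shape != y.shape:
        raise ValueError("selection must map one-to-one between structures")
    centered = x - x.mean(axis=0)
    # collinear selections leave a rotational degree of freedom undetermined
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; fit is ill-defined")
    R, t = _kabsch(x, y)
    fitted_sel = x @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted_sel - y) ** 2, axis=1))))
    fitted = Conformation(
        mobile.topology,
        mobile.coordinates @ R.T + t,
        time=mobile.time,
        source_label=mobile.source_label,
    )
    return SuperpositionResult(R, t, rmsd), fitted


def rmsd_value(
    a: np.ndarray, b: np.ndarray, fit: bool = True
) -> float:
    """RMSD between two coordinate sets, optionally after a Kabsch fit."""
    if fit:
        R, t = _kabsch(a, b)
        a = a @ R.T + t
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fit_ensemble(
    ensemble: Ensemble,
    reference: Conformation | None = None,
    selection: np.ndarray | None = None,
) -> Ensemble:
    """Superpose every frame onto ``reference`` (default: frame 0) using
    the selection; the transform is applied to all atoms."""
    ref = reference if reference is not None else ensemble.frame(0)
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    out = ensemble.copy()
    ref_xyz = ref.coordinates[sel]
    for i in range(out.n_frames):
        R, t = _kabsch(out.coordinates[i, sel], ref_xyz)
        out.coordinates[i] = out.coordinates[i] @ R.T + t
    return out


def rmsd_series(
    ensemble: Ensemble,
    reference: Conformation,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame least-squares RMSD (Å) to a reference structure."""
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    ref = reference.coordinates[sel]
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        out[i] = rmsd_value(ensemble.coordinates[i, sel], ref, fit=True)
    return out


def rmsf(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    fit: bool = True,
) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the ensemble mean.

    Frames are first fitted to frame 0 on the selection (removing
    rigid-body motion), then RMSF_i = sqrt(<|r_i - <r_i>|²>).
    """
    sel = (
        np.arange(ensemble.n_atoms) if selection is None else np.asarray(selection)
    )
    if ensemble.n_frames < 2:
        warnings.warn("single-frame ensemble: RMSF is identically zero")
        return np.zeros(len(sel))
    fitted = fit_ensemble(ensemble, selection=sel) if fit else ensemble
    xyz = fitted.coordinates[:, sel, :]
    mean = xyz.mean(axis=0)
    return np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(
    conformation: Conformation, selection: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration (Å).

    Default selection: all non-hydrogen atoms.  Distances are taken from
    the selection's centre of mass.
    """
    topo = conformation.topology
    sel = topo.select(heavy=True) if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise ValueError("empty selection for radius of gyration")
    m = topo.masses[sel]
    r = conformation.coordinates[sel]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    d2 = np.sum((r - com) ** 2, axis=1)
    return float(np.sqrt((m * d2).sum() / m.sum()))


def rg_series(ensemble: Ensemble, selection: np.ndarray | None = None) -> np.ndarray:
    return np.array(
        [radius_of_gyration(f, selection) for f in ensemble]
    )


def helix_axis_drift(
    ensemble: Ensemble,
    helix: str | tuple[int, int],
    projection_frame: Conformation | None = None,
    fit_selection: np.ndarray | None = None,
) -> list[HelixAxis]:
    """Helix axis (line through the first and last Cα of the helix) for
    every frame, after superposing the ensemble onto a projection frame.

    Use :func:`extend_axis_for_display` to obtain the +50 %-elongated
    endpoints used for rendering; the stored direction is unextended.
    """
    topo = ensemble.topology
    a, b = topo._resolve_range(helix)
    ca = topo.select(names=["CA"], region=(a, b))
    if len(ca) < 2:
        raise ValueError(f"helix range {a}-{b} needs at least 2 Cα atoms")
    first, last = ca[0], ca[-1]
    ref = projection_frame if projection_frame is not None else ensemble.frame(0)
    fitted = fit_ensemble(ensemble, reference=ref, selection=fit_selection)
    axes: list[HelixAxis] = []
    for i in range(fitted.n_frames):
        p0 = fitted.coordinates[i, first]
        p1 = fitted.coordinates[i, last]
        v = p1 - p0
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            warnings.warn(f"frame {i}: coincident helix endpoints; skipped")
            continue
        axes.append(
            HelixAxis(p0.copy(), p1.copy(), v / norm, time=float(fitted.times[i]))
        )
    return axes


def extend_axis_for_display(axis: HelixAxis, fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints elongated by ``fraction`` of the length at each end
    (default +50 % total), for rendering only."""
    v = axis.end_point - axis.start_point
    return axis.start_point - fraction * v, axis.end_point + fraction * v


def density_profile(
    values: np.ndarray,
    grid_min: float | None = None,
    grid_max: float | None = None,
    bin_width: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised probability density on a fixed-width histogram grid.

    Returns (bin centres, density); the density integrates to 1 over the
    grid.  Fixed-width histograms keep the profile deterministic.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a density profile")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = values.min() if grid_min is None else grid_min
    hi = values.max() if grid_max is None else grid_max
    if hi <= lo:
        hi = lo + bin_width  # constant sample: single-bin spike
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
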