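"""Reading, writing and reshaping conformational ensembles.

Multi-model PDB (MODEL/ENDMDL) is the interchange format; a plain
columnar text trajectory (one row per atom per frame) is supported for
synthetic data.  PDB parsing and formatting are delegated to biotite.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .core import Conformation, Ensemble, Topology, mass_of_element


class FormatError(ValueError):
    """Raised for malformed or inconsistent structure files."""


def read_multi_model_pdb(
    path: str | Path,
    source_label: str = "WT",
    stride: float = 100.0,
    regions: dict[str, tuple[int, int]] | None = None,
    helix_definitions: dict[str, tuple[int, int]] | None = None,
) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL record; a file without MODEL records yields a
    single-frame ensemble.  Atom order must be identical across models.
    Masses are assigned from the element column (or inferred from the
    atom name when the element column is blank).
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FormatError(f"inconsistent models in {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise FormatError(f"{path} contains no atoms")

    elements = []
    for el, name in zip(stack.element, stack.atom_name):
        el = str(el).strip().upper()
        if not el:
            from .core import element_from_name

            el = element_from_name(str(name))
        elements.append(el)
    topology = Topology(
        names=[str(n) for n in stack.atom_name],
        elements=elements,
        resids=stack.res_id,
        resnames=[str(r) for r in stack.res_name],
        chains=[str(c) if str(c).strip() else "A" for c in stack.chain_id],
        masses=[mass_of_element(e) for e in elements],
        regions=regions,
        helix_definitions=helix_definitions,
    )
    coords = np.asarray(stack.coord, dtype=float)
    return Ensemble(topology, coords, source_labels=source_label, stride=stride)


def write_multi_model_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as MODEL/ENDMDL records with 3-decimal coordinates."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    topo = ensemble.topology
    n = topo.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.zeros((n, 3), dtype=np.float32)
    array.atom_name = topo.names.astype("U6")
    array.element = topo.elements.astype("U2")
    array.res_id = topo.resids
    array.res_name = topo.resnames.astype("U3")
    array.chain_id = topo.chains.astype("U4")
    array.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([array] * ensemble.n_frames)
    stack.coord = ensemble.coordinates.astype(np.float32)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_columnar_trajectory(ensemble: Ensemble, path: str | Path) -> None:
    """Plain-text trajectory: frame, time_ps, serial, x, y, z (one row
    per atom per frame).  Requires a separately stored topology."""
    if ensemble.n_frames == 0:
        raise ValueError("cannot write an empty ensemble")
    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    frame_col = np.repeat(np.arange(n_frames), n_atoms)
    df = pd.DataFrame(
        {
            "frame": frame_col,
            "time_ps": np.repeat(ensemble.times, n_atoms),
            "serial": np.tile(np.arange(1, n_atoms + 1), n_frames),
            "x": ensemble.coordinates[..., 0].ravel(),
            "y": ensemble.coordinates[..., 1].ravel(),
            "z": ensemble.coordinates[..., 2].ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_columnar_trajectory(
    path: str | Path,
    topology: Topology,
    source_label: str = "WT",
    stride: float = 100.0,
) -> Ensemble:
    df = pd.read_csv(path, sep="\t")
    frames = np.unique(df["frame"].to_numpy())
    n_atoms = topology.n_atoms
    coords = np.empty((len(frames), n_atoms, 3), dtype=float)
    times = np.empty(len(frames), dtype=float)
    for k, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("serial")
        if len(sub) != n_atoms:
            raise FormatError(
                f"frame {f} has {len(sub)} atoms, topology has {n_atoms}"
            )
        coords[k] = sub[["x", "y", "z"]].to_numpy()
        times[k] = sub["time_ps"].iloc[0]
    return Ensemble(topology, coords, times, source_label, stride=stride)


def concatenate(
    ensembles: Sequence[Ensemble], labels: Sequence[str] | None = None
) -> Ensemble:
    """Merge ensembles frame-wise, keeping per-frame source labels.

    All inputs must share the same atom names and order.  Cross-protein
    merges (mutants differ in side chains) should therefore be done on a
    backbone or Cα atom subset via :meth:`Ensemble.subset_atoms` first.
    Times are offset so that they remain strictly increasing within each
    relabelled source.
    """
    if not ensembles:
        raise ValueError("nothing to concatenate")
    if labels is not None and len(labels) != len(ensembles):
        raise ValueError("one label per ensemble required")
    ref = ensembles[0].topology
    for e in ensembles[1:]:
        if e.topology != ref:
            raise ValueError(
                "topology mismatch: ensembles must share atom names/order "
                "(select a common backbone/CA subset before merging)"
            )
    if len(ensembles) == 1 and labels is None:
        return ensembles[0]
    coords = np.concatenate([e.coordinates for e in ensembles], axis=0)
    times = np.concatenate([e.times for e in ensembles])
    if labels is None:
        src = np.concatenate([e.source_labels for e in ensembles])
    else:
        src = np.concatenate(
            [np.full(e.n_frames, lab, dtype=object) for e, lab in zip(ensembles, labels)]
        )
    # de-duplicate times within each label so the per-source ordering stays strict
    out_times = times.copy()
    for lab in np.unique(src.astype(str)):
        mask = src.astype(str) == lab
        t = out_times[mask]
        for i in range(1, len(t)):
            if t[i] <= t[i - 1]:
                t[i:] += t[i - 1] - t[i] + ensembles[0].stride
        out_times[mask] = t
    return Ensemble(ref, coords, out_times, list(src), stride=ensembles[0].stride)


def stride_sample(ensemble: Ensemble, step: float) -> Ensemble:
    """Keep frames every ``step`` ps; ``step`` must be a multiple of the
    current recording interval."""
    if step < ensemble.stride:
        raise ValueError(
            f"step {step} ps is smaller than the recording interval "
            f"{ensemble.stride} ps"
        )
    ratio = step / ensemble.stride
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"step {step} ps is not a multiple of the recording interval "
            f"{ensemble.stride} ps"
        )
    k = int(round(ratio))
    if k == 1:
        return ensemble
    pieces = []
    for lab in pd.unique(ensemble.source_labels.astype(str)):
        idx = np.nonzero(ensemble.source_labels.astype(str) == lab)[0]
        pieces.append(idx[::k])
    keep = np.sort(np.concatenate(pieces))
    out = ensemble.take_frames(keep)
    out.stride = float(step)
    return out
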