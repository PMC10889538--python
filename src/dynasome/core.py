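"""Core containers for conformational ensembles.

An :class:`Ensemble` is an ordered stack of conformations sharing one
:class:`Topology`.  Frames carry a time stamp (ps) and a source label so
that ensembles from several proteins (e.g. a wild type and its point
mutants) can be merged while remaining separable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

# Standard atomic weights (amu), sufficient for protein heavy atoms + H.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "F": 18.998,
    "CL": 35.45,
}
DEFAULT_MASS = 12.011

BACKBONE_NAMES = ("N", "CA", "C", "O", "H", "OXT")


def mass_of_element(element: str) -> float:
    """Atomic mass for an element symbol; unknown symbols fall back to
    carbon's mass with a warning."""
    key = element.strip().upper()
    if key in ELEMENT_MASSES:
        return ELEMENT_MASSES[key]
    warnings.warn(f"unknown element {element!r}; assigning default mass")
    return DEFAULT_MASS


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (leading alpha characters)."""
    stripped = name.strip()
    # two-letter elements occurring in proteins
    if stripped[:2].upper() in ("SE", "CL"):
        return stripped[:2].upper()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of the topology."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.serial}: mass must be positive")


class Topology:
    """Fixed atom ordering plus named residue ranges.

    Residue numbering is 1-based biological numbering and is never
    rewritten on read.  ``regions`` and ``helix_definitions`` map names
    (e.g. ``"L-loop"``, ``"TM1"``, ``"H1-L"``) to inclusive residue
    ranges ``(first, last)``.
    """

    def __init__(
        self,
        names: Sequence[str],
        elements: Sequence[str] | None = None,
        resids: Sequence[int] | None = None,
        resnames: Sequence[str] | None = None,
        chains: Sequence[str] | None = None,
        masses: Sequence[float] | None = None,
        regions: Mapping[str, tuple[int, int]] | None = None,
        helix_definitions: Mapping[str, tuple[int, int]] | None = None,
    ) -> None:
        n = len(names)
        self.names = np.asarray(names, dtype="U6")
        if elements is None:
            elements = [element_from_name(nm) for nm in names]
        self.elements = np.asarray(elements, dtype="U2")
        self.resids = (
            np.ones(n, dtype=int) if resids is None else np.asarray(resids, dtype=int)
        )
        self.resnames = (
            np.full(n, "UNK", dtype="U3")
            if resnames is None
            else np.asarray(resnames, dtype="U3")
        )
        self.chains = (
            np.full(n, "A", dtype="U1")
            if chains is None
            else np.asarray(chains, dtype="U1")
        )
        if masses is None:
            masses = [mass_of_element(e) for e in self.elements]
        self.masses = np.asarray(masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ValueError("all atomic masses must be positive")
        for arr in (self.elements, self.resids, self.resnames, self.chains, self.masses):
            if len(arr) != n:
                raise ValueError("topology annotation arrays must share one length")
        self.regions: dict[str, tuple[int, int]] = dict(regions or {})
        self.helix_definitions: dict[str, tuple[int, int]] = dict(
            helix_definitions or {}
        )
        self._check_ranges()

    def _check_ranges(self) -> None:
        if self.n_atoms == 0:
            return
        lo, hi = int(self.resids.min()), int(self.resids.max())
        for label, (a, b) in {**self.regions, **self.helix_definitions}.items():
            if a > b or a < lo or b > hi:
                raise ValueError(
                    f"range {label}=({a},{b}) outside sequence {lo}..{hi}"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Sorted unique residue indices."""
        return np.unique(self.resids)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=i + 1,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_index=int(self.resids[i]),
            residue_name=str(self.resnames[i]),
            chain=str(self.chains[i]),
            mass=float(self.masses[i]),
        )

    def __len__(self) -> int:
        return self.n_atoms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            np.array_equal(self.names, other.names)
            and np.array_equal(self.resids, other.resids)
            and np.array_equal(self.resnames, other.resnames)
        )

    # ------------------------------------------------------------------
    # selections
    # ------------------------------------------------------------------
    def select(
        self,
        names: Sequence[str] | None = None,
        region: str | tuple[int, int] | None = None,
        heavy: bool = False,
        elements: Sequence[str] | None = None,
        exclude_region: str | tuple[int, int] | None = None,
    ) -> np.ndarray:
        """Return atom indices matching all given filters.

        ``region`` may be a registered region name or an explicit
        inclusive ``(first, last)`` residue range.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            mask &= np.isin(self.names, list(names))
        if region is not None:
            a, b = self._resolve_range(region)
            mask &= (self.resids >= a) & (self.resids <= b)
        if exclude_region is not None:
            a, b = self._resolve_range(exclude_region)
            mask &= ~((self.resids >= a) & (self.resids <= b))
        if heavy:
            mask &= self.elements != "H"
        if elements is not None:
            mask &= np.isin(self.elements, [e.upper() for e in elements])
        return np.nonzero(mask)[0]

    def _resolve_range(self, region: str | tuple[int, int]) -> tuple[int, int]:
        if isinstance(region, str):
            if region in self.regions:
                return self.regions[region]
            if region in self.helix_definitions:
                return self.helix_definitions[region]
            raise KeyError(f"unknown region {region!r}")
        a, b = region
        return int(a), int(b)

    def ca_indices(self, region: str | tuple[int, int] | None = None) -> np.ndarray:
        return self.select(names=["CA"], region=region)

    def subset(self, indices: np.ndarray) -> "Topology":
        """Topology restricted to the given atom indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        sub_resids = self.resids[idx]
        lo, hi = (int(sub_resids.min()), int(sub_resids.max())) if len(idx) else (0, 0)

        def _clip(ranges: Mapping[str, tuple[int, int]]) -> dict[str, tuple[int, int]]:
            out = {}
            for k, (a, b) in ranges.items():
                if a <= hi and b >= lo:
                    out[k] = (max(a, lo), min(b, hi))
            return out

        return Topology(
            names=self.names[idx],
            elements=self.elements[idx],
            resids=sub_resids,
            resnames=self.resnames[idx],
            chains=self.chains[idx],
            masses=self.masses[idx],
            regions=_clip(self.regions),
            helix_definitions=_clip(self.helix_definitions),
        )


@dataclass
class Conformation:
    """One structure: per-atom coordinates in Å plus provenance."""

    topology: Topology
    coordinates: np.ndarray
    time: float = 0.0
    source_label: str = "WT"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.coordinates.shape} does not match "
                f"topology with {self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    def copy(self) -> "Conformation":
        return Conformation(
            self.topology, self.coordinates.copy(), self.time, self.source_label
        )


class Ensemble:
    """Ordered conformations sharing one topology.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)``; ``times`` is in
    ps and strictly increasing within one source; ``source_labels`` keeps
    per-frame provenance through concatenation.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        times: np.ndarray | None = None,
        source_labels: Sequence[str] | str = "WT",
        stride: float = 100.0,
    ) -> None:
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[1:] != (
            topology.n_atoms,
            3,
        ):
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        n = self.coordinates.shape[0]
        if times is None:
            times = np.arange(n, dtype=float) * stride
        self.times = np.asarray(times, dtype=float)
        if isinstance(source_labels, str):
            source_labels = [source_labels] * n
        self.source_labels = np.asarray(source_labels, dtype=object)
        if len(self.times) != n or len(self.source_labels) != n:
            raise ValueError("times/source_labels must match the frame count")
        self.stride = float(stride)
        self._check_times()

    def _check_times(self) -> None:
        for label in np.unique(self.source_labels):
            t = self.times[self.source_labels == label]
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times must be strictly increasing within source {label!r}"
                )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> Conformation:
        return Conformation(
            self.topology,
            self.coordinates[i],
            time=float(self.times[i]),
            source_label=str(self.source_labels[i]),
        )

    def __iter__(self) -> Iterator[Conformation]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def copy(self) -> "Ensemble":
        return Ensemble(
            self.topology,
            self.coordinates.copy(),
            self.times.copy(),
            list(self.source_labels),
            self.stride,
        )

    def take_frames(self, indices: Sequence[int]) -> "Ensemble":
        idx = np.asarray(indices, dtype=int)
        return Ensemble(
            self.topology,
            self.coordinates[idx],
            self.times[idx],
            list(self.source_labels[idx]),
            self.stride,
        )

    def subset_atoms(self, indices: np.ndarray) -> "Ensemble":
        idx = np.asarray(indices, dtype=int)
        return Ensemble(
            self.topology.subset(idx),
            self.coordinates[:, idx, :],
            self.times,
            list(self.source_labels),
            self.stride,
        )
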