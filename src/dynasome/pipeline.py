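"""End-to-end orchestration of the ensemble analyses.

``run_dynasome`` chains stride-sampling, fitting, descriptor
statistics, contact detection, secondary-structure and RMSD clustering,
PCA with cross-correlation and the free-energy landscape;
``run_pocketome`` runs the grid cavity tracker.  Every artefact is a
CSV/JSON file listed in a manifest that records the producing stage
and parameters.  Runs are deterministic for a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, geometry, interactions, landscape, motions, pockets, secondary
from .core import Ensemble
from .io import concatenate, read_multi_model_pdb, stride_sample
from .synthetic import (
    WellSpec,
    build_two_domain_toy,
    plant_cavity_shell,
    sample_mixture_ensemble,
)

log = logging.getLogger("dynasome")
_FLOAT_FMT = "%.6g"


@dataclass
class AnalysisConfig:
    """Declarative parameters for a full run (defaults are the
    operating points used throughout the analyses)."""

    inputs: list = field(default_factory=list)  # [{"path":…, "label":…}]
    out_dir: str = "dynasome_out"
    seed: int = 0
    stride_ps: float = 100.0
    # regions
    fit_region: str | None = None  # e.g. "TMD" / None = all atoms
    analysis_region: str | None = "L-loop"
    # H-bonds / contacts
    hbond_distance: float = 3.6
    hbond_angle: float = 90.0
    hbond_min_frequency: float = 0.6
    hydrophobic_cutoff: float = 4.0
    # clustering
    cluster_cutoff: float = 4.0
    sweep_r_min: float = 2.4
    sweep_r_max: float = 7.0
    sweep_step: float = 0.2
    # PCA / landscape
    n_projection_modes: int = 3
    porcupine_threshold: float = 2.0
    temperature: float = 310.0
    knn_k: int | None = None
    fel_grid: int = 100
    min_barrier: float = 0.5
    # pockets
    pocket_isovalue: float = 0.5
    pocket_grid_spacing: float = 0.5
    probe_radius: float = 1.4
    # synthetic fallback suite
    synthetic_frames: int = 60
    synthetic_sources: int = 3

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


class _Manifest:
    def __init__(self, out_dir: Path) -> None:
        self.out_dir = out_dir
        self.entries: list[dict] = []

    def add(self, path: Path, stage: str, params: dict) -> None:
        self.entries.append(
            {
                "artifact": path.name,
                "stage": stage,
                "parameters": {k: _jsonable(v) for k, v in params.items()},
            }
        )

    def write(self, config: AnalysisConfig) -> Path:
        payload = {
            "config": {k: _jsonable(v) for k, v in asdict(config).items()},
            "artifacts": self.entries,
        }
        path = self.out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
        return path


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return result

        return wrapped

    return deco


def _load_ensembles(config: AnalysisConfig) -> list[Ensemble]:
    if config.inputs:
        out = []
        for item in config.inputs:
            ens = read_multi_model_pdb(
                item["path"], source_label=item.get("label", Path(item["path"]).stem)
            )
            out.append(ens)
        return out
    return synthetic_suite(config)


def synthetic_suite(config: AnalysisConfig) -> list[Ensemble]:
    """Standard synthetic inputs: a two-domain toy whose disordered
    loop hops between source-specific wells."""
    topo, base = build_two_domain_toy(4, 45, seed=config.seed)
    loop_sel = topo.select(region="L-loop")
    rng = np.random.default_rng(config.seed)
    ensembles = []
    for s in range(config.synthetic_sources):
        shift = np.zeros((topo.n_atoms, 3))
        shift[loop_sel] = rng.normal(0.0, 3.0, size=3)  # per-source loop well
        center = base.coordinates + shift
        ens, _ = sample_mixture_ensemble(
            base,
            [WellSpec(center=center, population=1.0, spread=0.4)],
            n_frames=config.synthetic_frames,
            seed=config.seed + 100 + s,
            perturb_selection=loop_sel,
            stride=config.stride_ps,
            source_label=f"S{s}" if s else "WT",
        )
        ensembles.append(ens)
    return ensembles


@_stage("dynasome")
def run_dynasome(config: AnalysisConfig) -> Path:
    """Full conformational-dynamics characterisation; returns the
    manifest path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    ensembles = _load_ensembles(config)
    topo = ensembles[0].topology

    def region_sel(region):
        if region is None:
            return np.arange(topo.n_atoms)
        if region == "TMD":
            tm = [r for r in topo.regions if r.startswith("TM")]
            return np.concatenate([topo.select(region=r) for r in tm])
        return topo.select(region=region)

    fit_sel = topo.ca_indices() if config.fit_region is None else np.intersect1d(
        region_sel(config.fit_region), topo.ca_indices()
    )

    # per-source descriptor series
    rows = []
    for ens in ensembles:
        fitted = geometry.fit_ensemble(ens, selection=fit_sel)
        ref = fitted.frame(0)
        rmsd = geometry.rmsd_series(fitted, ref, selection=topo.ca_indices())
        rg = geometry.rg_series(fitted)
        label = str(ens.source_labels[0])
        for t, a, g in zip(fitted.times, rmsd, rg):
            rows.append({"source": label, "time_ps": t, "rmsd": a, "rg": g})
    df = pd.DataFrame(rows)
    p = out_dir / "descriptors.csv"
    df.to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "descriptors", {"fit_region": config.fit_region})

    # RMSF per residue, per source
    rmsf_rows = []
    ca = topo.ca_indices()
    for ens in ensembles:
        vals = geometry.rmsf(ens, selection=ca)
        label = str(ens.source_labels[0])
        for rid, v in zip(topo.resids[ca], vals):
            rmsf_rows.append({"source": label, "residue": int(rid), "rmsf": v})
    p = out_dir / "rmsf.csv"
    pd.DataFrame(rmsf_rows).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "rmsf", {})

    # contacts on the first ensemble (explicit hydrogens required)
    hb = interactions.hbond_occurrence(
        ensembles[0], min_frequency=config.hbond_min_frequency
    )
    hb_rows = [
        {
            "pair": s.label,
            "frequency": s.frequency,
            "mean_distance": float(np.nanmean(s.distance)),
            "strength": interactions.strength_scale(float(np.nanmean(s.distance))),
        }
        for s in hb
    ]
    p = out_dir / "hbonds.csv"
    pd.DataFrame(hb_rows, columns=["pair", "frequency", "mean_distance", "strength"]).to_csv(
        p, index=False, float_format=_FLOAT_FMT
    )
    manifest.add(p, "hbonds", {"min_frequency": config.hbond_min_frequency})

    hydro = interactions.detect_hydrophobic_contacts(
        ensembles[0].frame(0), cutoff=config.hydrophobic_cutoff
    )
    p = out_dir / "hydrophobic_contacts.csv"
    pd.DataFrame(
        [
            {
                "residue_1": c.donor_label,
                "residue_2": c.acceptor_label,
                "distance": c.distance,
            }
            for c in hydro
        ],
        columns=["residue_1", "residue_2", "distance"],
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "hydrophobic_contacts", {"cutoff": config.hydrophobic_cutoff})

    # secondary structure on the first ensemble
    assignments = secondary.assign_ensemble(ensembles[0])
    region = (
        topo.regions.get(config.analysis_region)
        if config.analysis_region
        else None
    )
    ss_rows = [
        {
            "frame": i,
            "ss": a.full_string,
            "helical_content": secondary.helical_content(a, region),
        }
        for i, a in enumerate(assignments)
    ]
    p = out_dir / "secondary_structure.csv"
    pd.DataFrame(ss_rows).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "secondary_structure", {"region": config.analysis_region})

    ss_cluster = secondary.cluster_by_ss(assignments)
    p = out_dir / "ss_clusters.csv"
    pd.DataFrame(
        {"frame": np.arange(len(assignments)), "cluster": ss_cluster.labels}
    ).to_csv(p, index=False)
    manifest.add(
        p,
        "ss_clustering",
        {
            "pruning_distance": ss_cluster.pruning_distance,
            "silhouette": ss_cluster.silhouette,
        },
    )

    # merged ensemble on Cα for cross-protein stages
    ca_subsets = [e.subset_atoms(ca) for e in ensembles]
    merged = concatenate(ca_subsets)
    merged_topo = merged.topology
    merged_fit = geometry.fit_ensemble(merged)
    analysis_sel = (
        merged_topo.select(region=config.analysis_region)
        if config.analysis_region and config.analysis_region in merged_topo.regions
        else np.arange(merged_topo.n_atoms)
    )

    cluster = clustering.reference_cluster(
        merged_fit, analysis_sel, cutoff=config.cluster_cutoff, seed=config.seed
    )
    p = out_dir / "rmsd_clusters.csv"
    pd.DataFrame(
        {
            "frame": np.arange(merged_fit.n_frames),
            "source": [str(s) for s in merged_fit.source_labels],
            "cluster": cluster.labels,
        }
    ).to_csv(p, index=False)
    manifest.add(
        p,
        "rmsd_clustering",
        {"cutoff": config.cluster_cutoff, "coverage": cluster.coverage},
    )

    sweep = clustering.cutoff_sweep(
        merged_fit,
        analysis_sel,
        r_min=config.sweep_r_min,
        r_max=config.sweep_r_max,
        step=config.sweep_step,
        seed=config.seed,
    )
    p = out_dir / "cutoff_sweep.csv"
    sweep.to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "cutoff_sweep", {})

    model = motions.pca(merged_fit, analysis_sel)
    p = out_dir / "pca_spectrum.csv"
    pd.DataFrame(
        {
            "mode": np.arange(1, model.n_modes + 1),
            "eigenvalue": model.eigenvalues,
            "explained_variance": model.explained_variance,
            "cumulative_variance": model.cumulative_variance,
        }
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "pca", {"selection": "CA+region"})

    proj = motions.project(merged_fit, model, n_modes=config.n_projection_modes)
    p = out_dir / "pca_projections.csv"
    pd.DataFrame(
        {
            "source": [str(s) for s in merged_fit.source_labels],
            **{f"pc{i + 1}": proj[:, i] for i in range(proj.shape[1])},
        }
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "pca_projections", {"n_modes": config.n_projection_modes})

    arrows, amp, exported = motions.mode_displacements(
        model, 0, amplitude_threshold=config.porcupine_threshold
    )
    p = out_dir / "mode1_arrows.csv"
    pd.DataFrame(
        {
            "atom": exported,
            "amplitude": amp[exported],
            "dx": arrows[exported, 0],
            "dy": arrows[exported, 1],
            "dz": arrows[exported, 2],
        }
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "porcupine", {"threshold": config.porcupine_threshold})

    corr = motions.cross_correlation(merged_fit, np.arange(merged_topo.n_atoms))
    p = out_dir / "cross_correlation.csv"
    pd.DataFrame(
        corr.values, index=corr.residue_ids, columns=corr.residue_ids
    ).to_csv(p, float_format=_FLOAT_FMT)
    manifest.add(p, "cross_correlation", {})

    surface = landscape.free_energy_landscape(
        proj[:, :2],
        temperature=config.temperature,
        k=config.knn_k,
        grid_size=config.fel_grid,
    )
    wells = landscape.detect_wells(surface, min_barrier=config.min_barrier)
    landscape.assign_frames_to_wells(wells, surface, proj[:, :2])
    composition = landscape.well_composition(
        wells, merged_fit.source_labels
    )
    p = out_dir / "fel_surface.csv"
    gx, gy = np.meshgrid(surface.grid_x, surface.grid_y, indexing="ij")
    pd.DataFrame(
        {
            "pc1": gx.ravel(),
            "pc2": gy.ravel(),
            "probability": surface.probability.ravel(),
            "delta_g": surface.delta_g.ravel(),
        }
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(p, "fel", {"temperature": config.temperature})

    p = out_dir / "wells.json"
    with open(p, "w") as fh:
        json.dump(
            [
                {
                    "label": w.label,
                    "minimum": list(w.minimum_coords),
                    "depth": w.depth,
                    "n_frames": int(len(w.member_frames)),
                    "composition": w.composition,
                }
                for w in wells
            ],
            fh,
            indent=1,
            sort_keys=True,
        )
    manifest.add(p, "wells", {"min_barrier": config.min_barrier})

    return manifest.write(config)


@_stage("pocketome")
def run_pocketome(config: AnalysisConfig, ensemble: Ensemble | None = None) -> Path:
    """Cryptic-pocket tracking; returns the manifest path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    if ensemble is None:
        ensemble = _pocket_suite(config)
    pm = pockets.pocket_frequency_map(
        ensemble,
        isovalue=config.pocket_isovalue,
        grid_spacing=config.pocket_grid_spacing,
        probe_radius=config.probe_radius,
    )
    rows = []
    for i, label in enumerate(pm.labels):
        series = pockets.pocket_volume_series(ensemble, pm, i)
        lining = pockets.lining_residues(
            ensemble.frame(0), pm.grid.node_coords(pm.components[i])
        )
        resnames = [
            str(ensemble.topology.resnames[np.nonzero(ensemble.topology.resids == r)[0][0]])
            for r in lining["residues"]
        ]
        score = pockets.hydrophobicity_score(resnames)
        for f, v in enumerate(series.volumes):
            rows.append(
                {
                    "pocket": label,
                    "frame": f,
                    "volume": v,
                    "arginine_count": lining["arginine_count"],
                    "hydrophobicity": np.nan if score is None else score,
                }
            )
    p = out_dir / "pocket_volumes.csv"
    pd.DataFrame(
        rows, columns=["pocket", "frame", "volume", "arginine_count", "hydrophobicity"]
    ).to_csv(p, index=False, float_format=_FLOAT_FMT)
    manifest.add(
        p,
        "pocketome",
        {
            "isovalue": config.pocket_isovalue,
            "n_pockets": len(pm.components),
            "mean_volumes": pm.mean_volumes,
        },
    )
    return manifest.write(config)


def _pocket_suite(config: AnalysisConfig) -> Ensemble:
    """Synthetic pocket input: a cavity shell breathing around r = 3 Å."""
    rng = np.random.default_rng(config.seed)
    frames = []
    base, _ = plant_cavity_shell(3.0)
    for i in range(12):
        shell, _ = plant_cavity_shell(3.0 + 0.2 * float(rng.uniform(-1, 1)))
        frames.append(shell.coordinates)
    return Ensemble(base.topology, np.stack(frames), stride=config.stride_ps)


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO if verbose else logging.WARNING)
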