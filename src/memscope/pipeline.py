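"""Configuration-driven orchestration of the analysis stages.

A single YAML config enables any subset of the stages (curvature,
contacts/occupancy, clustering, density-height correlation,
orientation), carries all analysis parameters (contact cutoff 10 A,
DBSCAN 28 A / 5 molecules, grid edge 18 A, 200-frame rolling window by
default) and fixes the output directory and seed.  Stages run in
dependency order (I/O, leaflet assignment, then the independent
analyses), write CSV tables plus a machine-readable run manifest, and
a rerun with identical config and inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clusters import ClusterSpec, assign_leaflets, cluster_series
from .contacts import ContactSpec, contact_frequency, contact_series, occupancy_profile
from .curvature import curvature_series
from .frame import BeadFrame
from .gridcorr import GridSpec, correlation_series
from .io import read_frames, write_score_structure
from .orientation import orientation_angles

__all__ = ["AnalysisConfig", "rolling_mean", "run_pipeline"]

log = logging.getLogger(__name__)


def rolling_mean(series: Sequence[float], window: int = 200) -> np.ndarray:
    """Trailing rolling average used for time-series smoothing.

    The first ``window - 1`` entries average all available preceding
    points (shrinking window), so output length equals input length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(series, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    return (pd.Series(values)
            .rolling(window, min_periods=1).mean().to_numpy())


@dataclass
class AnalysisConfig:
    """Pipeline configuration; defaults follow the analysis protocol
    (10 A contact cutoff, DBSCAN eps 28 A / min 5, 18 A grid squares,
    200-frame rolling window)."""

    topology: str = ""
    trajectory: str | None = None
    outdir: str = "results"
    seed: int = 0
    subsample: int = 1  # analyze every k-th frame

    stages: dict = field(default_factory=lambda: {
        "curvature": True, "contacts": True, "clusters": True,
        "correlation": True, "orientation": False,
    })

    contact_cutoff: float = 10.0
    contact_convention: str = "minimum-image"
    occupancy_species: list = field(default_factory=lambda: ["DPG3"])
    occupancy_window: list | None = None  # [start, end] frame positions

    cluster_eps: float = 28.0
    cluster_min_points: int = 5
    cluster_species: str = "DPG3"
    cluster_leaflet: str = "upper"

    grid_edge: float = 18.0
    correlation_species: list = field(default_factory=lambda: ["DPG3"])

    surface_form: str = "plane_gaussian"
    rolling_window: int = 200

    orientation_residue_a: int | None = None
    orientation_residue_b: int | None = None

    def __post_init__(self) -> None:
        if self.rolling_window < 1:
            raise ValueError("rolling window must be >= 1")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if not cfg.topology:
            raise ValueError("config must name a topology file")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: AnalysisConfig,
                 frames: list[BeadFrame] | None = None) -> dict[str, Path]:
    """Execute the enabled stages; returns the written file paths.

    ``frames`` may be supplied directly (e.g. a synthetic scene) to
    bypass file reading.  Any stage failure aborts with an error naming
    the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if frames is None:
        log.info("stage io: reading %s", config.topology)
        frames = read_frames(config.topology, config.trajectory)
    if config.subsample > 1:
        frames = frames[::config.subsample]
    if not frames:
        raise RuntimeError("stage io: no frames to analyze")

    log.info("stage leaflets: assigning from frame %d", frames[0].index)
    try:
        leaflet_map = assign_leaflets(frames[0])
    except ValueError:
        leaflet_map = {}

    def _run(stage: str, fn) -> None:
        if not config.stages.get(stage, False):
            return
        log.info("stage %s: %d frames", stage, len(frames))
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    def _curvature() -> None:
        df = curvature_series(frames, leaflet_map,
                              form_id=config.surface_form)
        df["mean_abs_gaussian_A2_rolling"] = rolling_mean(
            df["mean_abs_gaussian_A2"], config.rolling_window)
        path = outdir / "curvature.csv"
        _write_csv(df, path)
        outputs["curvature"] = path

    def _contacts() -> None:
        spec = ContactSpec(config.contact_cutoff, config.contact_convention)
        matrices = contact_series(frames, spec)
        pairs, per_residue = contact_frequency(matrices)
        path = outdir / "contact_pairs.csv"
        _write_csv(pairs, path)
        outputs["contact_pairs"] = path
        species_of = {int(m): str(s) for m, s in
                      zip(frames[0].molids, frames[0].species)}
        window = tuple(config.occupancy_window) if config.occupancy_window \
            else None
        occ = pd.DataFrame({"residue": matrices[0].ids_a,
                            "n_contacts": per_residue.values})
        for sp in config.occupancy_species:
            occ[f"occupancy_{sp}"] = occupancy_profile(
                matrices, species_of, sp, window).values
        path = outdir / "occupancy.csv"
        _write_csv(occ, path)
        outputs["occupancy"] = path
        bb = frames[0].subframe(np.flatnonzero(frames[0].names == "BB"))
        if bb.n_beads:
            path = outdir / "contact_frequency.pdb"
            write_score_structure(bb, per_residue.to_dict(), path)
            outputs["contact_pdb"] = path

    def _clusters() -> None:
        spec = ClusterSpec(config.cluster_eps, config.cluster_min_points)
        df, labelings = cluster_series(frames, config.cluster_species,
                                       config.cluster_leaflet, spec,
                                       leaflet_map)
        path = outdir / "clusters.csv"
        _write_csv(df, path)
        outputs["clusters"] = path
        labels_path = outdir / "cluster_labels.json"
        with open(labels_path, "w") as fh:
            json.dump({str(l.frame_index): l.as_mapping() for l in labelings},
                      fh, sort_keys=True)
        outputs["cluster_labels"] = labels_path

    def _correlation() -> None:
        df = correlation_series(frames, config.correlation_species,
                                GridSpec(config.grid_edge), leaflet_map)
        path = outdir / "correlation.csv"
        _write_csv(df, path)
        outputs["correlation"] = path

    def _orientation() -> None:
        if config.orientation_residue_a is None or \
                config.orientation_residue_b is None:
            raise ValueError("orientation stage needs residue_a and "
                             "residue_b")
        df = orientation_angles(frames, config.orientation_residue_a,
                                config.orientation_residue_b)
        path = outdir / "orientation.csv"
        _write_csv(df, path)
        outputs["orientation"] = path

    _run("curvature", _curvature)
    _run("contacts", _contacts)
    _run("clusters", _clusters)
    _run("correlation", _correlation)
    _run("orientation", _orientation)

    manifest = {
        "config": config.to_dict(),
        "n_frames": len(frames),
        "outputs": {k: str(v.name) for k, v in sorted(outputs.items())},
        "versions": {
            "memscope": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    outputs["manifest"] = manifest_path
    return outputs


def output_hashes(outputs: dict[str, Path]) -> dict[str, str]:
    """SHA-256 of every produced file (reproducibility checks)."""
    out = {}
    for key, path in sorted(outputs.items()):
        out[key] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return out
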