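"""Reading and writing coordinate/trajectory files.

MDAnalysis handles the formats (GRO, PDB, XTC, TRR); this module
converts between its Universe and the package's :class:`BeadFrame`
containers.  Internal units are angstrom and picosecond (MDAnalysis'
native units), so cutoffs quoted in angstrom apply directly.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from .frame import (BB_BEAD_NAMES, D_BEAD_NAMES, BeadFrame, canonical_species,
                    species_matches)

__all__ = [
    "read_frames",
    "write_gro",
    "write_trajectory",
    "write_score_structure",
    "resolve_reference_points",
]

log = logging.getLogger(__name__)


def _universe_to_frame(u: "mda.Universe", index: int, fallback_time: float,
                       ) -> BeadFrame:
    ts = u.trajectory.ts
    box = ts.dimensions[:3] if ts.dimensions is not None else None
    if box is None or not np.all(np.asarray(box) > 0):
        # structure files without a box record: fall back to the coordinate
        # extent so downstream gridding still has positive lengths
        ext = np.ptp(u.atoms.positions, axis=0)
        box = np.maximum(ext, 1.0)
        log.warning("no box in file; using coordinate extent %s A", box)
    t = float(ts.time) if ts.time is not None else fallback_time
    return BeadFrame(
        coordinates=u.atoms.positions.astype(float).copy(),
        names=u.atoms.names.astype(object),
        resids=u.atoms.resids.astype(int),
        molids=u.atoms.resindices.astype(int) + 1,
        species=u.atoms.resnames.astype(object),
        box=np.asarray(box, dtype=float),
        time=t,
        index=index,
    )


def read_frames(topology_path, trajectory_path=None,
                format_hint: str | None = None) -> list[BeadFrame]:
    """Read a coordinate file (GRO/PDB), optionally with a trajectory
    (XTC/TRR/multi-model PDB), into a list of BeadFrames.

    Coordinates come back in angstrom and times in picoseconds.  Frame
    times are made strictly increasing (files without time records get
    the frame index in ps).  A bead-count mismatch between topology and
    trajectory raises ``ValueError`` naming both counts.
    """
    kwargs = {}
    if format_hint:
        kwargs["format"] = format_hint
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_path is not None:
                u = mda.Universe(str(topology_path), str(trajectory_path),
                                 **kwargs)
            else:
                u = mda.Universe(str(topology_path), **kwargs)
    except Exception as exc:  # MDAnalysis parsers raise a wide range
        raise ValueError(
            f"could not parse {topology_path}"
            + (f" with {trajectory_path}" if trajectory_path else "")
            + f": {exc}") from exc
    frames: list[BeadFrame] = []
    last_t = -np.inf
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, _ in enumerate(u.trajectory):
                fr = _universe_to_frame(u, i, fallback_time=float(i))
                if fr.time <= last_t:
                    fr.time = last_t + 1.0
                last_t = fr.time
                frames.append(fr)
    except Exception as exc:
        raise ValueError(
            f"trajectory {trajectory_path or topology_path} does not match "
            f"the {u.atoms.n_atoms}-bead topology: {exc}") from exc
    return frames


def _frame_to_universe(frame: BeadFrame) -> "mda.Universe":
    # residues are (molecule, residue-id) pairs: one per lipid molecule,
    # one per protein residue
    keys = list(zip(frame.molids.tolist(), frame.resids.tolist()))
    resindex_of: dict[tuple[int, int], int] = {}
    res_first: list[int] = []
    for i, key in enumerate(keys):
        if key not in resindex_of:
            resindex_of[key] = len(res_first)
            res_first.append(i)
    atom_resindex = np.array([resindex_of[key] for key in keys])
    n_res = len(res_first)
    u = mda.Universe.empty(frame.n_beads, n_residues=n_res,
                           atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", [str(n) for n in frame.names])
    u.add_TopologyAttr("resnames",
                       [str(frame.species[i]) for i in res_first])
    u.add_TopologyAttr("resids",
                       [int(frame.resids[i]) for i in res_first])
    u.atoms.positions = frame.coordinates
    u.dimensions = np.array([frame.box[0], frame.box[1], frame.box[2],
                             90.0, 90.0, 90.0])
    return u


def write_gro(frame: BeadFrame, path) -> None:
    """Write one frame as GRO (nm on disk, per the format)."""
    u = _frame_to_universe(frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(frames: Sequence[BeadFrame], path) -> None:
    """Write a multi-frame trajectory (XTC/TRR by extension, or
    multi-model PDB)."""
    if not frames:
        raise ValueError("no frames to write")
    u = _frame_to_universe(frames[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=frames[0].n_beads) as w:
            for fr in frames:
                u.atoms.positions = fr.coordinates
                u.trajectory.ts.time = fr.time
                u.trajectory.ts.frame = fr.index
                w.write(u.atoms)


def write_score_structure(frame: BeadFrame,
                          per_residue_scores: Mapping[int, float],
                          path) -> None:
    """Write a PDB whose B-factor column carries per-residue scores.

    Every atom of a residue gets that residue's score (2 decimals, PDB
    fixed width); residues without a score get 0.00.  Scores outside
    the 6-character field are clamped with a warning.
    """
    scores = np.zeros(frame.n_beads)
    for i, resid in enumerate(frame.resids):
        scores[i] = float(per_residue_scores.get(int(resid), 0.0))
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    lo, hi = -99.99, 999.99  # %6.2f field limits
    if np.any(scores < lo) or np.any(scores > hi):
        log.warning("scores clamped to the PDB B-factor field [%s, %s]",
                    lo, hi)
        scores = np.clip(scores, lo, hi)
    u = _frame_to_universe(frame)
    u.add_TopologyAttr("tempfactors", scores)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def resolve_reference_points(frame: BeadFrame, role: str,
                             ) -> tuple[np.ndarray, list[int]]:
    """Reference points for contact analysis.

    ``role="protein-residue"``: each residue's backbone (BB) bead
    position, ids are residue ids.  ``role="lipid-molecule"``: each
    molecule's centre of geometry over all its beads, except GM3
    (DPG3) molecules which use their carboxyl-group D bead; ids are
    molecule ids.  Order follows first appearance in the frame.
    """
    if role == "protein-residue":
        bb_mask = np.isin(frame.names, BB_BEAD_NAMES)
        resids, first = np.unique(frame.resids, return_index=True)
        order = np.argsort(first)
        pts, ids = [], []
        for resid in resids[order]:
            idx = np.flatnonzero((frame.resids == resid) & bb_mask)
            if not len(idx):
                raise ValueError(f"residue {resid} has no BB bead")
            pts.append(frame.coordinates[idx[0]])
            ids.append(int(resid))
        return np.array(pts), ids
    if role == "lipid-molecule":
        gm3 = species_matches(frame.species, "DPG3")
        d_mask = np.isin(frame.names, D_BEAD_NAMES)
        mols, first = np.unique(frame.molids, return_index=True)
        order = np.argsort(first)
        pts, ids = [], []
        for mol in mols[order]:
            idx = np.flatnonzero(frame.molids == mol)
            if gm3[idx[0]]:
                d_idx = idx[d_mask[idx]]
                if not len(d_idx):
                    raise ValueError(f"GM3 molecule {mol} has no D bead")
                pts.append(frame.coordinates[d_idx[0]])
            else:
                pts.append(frame.coordinates[idx].mean(axis=0))
            ids.append(int(mol))
        return np.array(pts), ids
    raise ValueError(f"unknown role {role!r}; expected 'protein-residue' "
                     "or 'lipid-molecule'")
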