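"""Protein-lipid contacts and residue occupancy.

A contact is a pair of reference points (a residue's BB bead, a lipid
molecule's centre of geometry, or a GM3 D bead) strictly closer than a
cutoff (default 10 A).  Distances use the minimum image in the
membrane plane (x, y) by default, since the bilayer patch is periodic
in-plane; a raw-Euclidean convention is available.  Detection runs on
a cell list with bin width equal to the cutoff; its correctness is
defined by the brute-force all-pairs computation it is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .frame import BeadFrame, species_matches
from .io import resolve_reference_points

__all__ = [
    "ContactSpec",
    "ContactMatrix",
    "contact_matrix",
    "contact_series",
    "contact_frequency",
    "occupancy",
    "occupancy_profile",
]

MINIMUM_IMAGE = "minimum-image"
RAW = "raw"


@dataclass(frozen=True)
class ContactSpec:
    """Contact definition: cutoff in angstrom and distance convention."""

    cutoff: float = 10.0
    convention: str = MINIMUM_IMAGE  # periodic in x and y, raw in z

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.convention not in (MINIMUM_IMAGE, RAW):
            raise ValueError(f"unknown distance convention "
                             f"{self.convention!r}")


@dataclass
class ContactMatrix:
    """Boolean contact relation for one frame."""

    ids_a: list[int]
    ids_b: list[int]
    contacts: np.ndarray  # (len(ids_a), len(ids_b)) bool
    frame_index: int = 0

    def count_for(self, id_a: int) -> int:
        return int(self.contacts[self.ids_a.index(id_a)].sum())


def _displacements(a: np.ndarray, b: np.ndarray, box: np.ndarray | None,
                   convention: str) -> np.ndarray:
    """(na, nb, 3) displacement vectors under the stated convention."""
    d = a[:, None, :] - b[None, :, :]
    if convention == MINIMUM_IMAGE:
        if box is None:
            raise ValueError("minimum-image distances require a box")
        for dim in (0, 1):  # periodic in-plane only
            L = box[dim]
            d[:, :, dim] -= L * np.round(d[:, :, dim] / L)
    return d


def brute_force_contacts(points_a: np.ndarray, points_b: np.ndarray,
                         spec: ContactSpec,
                         box: np.ndarray | None = None) -> np.ndarray:
    """All-pairs contact matrix; the correctness reference."""
    d = _displacements(np.asarray(points_a, float),
                       np.asarray(points_b, float), box, spec.convention)
    return np.sqrt((d * d).sum(axis=2)) < spec.cutoff


def contact_matrix(points_a: np.ndarray, points_b: np.ndarray,
                   spec: ContactSpec = ContactSpec(),
                   box: Sequence[float] | None = None,
                   ids_a: Sequence[int] | None = None,
                   ids_b: Sequence[int] | None = None,
                   frame_index: int = 0) -> ContactMatrix:
    """Contact matrix between two point sets for one frame.

    Strict inequality at the cutoff: a pair exactly at the cutoff is
    not a contact.  Uses a cell list with bin width = cutoff.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("point lists must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    box_arr = np.asarray(box, dtype=float) if box is not None else None
    if spec.convention == MINIMUM_IMAGE and box_arr is None:
        raise ValueError("minimum-image distances require a box")

    na, nb = len(a), len(b)
    out = np.zeros((na, nb), dtype=bool)
    cutoff = spec.cutoff
    periodic = spec.convention == MINIMUM_IMAGE

    # bin geometry: in periodic dims bins tile the box with width >= cutoff;
    # in aperiodic dims bins tile the data extent
    awork = a.copy()
    bwork = b.copy()
    nbins = np.empty(3, dtype=int)
    width = np.empty(3)
    origin = np.empty(3)
    for dim in range(3):
        if periodic and dim < 2:
            L = box_arr[dim]
            awork[:, dim] %= L
            bwork[:, dim] %= L
            nbins[dim] = max(1, int(np.floor(L / cutoff)))
            width[dim] = L / nbins[dim]
            origin[dim] = 0.0
        else:
            lo = min(awork[:, dim].min(), bwork[:, dim].min())
            hi = max(awork[:, dim].max(), bwork[:, dim].max())
            span = max(hi - lo, cutoff)
            nbins[dim] = max(1, int(np.floor(span / cutoff)))
            width[dim] = span / nbins[dim] + 1e-9
            origin[dim] = lo

    def bin_index(pts: np.ndarray) -> np.ndarray:
        idx = np.floor((pts - origin) / width).astype(int)
        return np.clip(idx, 0, nbins - 1)

    bins_b = bin_index(bwork)
    cells: dict[tuple[int, int, int], list[int]] = {}
    for j, cell in enumerate(map(tuple, bins_b)):
        cells.setdefault(cell, []).append(j)

    bins_a = bin_index(awork)
    cut2 = cutoff * cutoff
    for i in range(na):
        cx, cy, cz = bins_a[i]
        cand: list[int] = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    x, y, z = cx + dx, cy + dy, cz + dz
                    if periodic:
                        x %= nbins[0]
                        y %= nbins[1]
                    elif not (0 <= x < nbins[0] and 0 <= y < nbins[1]):
                        continue
                    if not 0 <= z < nbins[2]:
                        continue
                    cand.extend(cells.get((x, y, z), ()))
        if not cand:
            continue
        cand_idx = np.array(sorted(set(cand)))
        d = awork[i] - bwork[cand_idx]
        if periodic:
            for dim in (0, 1):
                L = box_arr[dim]
                d[:, dim] -= L * np.round(d[:, dim] / L)
        hit = (d * d).sum(axis=1) < cut2
        out[i, cand_idx[hit]] = True

    return ContactMatrix(
        list(ids_a) if ids_a is not None else list(range(na)),
        list(ids_b) if ids_b is not None else list(range(nb)),
        out, frame_index)


def contact_series(frames: Iterable[BeadFrame],
                   spec: ContactSpec = ContactSpec()) -> list[ContactMatrix]:
    """Per-frame contact matrices between protein residues (BB beads)
    and lipid molecules (centre of geometry / GM3 D bead)."""
    matrices = []
    for fr in frames:
        prot_idx = np.flatnonzero(fr.names == "BB")
        lip_idx = np.flatnonzero(fr.names != "BB")
        if not len(prot_idx) or not len(lip_idx):
            raise ValueError(f"frame {fr.index}: need both protein and "
                             "lipid beads for contact analysis")
        pts_a, ids_a = resolve_reference_points(fr.subframe(prot_idx),
                                                "protein-residue")
        pts_b, ids_b = resolve_reference_points(fr.subframe(lip_idx),
                                                "lipid-molecule")
        matrices.append(contact_matrix(pts_a, pts_b, spec, fr.box,
                                       ids_a, ids_b, fr.index))
    return matrices


def contact_frequency(matrices: Sequence[ContactMatrix],
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Contact counts over frames.

    Returns a per-pair table (id_a, id_b, n_frames_in_contact) and a
    per-residue Series (sum over all partners), the latter suitable for
    B-factor export via :func:`memscope.io.write_score_structure`.
    """
    if not matrices:
        raise ValueError("need at least one contact matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.ids_a != first.ids_a or m.ids_b != first.ids_b:
            raise ValueError("inconsistent id sets across frames")
    total = np.zeros(first.contacts.shape, dtype=int)
    for m in matrices:
        total += m.contacts
    ia, ib = np.nonzero(total)
    pairs = pd.DataFrame({
        "id_a": [first.ids_a[i] for i in ia],
        "id_b": [first.ids_b[j] for j in ib],
        "n_frames": total[ia, ib],
    })
    per_residue = pd.Series(total.sum(axis=1), index=first.ids_a,
                            name="n_contacts")
    return pairs, per_residue


def occupancy(matrices: Sequence[ContactMatrix], residue_id: int,
              species_of: Mapping[int, str], species: str,
              window: tuple[int, int] | None = None) -> float:
    """Fraction of window frames in which ``residue_id`` contacts at
    least one molecule of ``species``.

    ``window`` is an inclusive (start, end) pair of positions in the
    frame sequence; by default the whole sequence.
    """
    if not matrices:
        raise ValueError("need at least one contact matrix")
    n = len(matrices)
    if window is None:
        window = (0, n - 1)
    start, end = window
    start = max(start, 0)
    end = min(end, n - 1)
    if end < start:
        raise ValueError("empty frame window")
    first = matrices[0]
    try:
        row = first.ids_a.index(residue_id)
    except ValueError:
        raise ValueError(f"residue {residue_id} not in contact matrices")
    sp_labels = np.array([species_of.get(int(m), "") for m in first.ids_b],
                         dtype=object)
    col_mask = species_matches(sp_labels, species)
    hits = sum(
        1 for m in matrices[start:end + 1]
        if m.contacts[row, col_mask].any()
    )
    return hits / (end - start + 1)


def occupancy_profile(matrices: Sequence[ContactMatrix],
                      species_of: Mapping[int, str], species: str,
                      window: tuple[int, int] | None = None) -> pd.Series:
    """Occupancy of every residue against one lipid species."""
    if not matrices:
        raise ValueError("need at least one contact matrix")
    vals = {rid: occupancy(matrices, rid, species_of, species, window)
            for rid in matrices[0].ids_a}
    return pd.Series(vals, name=f"occupancy_{species}")
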