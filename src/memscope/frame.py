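"""Core in-memory containers for coarse-grained trajectory frames.

A :class:`BeadFrame` holds one frame of a coarse-grained system: bead
coordinates in angstrom, bead names (e.g. ``PO4``, ``BB``, ``D``),
residue ids, molecule ids, species labels (residue names such as
``POPC`` or ``DPG3``) and the periodic box.  All analyses in this
package operate on BeadFrames; file formats are converted to and from
them at the I/O boundary (internal units are angstrom and picosecond
throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BeadFrame",
    "SelectionSpec",
    "SPECIES_ALIASES",
    "canonical_species",
    "species_matches",
    "merge_frames",
]

#: Editable alias table mapping between common lipid names and their
#: coarse-grained residue names (GM3 lipids carry DPG3 beads, PIP2 carries
#: POP2 beads).  Selections written with either name match both.
SPECIES_ALIASES: dict[str, str] = {
    "GM3": "DPG3",
    "DPG3": "GM3",
    "PIP2": "POP2",
    "POP2": "PIP2",
}

#: Bead names recognised as the carboxyl-group reference bead of GM3.
D_BEAD_NAMES: tuple[str, ...] = ("D",)

#: Bead names recognised as the phosphate-role membrane surface marker.
PO4_BEAD_NAMES: tuple[str, ...] = ("PO4",)

#: Bead names recognised as the protein backbone bead.
BB_BEAD_NAMES: tuple[str, ...] = ("BB",)


def canonical_species(name: str) -> frozenset[str]:
    """Return the set of residue names equivalent to ``name``."""
    alias = SPECIES_ALIASES.get(name)
    return frozenset({name, alias}) if alias else frozenset({name})


def species_matches(labels: np.ndarray, name: str) -> np.ndarray:
    """Boolean mask of ``labels`` matching ``name`` or any alias of it."""
    out = np.zeros(len(labels), dtype=bool)
    for nm in canonical_species(name):
        out |= labels == nm
    return out


@dataclass
class BeadFrame:
    """One trajectory frame of a coarse-grained system.

    Parameters
    ----------
    coordinates:
        ``(N, 3)`` float array, angstrom.
    names:
        ``(N,)`` bead names.
    resids:
        ``(N,)`` integer residue ids.
    molids:
        ``(N,)`` integer molecule ids (one id per lipid molecule or per
        protein chain/pentamer).
    species:
        ``(N,)`` residue/species labels.
    box:
        ``(3,)`` orthorhombic box lengths, angstrom.
    time:
        Frame time in picoseconds.
    index:
        Frame index within its trajectory.
    """

    coordinates: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    molids: np.ndarray
    species: np.ndarray
    box: np.ndarray
    time: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.names = np.asarray(self.names, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.molids = np.asarray(self.molids, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.coordinates)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        for arr, label in (
            (self.names, "names"),
            (self.resids, "resids"),
            (self.molids, "molids"),
            (self.species, "species"),
        ):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} beads")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths (angstrom)")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    def copy(self) -> "BeadFrame":
        return BeadFrame(
            self.coordinates.copy(),
            self.names.copy(),
            self.resids.copy(),
            self.molids.copy(),
            self.species.copy(),
            self.box.copy(),
            self.time,
            self.index,
        )

    def with_coordinates(self, coordinates: np.ndarray, *, time: float | None = None,
                         index: int | None = None) -> "BeadFrame":
        """Copy of this frame with new coordinates (topology shared)."""
        out = replace(self, coordinates=np.asarray(coordinates, dtype=float))
        if time is not None:
            out.time = time
        if index is not None:
            out.index = index
        return out

    # -- selection ---------------------------------------------------------

    def indices(self, spec: "SelectionSpec",
                leaflet_map: Mapping[int, str] | None = None) -> np.ndarray:
        return spec.resolve(self, leaflet_map)

    def subframe(self, idx: np.ndarray) -> "BeadFrame":
        """Frame restricted to beads ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return BeadFrame(
            self.coordinates[idx],
            self.names[idx],
            self.resids[idx],
            self.molids[idx],
            self.species[idx],
            self.box,
            self.time,
            self.index,
        )

    def molecule_ids(self, species: str | None = None) -> np.ndarray:
        """Unique molecule ids, optionally restricted to one species."""
        if species is None:
            mask = np.ones(self.n_beads, dtype=bool)
        else:
            mask = species_matches(self.species, species)
        return np.unique(self.molids[mask])


@dataclass
class SelectionSpec:
    """Declarative bead selection.

    All filters are optional; a bead is selected when it passes every
    supplied filter.  Resolution is order-stable (ascending bead index)
    and idempotent.
    """

    species: str | Sequence[str] | None = None
    names: str | Sequence[str] | None = None
    leaflet: str | None = None  # "upper" | "lower"; needs a leaflet map
    resid_range: tuple[int, int] | None = None  # inclusive

    def resolve(self, frame: BeadFrame,
                leaflet_map: Mapping[int, str] | None = None) -> np.ndarray:
        mask = np.ones(frame.n_beads, dtype=bool)
        if self.species is not None:
            wanted = [self.species] if isinstance(self.species, str) else list(self.species)
            m = np.zeros(frame.n_beads, dtype=bool)
            for sp in wanted:
                m |= species_matches(frame.species, sp)
            mask &= m
        if self.names is not None:
            wanted = [self.names] if isinstance(self.names, str) else list(self.names)
            m = np.zeros(frame.n_beads, dtype=bool)
            for nm in wanted:
                m |= frame.names == nm
            mask &= m
        if self.resid_range is not None:
            lo, hi = self.resid_range
            mask &= (frame.resids >= lo) & (frame.resids <= hi)
        if self.leaflet is not None:
            if leaflet_map is None:
                raise ValueError("leaflet filter requires a leaflet map")
            m = np.fromiter(
                (leaflet_map.get(int(mid)) == self.leaflet for mid in frame.molids),
                dtype=bool, count=frame.n_beads,
            )
            mask &= m
        return np.flatnonzero(mask)


def merge_frames(*frames: BeadFrame, renumber: bool = True) -> BeadFrame:
    """Concatenate frames into one (e.g. membrane + capsid shell).

    With ``renumber`` the molecule and residue ids of later fragments are
    offset past the maximum of earlier ones so ids stay unique.
    """
    if not frames:
        raise ValueError("no frames to merge")
    coords, names, resids, molids, species = [], [], [], [], []
    mol_off = 0
    res_off = 0
    for fr in frames:
        coords.append(fr.coordinates)
        names.append(fr.names)
        species.append(fr.species)
        if renumber:
            resids.append(fr.resids + res_off)
            molids.append(fr.molids + mol_off)
            if fr.n_beads:
                res_off = int(np.max(resids[-1]))
                mol_off = int(np.max(molids[-1]))
        else:
            resids.append(fr.resids)
            molids.append(fr.molids)
    first = frames[0]
    return BeadFrame(
        np.concatenate(coords),
        np.concatenate(names),
        np.concatenate(resids),
        np.concatenate(molids),
        np.concatenate(species),
        first.box,
        first.time,
        first.index,
    )
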