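"""Cross-correlation between lipid species density and membrane height.

Each frame's membrane plane is tiled by squares of edge 18 A (a final
partial row/column is kept as a smaller square so molecule counts are
conserved).  Square i carries the molecule count L_i of the species of
interest and the height deviation dz_i: the mean z of the phosphate
beads in the square minus the mean over the whole membrane in that
frame.  The per-frame coefficient is the population Pearson
correlation of (L_i, dz_i) over squares that contain at least one
phosphate bead; it is undefined (NaN) when either field has zero
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import _cog_reference_points, assign_leaflets
from .frame import BeadFrame, PO4_BEAD_NAMES, species_matches

__all__ = [
    "GridSpec",
    "GridField",
    "grid_fields",
    "cross_correlation",
    "correlation_series",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Square tiling of the membrane plane; edge length in angstrom."""

    edge: float = 18.0

    def __post_init__(self) -> None:
        if self.edge <= 0:
            raise ValueError("grid edge must be positive")

    def edges(self, length: float) -> np.ndarray:
        n = int(np.ceil(length / self.edge - 1e-9))
        e = np.arange(n + 1, dtype=float) * self.edge
        e[-1] = length
        return e


@dataclass
class GridField:
    """Per-square species counts and height deviations for one frame.

    ``dz`` is NaN for squares without phosphate beads; those squares
    are excluded from the correlation (``defined`` mask).
    """

    counts: np.ndarray  # (n_squares,) int
    dz: np.ndarray      # (n_squares,) float, NaN = missing
    frame_index: int
    species: str

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.dz)

    @property
    def n_squares(self) -> int:
        return len(self.counts)


def grid_fields(frame: BeadFrame, species: str,
                grid: GridSpec = GridSpec(), leaflet: str = "upper",
                leaflet_map: Mapping[int, str] | None = None,
                dz_leaflet: str | None = "upper",
                po4_names: Sequence[str] = PO4_BEAD_NAMES) -> GridField:
    """Per-square species counts L_i and height deviations dz_i.

    ``leaflet`` restricts the counted species molecules to their
    first-frame leaflet of origin; ``dz_leaflet`` selects the phosphate
    beads defining the height field (default the upper leaflet, the
    surface the curvature analysis fits; ``None`` uses all phosphate
    beads).  Squares tile [0, Lx) x [0, Ly); coordinates are wrapped
    into the box first, so the counts over all squares sum to the
    number of species molecules.
    """
    if leaflet_map is None:
        leaflet_map = assign_leaflets(frame)
    ex = grid.edges(frame.box[0])
    ey = grid.edges(frame.box[1])
    nx, ny = len(ex) - 1, len(ey) - 1
    if nx < 1 or ny < 1:
        raise ValueError("box smaller than one grid square")

    def square_of(xy: np.ndarray) -> np.ndarray:
        x = np.mod(xy[:, 0], frame.box[0])
        y = np.mod(xy[:, 1], frame.box[1])
        ix = np.clip(np.searchsorted(ex, x, side="right") - 1, 0, nx - 1)
        iy = np.clip(np.searchsorted(ey, y, side="right") - 1, 0, ny - 1)
        return ix + nx * iy

    # species molecule counts from reference points (centres of geometry)
    sp_mask = species_matches(frame.species, species)
    counts = np.zeros(nx * ny, dtype=int)
    if np.any(sp_mask):
        mols = np.unique(frame.molids[sp_mask])
        keep = [m for m in mols if leaflet_map.get(int(m)) == leaflet]
        if keep:
            idx = np.flatnonzero(np.isin(frame.molids, keep))
            pts, _ = _cog_reference_points(frame.subframe(idx))
            np.add.at(counts, square_of(pts[:, :2]), 1)
        else:
            log.warning("species %s absent from the %s leaflet", species,
                        leaflet)
    else:
        log.warning("species %s absent from frame %d", species, frame.index)

    # height deviation field from phosphate beads
    po4 = np.isin(frame.names, po4_names)
    if dz_leaflet is not None:
        in_leaflet = np.fromiter(
            (leaflet_map.get(int(m)) == dz_leaflet for m in frame.molids),
            dtype=bool, count=frame.n_beads)
        po4 = po4 & in_leaflet
    dz = np.full(nx * ny, np.nan)
    if np.any(po4):
        zp = frame.coordinates[po4, 2]
        sq = square_of(frame.coordinates[po4, :2])
        mean_all = float(zp.mean())
        sums = np.zeros(nx * ny)
        nper = np.zeros(nx * ny, dtype=int)
        np.add.at(sums, sq, zp)
        np.add.at(nper, sq, 1)
        occupied = nper > 0
        dz[occupied] = sums[occupied] / nper[occupied] - mean_all
    return GridField(counts, dz, frame.index, species)


def cross_correlation(field: GridField) -> float:
    """Population Pearson correlation of (L_i, dz_i) over defined squares.

    NaN when either field is constant (zero standard deviation); raises
    if fewer than two squares have a defined height.
    """
    mask = field.defined
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least two squares with phosphate beads")
    L = field.counts[mask].astype(float)
    dz = field.dz[mask]
    sL = L.std()  # population (1/N) moments; the 1/N choice cancels in rho
    sZ = dz.std()
    if sL == 0.0 or sZ == 0.0:
        return float("nan")
    return float(((L - L.mean()) * (dz - dz.mean())).mean() / (sL * sZ))


def correlation_series(frames: Iterable[BeadFrame],
                       species: Sequence[str],
                       grid: GridSpec = GridSpec(),
                       leaflet_map: Mapping[int, str] | None = None,
                       dz_leaflet: str | None = "upper") -> pd.DataFrame:
    """Per-frame density-height correlation for each species.

    Species are stratified by their first-frame leaflet of origin;
    each (species, leaflet) stratum present in the first frame yields
    one row per frame with columns ``frame``, ``time_ps``, ``species``,
    ``leaflet_origin``, ``rho`` and ``n_squares``.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    if leaflet_map is None:
        leaflet_map = assign_leaflets(frames[0])
    strata: list[tuple[str, str]] = []
    for sp in species:
        mask = species_matches(frames[0].species, sp)
        sides = {leaflet_map.get(int(m))
                 for m in np.unique(frames[0].molids[mask])}
        for side in ("upper", "lower"):
            if side in sides:
                strata.append((sp, side))
    rows = []
    for fr in frames:
        for sp, side in strata:
            field = grid_fields(fr, sp, grid, leaflet=side,
                                leaflet_map=leaflet_map,
                                dz_leaflet=dz_leaflet)
            rows.append({
                "frame": fr.index,
                "time_ps": fr.time,
                "species": sp,
                "leaflet_origin": side,
                "rho": cross_correlation(field),
                "n_squares": int(field.defined.sum()),
            })
    return pd.DataFrame(rows)
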