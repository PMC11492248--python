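"""Leaflet assignment, DBSCAN lipid clustering and membrane triangulation.

Lipid molecules are frozen into upper/lower leaflets from their
positions in the first frame, and each species' reference points
(molecular centres of geometry) are clustered per frame with DBSCAN at
a 28 A neighbourhood radius and a five-molecule minimum.  DBSCAN is
implemented here (rather than delegated) so that an in-plane periodic
distance option exists and the algorithm can be validated against an
independent reference; a point counts towards its own neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .frame import BeadFrame, PO4_BEAD_NAMES, species_matches
from .io import resolve_reference_points

__all__ = [
    "ClusterSpec",
    "ClusterLabeling",
    "assign_leaflets",
    "dbscan_labels",
    "dbscan_cluster",
    "cluster_series",
    "height_triangulation",
    "choose_cluster_params",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterSpec:
    """DBSCAN parameters: neighbourhood radius (A), minimum cluster
    membership (the point itself included) and distance convention."""

    eps: float = 28.0
    min_points: int = 5
    convention: str = "raw"  # or "minimum-image" (periodic in x, y)

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.convention not in ("raw", "minimum-image"):
            raise ValueError(f"unknown convention {self.convention!r}")


@dataclass
class ClusterLabeling:
    """Per-molecule cluster labels for one frame (-1 = noise)."""

    ids: list[int]
    labels: np.ndarray
    frame_index: int = 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if np.any(self.labels >= 0) else 0

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == -1))

    def sizes(self) -> np.ndarray:
        if self.n_clusters == 0:
            return np.zeros(0, dtype=int)
        return np.bincount(self.labels[self.labels >= 0],
                           minlength=self.n_clusters)

    def as_mapping(self) -> dict[int, int]:
        return {int(i): int(l) for i, l in zip(self.ids, self.labels)}


def assign_leaflets(frame: BeadFrame,
                    po4_names: Sequence[str] = PO4_BEAD_NAMES,
                    ) -> dict[int, str]:
    """Freeze each lipid molecule into the upper or lower leaflet.

    The midplane is the mean z of all lipid phosphate-role beads in the
    given (first) frame; molecules whose phosphate sits above it are
    upper, the rest lower.  The returned map is meant to be reused for
    every later frame, so lipids that subsequently cross the midplane
    keep their original assignment.
    """
    po4 = np.isin(frame.names, po4_names) & (frame.names != "BB")
    if not np.any(po4):
        raise ValueError("no lipid phosphate beads; cannot assign leaflets")
    mid = float(frame.coordinates[po4, 2].mean())
    out: dict[int, str] = {}
    for mol in np.unique(frame.molids[po4]):
        idx = np.flatnonzero((frame.molids == mol) & po4)
        z = float(frame.coordinates[idx, 2].mean())
        out[int(mol)] = "upper" if z > mid else "lower"
    sides = set(out.values())
    if len(sides) == 1:
        log.warning("all lipids assigned to the %s leaflet; the membrane "
                    "appears single-leaflet", sides.pop())
    return out


def _neighbor_lists(points: np.ndarray, eps: float,
                    box: np.ndarray | None, convention: str,
                    ) -> list[np.ndarray]:
    """Index lists of points within eps (inclusive) of each point."""
    n = len(points)
    d = points[:, None, :] - points[None, :, :]
    if convention == "minimum-image":
        if box is None:
            raise ValueError("minimum-image distances require a box")
        for dim in (0, 1):
            L = box[dim]
            d[:, :, dim] -= L * np.round(d[:, :, dim] / L)
    dist2 = (d * d).sum(axis=2)
    mask = dist2 <= eps * eps
    return [np.flatnonzero(mask[i]) for i in range(n)]


def dbscan_labels(points: np.ndarray, eps: float = 28.0, min_points: int = 5,
                  box: Sequence[float] | None = None,
                  convention: str = "raw") -> np.ndarray:
    """DBSCAN labels for a point set; -1 marks noise.

    Core points have at least ``min_points`` neighbours within ``eps``
    (themselves included); clusters are maximal sets of
    density-connected core points plus their border points.  Points
    are visited in ascending index order, so labels are contiguous
    integers starting at 0 and deterministic for a given ordering; a
    border point reachable from several clusters joins the first one
    that claims it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-D array")
    n = len(pts)
    if n == 0:
        raise ValueError("need at least one point")
    box_arr = np.asarray(box, dtype=float) if box is not None else None
    neigh = _neighbor_lists(pts, eps, box_arr, convention)
    labels = np.full(n, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    cluster = -1
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        if len(neigh[i]) < min_points:
            continue  # noise unless later claimed as a border point
        cluster += 1
        labels[i] = cluster
        seeds = list(neigh[i])
        k = 0
        while k < len(seeds):
            j = seeds[k]
            k += 1
            if labels[j] == -1:
                labels[j] = cluster
            if not visited[j]:
                visited[j] = True
                if len(neigh[j]) >= min_points:
                    seeds.extend(neigh[j])
    return labels


def dbscan_cluster(points: np.ndarray, spec: ClusterSpec = ClusterSpec(),
                   box: Sequence[float] | None = None,
                   ids: Sequence[int] | None = None,
                   frame_index: int = 0) -> ClusterLabeling:
    labels = dbscan_labels(points, spec.eps, spec.min_points, box,
                           spec.convention)
    return ClusterLabeling(
        list(ids) if ids is not None else list(range(len(labels))),
        labels, frame_index)


def cluster_series(frames: Iterable[BeadFrame], species: str,
                   leaflet: str = "upper",
                   spec: ClusterSpec = ClusterSpec(),
                   leaflet_map: Mapping[int, str] | None = None,
                   ) -> tuple[pd.DataFrame, list[ClusterLabeling]]:
    """Cluster one species' molecules per frame; count/size time series.

    Reference points are molecular centres of geometry for every
    species (the D-bead contact convention does not apply to
    clustering).  Molecules are restricted to those assigned to
    ``leaflet`` in the first frame.  ``mean_size`` is NaN on frames
    with no cluster.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    if leaflet_map is None:
        leaflet_map = assign_leaflets(frames[0])
    sp_mask0 = species_matches(frames[0].species, species)
    if not np.any(sp_mask0):
        raise ValueError(f"species {species!r} not present")
    wanted = {mol for mol in np.unique(frames[0].molids[sp_mask0])
              if leaflet_map.get(int(mol)) == leaflet}
    if not wanted:
        raise ValueError(f"species {species!r} absent from the {leaflet} "
                         "leaflet")
    rows = []
    labelings = []
    for fr in frames:
        keep = np.flatnonzero(np.isin(fr.molids, sorted(wanted)))
        pts, ids = _cog_reference_points(fr.subframe(keep))
        lab = dbscan_cluster(pts, spec, fr.box, ids, fr.index)
        sizes = lab.sizes()
        rows.append({
            "frame": fr.index,
            "time_ps": fr.time,
            "n_clusters": lab.n_clusters,
            "mean_size": float(sizes.mean()) if len(sizes) else np.nan,
            "n_noise": lab.n_noise,
        })
        labelings.append(lab)
    return pd.DataFrame(rows), labelings


def _cog_reference_points(frame: BeadFrame) -> tuple[np.ndarray, list[int]]:
    """Centre of geometry of every molecule (all species alike)."""
    mols, first = np.unique(frame.molids, return_index=True)
    order = np.argsort(first)
    pts = [frame.coordinates[frame.molids == mol].mean(axis=0)
           for mol in mols[order]]
    return np.array(pts), [int(m) for m in mols[order]]


def height_triangulation(points: np.ndarray,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planar Delaunay triangulation of PO4 beads, coloured by height.

    Returns ``(vertices, simplices, values)`` where ``values[t]`` is the
    mean z of triangle t's three vertices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least three (x, y, z) points")
    try:
        tri = Delaunay(pts[:, :2])
    except QhullError as exc:
        raise ValueError(f"cannot triangulate: degenerate planar "
                         f"configuration ({exc})") from exc
    if len(tri.simplices) == 0:
        raise ValueError("cannot triangulate: collinear points")
    values = pts[tri.simplices, 2].mean(axis=1)
    return pts, tri.simplices, values


def choose_cluster_params(points: np.ndarray,
                          eps_grid: Sequence[float],
                          min_points_grid: Sequence[int],
                          box: Sequence[float] | None = None,
                          convention: str = "raw") -> tuple[ClusterSpec, int]:
    """Grid search for the (eps, min_points) pair that minimises the
    unclustered (noise) group in one frame; ties prefer smaller eps
    then smaller min_points.  Returns the spec and its noise count.
    """
    best: tuple[int, float, int] | None = None
    for eps in sorted(eps_grid):
        for mp in sorted(min_points_grid):
            labels = dbscan_labels(points, eps, mp, box, convention)
            noise = int(np.sum(labels == -1))
            key = (noise, eps, mp)
            if best is None or key < best:
                best = key
    assert best is not None
    noise, eps, mp = best
    return ClusterSpec(eps=eps, min_points=mp, convention=convention), noise
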