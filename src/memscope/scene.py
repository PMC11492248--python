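"""Synthetic coarse-grained membrane/capsid scenes with exact ground truth.

Fixtures for every analysis stage are constructed, not simulated: a
roughly planar bilayer patch whose upper-leaflet surface follows a
known analytic height function (so curvature has a closed form), a
stated lipid species mixture per leaflet, optional planted lipid
clusters of known membership, a rigid icosahedral capsid shell, and
scripted rigid rotations.  Every generator is deterministic for a
fixed seed and returns a :class:`SceneTruth` recording the ground
truth the downstream analyses are expected to recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import cdist

from .curvature import FORMS
from .frame import BeadFrame, merge_frames, species_matches

__all__ = [
    "SurfaceParams",
    "Composition",
    "SceneTruth",
    "make_membrane_frame",
    "plant_species_clusters",
    "make_capsid_shell",
    "make_trajectory",
]

#: Vertical offsets (angstrom) of the auxiliary beads of each synthetic
#: lipid relative to its PO4 bead, signed towards the bilayer core.
TAIL_OFFSET = 10.0
D_BEAD_OFFSET = 6.0
CAPSID_SPECIES = "CAPS"


@dataclass
class SurfaceParams:
    """Parameters of the plane + Gaussian-dimple height surface (angstrom).

    ``A < 0`` is a downward dimple of in-plane widths ``sx``, ``sy``
    centred at ``(x0, y0)``; ``c0 + c1 x + c2 y`` is the underlying
    plane.
    """

    c0: float = 50.0
    c1: float = 0.0
    c2: float = 0.0
    A: float = 0.0
    x0: float = 0.0
    y0: float = 0.0
    sx: float = 80.0
    sy: float = 80.0
    form_id: str = "plane_gaussian"

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("dimple widths sx, sy must be positive")

    def vector(self) -> np.ndarray:
        return np.array([self.c0, self.c1, self.c2, self.A,
                         self.x0, self.y0, self.sx, self.sy])

    def height(self, x, y) -> np.ndarray:
        z = FORMS[self.form_id].height(self.vector(), np.asarray(x, float),
                                       np.asarray(y, float))
        if not np.all(np.isfinite(z)):
            raise ValueError("surface evaluates to non-finite heights")
        return z


# Leaflet mixtures of the emulated plasma-membrane patch.
UPPER_RATIO = {"POPC": 25, "DOPC": 25, "POPE": 8, "DOPE": 7, "CHOL": 25,
               "DPG3": 10}
LOWER_RATIO = {"POPC": 5, "DOPC": 5, "POPE": 20, "DOPE": 20, "CHOL": 25,
               "POPS": 8, "DOPS": 7, "POP2": 10}


@dataclass
class Composition:
    """Integer mixing ratio of lipid species within one leaflet."""

    parts: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.parts.values()):
            raise ValueError("ratio parts must be non-negative")
        if not any(v > 0 for v in self.parts.values()):
            raise ValueError("at least one species must have a positive part")

    @classmethod
    def default_upper(cls) -> "Composition":
        return cls(dict(UPPER_RATIO))

    @classmethod
    def default_lower(cls) -> "Composition":
        return cls(dict(LOWER_RATIO))

    def counts(self, n: int) -> dict[str, int]:
        """Apportion ``n`` molecules by largest remainder; conserves n."""
        if n < 0:
            raise ValueError("molecule count must be non-negative")
        total = sum(self.parts.values())
        quotas = {s: n * p / total for s, p in self.parts.items()}
        counts = {s: int(math.floor(q)) for s, q in quotas.items()}
        short = n - sum(counts.values())
        # ties broken by species insertion order (stable sort)
        order = sorted(self.parts, key=lambda s: quotas[s] - counts[s],
                       reverse=True)
        for s in order[:short]:
            counts[s] += 1
        return counts


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene.

    ``surface`` is one :class:`SurfaceParams` (static scene) or one per
    frame; ``planted_cluster_labels`` maps molecule id to cluster id
    (-1 = deliberately unclustered); ``rotation_schedule`` maps frame
    index to the capsid rotation angle in degrees about
    ``rotation_axis``; ``planted_contact_pairs`` is a set of
    (residue id, molecule id) pairs constructed to be in contact.
    """

    surface: SurfaceParams | list[SurfaceParams] | None = None
    planted_cluster_labels: dict[int, int] = field(default_factory=dict)
    rotation_schedule: dict[int, float] = field(default_factory=dict)
    rotation_axis: tuple[float, float, float] | None = None
    planted_contact_pairs: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.rotation_schedule = {
            int(k): float(v) % 360.0 for k, v in self.rotation_schedule.items()
        }

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for lab in self.planted_cluster_labels.values():
            if lab >= 0:
                sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def to_json(self, path) -> None:
        surf = self.surface
        if isinstance(surf, SurfaceParams):
            surf_ser = asdict(surf)
        elif surf is None:
            surf_ser = None
        else:
            surf_ser = [asdict(s) for s in surf]
        payload = {
            "surface": surf_ser,
            "planted_cluster_labels": {str(k): v for k, v in
                                       self.planted_cluster_labels.items()},
            "rotation_schedule": {str(k): v for k, v in
                                  self.rotation_schedule.items()},
            "rotation_axis": list(self.rotation_axis) if self.rotation_axis else None,
            "planted_contact_pairs": sorted(list(p) for p in
                                            self.planted_contact_pairs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SceneTruth":
        with open(path) as fh:
            payload = json.load(fh)
        surf = payload.get("surface")
        if isinstance(surf, dict):
            surface = SurfaceParams(**surf)
        elif isinstance(surf, list):
            surface = [SurfaceParams(**s) for s in surf]
        else:
            surface = None
        return cls(
            surface=surface,
            planted_cluster_labels={int(k): int(v) for k, v in
                                    payload["planted_cluster_labels"].items()},
            rotation_schedule={int(k): float(v) for k, v in
                               payload["rotation_schedule"].items()},
            rotation_axis=tuple(payload["rotation_axis"])
            if payload.get("rotation_axis") else None,
            planted_contact_pairs={tuple(p) for p in
                                   payload["planted_contact_pairs"]},
        )


# --------------------------------------------------------------------------
# in-plane placement


def _place_in_plane(n: int, lx: float, ly: float, min_spacing: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Blue-noise-like stratified placement of n points in [0,lx)x[0,ly).

    Points are laid on a jittered grid whose cell pitch exceeds the
    minimum spacing, which guarantees the hard minimum distance (also
    across the periodic wrap) while reaching realistic area-per-lipid
    densities deterministically.
    """
    if n == 0:
        return np.zeros((0, 2))
    ncol = max(1, int(math.floor(lx / max(min_spacing, 1e-9))))
    # grow rows/cols to fit n cells, preferring near-square cells
    ncol = max(1, int(round(math.sqrt(n * lx / ly))))
    nrow = int(math.ceil(n / ncol))
    while ncol * nrow < n:
        nrow += 1
    ax = lx / ncol
    ay = ly / nrow
    if min(ax, ay) < min_spacing:
        raise ValueError(
            f"cannot place {n} points with {min_spacing} A spacing in a "
            f"{lx:.0f} x {ly:.0f} A patch")
    jx = (ax - min_spacing) / 2.0
    jy = (ay - min_spacing) / 2.0
    cells = rng.permutation(ncol * nrow)[:n]
    ix = cells % ncol
    iy = cells // ncol
    x = (ix + 0.5) * ax + rng.uniform(-jx, jx, size=n)
    y = (iy + 0.5) * ay + rng.uniform(-jy, jy, size=n)
    return np.column_stack([x, y])


def make_membrane_frame(surface: SurfaceParams,
                        composition: Composition | Sequence[Composition] | None = None,
                        n_per_leaflet: int = 500,
                        box: Sequence[float] = (500.0, 500.0, 500.0),
                        seed: int = 0,
                        bilayer_thickness: float = 40.0,
                        min_spacing: float = 8.0,
                        z_noise_sd: float = 0.0) -> tuple[BeadFrame, SceneTruth]:
    """Construct a two-leaflet bilayer patch laid on an analytic surface.

    Upper-leaflet PO4 beads sit exactly on ``z = surface(x, y)`` (plus
    optional Gaussian height noise) and lower-leaflet PO4 beads at
    ``surface(x, y) - bilayer_thickness``.  Each lipid carries a PO4
    surface-marker bead and a C1 tail bead (its centre of geometry
    proxy); GM3 (DPG3) lipids additionally carry a headgroup D bead.
    Species are apportioned by largest remainder of the leaflet ratio.

    ``composition`` may be a single :class:`Composition` (both
    leaflets) or an (upper, lower) pair; the default is the emulated
    plasma-membrane mixture.
    """
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths")
    if n_per_leaflet < 0:
        raise ValueError("n_per_leaflet must be non-negative")
    if composition is None:
        comps = (Composition.default_upper(), Composition.default_lower())
    elif isinstance(composition, Composition):
        comps = (composition, composition)
    else:
        comps = tuple(composition)
        if len(comps) != 2:
            raise ValueError("composition must be one Composition or an "
                             "(upper, lower) pair")
    for comp in comps:
        if n_per_leaflet < sum(1 for v in comp.parts.values() if v > 0):
            raise ValueError("n_per_leaflet smaller than the number of "
                             "species in the ratio")
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    names: list[str] = []
    resids: list[int] = []
    molids: list[int] = []
    species: list[str] = []
    mol = 0
    for leaflet, comp in zip(("upper", "lower"), comps):
        xy = _place_in_plane(n_per_leaflet, box[0], box[1], min_spacing, rng)
        counts = comp.counts(n_per_leaflet)
        labels = np.array(
            [s for s, c in counts.items() for _ in range(c)], dtype=object)
        labels = labels[rng.permutation(n_per_leaflet)]
        z_surf = surface.height(xy[:, 0], xy[:, 1])
        if leaflet == "lower":
            z_surf = z_surf - bilayer_thickness
        if z_noise_sd > 0:
            z_surf = z_surf + rng.normal(0.0, z_noise_sd, size=n_per_leaflet)
        sign = -1.0 if leaflet == "upper" else 1.0  # towards bilayer core
        for i in range(n_per_leaflet):
            mol += 1
            x, y, zp = xy[i, 0], xy[i, 1], z_surf[i]
            beads = [("PO4", zp), ("C1", zp + sign * TAIL_OFFSET)]
            if labels[i] == "DPG3":
                beads.append(("D", zp - sign * D_BEAD_OFFSET))
            for bead_name, z in beads:
                coords.append(np.array([x, y, z]))
                names.append(bead_name)
                resids.append(mol)
                molids.append(mol)
                species.append(str(labels[i]))
    frame = BeadFrame(
        np.array(coords) if coords else np.zeros((0, 3)),
        np.array(names, dtype=object),
        np.array(resids, dtype=int),
        np.array(molids, dtype=int),
        np.array(species, dtype=object),
        box,
    )
    return frame, SceneTruth(surface=surface)


# --------------------------------------------------------------------------
# planted clusters


def _sample_separated(n: int, low: np.ndarray, high: np.ndarray,
                      min_sep: float, rng: np.random.Generator,
                      fixed: np.ndarray | None = None,
                      max_attempts: int = 200_000) -> np.ndarray:
    """Dart-throwing sampler: n points in a rectangle, pairwise > min_sep
    and > min_sep from every ``fixed`` point."""
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"cannot place {n} points {min_sep:.0f} A apart in the box: "
                "impossible packing")
        p = rng.uniform(low, high)
        if fixed is not None and len(fixed) and (
                np.min(np.linalg.norm(fixed - p, axis=1)) <= min_sep):
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) <= min_sep:
            continue
        pts.append(p)
    return np.array(pts)


def _blob_offsets(size: int, spread: float, eps: float,
                  rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Offsets of one planted blob: uniform in a disc of radius ``spread``,
    resampled until the blob is one DBSCAN-connected cluster (size >= 5)."""
    from .clusters import dbscan_labels  # late import avoids a cycle
    from .contacts import ContactSpec

    for _ in range(max_tries):
        r = spread * np.sqrt(rng.uniform(0, 1, size=size))
        th = rng.uniform(0, 2 * np.pi, size=size)
        off = np.column_stack([r * np.cos(th), r * np.sin(th)])
        if size < 5:
            return off
        pts = np.column_stack([off, np.zeros(size)])
        labels = dbscan_labels(pts, eps=eps, min_points=5)
        if np.all(labels == 0):
            return off
    raise ValueError("could not build a density-connected blob; "
                     "increase spread or size")


def plant_species_clusters(frame: BeadFrame, species: str, k: int, size: int,
                           spread: float, seed: int = 0, eps: float = 28.0,
                           surface: SurfaceParams | None = None,
                           ) -> tuple[BeadFrame, SceneTruth]:
    """Relocate molecules of one species into k planted clusters.

    ``k`` disjoint groups of ``size`` molecules are moved into blobs of
    radius about ``spread`` whose centres are mutually separated by
    more than ``2 * (spread + eps)``; every remaining molecule of the
    species is re-laid more than ``eps`` from every blob member and
    from every other remaining molecule, so a DBSCAN pass at ``eps``
    recovers exactly the planted memberships (remaining molecules are
    noise).  Other species are untouched.  When ``surface`` is given,
    relocated beads keep their height offset relative to it.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    mols = frame.molecule_ids(species)
    if k * size > len(mols):
        raise ValueError(f"k*size = {k * size} exceeds the {len(mols)} "
                         f"molecules of species {species}")
    rng = np.random.default_rng(seed)
    box = frame.box
    margin = spread + 1.2 * eps
    if 2 * margin >= min(box[0], box[1]):
        raise ValueError("box too small for the requested blob geometry")
    low = np.array([margin, margin])
    high = np.array([box[0] - margin, box[1] - margin])
    centers = _sample_separated(k, low, high, 2 * (spread + eps) * 1.02, rng)

    order = rng.permutation(mols)
    members = order[:k * size]
    rest = order[k * size:]

    new_frame = frame.copy()
    member_xy: list[np.ndarray] = []
    labels: dict[int, int] = {}

    def _move(mol: int, new_xy: np.ndarray) -> None:
        idx = np.flatnonzero(new_frame.molids == mol)
        po4 = idx[new_frame.names[idx] == "PO4"]
        anchor = new_frame.coordinates[po4[0] if len(po4) else idx[0], :2]
        delta = np.zeros(3)
        delta[:2] = new_xy - anchor
        if surface is not None:
            z_old = surface.height(anchor[0], anchor[1])
            z_new = surface.height(new_xy[0], new_xy[1])
            delta[2] = float(z_new - z_old)
        new_frame.coordinates[idx] += delta

    for b in range(k):
        off = _blob_offsets(size, spread, eps, rng)
        for j, mol in enumerate(members[b * size:(b + 1) * size]):
            xy = centers[b] + off[j]
            _move(int(mol), xy)
            member_xy.append(xy)
            labels[int(mol)] = b
    member_xy_arr = np.array(member_xy) if member_xy else np.zeros((0, 2))
    pad = 0.5 * eps
    rest_xy = _sample_separated(
        len(rest), np.array([pad, pad]), np.array([box[0] - pad, box[1] - pad]),
        1.05 * eps, rng, fixed=member_xy_arr)
    for j, mol in enumerate(rest):
        _move(int(mol), rest_xy[j])
        labels[int(mol)] = -1
    return new_frame, SceneTruth(surface=surface,
                                 planted_cluster_labels=labels)


# --------------------------------------------------------------------------
# capsid shell


def _icosahedron_vertices() -> np.ndarray:
    phi = (1 + math.sqrt(5)) / 2
    verts = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            verts += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(verts)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_capsid_shell(center: Sequence[float] = (0.0, 0.0, 0.0),
                      radius: float = 125.0, beads_per_face: int = 20,
                      seed: int = 0, cap_half_angle_deg: float = 31.0,
                      ) -> BeadFrame:
    """Rigid icosahedral shell of backbone beads.

    Beads lie exactly on a sphere of the given radius (default 125 A,
    i.e. a ~25 nm capsid diameter), grouped into 12 spherical caps
    around the icosahedral vertex directions.  The pentamer index
    (1-12) is stored as the molecule id; each bead is one synthetic
    residue with a BB bead, so the shell plugs directly into the
    contact and orientation analyses.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if beads_per_face <= 0:
        raise ValueError("beads_per_face must be positive")
    center = np.asarray(center, dtype=float)
    rng = np.random.default_rng(seed)
    verts = _icosahedron_vertices()
    cos_cap = math.cos(math.radians(cap_half_angle_deg))
    golden_angle = math.pi * (3 - math.sqrt(5))
    coords = []
    molids = []
    for pent, v in enumerate(verts, start=1):
        # local orthonormal frame with v as the pole
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, v)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(v, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(v, e1)
        phase = rng.uniform(0, 2 * math.pi)
        for b in range(beads_per_face):
            cos_t = 1.0 - (1.0 - cos_cap) * (b + 0.5) / beads_per_face
            sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            ang = phase + b * golden_angle
            d = cos_t * v + sin_t * (math.cos(ang) * e1 + math.sin(ang) * e2)
            coords.append(center + radius * d / np.linalg.norm(d))
            molids.append(pent)
    n = len(coords)
    return BeadFrame(
        np.array(coords),
        np.array(["BB"] * n, dtype=object),
        np.arange(1, n + 1),
        np.array(molids, dtype=int),
        np.array([CAPSID_SPECIES] * n, dtype=object),
        np.full(3, 2 * radius + 50.0),
    )


# --------------------------------------------------------------------------
# trajectories


def make_trajectory(base: BeadFrame, n_frames: int,
                    rotation_schedule: Sequence[float] | None = None,
                    rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
                    dimple_schedule: Sequence[SurfaceParams] | None = None,
                    base_surface: SurfaceParams | None = None,
                    seed: int = 0, dt: float = 1000.0,
                    z_noise_sd: float = 0.0,
                    ) -> tuple[list[BeadFrame], SceneTruth]:
    """Scripted trajectory from a base frame.

    Capsid beads (species ``CAPS``) are rigidly rotated about their
    base-frame centroid by ``rotation_schedule[i]`` degrees around
    ``rotation_axis``; membrane beads are re-laid on
    ``dimple_schedule[i]`` keeping each bead's height offset relative
    to ``base_surface`` (defaults to the first schedule entry).  Frame
    times increase by ``dt`` picoseconds.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if rotation_schedule is not None and len(rotation_schedule) != n_frames:
        raise ValueError("rotation schedule length != n_frames")
    if dimple_schedule is not None and len(dimple_schedule) != n_frames:
        raise ValueError("dimple schedule length != n_frames")
    rng = np.random.default_rng(seed)
    cap_mask = species_matches(base.species, CAPSID_SPECIES)
    mem_mask = ~cap_mask
    centroid = (base.coordinates[cap_mask].mean(axis=0)
                if np.any(cap_mask) else np.zeros(3))
    axis = np.asarray(rotation_axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if rotation_schedule is not None and nrm == 0:
        raise ValueError("rotation axis must be non-zero")
    axis = axis / nrm if nrm else axis

    offsets = None
    if dimple_schedule is not None:
        s0 = base_surface if base_surface is not None else dimple_schedule[0]
        xy = base.coordinates[mem_mask, :2]
        offsets = base.coordinates[mem_mask, 2] - s0.height(xy[:, 0], xy[:, 1])

    frames: list[BeadFrame] = []
    truth = SceneTruth(
        surface=list(dimple_schedule) if dimple_schedule is not None else None,
        rotation_schedule={i: float(rotation_schedule[i])
                           for i in range(n_frames)}
        if rotation_schedule is not None else {},
        rotation_axis=tuple(axis) if rotation_schedule is not None else None,
    )
    for i in range(n_frames):
        coords = base.coordinates.copy()
        if dimple_schedule is not None:
            xy = coords[mem_mask, :2]
            z = dimple_schedule[i].height(xy[:, 0], xy[:, 1]) + offsets
            if z_noise_sd > 0:
                z = z + rng.normal(0.0, z_noise_sd, size=len(z))
            coords[mem_mask, 2] = z
        if rotation_schedule is not None and np.any(cap_mask):
            rot = Rotation.from_rotvec(
                np.radians(float(rotation_schedule[i])) * axis)
            coords[cap_mask] = centroid + rot.apply(coords[cap_mask] - centroid)
        frames.append(base.with_coordinates(coords, time=i * dt, index=i))
    return frames, truth


def plant_contacts(frame: BeadFrame, pairs: Sequence[tuple[int, int]],
                   distance: float = 5.0, seed: int = 0,
                   ) -> tuple[BeadFrame, SceneTruth]:
    """Move lipid molecules so their reference points sit ``distance``
    angstrom from given protein residues' BB beads (ground-truth
    contacts for testing)."""
    from .io import resolve_reference_points

    rng = np.random.default_rng(seed)
    new_frame = frame.copy()
    truth_pairs: set[tuple[int, int]] = set()
    for resid, molid in pairs:
        bb = np.flatnonzero((new_frame.resids == resid)
                            & (new_frame.names == "BB"))
        if not len(bb):
            raise ValueError(f"residue {resid} has no BB bead")
        target = new_frame.coordinates[bb[0]]
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        idx = np.flatnonzero(new_frame.molids == molid)
        if not len(idx):
            raise ValueError(f"molecule {molid} not found")
        sub = new_frame.subframe(idx)
        ref, _ = resolve_reference_points(sub, role="lipid-molecule")
        new_frame.coordinates[idx] += (target + distance * d) - ref[0]
        truth_pairs.add((int(resid), int(molid)))
    return new_frame, SceneTruth(planted_contact_pairs=truth_pairs)
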