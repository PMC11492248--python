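# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-scene generator does and does not
emulate, and the known limitations.

## Units and containers

All coordinates are angstrom and all times picoseconds internally;
conversions happen only at file boundaries (GRO and XTC store nanometres).
A trajectory is a sequence of `BeadFrame`s: coordinates, bead names,
residue ids, molecule ids, species labels (residue names), orthorhombic box
and time. Species selections are alias-aware (GM3 ↔ DPG3, PIP2 ↔ POP2), so
selections written against common lipid names also match the CG residue
names. Coordinates are assumed wrapped into the primary box; no unwrapping
is performed — analyses that need it use minimum-image distances in the
membrane plane.

## Membrane curvature

The upper-leaflet PO4 bead cloud of each frame is fitted with a parametric
height function. The default family is a tilted plane plus one anisotropic
Gaussian dimple,

    z(x, y) = c0 + c1·x + c2·y + A·exp(−((x−x0)²/(2sx²) + (y−y0)²/(2sy²)))

chosen because a roughly planar patch with a single capsid-induced
depression is the geometry of interest; a pure plane, a biquadratic
polynomial and a separable cosine bump are registry alternatives selected
by `form_id`, and new families plug in by registering height/derivative
callables.

Fitting is Levenberg–Marquardt least squares (`scipy.optimize.least_squares`,
`method="lm"`) from a deterministic initial guess: `c0` = mean height,
`c1 = c2 = 0`, dimple seeded at the lowest bead with the observed depth,
widths at one sixth of the patch extent. Tolerances are `ftol = xtol =
gtol = 1e-12` with a 10⁴-evaluation budget (exhaustion raises, carrying the
last iterate); the tight tolerances are what make the noise-free recovery
and scaling-law properties hold to 1e-6 relative. Each frame is fitted
independently (a warm-start flag exists but is off by default). Degenerate
inputs — fewer points than parameters, or planar coordinates of rank < 3 —
raise before optimization. Fitted Gaussian widths are reported as absolute
values (the sign is not identifiable).

Curvatures are the Monge-patch *normal* curvatures along the box axes,

    κx = z_xx / (1 + z_x²)^{3/2},   κy = z_yy / (1 + z_y²)^{3/2}

evaluated from analytic derivatives of the fitted form at each bead's
(x, y); the x/y axes are treated as the principal directions of the nearly
axis-aligned patch. A full shape-operator eigendecomposition
(`shape_operator_curvatures`) is available where that assumption is too
strong. Each bead gets the unsigned Gaussian curvature `|K| = |κx·κy|`, and
the frame observable is the arithmetic mean over the analyzed beads (not
over a uniform grid), since the assignment is per bead.

## Contacts and occupancy

Reference points: protein residues use their BB bead; lipid molecules use
the centre of geometry of all their beads, except GM3, whose centre of
geometry is buried in the membrane and which therefore uses its
carboxyl-group D bead. A contact is a pair of reference points *strictly*
closer than the cutoff (default 10 Å); a pair exactly at the cutoff is not
in contact.

Distances are minimum-image in x and y (the bilayer is periodic in-plane)
and raw in z by default; a raw-Euclidean convention reproduces naive
behaviour. Detection runs on a cell list with bin width equal to the
cutoff; correctness is defined by the brute-force all-pairs computation the
tests compare against, not by the acceleration. Contact frequency is
counted both per pair and per residue (sum over partners); the per-residue
counts can be written into the PDB B-factor column (two decimals, values
clamped to the 6-character field with a warning). Occupancy of a residue by
a species is the fraction of window frames with at least one contact to any
molecule of that species; the window is an inclusive frame-position pair.

## Leaflets and clustering

Leaflet assignment is frozen at the first frame: the midplane is the mean z
of all lipid phosphate beads, molecules above it are "upper". Lipids that
later cross the midplane keep their original label. A deeply dimpled first
frame can place dimple-bottom upper lipids below the global midplane; for
synthetic fixtures the assignment is therefore taken from the flat initial
frame (or from construction truth), matching how a real trajectory starts
from an undeformed membrane.

DBSCAN is implemented in the package (neighbourhood radius eps = 28 Å,
minimum membership 5 *including the point itself*; both defaults follow the
noise-minimisation criterion on the final-frame GM3 pool, and a grid-search
utility `choose_cluster_params` re-runs that criterion on any frame).
Points are visited in ascending index order with FIFO expansion, so labels
are contiguous from 0 and deterministic; noise is −1. Clustering distances
are raw Euclidean by default with an in-plane minimum-image option — the
in-repo implementation exists precisely so that the periodic option and
oracle comparisons are possible; scikit-learn's DBSCAN appears only as an
independent cross-check in the tests. Which cluster claims a border point
shared between two clusters is order-dependent (inherent to DBSCAN); noise
status and the core-point partition are not.

Clustering uses centres of geometry for *all* species, including GM3 — the
D-bead convention applies to contacts only. The per-frame series reports
cluster count, mean size over non-noise clusters (NaN when no cluster
exists) and noise count. The 2-D height map is a planar Delaunay
triangulation of upper-leaflet PO4 beads with each triangle coloured by the
mean z of its vertices.

## Density–height correlation

Each frame's membrane plane is tiled from the box origin with squares of
edge 18 Å; a final partial row/column is kept as a smaller square so the
per-square counts sum exactly to the number of molecules of the species
(coordinates are wrapped into the box first). `L_i` counts the species'
reference points; `Δz_i` is the mean PO4 height in square i minus the mean
over the whole membrane that frame, taken from upper-leaflet PO4 beads by
default (the surface the curvature stage fits; an option uses all PO4
beads). Squares with no PO4 bead are excluded; squares with PO4 beads but
zero species count contribute `L_i = 0` — they carry signal.

The coefficient is the Pearson correlation with population (1/N) moments;
the 1/N-vs-1/(N−1) choice cancels in ρ. ρ is reported missing (NaN) when
either field has zero variance, and fewer than two defined squares is an
error. Species are stratified by their first-frame leaflet of origin, so
e.g. upper- and lower-leaflet POPC are separate series.

## Orientation

The tracked quantity is the angle between the unit vector joining two
chosen residues' BB beads in frame t and the same vector in the first
frame: `arccos(clamp(v_t·v_0, −1, 1))` in degrees, in [0, 180]. The residue
pair is a configuration input (a chord roughly parallel to the capsid
diameter works best). Rotations about the axis parallel to v₀ are invisible
to this single-vector measure — a documented limitation, not a defect. No
minimum-image correction is applied within the capsid, which is a compact
rigid body assumed whole in the box.

## Pipeline

A YAML config carries input paths, stage toggles, all analysis parameters
(contact cutoff 10 Å, DBSCAN 28 Å / 5, grid edge 18 Å, 200-frame rolling
window), an every-k-th-frame subsampling factor for desk-scale runs, an
output directory and a seed. Stages run in dependency order (I/O → leaflet
assignment → the five independent analyses); any failure aborts with the
stage name. Outputs are CSV tables plus a JSON manifest (config echo,
package/library versions, frame count) containing no timestamps, so a rerun
with identical config and inputs is bit-identical. The rolling average is a
trailing window whose first `window−1` entries shrink to the available
history, preserving series length.

## Synthetic scenes: what they emulate and what they do not

The generator reproduces the *geometry and labelling* of the simulated
systems: a ~50 × 50 nm bilayer patch with the stated leaflet mixtures
(largest-remainder apportionment of the integer ratios), a 40 Å inter-PO4
bilayer thickness (a typical CG value; only the relative leaflet separation
matters for leaflet tests), upper-leaflet surfaces with known analytic
curvature, a rigid icosahedral shell of 125 Å radius (~25 nm capsid
diameter) whose pentamer index is the molecule id, planted clusters with
recorded memberships, and scripted rigid rotations.

In-plane lipid placement is blue-noise-like stratified sampling: positions
are drawn on a jittered grid whose pitch exceeds the minimum spacing
(default 8 Å, a realistic area-per-lipid scale), which guarantees the hard
minimum distance — including across the periodic boundary — at densities
where plain dart throwing stalls, and is deterministic per seed. Each
synthetic lipid is minimal: a PO4 surface-marker bead, a C1 tail bead
(centre-of-geometry proxy), and for GM3 a headgroup D bead.

Cluster planting relocates k disjoint groups into discs of radius ≈ spread
whose centres are separated by more than 2·(spread + eps); blob offsets are
resampled until the blob is one density-connected cluster, and the
remaining molecules of the species are re-laid more than eps from every
blob member *and from each other*, so planted memberships are exactly
recoverable by construction for any seed (remaining molecules are noise).

Not emulated: physical dynamics of any kind (frames are constructed, not
simulated — no diffusion, no thermal roughness unless a height-noise SD is
requested), solvent/ion beads, realistic lipid internal structure, membrane
undulation spectra, or protein conformational change. Passing tests
therefore demonstrate the *correctness of the measurements* on scenes with
known answers, not the biological behaviour of real trajectories; on real
data the same code paths apply unchanged, but statistical properties
(noise in fits, border-point ambiguity in DBSCAN) will reflect the data.

## Problem sizes

Verification runs use desk-scale scenes chosen to exercise every code path
quickly: 2,500-bead upper leaflets for curvature recovery, 200 random
100 × 100 scenes for the contact oracle, 100 random 300-point scenes plus a
planted grid (k ∈ {1,2,3} × size ∈ {5,10,40}) for DBSCAN, 100 seeds for the
correlation null, and a 20-frame membrane + capsid trajectory for pipeline
determinism. `scripts/acceptance.py` recomputes all of these from scratch.
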