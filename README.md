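# memscope

Analysis toolkit for coarse-grained (CG) molecular-dynamics trajectories of
virus-capsid / plasma-membrane systems. It quantifies how a bound icosahedral
capsid deforms a lipid bilayer and how lipid species reorganize around it:

- **Membrane curvature** — the upper-leaflet phosphate (PO4) bead cloud of
  every frame is fitted with a Monge-patch height function
  `z(x,y) = c0 + c1·x + c2·y + A·exp(−((x−x0)²/2sx² + (y−y0)²/2sy²))`
  by Levenberg–Marquardt least squares; normal curvatures along the box axes
  are `κx = z_xx/(1+z_x²)^{3/2}` and `κy = z_yy/(1+z_y²)^{3/2}`, each bead is
  assigned the unsigned Gaussian curvature `|K| = |κx·κy|`, and the per-frame
  observable is the mean of `|K|` over beads (Å⁻²).
- **Protein–lipid contacts and occupancy** — a contact is two reference
  points (protein backbone BB bead; lipid centre of geometry, or the
  carboxyl-group D bead for GM3) strictly closer than 10 Å; contact
  frequencies can be written into the PDB B-factor column, and occupancy is
  the fraction of window frames in which a residue touches at least one
  molecule of a species.
- **Lipid clustering** — molecules are frozen into leaflets from the first
  frame; each species' centres of geometry are clustered per frame with an
  in-repo DBSCAN (eps 28 Å, minimum 5 molecules), giving cluster-count and
  mean-size time series, plus a Delaunay height-map triangulation.
- **Density–height correlation** — the membrane plane is tiled with 18 Å
  squares; the per-frame Pearson correlation between per-square molecule
  counts `L_i` and height deviations `Δz_i` measures whether a species
  concentrates where the membrane dips.
- **Capsid orientation** — the angle between a body-fixed residue-pair
  vector and its first-frame direction, from the clamped dot product, in
  degrees.
- **Synthetic scenes** — every stage is verifiable against exact ground
  truth: bilayer patches laid on analytic surfaces with the plasma-membrane
  species mixture (upper leaflet POPC/DOPC/POPE/DOPE/CHOL/DPG3 = 25:25:8:7:25:10,
  lower POPC/DOPC/POPE/DOPE/CHOL/POPS/DOPS/POP2 = 5:5:20:20:25:8:7:10),
  planted lipid clusters, a rigid 125 Å icosahedral shell, and scripted
  rotations.

File I/O (GRO/PDB/XTC/TRR) goes through MDAnalysis; internal units are
angstrom and picosecond.

## Worked example

```python
from memscope import SurfaceParams, bead_curvatures, fit_surface, \
    make_membrane_frame

truth = SurfaceParams(c0=50, A=-30, x0=250, y0=250, sx=80, sy=80)
frame, _ = make_membrane_frame(truth, n_per_leaflet=1000,
                               box=(500, 500, 500), seed=1)
po4 = (frame.molids <= 1000) & (frame.names == "PO4")
fit = fit_surface(frame.coordinates[po4])
print(fit.coefficients)
print(bead_curvatures(fit, frame.coordinates[po4][:, :2]).mean_abs_gaussian)
```

prints

```
{'c0': 50.0, 'c1': -5.886348798077411e-18, 'c2': -6.093577770663317e-20,
 'A': -30.000000000000004, 'x0': 250.0, 'y0': 250.0,
 'sx': 79.99999999999999, 'sy': 80.0}
9.873774317127967e-07
```

i.e. the fit recovers the generating surface exactly and a 30 Å-deep,
80 Å-wide dimple in a 50 nm patch carries a mean unsigned Gaussian curvature
of ~1e-6 Å⁻² — the scale of curvature a capsid-sized indentation induces.
The `examples/` directory has one short script per capability (curvature,
contacts/occupancy, clustering, correlation, orientation, full pipeline),
each printing the numbers it computes and what they mean.

A thin CLI mirrors the stages:

```bash
memscope synth --n-per-leaflet 500 --dimple-amplitude -30 --out scene
memscope curvature --topology scene.gro --out curvature.csv
memscope run --config analysis.yaml
```

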