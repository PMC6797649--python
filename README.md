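# lsmd — Laplacian shape matching with a differential displacement field

Non-rigid registration of largely deformed closed surfaces (for example lung
lobes in inflated and deflated states), built around a progressive
Laplacian-based shape-matching loop that smooths the *displacement field*
(not the surface) while it matches, plus the evaluation metrics and the
inter-subject statistical deformation model computed from the registered
meshes.

The package contains:

- `lsmd.mesh` — triangle-mesh container, one-ring adjacency, the uniform
  (and optional cotangent) discrete Laplacian;
- `lsmd.io` — PLY and STL readers/writers (ASCII and binary), including a
  per-vertex `ux uy uz` displacement triple in PLY;
- `lsmd.decimate` — quadric edge-collapse resampling to an exact vertex
  count (closed genus-0 in, closed genus-0 out);
- `lsmd.registration` — the main method (`register_lsmd`), its ablation
  without displacement smoothing (`register_lsm`), piecewise-affine and
  affine baselines, affine/moment pre-alignment, and average-shape template
  construction;
- `lsmd.metrics` — symmetric mean/Hausdorff surface distances
  (point-to-triangle), displacement-Laplacian smoothness, target
  displacement error, enclosed volumes and table summaries;
- `lsmd.statmodel` — SVD deformation model (mean + eigenmodes), mode
  synthesis at `w·sqrt(eigenvalue)`, variance explained, state
  interpolation, distance-from-hilum linearity fits;
- `lsmd.synthetic` — seeded generator of lobe-like closed meshes and
  analytic "deflation" deformations (contraction toward a hilum point,
  rotation, bending, apical collapse, surface noise) with independent
  remeshing and exact ground-truth displacement fields;
- `lsmd.experiment` — the end-to-end benchmark: simulate a population,
  build the template, register every case with every method, summarize
  metrics and fit the deformation model.

## Command line

```sh
# write a synthetic population (PLY meshes + exact truth fields)
lsmd simulate --cases 11 --seed 7 --out pop/

# build the average-shape template from the inflated surfaces
lsmd template --surfaces pop/case-01/inflated.ply \
              --surfaces pop/case-02/inflated.ply --vertices 400 --out T.ply

# register it (methods: lsmd, lsm, pwa, affine)
lsmd register --template T.ply --target pop/case-01/inflated.ply \
              --method lsmd --out M_I.ply --trace trace.csv
lsmd register --template T.ply --target pop/case-01/deflated.ply \
              --method lsmd --out M_D.ply

# evaluate distances / smoothness / target displacement error
lsmd evaluate --pair M_I.ply pop/case-01/inflated.ply \
              --displacement M_I.ply --points pop/case-01/points.csv \
              --deflated M_D.ply --out report.json

# fit the statistical deformation model from registered pairs
lsmd statmodel --samples registered/ --out model.npz

# or run the whole benchmark in one go
lsmd experiment --cases 11 --seed 7 --iterations 300 --out report.json
```

Registration parameters (`delta`, `gamma`, `lam`, `m`, the Q-threshold
fractions, iteration caps) can be overridden with `--config cfg.yaml`, whose
keys mirror `lsmd.RegistrationConfig`.

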