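# porerim

Quantitative analysis of gold-particle decoration at membrane-pore rims in
calibrated 2D projection images (e.g. cryo-EM of porated liposomes labeled
with ~1.3 nm nanogold), together with a synthetic scene generator that
renders porated vesicles with full ground truth.

The package answers questions of the form: are particles concentrated at
pore edges, at what linear density, and is that density independent of
pore size?

## What it does

- **`porerim.scene`** — builds 3D porated-vesicle models (sphere radius R,
  membrane thickness, pore half-angle; pore diameter d = 2·R·sin(half-angle)),
  decorates the rim with particles at a chosen linear density (Poisson or
  fixed counts, truncated Gaussian radial jitter), scatters nonspecific
  background particles over the membrane, projects orthographically at an
  arbitrary tilt, and renders calibrated 8-bit images in which gold is the
  darkest feature (intensity 40; membrane 80–150; lumen/exterior ≥ 180).
- **`porerim.detect`** — detects particle clusters by a closed intensity
  band (default 30–50 of 256) and a physical minimum area (default
  0.32 nm²), reporting per-cluster pixel sets, areas and centroids in nm.
  Includes the analytic inclusion fraction for normally distributed
  particle diameters.
- **`porerim.geometry`** — polylines, ROI polygons, shoelace areas,
  boundary-inclusive point membership, shortest point-to-edge distances,
  the averaged outer/inner pore perimeter, ellipse (foreshortened)
  perimeters via complete elliptic integrals, the (π−2)/π ≈ 36% worst-case
  projection error bound, and circularity-based orientation classing.
- **`porerim.stats`** — region particle densities (particle area /
  non-particle area, with optional control normalization), edge-distance
  histograms, interparticle spacing (perimeter / count, an upper bound on
  molecular spacing), area-vs-circumference regression (with and without
  intercept), and a Mann-Whitney test that is exact by full enumeration
  for n1+n2 ≤ 14 (midranks for ties; normal approximation with continuity
  and tie correction otherwise).
- **`porerim.pipeline` / CLI** — reproducible simulate → detect → measure →
  report runs: identical config + seed give byte-identical images and CSVs.

## CLI

```sh
# render a synthetic cohort with ground-truth annotations
porerim simulate --seed 1 --n-vesicles 10 --pixel-size 0.2 --out runs/sim

# detect particles and compute rim statistics
porerim measure --in runs/sim --out runs/meas --band 30:50 --min-area 0.32

# summarize (add --plot for an area-vs-perimeter scatter)
porerim report --in runs/meas
```

`measure` writes tidy CSVs: `densities.csv` (per-region particle
densities), `pores.csv` (perimeter, particle area/count, spacing,
circularity), `distances.csv` (particle-to-edge distances), `tests.csv`
(rank tests), plus `summary.json` and a `run.log` with input hashes.
A YAML config (`--config`) can set every simulation/detection parameter;
CLI flags override it.

## File formats

- Images: 8-bit single-channel TIFF/PNG with the pixel size (nm/px) in a
  `<name>.tif.pixelsize.json` sidecar (and TIFF resolution tags); an
  explicit `--pixel-size` wins over the sidecar.
- Annotations: JSON with `edge`, `outer`, `inner` polylines and labeled
  `regions` polygons, all in nm, image frame (y down); see
  `porerim/io.py` for the schema.

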