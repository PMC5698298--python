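# nanomap

Analysis pipeline for high-speed AFM height images of surface-deposited,
protein-labeled DNA molecules — from raw nm-valued frames to per-molecule
contour lengths, label positions, population statistics, and translocation
calls — together with a physics-based synthetic frame generator so every
stage can be validated against ground truth without instrument data.

## What it does

- **simgen** — simulates 2D worm-like-chain DNA conformations (optionally
  flow-elongated), draws Bernoulli label occupancy from a reference map,
  and renders tip-dilated height frames (0.3-nm backbone ridge, 3-nm label
  bumps, scan-line offsets, pixel noise) plus ground-truth tables.
- **imageproc** — per-scan-line polynomial flattening (foreground-excluded,
  iterated to a fixed point), adaptive ridge segmentation (oriented filter
  bank + hysteresis reconstruction + fragment-end bridging), and stitching
  of overlapping frames via known origins.
- **tracing** — skeletonization, pruning to the longest end-to-end geodesic,
  quality flags (branched / looped / edge-clipped / too-short), smoothing
  cubic-spline backbone fit, and arc length by adaptive quadrature.
- **labelcall** — height profiles sampled along the spline, peak detection
  with prominence/separation gates, sub-pixel centroid label positions in nm
  and bp.
- **popstats** — nm↔bp calibration (2.94 bp/nm default), trimmed Gaussian
  population fits, logit-scale proportion statistics with back-transform,
  per-site labeling rates with off-target classification, and ladder
  resolution analysis.
- **mapmatch** — guide-site search on sequence (protospacer + PAM, mismatch
  budget), molecule orientation and optimal label↔site assignment, and
  translocation breakpoint calling from hybrid label patterns.
- **iface** — TIFF/ASCII height-image I/O with JSON sidecars, strict YAML
  run configuration, deterministic end-to-end pipeline runs, CLI.

## CLI

```sh
nanomap simulate -c run.yaml -o frames/        # synthetic frames + truth
nanomap analyze  -i frames/ -o out/            # measurements.tsv + report.json
nanomap stats    -i out/measurements.tsv       # Gaussian population fit
nanomap ladder   -i ladder.tsv                 # smallest resolved step
nanomap map --fasta locus.fa --guide ACGT... -o map.tsv
nanomap translocate -i out/measurements.tsv --map-a bcl2.tsv --map-b igh.tsv
```

A YAML config supplies stage parameters (see `nanomap.iface.config.RunConfig`);
command-line flags override it. Outputs refuse to overwrite without
`--force`, and every run report records the config hash and seed.

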