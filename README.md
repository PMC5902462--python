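# gutmech

Quantitative analysis of tension-driven growth of tubular embryonic organs:

- **morphometry** — silhouette photograph → subpixel contour → Voronoi
  medial axis → midline length, diameter profile and solid-of-revolution
  volume (`V = ∫ π r(s)² ds`), plus an independent Bezier axisymmetric
  reconstruction used as a cross-check (the two routes agree to a few
  percent on synthetic tubes).
- **biomechanics** — buoyancy-corrected hanging-weight force, per-branch
  tension, applied stress `σ = 4F/πd²`, elastic strain, effective tissue
  viscosity `η = σΔT/(Δl/l)`, relative growth metrics, dry-mass and
  cell-number changes against reference densities, glass-fiber cantilever
  calibration (°/N) and deflection → dry-mass conversion, proliferation
  density arithmetic.
- **motility** — kymograph construction from time-lapse movies and spectral
  extraction of contraction-wave frequency (mHz) and propagation speed
  (mm/s), including direction and a mixed-frequency flag.
- **cohort_stats** — median/IQR/mean summaries, two-tailed Mann-Whitney U
  (exact for small tie-free samples, tie/continuity-corrected normal
  approximation otherwise), OLS stress-response trend fits.
- **synthetic** — generators for every input with stored ground truth:
  curved-tube phantom silhouettes, before/after growth cohorts following a
  configurable stress-response law, peristalsis movies with known wave
  frequency/speed, and linear cantilever calibration tables.

All quantities use mm / mm³ / mg / μN / Pa; unit conversions are
centralized in `gutmech.biomechanics`.

## Command line

The `gutmech` entry point exposes the pipeline stages:

```sh
# generate a synthetic phantom with ground truth, then measure it
gutmech simulate --kind phantom --spec phantom.json --out sim/
gutmech measure sim/phantom.tif --scale 0.02 --out morph.csv

# before/after growth table with stresses, relative changes, viscosity
gutmech growth --before before.csv --after after.csv --masses masses.csv --out growth.csv

# kymograph + wave statistics from a multi-page TIFF movie
gutmech motility movie.tif --roi 2,20,498,20 --width 33 --scale 0.02 --dt 2 --out mot

# cantilever calibration and dry-mass conversion
gutmech weigh --calibration calibration.csv --deflections deflections.csv --out mass.csv

# group summaries, pairwise Mann-Whitney tests, stress-trend fits
gutmech stats --records growth.csv --out stats
```

`simulate` also produces cohorts (`--kind cohort`), movies (`--kind movie`)
and calibration tables (`--kind calibration`); specs are JSON files whose
fields mirror the dataclasses in `gutmech.synthetic`.

CSV outputs carry a one-line `# gutmech …` provenance comment; read them
back with `gutmech.cli.read_csv` or `pandas.read_csv(..., comment="#")`.

## Conventions worth knowing

- Reported tube length runs between the two end-cap centers of the
  silhouette (the swept-disk midline), not tip-to-tip; phantom ground
  truth uses the same convention.
- Mean diameter is the arclength-weighted mean of the diameter profile.
- Default segmentation threshold is isodata (intermeans); pass an explicit
  `threshold` to override.
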