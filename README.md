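# qpihuvec

Quantitative-phase-imaging (QPI) analysis for endothelial-cell assays:
per-cell morphometry, tube-network quantification and three-parameter
logistic pharmacology, plus a synthetic phantom generator with exact
analytic ground truth that the whole measurement stack is validated against.

QPI instruments report, per pixel, the optical path difference (OPD) a cell
introduces. Because OPD is proportional to the nonaqueous material along the
light path, a phase image is simultaneously a *shape* map (thickness,
footprint, sphericity) and a *mass* map (dry mass in picograms). This package
turns such images into tidy per-cell, per-network and per-well tables, and —
because real reference data is rarely available pixel-for-pixel — ships a
generator that renders cap-shaped cell phantoms and tube-network phantoms
whose true area, dry mass, sphericity and graph topology are known exactly
from the generating solids.

## Capabilities

- **phantoms** — render spherical-cap / ellipsoidal-cap / Gaussian-bump cells
  (single, fields with sub-gate debris, drifting timelapses), tube networks
  from seed graphs, and logistic dose–response tables, each with a
  ground-truth record computed analytically.
- **morphometry** — watershed segmentation, a 400 µm² cell/debris size gate,
  per-cell area, dry mass, optical thickness, sphericity
  (equal-volume-hemisphere convention: a hemisphere scores 1), length/width
  ratio, fluorescence pairing with a 50 AU background cut, and a
  sphericity-0.25 population split.
- **tube_network** — binary mask → skeleton → graph with segments, junctions,
  extremities and branches; spur pruning; junction merging; boundary-clipped
  branch flags; metrics and baseline-normalised timecourses.
- **pharmacology** — three-parameter logistic
  `Y = Bottom + (Top − Bottom) / (10^(LogEC50 − X) + 1)` fits with standard
  errors, per-experiment fitting, potency tables (pEC50 ± SEM, span ± SEM),
  vehicle normalisation and percent-of-baseline utilities.
- **pipeline + CLI** — three assay runners (morphology, tubulogenesis,
  concentration–response) producing deterministic CSV outputs with SHA-256
  manifests, and a thin `qpihuvec` command-line wrapper.

## Worked example

Render a hemisphere phantom, measure it, and check the sphericity identity:

```python
from qpihuvec import CellPhantomSpec, render_cell, segment, measure

# height == footprint radius -> a hemisphere; its natural dry mass follows
# from volume x refractive increment (no dry_mass rescale, which would
# change the height and with it the shape)
spec = CellPhantomSpec("spherical_cap", footprint_radii=(15.0, 15.0),
                       height=15.0)
image, truth = render_cell(spec, canvas=(128, 128))
record = measure(image, segment(image))[0]
print(f"truth sphericity {truth.objects[0].sphericity:.3f}, "
      f"measured {record.sphericity:.3f}, dry mass {record.dry_mass:.1f} pg")
```

prints

```
truth sphericity 1.000, measured 1.000, dry mass 1571.4 pg
```

Fit a dose–response curve and summarise potency:

```python
import numpy as np
from qpihuvec import simulate_dose_response, fit_3pl

concs = list(np.linspace(-13.0, np.log10(3e-9), 8))   # 100 fM – 3 nM
table, _ = simulate_dose_response(top=1.87, bottom=1.70, log_ec50=-10.34,
                                  concentrations=concs, n_replicates=2,
                                  noise_sd=0.0)
fit = fit_3pl(table)
print(f"pEC50 {fit.pec50:.4f}, span {fit.span:.4f}")
```

prints

```
pEC50 10.3400, span 0.1700
```

The `examples/` directory contains narrative scripts for each capability
(phantom rendering, morphometry, tube networks, pharmacology, full assay
pipelines); each runs offline in seconds and prints its results.

The CLI mirrors the library:

```sh
qpihuvec simulate field --seed 1 --out-dir scratch/demo
qpihuvec measure --phase scratch/demo/phase.tif --out scratch/demo/cells.csv
qpihuvec simulate dose --seed 1 --out-dir scratch/demo
qpihuvec fit --table scratch/demo/dose_response.csv \
    --group-by experiment_id,replicate_id --out scratch/demo/potency.csv
```

## Reproduction

- Tests: `python -m pytest -q tests/` (the suite validates every stage
  against analytic oracles; see `docs/methods.md` for the conventions).
- Acceptance targets:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  writes nine target values (logistic recoveries, shape baselines, the debris
  gate percentage) as `{"t<i>": {"value": ..., "n": ...}}`. All randomness
  derives from `--seed`; repeated runs with the same seed are identical.

## Layout

```
src/qpihuvec/     library (geometry, phantoms, morphometry, tube_network,
                  pharmacology, pipeline, io, cli)
tests/            pytest suite, oracle-based; tests/test_acceptance.py maps
                  one test to each acceptance criterion
scripts/          acceptance.py target computation
examples/         runnable narrative scripts
docs/methods.md   measurement model, conventions, numerical choices, limits
```
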