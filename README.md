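# forktrace

Analysis of single-molecule DNA replication experiments on
flow-stretched DNA: from TIRF movies or trace tables to replisome
kinetics, fork-rotation statistics, stretching forces and polymerase
stoichiometry.

## The problem

In single-molecule replication assays, surface-tethered DNA molecules
are replicated by a reconstituted replisome (the T7 bacteriophage
system: gp4 helicase-primase, gp5/trx polymerase, gp2.5 ssDNA-binding
protein) while the stained lagging-strand product is imaged as a bright
blob moving along the template. A molecule tethered through a single
biotin can swivel freely (*unconstrained*); multi-biotin attachment
blocks rotation and creates a topological barrier (*constrained*).
Comparing the two conditions asks how replisomes cope with torsional
strain: via changes in speed, pausing, processivity, fork rotation
(the lagging strand wrapping around the leading strand), and polymerase
exchange.

`forktrace` implements the complete quantitative pipeline for such
experiments, for researchers analysing their own movies or trace tables:

- **localize** — spot detection with subpixel 2-D Gaussian fits, annulus
  intensity integration (radii 3/12 px), fiducial-based drift
  correction, nearest-neighbour linking, and registration of
  trajectories onto the DNA axis in base pairs.
- **changepoint** — the core engine: kinetic change-point segmentation
  of noisy traces into piecewise-linear regimes (replication) or
  constant plateaus (photobleaching steps). Recursive binary
  segmentation with a scan-corrected F-test at 95 % confidence and
  backward pruning; an exhaustive-search oracle is included for testing.
- **kinetics** — burst rate (duration-weighted mean slope of segments at
  or above 15 bp/s), merged pause events (segments below 15 bp/s),
  processivity (fitted endpoint of the final segment), completion
  fraction, and the photo-nicking survival fit
  `y = y0 · 0.5^(x/b)` where `b` is the half-life.
- **kymo** — kymographs by strip-averaging (5 px each side of the DNA),
  window-2 smoothing, per-kymograph Otsu thresholding (256 bins) and
  blob-size series.
- **transverse** — strand-length traces (parental / leading / lagging)
  from per-frame segmentation masks, Dickey–Fuller stationarity tests,
  and the fork-rotation statistic: the variance of the first-differenced
  lagging-strand length (kb²).
- **wlcforce** — worm-like chain forces
  `f = (k_B T / A) · [z/L + 1/(4(1−z/L)²) − 1/4]` with A = 50 nm,
  T = 296.15 K and 0.34 nm/bp, binned by product length (3 kb bins,
  1.5 kb step, < 5 kb excluded).
- **stoich** — polymerase counts: background-subtracted spot intensity
  divided by the single-fluorophore step size calibrated from
  photobleaching staircases (median step amplitude).
- **simkit** — a first-class synthetic-data generator emulating every
  data type above with ground truth, so each stage is verifiable by
  parameter recovery.
- **interface / cli** — YAML-configured pipeline drivers with
  reproducibility manifests, and the `forktrace` command-line tool.

## Worked example

Simulate a cohort of freely rotating molecules and recover its kinetics:

```python
from forktrace import simkit
from forktrace.kinetics import analyze_cohort, summarize_condition

traces, truth = simkit.simulate_kinetic_traces(
    simkit.KINETIC_PRESETS["unconstrained"], n=50, seed=7
)
cond = summarize_condition(analyze_cohort(traces))
print(f"burst rate  : {cond['burst_rate_mean']:.1f} +/- {cond['burst_rate_sem']:.1f} bp/s")
print(f"processivity: {cond['processivity_mean_bp']/1000:.1f} +/- {cond['processivity_sem_bp']/1000:.1f} kb")
print(f"completed   : {100*cond['completion_fraction']:.0f} %")
print(f">=1 pause   : {100*cond['pause_fraction_any']:.0f} %  (n = {cond['n']})")
```

```
burst rate  : 97.2 +/- 4.4 bp/s
processivity: 23.3 +/- 0.9 kb
completed   : 70 %
>=1 pause   : 16 %  (n = 50)
```

Each trace is segmented by the change-point engine; segments slower
than 15 bp/s count as pauses, the endpoint of the last segment is the
processivity (completed when within 1 kb of the 27 kb template), and
the cohort statistics recover the generator's parameters (99 bp/s mean
burst rate, 75 % completion, 13 % pausing) within sampling error at
this n.

The same stages are available from the shell:

```bash
forktrace simulate kinetics --preset unconstrained --n 50 --seed 7 --out sim/
forktrace kinetics --traces sim/traces.csv --template-bp 27000 --out results/
```

## Documentation

`docs/methods.md` describes the statistical models, the generator's
assumptions and what recovery tests do and do not establish, the
numerical choices (tie-breaking, tolerances, degenerate inputs), and
known limitations.
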