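# Methods

This note documents the statistical models, default parameters and
design choices behind `forktrace`, and what the synthetic-data recovery
tests do and do not establish.

## Kinetic change-point segmentation

Replication traces (lagging-strand position vs. time, bp) are segmented
by recursive binary segmentation. In each region the candidate
breakpoint minimising the combined residual sum of squares (RSS) of a
two-piece ordinary-least-squares fit is located with prefix sums (O(n)
per region) and accepted if an F statistic

F = [(RSS₀ − RSS₁)/p] / [RSS₁/(n − 2p)]

exceeds the critical value, where p = 2 for lines and p = 1 for
constant plateaus (photobleaching steps). Because the tested breakpoint
is the best of all admissible candidates — a scan statistic — the
critical value carries a Bonferroni correction over the candidate
count; without it essentially every few-hundred-point pure-noise region
acquires spurious splits. After the recursion, a backward-pruning pass
re-tests each interior boundary against its merged neighbourhood and
removes the weakest until all are significant; this eliminates the
short spurious segments binary segmentation leaves when it misplaces a
boundary by a few samples. Ties in RSS break toward the earliest
breakpoint; minimum segment lengths are 3 points (lines) and 2 points
(plateaus); the default confidence is 0.95 (0.99 is recommended for
step counting, where plateaus are long and false extra steps are the
dominant error). An exhaustive single-breakpoint search
(`oracle_best_split`) provides an independent oracle; property tests
assert the engine's first accepted split equals the oracle's global
optimum on random traces.

Traces shorter than twice the minimum segment length yield a single
flagged segment. NaN samples and non-increasing time stamps are
rejected.

## Replication kinetics

Segments with slope strictly below 15 bp/s (about a six-fold reduction
from the median rate) are pauses; a slope of exactly 15 bp/s is a
burst. Adjacent pause segments merge into one pause event. A trailing
run of sub-threshold segments reaching the end of the trace is the
post-termination plateau, not a pause. The burst rate is the
duration-weighted mean slope over burst segments (an unweighted variant
is exposed as a flag; the averaging convention is not uniquely
determined by the quantities being reproduced, so both are reported
side by side per molecule). Processivity is the fitted position at the
end of the last segment, clamped to [0, template]; completion means
reaching the 27 kb template within a 1 kb tolerance. Molecules with no
burst segment are excluded (`no_burst`), as are molecules whose final
segment is still a burst short of the template — their kinetics are
censored by the movie end (`active_at_end`; configurable).

## Photo-nicking survival

Molecule areas are step-fitted; the first upward step exceeding twice
the pre-step residual SD is the nick time, otherwise the molecule is
right-censored at the movie end. The fraction of unnicked molecules
over time (percent scale, 100 % at t = 0 by construction) is fitted by
nonlinear least squares with y = y0 · 0.5^(x/b); b is the half-life.
A curve with no events has no finite half-life and is flagged
`degenerate` with b = ∞.

## Kymographs and blob size

Kymograph rows average the 11 perpendicular pixels (5 each side) along
the DNA axis per frame, sampled by bilinear interpolation. Smoothing is
a left-aligned length-2 moving average along the position axis (the
position reading of the ambiguous "window size 2"; configurable).
Thresholds are per-kymograph Otsu on a 256-bin histogram with ties
broken toward the lower threshold (implemented in-package so the tie
rule is pinned; cross-checked against scikit-image within one bin
width). Blob size per frame is the white-pixel count; the occupied
column span is also emitted because a linear (µm) size reading is
plausible for either. The end-of-reaction summary averages the five
rows at offsets −10…−6 from the final row.

## Transverse-flow statistics

Strand lengths come from skeletonised per-frame masks; geodesic length
is 1 + Σ steps (1 axially, √2 diagonally, skipping diagonals bridged by
an axial pixel), so a straight n-pixel strand measures n px. Base-pair
calibration uses the fully replicated leading strand (27 kb / final
leading length in px) per molecule. Missing strands in a frame are
missing values, never zero, and difference-based statistics drop pairs
spanning a gap rather than interpolate.

The fork-rotation statistic is the sample variance (n − 1 denominator)
of the first-differenced lagging-strand length in kb². For a smoothly
growing trace with i.i.d. measurement noise of SD σ its expectation is
2σ² (+ a negligible term from the slope change at termination); wrap
events add large jumps and inflate it. Stationarity is checked with the
augmented Dickey–Fuller test (statsmodels; constant-only regression,
lag 1 by default — the lag order is not critical at these trace
lengths) before and after differencing.

## Worm-like chain forces

f(z; L) = (k_B T / A) · [z/L + 1/(4(1 − z/L)²) − 1/4], with
persistence length A = 50 nm, T = 296.15 K (k_B T = 4.0888 pN·nm — a
single constant source used everywhere) and contour length 0.34 nm per
base pair. The arch force uses the parental + leading base-pair content
as contour and the measured arch end-to-end extension; the lagging
force uses the leading-strand content as the expected contour. Frames
with z ≥ L are flagged and excluded from summaries. Forces are
summarised as the per-bin median over overlapping product-length bins
([1.5k·k, 1.5k·k + 3 kb), products < 5 kb excluded) with a least-squares
trend line through the bin medians; per-molecule medians are reported
as median ± MAD. The numeric inverse (extension from force, needed by
the simulator) is Brent bisection on [0, L(1 − 10⁻⁶)] at 10⁻⁹ relative
tolerance.

## Stoichiometry

Movies are flat-fielded by dividing by the blurred (Gaussian σ = 20 px,
normalised convolution to stay unbiased at borders) temporal median
frame, normalised to unit mean and floored at 1 % of its mean. The
single-fluorophore step size is the median absolute downward step
amplitude pooled over calibration bleaching traces — the median rather
than the mean because coincident double-bleaches contaminate the upper
tail. Polymerase counts are background-subtracted integrated intensity
(annulus method, radii 3/12 px) divided by the step size, left
real-valued; negative corrected intensities clip to zero with a flag.
A labelling-efficiency correction (÷ 0.94) is available but off by
default, since the reported counts are raw. Whether counts should be
time-averaged is not determined by the reproduced quantities; the
per-molecule record here is a single integrated intensity, and the
time-resolved series is available through the localization layer.

## The synthetic generator

`simkit` emulates the statistical structure the analysis assumes — not
the physics of DNA under flow. Its defaults encode the two experimental
conditions:

| parameter | unconstrained | constrained |
|---|---|---|
| burst rate mean (bp/s) | 99 | 96 |
| between-molecule rate SD (bp/s) | 41 | 44 |
| P(exactly one pause) | 0.12 | 0.18 |
| P(exactly two pauses) | 0.01 | 0.04 |
| completion probability | 0.75 | 0.57 |
| incomplete termination (kb, uniform) | 8–27 | 11.2–27 |
| mean polymerases | 3.8 | 11.4 |

Shared defaults: 27 kb template, 5 s frame interval, 30 min movies,
60 bp per-frame localization noise (≈ 0.2 px at 300 bp/px — typical
subpixel precision for a bright blob). Each molecule draws one rate
from a normal truncated at ±2 SD (resampled; symmetric truncation keeps
the mean exact, and rates stay physical). The between-molecule SDs are
set so the standard error at the cohort sizes used (n = 186 / 79)
matches the reported uncertainties; the same rule sets the polymerase
count SDs (0.87 / 1.50 at n = 75 / 56, counts being rounded normals).
Incomplete molecules terminate uniformly on the stated range, with
endpoints calibrated so the mixture mean matches the observed mean
processivity (24.6 / 23.6 kb).

Pause durations are a shifted exponential: 25 s minimum + Exp(5 s),
mean 30 s. The floor and a 3 kb start/termination margin on pause
positions encode *resolvability*: at a 5 s frame interval with 3-point
minimum segments, a pause shorter than ~5 frames, or one leaving fewer
than ~3 frames of synthesis on either side, appears only as an
intercept offset between two parallel burst lines (or blends into the
terminal plateau) and is invisible to any segment-slope classifier.
The pause probabilities therefore describe pauses resolvable at the
experimental time resolution, which is also what a detected-pause count
from real data represents. Both knobs are preset fields.

Transverse traces add `lagging_scale` = 0.8 for ssDNA-binding-protein
compaction (configurable, not inferred), per-frame Gaussian length
noise (0.95 kb SD on the lagging arm, so the first-difference variance
is 2σ² ≈ 1.8 kb²), and — for the constrained preset — Poisson-timed
wrap/unwrap toggles (0.01 /s) that collapse the extended lagging length
by up to 10 kb toward a 0.9 kb compact floor, unwrapping during pauses.
The wrap parameters are qualitative: only the ordering (constrained
fluctuation variance exceeds unconstrained) is asserted, not its value.

Rendered movies use an isotropic Gaussian PSF (σ = 1.3 px), 100 nm
pixels, a stained-DNA ridge, immobile fiducials, optional linear stage
drift and Poisson + Gaussian read noise. Nicking traces step a
molecule's apparent area from compact to relaxed at exponential times
with rate ln 2 / half-life.

All draws come from one `numpy.random.Generator` per call, seeded
explicitly: identical (preset, n, seed) give bit-identical outputs.

### What recovery tests show — and what they do not

Passing recovery at the study's cohort sizes shows the estimators are
unbiased and correctly scaled *under the generator's assumptions*:
piecewise-constant rates, Gaussian localization noise, exponential
dwell times, step-wise photophysics. Real data add correlated noise,
photobleaching of the DNA stain, heterogeneous tether geometry,
blinking fluorophores and drift beyond the linear model — none of which
the generator emulates. The tests validate the analysis code, not the
biology.

## Problem sizes

The test suite and the acceptance script use the study's cohort sizes
directly (186 / 79 kinetic trajectories of 361 frames; 200 calibration
traces; 75 / 56 replisomes; 24-molecule transverse cohorts), since the
whole analysis runs in seconds at that scale. Simulation-based error
control checks (false-split rate, ADF size/power) use 100 seeds.

## Known limitations

- Binary segmentation with per-region family-wise control does not
  control the global false-split rate across a long multi-segment
  trace; with the scan correction the residual rate is small but not
  zero.
- Pauses at the extreme ends of synthesis are fundamentally
  unidentifiable at this frame interval (see above); detected pause
  fractions are therefore biased low by however many such events real
  molecules contain.
- The greedy nearest-neighbour linker can swap identities when
  trajectories approach within the step limit between frames.
- The skeleton length of strongly curved or branched masks
  underestimates the traced curve; strands here are near-straight by
  construction.
- `fit_survival` fits the plotted survival fractions by least squares,
  matching the analysed procedure, rather than maximum-likelihood
  censored survival estimation.
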