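# Methods

## Overview

`phenofft` implements a four-stage analysis of continuous label-free
live-cell imaging: (1) per-cell records of 11 phenotypic parameters
over imaging cycles, (2) condition-level population mean/SD series,
(3) reduction of each series to its dominant discrete-Fourier feature
(frequency index, amplitude, phase), and (4) correlation-distance
hierarchical clustering of conditions for mode-of-action (MoA)
inference. Because the emulated study's raw data are not deposited, a
synthetic-data generator is part of the package proper and defines the
conditions under which everything is tested.

## The synthetic acquisition model

An acquisition is a square field (default 236 µm side) imaged at a
fixed interval (default 3 min) for a fixed duration (default 20 h,
hence 400 cycles), starting with a uniform draw of 15–25 cells. Cycle
indices are 1-based; cycle c occurs at time c·interval.

Each archetype fixes, per parameter, a piecewise-linear population-mean
trajectory (knots at the phenotype chronology: disruptor contraction at
2 h, stabilizer arrest at 10 h, late events near the end), held flat
outside the outer knots. A cell's value is

    value(c) = mean(c) · effect + ε(c)

with a lognormal multiplicative effect per (cell, parameter)
(unit mean, scale `cell_effect_sd`, default 0.1 — response
heterogeneity) and stationary AR(1) Gaussian noise with lag-one
coefficient 0.6 and per-parameter stationary SD (e.g. 25 µm² for area,
0.0012 for RI) sized so population SD bands are visibly nonzero at
15–25 cells. Values are clipped to each parameter's physical domain
(eccentricity to [0, 1], positive quantities to > 0).

Three deliberate exceptions to the plain multiplicative model:

- **Mean RI** applies the effect to the excess over the medium index
  (n_m = 1.333, aqueous medium): RI = n_m + (mean − n_m)·effect + ε. A
  multiplicative effect on the absolute index would move cells far
  outside any physical range (1.35 ± 10% spans 1.22–1.49); optically,
  cell-to-cell variability lives in the dry-mass-related excess.
- **Area %** is derived exactly as 100·area/field², so the defining
  identity holds to machine precision.
- **Volume** is derived as dry mass / dry-mass density, making
  DMD·V = DM exact by construction; volume is carried as an internal
  column of the records table.

Events: the control archetype divides (0.02 per cell per hour;
daughters start fresh tracks with their own effects — mass halving at
division is not modeled), the disruptor dies (per-cycle hazard 0.003
after a 12 h necrosis onset; records stop at death), and the stabilizer
arrests (encoded in its trajectories: form factor up, eccentricity and
perimeter down after cycle 200). Reproducibility is exact: the RNG is
keyed on (seed, CRC32 of archetype name), so conditions sharing a seed
have independent but fully deterministic streams.

Calibration: every knot lies inside the published per-parameter axis
ranges (e.g. RI 1.34–1.37, DM 80–250 pg), with margins sized so the
population mean — whose multiplicative-effect SD is ≈ 0.1/√15 ≈ 2.6%
at the minimum cell count — stays inside the ranges at every cycle
across seeds. This is verified by sweep in the test suite, not assumed.

### Image frames

`simulate_field_frames` renders the same trajectory targets (same seed)
as per-cycle grids: an integer label mask, an RI map and an optical-
height map (default 0.5 µm/pixel, i.e. 472×472; chosen for desk-scale
speed, not to model instrument optics). Cells are rotated ellipses with
the target area and axis ratio, placed on a jittered grid that
guarantees non-overlap whenever each cell's bounding radius is below
half the grid pitch (otherwise a generation error suggests a larger
field or fewer cells; with default cell sizes the field accommodates
roughly 16–25 cells depending on noise draws). Rendered eccentricity is
capped at 0.94 (axis ratio ≈ 3) because a fixed-area ellipse grows an
unbounded major axis as e → 1; area remains the binding target. The RI
inside a cell is its target mean plus zero-mean Gaussian texture scaled
from the granularity target; the height profile is a half-ellipsoid
dome rescaled so the rasterized dry-mass sum (1/α)·Σ(RI−n_m)·h·px²
matches the trajectory's dry mass. Consequently frames track area,
eccentricity, mean RI and dry mass (within rasterization tolerance,
≤ 5%); DMD is emergent (≈ (RI−n_m)/α for a near-uniform cell) and is
*not* forced to the trajectory value — the three quantities cannot be
matched simultaneously by a uniform-RI ellipse.

## Morphometry

Feature definitions are stated in `phenofft.morphometry` (the source
instrument's definitions are proprietary): pixel-count area; Crofton
4-direction perimeter (chosen over boundary-polygon length, which
overestimates a rasterized disk by ~7%; Crofton is within 4% at
r = 10 px and converges); form factor 4πA/P² with compactness its exact
reciprocal; extent from the axis-aligned bounding box; eccentricity of
the second-moment equivalent ellipse (scikit-image regionprops);
mean RI over the label; dry mass, volume and DMD from the RI and height
maps with α = 0.19 µm³/pg (mid-range of the standard 0.18–0.21 for
cellular dry matter — the emulated study does not state its value);
granularity = 5 + 2000·SD(RI − Gaussian-smoothed RI, 2 µm window)
inside the label, an affine map placing realistic RI texture SDs
(0–0.005) on the conventional 5–15 display scale. Labels under
5 pixels are skipped as sub-resolution. The area-% denominator is the
full field area (0.4–2% for typical cells at 15–25 per field).

## Aggregation and centering

Population statistics use all alive cells at each cycle; SD uses the
n−1 denominator. Cycles with no alive cells are filled by
last-observation-carried-forward and flagged, so spectra keep a
full-length series. Centering/scaling is per condition and per
parameter (each series z-scored independently over its cycles, sample
SD); a zero-variance series is an error rather than silently passed on,
because a constant series carries no frequency information. Pooled
centering across conditions is a coherent alternative; per-condition
centering was chosen so each condition's spectrum is invariant to the
other conditions present in a run.

## Dominant-Fourier reduction

The DFT uses the e^{−i2πkn/N} convention (numpy's FFT; an O(N²) direct
summation serves as the independent oracle in the tests). The dominant
feature is the argmax of |X_k| over k ∈ [1, ceil(N/2)−1]: DC is
excluded because the series is centered, and for even N the Nyquist bin
is excluded because it carries no phase. Ties break toward the smaller
k (the lower frequency, which carries the main trend). Amplitude is
reported as 2|X_k|/N so a unit cosine reads 1 — any fixed scaling
cancels after the later z-scoring, so this choice only affects
readability of unnormalized output. Phase is arg X_k\* in (−π, π]; for
a·cos(2πkn/N + φ) the convention recovers phase = φ exactly. Period
N/k\* is exposed as a derived quantity. The feature matrix z-scores
each of the 22 columns across conditions (sample SD, requiring ≥ 3
conditions); amplitude and phase blocks are normalized independently.
An absolute-value companion view is available for bar-chart style
summaries.

## Condition correlation and clustering

`condition_correlation` standardizes columns (z-score across
conditions) and then computes Pearson correlation between condition
rows. Column standardization is idempotent — it changes nothing for a
matrix already normalized by `build_feature_matrix` — but makes the
result well-defined for externally supplied tables whose column scaling
is unknown or inconsistent. This matters for the packaged reference
table: its printed columns are not zero-mean under any single obvious
scaling, and only after re-standardization does the published structure
(negative stabilizer–disruptor correlations, the {Control, PTX} vs
{CLC, VBL} split) emerge from the printed values. The trade-off is that
row-level Pearson affine invariance holds for the correlation core but
not across the standardization step, since rescaling one row perturbs
the column statistics; the tests pin both facts.

Clustering is agglomerative on d = 1 − r (the standard distance for
correlation heat-map dendrograms) with average linkage by default
(single/complete available); flat labels come from a maxclust cut. The
end-to-end recovery harness pipes replicate record sets through the
whole chain and scores the k = n_archetypes cut against the true
archetype labels with the adjusted Rand index.

## Problem sizes and numerical choices

Default simulations (≤ 25 cells × 400 cycles × 11 parameters) run in
tens of milliseconds; the calibration sweep in the tests uses 3
archetypes × 20 seeds and the acceptance script adds a 100-field
initial-count sweep, each a few seconds on one CPU. Frame-based tests
use short runs (10 cycles × 5 cells at 0.5 µm/px, or 400 cycles at
4 µm/px) to keep rasterization tests fast. Tolerances: DFT vs direct
summation 1e-9 relative; mass-conservation identity 1e-9 (achieved at
machine precision); rasterized area 2%, Crofton perimeter 5%,
frame-to-trajectory round trip 5%.

## What the generator does and does not emulate

It reproduces the statistical shape of the emulated acquisitions:
population-mean trends per MoA with the published timing and axis
ranges, cell-to-cell heterogeneity, autocorrelated measurement noise,
division/death events, and a consistent image pathway. It does not
model cell migration or cell–cell contact, mitotic rounding of
individual control cells, mass partitioning at division, diffraction or
phase-reconstruction artifacts, segmentation or tracking errors, or a
second distinct disruptor compound (distinct disruptor conditions are
emulated as replicate seeds). Passing tests therefore demonstrate that
the analysis recovers MoA structure when the population dynamics differ
as described — not that it is robust to segmentation noise or subtler
MoA differences in real data.

## Known limitations

- The 22 features summarize one dominant spectral bin per parameter;
  multi-peak dynamics are collapsed (per-cell spectra are out of scope).
- With < 3 conditions the column z-scoring of the feature matrix is
  ill-defined and refused.
- The frame renderer is 2.5-D (height map), not a tomographic volume,
  and cannot satisfy independent RI, DM and DMD targets simultaneously.
- Archetype trajectories are piecewise-linear idealizations; real
  dose–response or cell-cycle-stage structure is not represented.
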