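# Methods

## Measurement model

The package measures vessel shape on 2D binary delineations of
lenticulostriate arteries. The measurement chain is:

1. **Projection** (optional). A 3D volume is collapsed by thin-slab
   minimum-intensity projection: each output pixel is the minimum over the
   slab voxels along the chosen axis. The slab is given in mm
   (center ± thickness/2) and resolved to whole voxels with ties rounded
   toward the slab center. Slab placement is a configuration input, not an
   algorithm: choosing the slab that captures a vessel's full course is an
   operator decision.
2. **Skeletonization.** The binary mask is thinned to a one-pixel-wide,
   8-connected medial skeleton (Zhang–Suen thinning via scikit-image).
   Foreground connectivity is 8-neighbor throughout, so one-pixel diagonal
   strokes from manual tracing stay connected.
3. **Spur pruning.** Thinning leaves short false side branches. Terminal
   branches are walked from each endpoint to their anchor (a junction or the
   main path) and removed when shorter than `min_branch_mm` (default 2 mm —
   below the shortest plausible LSA, above tracing jitter), iterating to a
   fixed point. Pixels on the longest geodesic path are never removed, so
   pruning cannot delete the vessel itself; a post-removal re-thinning pass
   clears the one-pixel bumps a removed spur can leave at its attachment
   point. Pruning is idempotent.
4. **Path extraction.** The centerline is the ordered pixel path realizing
   the longest geodesic distance between any two skeleton endpoints (Dijkstra
   over the 8-connected pixel graph, edge weights in mm). Ties prefer the
   path whose start pixel is lexicographically smallest in (row, col). A
   skeleton with more than one connected component is an error that reports
   the component count; in batch measurement such masks are skipped with a
   warning rather than aborting the run.
5. **Chain smoothing.** Summing steps along a digitized 8-connected chain
   overestimates true length by up to ~8% (staircase bias). A 3-point moving
   average (window 1 each side, shrinking symmetrically toward the ends so
   the endpoints are preserved exactly) reduces the bias to ~1% without
   shortening genuinely curved sections. This was chosen over calibrated
   step weights (Kulpa) because it also works with anisotropic pixel
   spacing, which is first-class here (clinical minIP grids are ~0.44 × 0.66
   mm). Larger windows start to erode real curvature; window 1 is the
   default and a configuration knob.

Pixel-to-mm conversion uses pixel centers with independent row/column
spacing. Masks travel as NIfTI (spacing in the header, preferred) or PNG
plus an explicit spacing override.

## Tortuosity metrics

Per vessel: VL = L_A (polyline path length), chord = L_C, DM = L_A/L_C, and

    VTI = 0.1 · SD_θ · N · M · L_A / L_C ,   VTI = 0 exactly when N = 0.

- **Frame.** Before computing angles, critical points and inflections, the
  centerline is rotated so its endpoint chord lies on the x-axis
  ("chord-aligned"). Measuring slope against the raw image x-axis would make
  N depend on how the subject lay in the scanner; alignment makes DM and VTI
  rigid-motion invariant. The image frame remains available (`align=False`).
- **Tangent angles** are estimated by central differences over ± `window`
  points (default 3, one-sided at the ends) and unwrapped along the path so
  consecutive values never jump by more than 180°. Degrees are the default
  unit; the choice only scales VTI through SD_θ and is configurable.
- **SD_θ** is the sample standard deviation (n − 1) of the unwrapped angles.
- **Critical points** N counts strict sign changes of the slope sequence,
  taken as sign changes of the tangent's y-component in the aligned frame
  (this counts horizontal-tangent crossings and is immune to the tangent
  passing through vertical). Zero-slope plateaus collapse to a single
  candidate so rasterized horizontal runs do not inflate N, and values
  within 1e-9 (relative) of zero are treated as zero so floating-point dust
  from a rigid motion cannot move a crossing.
- **Inflection segments** split the curve where the turning direction
  (sign of the discrete curvature) changes. A curvature-sign run only counts
  as a genuine bend when its integrated turning exceeds `min_turn_deg`
  (default 10°); weaker runs — digitization micro-wiggles — are merged into
  their strongest neighbor. Without this hysteresis the segment count on
  rasterized centerlines grows without bound as resolution increases and
  biases M toward 1. Segments cover the curve and share only cut points.
- **M** is the arithmetic mean of the per-segment arc/chord ratios. The
  aggregator across segments is a design choice (mean, max and sum are all
  defensible); the mean keeps M scale-free and exactly equal to DM when
  there is a single segment.
- **Subject summaries** are the vessel count plus mean, median and SD
  (n − 1) of VL, DM and VTI; a single-vessel subject reports SD = 0 rather
  than dropping out of downstream statistics.

## Synthetic phantoms

Curve families: straight line, circular arc (parameterized by subtended
angle; DM = φ / (2 sin(φ/2))), sinusoid (amplitude and half-wave count;
arc length by adaptive quadrature of √(1 + y′²)), and a seeded natural cubic
spline through jittered control points (ground truth by quadrature of the
spline derivative; critical points by dense sign counting at 200× sample
density). Curves are sampled uniformly in arc length — mimicking pixel-wise
delineation — with the chord on the x-axis. Rasterization resamples the
curve at just under one pixel per step and chains Bresenham segments, giving
a one-pixel-wide 8-connected stroke (nearest-pixel marking of dense samples
doubles pixels along diagonals, which thinning then erodes at the vessel
ends). Optional spur noise attaches short false branches at seeded random
path pixels.

## Simulated cohorts

`generate_cohort` emulates a community-dwelling elderly cohort: n = 125;
age ~ Normal(59.9, 7.1) truncated to [50, 82]; sex a balanced binary;
education ~ Normal(7.6, 4.0); ICV ~ Normal(1450, 130) mL; risk-factor
prevalences hypertension 40.8%, diabetes 15.2%, hyperlipidemia 14.4%,
smoking 28.8%; vessel count ~ round(Normal(8, 1.6)) clipped to [3, 14];
median vessel length ~ Normal(17.8, 3.3) mm (SD from the reported
interquartile range); DM and VTI summaries with plausible locations and
spreads; mild small-vessel-disease markers (log-normal WMH volume around
1.5 mL, mostly-zero lacune/microbleed counts, PVS scores near 1).

Two effect channels:

- **Binary risk factors** shift subject-level outcome summaries additively
  by a standardized mean difference in units of the outcome's noise SD.
  Effects act on per-subject summaries, not individual vessels, because
  that is the level at which the statistics operate. The source cohort
  reports only directions and p-values, not magnitudes, so the default
  "study effects" configuration uses moderate package defaults
  (−0.5 to −0.6 SD for smoking on VL/DM/VTI, −0.45 SD for hypertension on
  VTI).
- **Diameter–outcome associations** are induced by a Gaussian copula on
  ranks: a target Spearman ρ is converted to the latent Pearson correlation
  2·sin(πρ/6), so the rank correlation — the statistic actually used — is
  what comes out. Mean and median summaries of the same metric are coupled
  at ρ = 0.9, and a diameter correlated with one sibling receives the
  implied correlation with the other; an infeasible (non-positive-definite)
  target set raises instead of being clipped silently. Defaults use the
  reported rank correlations (MCA–count +0.278, MCA–median VTI −0.252,
  PCA–DM/VTI/VL +0.27 to +0.33).

What the simulator does **not** emulate: MRI physics, flow voids or
black-blood contrast; 3D branching trees; within-subject vessel-level
correlation structure; missing data; measurement error in diameters.
Passing tests therefore demonstrate correctness of the measurement and
statistical machinery under known ground truth, not robustness to real
acquisition artifacts.

## Statistics

- **Adjusted group comparison**: ANCOVA — OLS of the outcome on the binary
  group plus covariates (age, sex, ICV by default); the group term's
  partial F and p are reported with the covariate-adjusted mean difference.
  With no covariates this reduces exactly to one-way ANOVA.
- **Rank correlation**: partial Spearman — all variables rank-transformed
  (midranks for ties), covariate ranks regressed out of both variables,
  Pearson correlation of residuals with a t-test on n − 2 − k degrees of
  freedom. The adjustment mechanism for rank correlations is unspecified in
  the source analysis; partial correlation on ranks is the standard choice
  and equals classical Spearman exactly when no covariates are given.
- **Chi-square**: Pearson on the 2×2 table, no continuity correction by
  default (configurable).
- **Bonferroni**: p → min(1, p·m), applied within two families matching how
  the comparisons group — the risk-factor × outcome grid (m = 16) and the
  diameter × outcome grid (m = 35); the family label travels with each
  result.
- **ICC**: two-way, absolute-agreement, single-rater ICC(A,1) from the
  subjects × raters mean squares, for intra-observer repeat measurements.
- Missing data: listwise deletion per comparison, with the n used reported.

Calibration under the null configuration (1000 cohorts, n = 125) puts the
ANCOVA's type-I error at ~5% at α = 0.05; a −0.6 SD smoking effect on
median VL is detected in ~85% of 200 cohorts, always with the correct sign.
These rates are recomputed by `scripts/acceptance.py` on every run.

## Problem sizes

Phantom validation uses 20–24 curves with 400–600 sample points rasterized
at chord/50–chord/150; statistical calibration uses 1000 null and 200
effect cohorts of 125 subjects. These sizes give stable estimates (binomial
SE on the power estimate ~2.5%) while keeping the full test suite and the
acceptance script in the tens of seconds on one CPU.

## Known limitations

- **Rasterized VTI is resolution- and orientation-sensitive at the few-
  percent level.** DM, a ratio of integral quantities, is recovered within
  ~1% of analytic truth and is rotation-stable to <0.5% after
  rasterization. VTI contains the standard deviation of a *derivative*
  field estimated over a fixed number of pixels; its digitization noise has
  fixed pixel scale and an orientation-dependent (staircase-phase)
  component, so VTI measured from binary masks varies by roughly 3–10%
  when the same vessel is redrawn at a different orientation, across all
  estimator variants evaluated (moving-average smoothing, arc-length
  weighting, smoothing-spline subpixel refinement, Savitzky–Golay
  tangents). Comparisons of VTI across subjects imaged with a common
  protocol are unaffected in expectation, but single-vessel VTI values
  should not be over-interpreted at the percent level.
- The tangent window is specified in points, not mm; at very fine rasters
  the effective smoothing length shrinks accordingly.
- 2D only: vessels coursing perpendicular to the projection plane are
  foreshortened, as with any projection-based morphometry; no 3D
  skeletonization or torsion.
- The simulator's default effect sizes are package defaults, not estimates
  from data.
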