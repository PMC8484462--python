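# Methods

## Dry-mass quantification

Phase maps are stored as optical path difference (OPD) in nanometres per
pixel rather than radians: OPD is wavelength-free, so the biomass relation
needs no instrument constants beyond the pixel size. For a segmented region,

    mass [pg] = Σ OPD[nm] · (pixel_size[µm])² · 10⁻⁶ / α,

with the specific refractive increment α defaulting to 1.8 × 10⁻⁴ m³/kg, the
standard average for cellular dry matter. The sum runs over the region mask
only; a worked check (100 nm over 1000 pixels of (0.5 µm)² at the default α)
gives 138.89 pg and is asserted in the tests to hand-arithmetic precision.

## Synthetic scenes

The generator emulates a killing co-culture as a QPM sees it, not the
microscope physics. Each tumor cell is a rotated elliptical super-Gaussian
blob of order 2, `exp(−ln(100)·ρ⁴)`, zeroed beyond the normalized elliptical
radius ρ = 1 so the footprint boundary is crisp (the rendered edge falls to
1% of peak exactly at the nominal ellipse). The patch is rescaled so its
integrated OPD converts back to the prescribed mass exactly; rendering is
therefore the inverse of the biomass measurement up to discretization, and
the render → segment → measure round trip is held to 0.5% for
physiological mass/density combinations.

Dynamics, per frame interval Δt (default 15 min):

- **alive**: mass grows exponentially at `growth_rate_per_h` (default
  0.04 /h, a ~17 h doubling time typical of melanoma lines); area tracks
  mass at fixed per-cell density, drawn from 1.0–1.4 pg/µm² (peak OPD a few
  hundred nm).
- **killed**: from a seeded onset frame the area contracts at
  `shrink_rate_per_h` (default 0.4 /h) while density rises at
  `density_gain_per_h` (default equal, so mass is conserved during
  contraction); after `lysis_delay_frames` (default 2) the cell loses
  `lysis_loss_fraction` (default 0.5) of its mass at once and is frozen
  thereafter. This yields the documented ordering — area minimum at or
  before the density maximum, both before the lysis drop — which is a
  property test.
- **attackers**: small dense blobs (20–35 pg at 2.5 pg/µm², footprint well
  below the segmentation minimum-area cutoff) appear at
  `coculture_start_frame` (default 3) and random-walk an order of magnitude
  faster than tumor cells (3 vs 0.3 µm/frame). They are rendered but carry
  no ground truth: their role is to stress segmentation and tracking with
  transient contacts.

Fates are deterministic: after a seeded shuffle, the first
`round(kill_fraction · n)` cells are killed, so class counts are exact.
Initial positions are rejection-sampled with a separation margin; an
over-crowded configuration is an error, not a silent overlap. All draws come
from one `numpy` generator seeded by the config, so identical configs give
bit-identical scenes.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: interferometric reconstruction artifacts, halo
and background drift, focus changes, cell division, apoptosis not caused by
attack, partial or ambiguous kill signatures, and cell-shape irregularity
beyond smooth ellipses. Separability of the synthetic classes is
intentionally strong; results on these scenes validate the pipeline's
mechanics and bookkeeping, not clinical accuracy.

## Segmentation and features

Foreground = (OPD > local mean + offset) ∪ hysteresis-thresholded Gaussian
gradient magnitude, then hole filling, minimum-area filtering, 4-connected
labeling. Defaults: window 31 px, offset 8 nm, gradient σ 1.5 px, minimum
area 250 px (chosen to admit tumor cells, ~400 px and larger at the default
pixel size, while rejecting attacker-cell footprints). Edge hysteresis
thresholds default to offset/σ and half of it — an edge must climb the
threshold offset within about one smoothing scale.

Features follow the conventional region-property definitions (area, convex
and hole-filled area, eccentricity, axis lengths, extent, solidity,
perimeter, intensity extrema/mean over the OPD map in nm). Choices worth
noting:

- `shape_factor` is the dimensionless circularity 4πA/P² (1 for a circle);
  a literal 4πA/P variant is available behind a switch.
- `perimeter` uses the Crofton estimator, which is nearly unbiased on
  rasterized smooth shapes — a digital circle's circularity comes out ≈ 0.97
  — while `perimeter2` is the polygonal chain length (biased ~5% high on
  curved boundaries); the two are alternative edge weightings of the same
  boundary.
- `orientation` is measured from the x-axis, counter-clockwise positive
  (y-up), in [−90°, 90°], computed from central second moments.
- `filled_area` is the hole-filled region area (the conventional reading);
  a bounding-box reading would duplicate the denominator of `extent`.
- Geometric features are emitted in pixel units (with area also in µm²);
  percent-change inputs are unit-invariant, so the unit choice does not
  affect classification.
- Coordinates are 0-based, x = column, y = row; centroids are unweighted
  mask centroids; ties in reductions resolve in row-major scan order.

## Tracking, windows, exclusions

Linking between consecutive frames: mutual nearest neighbours within
`max_disp_um` (default 5 µm per 15-min frame) are accepted first; contested
leftovers are resolved by a Hungarian minimum-total-displacement assignment
restricted to the gate. Tracks are gap-free by construction (a missed
detection ends the track; no gap closing). Track ids are assigned in order
of first appearance. Cell division is not simulated and receives no special
handling in the linker.

Every run of three consecutive frames of a track is one classification
window (a track of length L yields L−2). Two exclusion rules are applied
before windows are used: (a) any track containing a cluster-flagged region
— area above 1.8× the running median region area, the signature of two
cells segmented as one — is dropped; (b) any track whose ordinary
least-squares biomass slope over the pre-co-culture frames is not strictly
positive is dropped (including tracks born after co-culture start, whose
growth cannot be verified). The slope uses the exact covariance/variance
form so that constant biomass is exactly zero and excluded by the strict
rule. When no pre-co-culture frames exist the growth rule is skipped with a
warning. Cells still growing during co-culture are retained deliberately:
they are the assay's potential false positives.

## Input formats and selection

For k selected features, A1/A2/A3 are the absolute values from the newest
1/2/3 frames (k, 2k, 3k values; A1 uses the newest frame, matching real-time
classification on arrival of a third image) and P1/P2 are signed fractional
changes (xₙ₊₁ − xₙ)/xₙ between consecutive frames (k and 2k values). The
preceding-frame denominator is the default; a following-frame variant is
available. Percent changes are kept as fractions, not ×100. A zero
denominator invalidates the window, which is dropped and counted. No
further standardization is applied to absolute inputs.

Selection ranks every feature (absolute values, x/y centroid coordinates
excluded as carrying no cell-state information) by stratified 5-fold
cross-validated single-feature AUC under each of the four families,
orienting AUC below 0.5 to 1 − AUC (a reversed threshold is an equally good
classifier). The consensus order is the mean rank across families, with
ties broken by the canonical feature order so the result is independent of
column order. A greedy top-down scan drops any feature whose |Pearson r|
with a better-ranked retained feature exceeds 0.95, and keeps the first ten
survivors.

## Classifiers, splits, sweep

Families use plain toolbox settings: Gaussian naive Bayes; L2 logistic
regression (C = 1); RBF SVM with the scale-gamma heuristic, scored by its
decision function; random forest with 100 trees, unlimited depth,
√(#features) per split, seeded. ROC/AUC is an explicit threshold sweep over
unique scores with trapezoidal integration, which equals the pairwise
concordance statistic (ties ½); the test suite verifies this against an
O(n²) oracle to 1e-12 and against an independent library implementation.

Splits are balanced per class and made at the track level — every pooled
window belongs to a distinct track (killed tracks contribute their
signature window, the one starting at kill onset; alive tracks one seeded
choice among co-culture windows), so no window of a training track can
appear in validation. Defaults mirror the study design: 200 windows per
class for training and three mutually disjoint validation sets of 67 per
class. The sweep trains every non-empty subset of the k features (1023 for
k = 10) per family and input type; the top configuration maximizes training
AUC with ties broken by fewer features, then lower subset bitmask.
Group comparisons are reported descriptively (mean/sd/max); no significance
testing.

## Dilution evaluation

Rare-event datasets mix `base_killed_count` (50) killed windows with
50·R alive windows at ratio 1:R, sampled without replacement within a
dataset and independently across the 30 datasets per ratio (the same alive
window may recur across datasets — unavoidable at high ratios). When the
alive pool cannot supply 50·R cases, the alive count is clipped to the pool
and the killed count reduced to `max(1, floor(n_alive/R))`, preserving the
ratio down to single-event datasets at extreme dilutions. The frozen model
is applied with no retraining or threshold refitting. The cross-system
check trains on the default generator ("system A") and evaluates on pools
from a slower-growing, smaller-celled configuration ("system B": growth
0.02 /h, 100–280 pg at 0.9–1.2 pg/µm²).

## Problem sizes and runtime choices

The full-scale runs (tests and `scripts/acceptance.py`) use 401 labeled
windows per class per dataset (enough for the 200 + 3×67 split), scenes of
16 tumor cells in 480×480 px with 10 frames, system-B pools of 60 killed
and 2400 alive windows, and dilution ratios to 1:100,000 under the clipping
rule (the alive pool, not 50·R, then bounds dataset size). These sizes keep
a complete run at minutes on one CPU while preserving every structural
property of the design (combination counts, split sizes, dilution
composition).

## Known limitations

- The linker is nearest-neighbour with a one-frame memory: no gap closing,
  no lineage handling, no attacker tracking.
- Cluster detection is a single area threshold against a running median; it
  cannot flag clusters of similarly-undersized debris.
- Probabilities are uncalibrated; the watch mode's default decision
  threshold (0.5 probability, 0 for the SVM decision function) is a
  convention, not an operating point chosen on ROC.
- Synthetic separability is strong; see the generator section for the list
  of real-data effects deliberately not modeled.
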