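# Methods

## Measurement model

All measurements operate on an unnormalized grayscale field `G(x, y) ∈ [0, 255]`
obtained as the per-pixel arithmetic mean of the three RGB channels of an
8-bit PNG. Coordinates are 0-based with `x` = column and `y` = row; pixel
centers sit at integer coordinates, and the *image center* is defined as
`((W−1)/2, (H−1)/2)` — radii are measured from this fixed point, not from a
computed centroid, because the imaging protocol centers the colony in the
frame.

### Radii and regions

Each image carries 16 manually selected points on the outer colony boundary
and 16 on the inner core boundary (the count is a parameter, minimum 3).
Two quantities are derived per region:

* **Average radius** — the mean Euclidean distance of the points from the
  image center. Sampling four points per image quadrant absorbs boundary
  asymmetry.
* **Minimal bounding circle** — the smallest circle containing all the
  points, computed exactly with Welzl's randomized incremental algorithm
  (duplicates removed first; a fixed shuffle seed keeps runs deterministic —
  the output circle is seed-independent). The centroid-max-distance
  approximation is deliberately not used. A pixel belongs to the circle iff
  its center satisfies `(x−cx)² + (y−cy)² ≤ r²`; no partial anti-aliased
  weighting.

Core fluorescence is the mean of `G` over the pixels inside the inner-point
minimal circle (clipped to the image). The minimal circle's center generally
differs from the image center; both are reported, and a flag
(`intensity_circle = "image"`) switches to an image-centered circle of the
average inner radius for sensitivity analysis. Note that the average-radius ≤
bounding-radius inequality is only guaranteed when distances are measured
from the minimal circle's own center; measured from the image center it is
reported without assertion.

### Trajectories

Per colony, the outer radius, inner radius, and core intensity are each
expressed as `100 · v_t / v_1` with the first available timepoint as
baseline. Missing baselines or gaps are errors, never interpolated; the
normalization is per colony (a cohort-baseline variant would hide
colony-to-colony variation and is not implemented). Cohort summaries report
per-timepoint mean and sample SD (n−1); a single-colony cohort reports SD 0
by convention, with a log note, to keep report schemas stable.

### Spiral complexity score

The core's band structure is reduced to a 1-D signal by sampling `G`
bilinearly along an Archimedean spiral `r(θ) = pitch · θ / 2π` starting at
the image center. The path holds 2000 samples at unit arc-length spacing:
each step advances θ by an iteratively corrected increment (initialized at
`Δθ = 1/√(r² + a²)`, `a = pitch/2π`) until the chord to the previous sample
is 1 px within 1e−3, which keeps consecutive spacing inside [0.9, 1.1] px and
the radial coordinate non-decreasing. 2000 unit steps reach a maximal radius
of `√(2·2000·a)` ≈ 50.5 px at the default pitch of 4 px/turn — chosen to
cover the central core region while staying inside a typical core; a warning
is emitted whenever the spiral exceeds the annotated core circle. Pitch and
interpolation scheme (bilinear default, nearest available) are exposed in
the config and recorded in every report so scores remain comparable across
runs.

The signal is scored over all `L − w + 1` stride-1 windows of `w = 20`
samples:

* **amplitude** = mean per-window `max − min`;
* **frequency** = mean per-window variance with denominator `w` (population
  variance, chosen for determinism and for the closed-form bound
  `frequency ≤ (range/2)²`).

Both scores are invariant under adding a constant to the signal and scale as
`c` and `c²` respectively under contrast scaling about the mean — these are
exact identities and are asserted as tests. Rotating the image by 90° leaves
the scores only approximately unchanged (within a few percent for banded
cores): the spiral re-samples an anisotropic field at 2000 discrete
positions, so equality holds only in distribution, not pointwise.

Per colony, the *maximal attained* amplitude and frequency over the days are
taken coordinate-wise by default (the maxima may fall on different days); a
`joint=True` option instead returns the single day with the largest score
norm. The amplitude–frequency scatter of these maxima is the phenotype
classification plot; no clustering algorithm is applied — the separation is
left to the reader (a two-group dominance check exists in the tests).

## Statistics

For each cohort × metric family, a one-way fixed-effects ANOVA across days is
followed by two-sided t-tests of each later day against day 1, Bonferroni
corrected with `m` = number of comparisons in the family (user-settable).
Welch's unequal-variance test is the default — group sizes and spreads differ
across days and cohorts — with pooled-variance and paired variants available.
Degenerate inputs are resolved explicitly: zero within-group variance with
unequal means reports `F = ∞, p = 0`; fully constant data reports
`F = 0, p = 1`; identical baseline/comparison pairs report `t = 0, p = 1`.
Significance tiers are rendered on adjusted p-values: `*` < 0.05, `#` < 0.01.
Because the three comparisons share the day-1 baseline, the realized
family-wise error under the null sits below the independent-test
approximation `1 − (1 − α/m)^m ≈ 0.049`; simulations in the test suite
confirm control at the 0.05 level.

## Synthetic data generator

The generator emulates the image statistics the pipeline measures — not
biofilm physics. A colony is a centered disc with three zones: dark
background (10), a uniform periphery annulus (140), and a core disc. The
outer radius interpolates geometrically from its day-1 value to the final
expansion ratio (only endpoint ratios are meaningful observables; geometric
interpolation gives smooth monotone expansion); the core radius does the
same with its own (near-1) ratio. Core mean intensity follows
`base · trend^(day−1)`.

The *wrinkled* preset adds `contrast · P(x, y)` on the core, where `P` is a
zero-mean field of 2–4 superposed oriented sinusoidal ridge sets with
per-colony random orientations and phases, spatial frequency
`density/100 px`, density growing per day. Sinusoids are sufficient to create
the band crossovers the windowed scores detect; real wrinkles additionally
branch, curve and cast shading that this model does not reproduce. Additive
Gaussian sensor noise (sd 4 by default) and 8-bit clamping/quantization are
applied last. Because band fields are exactly zero-mean over the core, the
recorded ground-truth core intensity equals `base · trend^(day−1)` up to
quantization (±0.5).

Cohort presets encode the observed endpoint conditions of the two growth
media: the smooth preset expands to 164 % (core 104 %) with intensity rising
to ~170 % by day 4; the wrinkled preset expands to 205 % (core 126 %) with
intensity falling to ~70 %, band density growing 1.4× per day from 3 bands
per 100 px, contrast 55. Default geometry is a 320×320 px frame with day-1
outer radius 70 px and core radius 58 px, so the default spiral (max radius
≈ 50.5 px) stays inside the core on every day. Boundary-point CSVs are
written with 16 points placed *exactly* on the true radii at uniform angles:
radius recovery is then exact by construction, and recovery tests isolate the
pipeline arithmetic rather than annotation noise — which also means the
synthetic SD of radius trajectories is 0, unlike manual annotations.

All randomness derives from one master seed: per-colony seeds come from
`SeedSequence([master, cohort_index, colony_index])`, ridge geometry from
stream `[colony_seed, 17]`, and per-day noise from `[colony_seed, 29, day]`,
so datasets regenerate bit-identically.

## Problem sizes and numerical choices

The test suite exercises the full chain on a 19-colony, 4-day cohort at
512×512 px and on smaller 256–320 px datasets elsewhere; the acceptance
script uses the 320 px defaults with 11 + 8 colonies and a 1000-replicate
null simulation. Geometric tolerances: minimal-circle containment 1e−9;
oracle agreement asserted at 1e−6; window statistics match a naive loop at
1e−9. Reports are tidy CSVs written deterministically; the JSON run summary
carries the only timestamp, plus the config hash and per-file SHA-256 input
hashes needed to re-execute a run.

## Known limitations

* Boundary points are manual inputs; the ray-casting suggester is a
  convenience that assumes a bright, roughly convex colony on a dark
  background and is never substituted silently for manual annotation.
* The complexity score depends on the (unreported) spiral pitch and
  interpolation; defaults are fixed and recorded, but absolute score values
  are only comparable between runs with identical spiral parameters.
* "Frequency" is a windowed variance, not a spectral estimate; signals with
  equal variance but different oscillation rates are not distinguished.
* The generator does not model annotation jitter, uneven illumination,
  vignetting, or core/periphery boundary diffusion, so pipeline accuracy on
  real micrographs is bounded below by annotation quality, not by the
  arithmetic verified here.
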