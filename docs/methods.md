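# Methods

## Segmentation model

A pixel is scored by `gris = c_r·R + c_g·G + c_b·B` on the raw 8-bit
channel intensities and labeled residue when `gris > threshold`
(strictly; a tie maps to background). Two consequences follow from the
strict inequality on unclipped gray values:

- **Positive-scale invariance.** Multiplying all four parameters by
  any k > 0 leaves the mask bit-identical, so only the direction of
  the parameter vector is identified; tuners should be expected to
  return any point on the optimal ray that lies inside the bounds.
- **Monotonicity.** Raising the threshold can only remove foreground
  from the pre-median mask.

Gray values are not clipped to [0, 255]: with coefficients in
[−10, 10] the index ranges over roughly ±7650 and the published tuned
values only make sense unclipped.

The full procedure is: (1) vegetation mask = the same
linear-combination-plus-threshold rule with vegetation parameters,
(2) residue candidate = the rule with residue parameters, (3) final
mask = candidate AND NOT vegetation, then a 5×5 median filter. The
vegetation default is the excess-green index (c_r, c_g, c_b) =
(−1, 2, −1) with threshold 20 — the standard green-cover detector for
field imagery; the original parameterization this step was built
around is not public, so the index is fully overridable in the config
(`vegetation:` block). The median filter is applied to the final
residue mask only; an optional flag (`median_vegetation`) also filters
the vegetation mask for users who read the procedure that way.

### Median filter

For binary input the 5×5 median equals a majority vote — "more than 12
of the 25 window samples are 1" — implemented as a separable integer
box count, which is exact (no floating-point ties). Borders are
handled by edge replication, so border windows still hold 25
(partially repeated) samples; replication avoids eroding residue that
touches the frame. A brute-force per-window `np.median` oracle backs
this in the tests.

### Template I/O

Internal mask polarity is fixed at 1 = residue everywhere. Scanned
tracings (dark marker ink on white paper) and white-on-black mask
images are both supported through the `foreground` flag of
`read_template`; binarization cuts at mid-scale (≥ 128 is bright).
Templates must already match the image dimensions; registration or
rescaling of mismatched templates is left to the user
(`resize_image` provides plain area-average resampling).

## Fitness and tuning

The objective is `S(A,B) = Σ|A−B| / (n·m)`, the normalized Hamming
distance between the computed mask and the template: 0 for identical
masks, 1 for complements, and a metric (symmetric, triangle
inequality), so "similarity" is reported as `100·(1−S)`. Over a
training set the objective is the unweighted mean of S across pairs.
(The original study reports a mean fitness of 0.2138 alongside a
similarity of 76.82%, although 100·(1−0.2138) = 78.62%; those two
printed numbers are mutually inconsistent, and this package defines
similarity strictly as 100·(1−S).)

The tuner is a generational, real-coded GA:

| setting | default | notes |
|---|---|---|
| population | 100 | fixed-size generational replacement |
| selection | roulette wheel | weight = 1 − S; S is minimized, and since S ∈ [0,1] this goodness transform is exact; an all-zero-weight population falls back to uniform |
| crossover | two-point, p = 0.8 | cuts at the 3 internal gene boundaries of the 4-gene chromosome (bit-level cuts are undefined for real genes); otherwise children copy their parents |
| mutation | Gaussian, scale 0.5, shrink 0.5 | σ_k = scale·(gene range)·(1 − shrink·k/max_generations), clamped to bounds afterwards; the linear schedule is the classical toolbox semantics of the scale/shrink vocabulary |
| elitism | 2 | best individuals survive unchanged, so the best fitness is non-increasing |
| bounds | coefficients [−10, 10], threshold [0, 255] | enforced at initialization and after every operator |
| stop | fitness < 0.05, 50-generation stall, or generation cap | stall means no improvement of the best fitness by more than 1e−9; the fitness test is applied to the best individual |

The threshold gene is kept real-valued (the published tuned threshold,
93.316, is not an integer); `GAConfig(integer_threshold=True)` rounds
it after every operator for users who want the integer encoding.
Offspring generation fills the population to exactly its fixed size;
the last child of the final pair is dropped when it would overshoot.

Inside `evolve` the per-candidate evaluation precomputes, once per
training image, the float color planes and the vegetation mask
(neither depends on the candidate genes); a test asserts this fast
path is arithmetically identical to running `segment` per candidate.
`fixed_coefficients` freezes (c_r, c_g, c_b) and evolves only the
threshold, which is how the GA is compared against exhaustive integer
threshold search in the tests.

## Coverage reporting

Percent cover is pixel counting; the set aggregate divides the pooled
residue-pixel count by the pooled pixel count (equal to the simple
mean of per-image percentages when all images share dimensions, and a
pixel-weighted mean otherwise). Because the aggregate is a convex
combination of per-image values, its error against templates is
bounded by the worst per-image error and typically much smaller —
over- and under-segmented images compensate. Reports round percents
to 2 decimals.

## Synthetic scenes

The generator emulates the study conditions — ground photographs of
wheat stubble with soil, vegetation, stones and shadows as distractors
— with exact per-pixel ground truth:

- Soil background at mean RGB (120, 95, 70), straws at (210, 175, 150)
  (sun-bleached tan), vegetation at (60, 140, 50), per-channel sd 15.
  The straw color sits at excess-green −10, comfortably below the
  vegetation cut, and responds strongly to blue-weighted residue
  indices; the palette is chosen so the straw/soil contrast is
  separable by some linear RGB combination — the method's working
  assumption — not to mimic a specific photograph.
- Per-pixel color noise is luminance-dominant (90% of the variance is
  a term shared across channels, the rest independent chroma noise;
  per-channel sd as configured). Uncontrolled field lighting varies
  brightness far more than hue, and hue-stable surfaces keep linear
  color indices well-behaved; fully channel-independent noise would
  make excess green fire on straw at unrealistic rates.
- Straws are hard-edged rotated rectangles (no anti-aliasing) drawn at
  random positions/orientations until the target residue fraction is
  reached (within about one straw's area; the default budget of 2000
  straws is a cap, and a positive target with a zero budget is
  rejected). Default straw dimensions scale with the image — length
  15–50% and width 1–3% of the shorter side — so miniatures used in
  tests keep straws wide enough (≥ 3 px) to survive the 5×5 median
  filter.
- Vegetation and shadows are accumulated elliptical patches up to
  their target fractions; stones are a fixed count of gray-beige
  blobs. Shadows darken whatever lies below them at draw time (straws
  are drawn last and are unshadowed). Rendering order is soil,
  shadows, stones, vegetation, straws; the vegetation ground truth
  keeps only pixels still visible under the straws, so the masks
  always describe the rendered image and are disjoint by construction.
- Every output is a pure function of the `SceneSpec`, including its
  seed. Scene defaults (640×480, residue target 0.5, vegetation 0.1,
  shadows 0.1, 5 stones) match the study's image format and roughly
  50% observed residue cover.

What the scenes do **not** model: perspective, anti-aliased or blurred
straw edges, straw translucency and self-shadowing, continuous
illumination gradients, color-calibration differences between cameras,
and the hand-tracing error of real templates (synthetic templates are
pixel-exact). Passing tests therefore demonstrate the correctness of
the algorithmic machinery and its behavior under the stated
assumptions, not field accuracy on real photographs — the shipped
`table1` preset, tuned on real imagery, is not expected to segment
synthetic scenes well, and conversely parameters tuned on synthetic
scenes are camera-specific calibrations like any other.

A **consistent pair** sets the template to the segmentation output
under known parameters, guaranteeing a zero-fitness optimum exists;
the tuning tests run at 64×48 (and 16×16 for the exhaustive-threshold
oracle) so a full 10-seed convergence study fits in seconds. Tuning
against a scene's true residue mask instead (the realistic task)
reaches fitness ≈ 0.07 on default miniatures — the same order as the
per-image fits reported for real field images.

## Numerical and degenerate-input choices

- Tie at `gris == threshold` → background, exactly as specified by the
  thresholding rule.
- Stall detection uses an absolute improvement epsilon of 1e−9 on the
  best fitness.
- `read_template` on a constant image returns all-zero for
  `foreground="dark"` (a blank white scan has no residue) and
  mid-scale comparison decides constant non-extreme values.
- Empty training sets, empty mask lists, zero-sized resize targets and
  infeasible scene specs raise `ValueError` before any computation.
- All randomness flows through `numpy.random.default_rng` seeded from
  the relevant config (`GAConfig.seed`, `SceneSpec.seed`, CLI
  `--seed`); identical inputs give bit-identical outputs.
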