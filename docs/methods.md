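# Methods

## The assay and what the package computes

A two-plate thermal place preference session confronts one unrestrained
mouse with two adjacent plates at different set temperatures for 5
minutes; the animal is placed on the colder plate at session start. The
standard screen repeats this over nine sessions covering 0–45 °C in
contiguous 5 °C pairs, and the whole screen is run at three timepoints:
before oxaliplatin (naive), after oxaliplatin but before the candidate
analgesic (pre-drug, the neuropathic baseline), and after the analgesic
(post-drug). The readout per cell is the percentage of session time on
the colder plate, `pct_colder`; analgesia is declared per session when a
significant pre-drug plate preference is lost or reversed post-drug.

## Tracking

The tracker implements classical frame differencing. Per consecutive
frame pair: resize (factor 0.5), grayscale (Rec. 601 luminance), median
filter (3×3); absolute difference; binarize (threshold 15 on the 0–255
scale); median filter the mask; count white pixels on each side of the
arena midline (half-open rule: the midline column belongs to the right
side). The side with more changed pixels is where the animal moved.

Numerical and policy choices:

- **Absolute** difference, not signed: a dark animal darkens pixels it
  enters and lightens ones it leaves; both mark its vicinity.
- The threshold is **fixed**; an adaptive variant can be configured but
  the defaults are deliberately the plain, reproducible pipeline.
- Iterations whose total changed-pixel count falls below
  `min_motion_pixels` (default 5 post-resize) are **unknown** — a frozen
  animal produces no differencing signal. Unknowns (and exact left/right
  ties) are resolved by **carrying forward** the last determined side,
  with leading unknowns backfilled from the first determined side; an
  animal cannot teleport between plates, so physical continuity justifies
  the rule. A recording with no determined iteration at all is an error,
  not a guess.
- Each iteration credits `1/frame_rate` seconds to its resolved side; the
  final frame opens no iteration. `pct_right` is computed as
  `100 − pct_left`, so conservation is exact by construction.
- The midline is specified in post-resize coordinates to avoid off-by-one
  drift between preprocessing and counting.
- Every adjacent frame pair is differenced by default; a `stride` option
  subsamples.

Recordings are read as numbered PNG/TIFF sequences or multi-page TIFF
stacks. These plain-image forms keep fixtures inspectable and the decoder
dependency-free; compressed video containers are intentionally not part
of the interchange surface.

## The synthetic agent

No animal recordings ship with the package, so a minimal generative model
supplies ground truth. Its purpose is to produce the assay's three
observable regimes — preference, loss, reversal — with interpretable
parameters, not to be a mechanistic model of murine thermoregulation.

- **Comfort score** `c(T) = −½((T−T₀)/w)² − g·max(0, T−T_h)²/w²` with
  optimum `T₀ = 26 °C` (inside the 22–30 °C murine preferendum), width
  `w = 8 °C`, heat-stress onset `T_h = 34 °C`, heat gain `g = 1`.
  Concave, maximal at the optimum, strictly decreasing toward 0 °C and
  decreasing faster above the onset. Only comfort *differences* matter.
- **Occupancy**: crossing attempts arrive as a Poisson process
  (`crossing_rate = 0.1 /s`, ~30 reconsiderations per 5-min session); at
  each attempt the agent settles on the left plate with probability
  `sigmoid(β·[c(T_left) − c(T_right)])`. The gain `β = 3` by default;
  `β = 0` is a fair coin regardless of temperatures. The session starts
  on the colder plate, per protocol.
- **Immobility**: each 10-s block is frozen with probability 0.1 —
  included specifically to exercise the tracker's carry-forward fallback.
- **Position**: within a plate the blob center follows an
  Ornstein–Uhlenbeck-style jitter (step SD 1.5 px/frame, pull 0.15 toward
  the plate center); a crossing redirects the pull to the other plate's
  center.
- **Rendering**: 64×128 px, 10 fps, plate backgrounds 175/185, blob disk
  radius 5 at intensity 40, Gaussian sensor noise SD 3, slow sinusoidal
  illumination drift (amplitude 4, period 60 s). The drift's
  frame-to-frame increment is far below the binarization threshold, which
  is exactly why differencing tolerates it. Sizes are desk-scale on
  purpose: a full 300 s session renders and tracks in seconds.
- **Treatment profiles** multiply (or, inside a temperature band, invert)
  the gain and deform the comfort curve. Oxaliplatin (cold
  hypersensitivity) is a +4 °C optimum shift with gain ×1.5, chosen so
  the neuropathic baseline shows a clear warm preference across all
  0–30 °C pairs and a cold preference above the heat-stress onset — the
  qualitative pre-drug pattern the assay reports. Band modifiers compose
  with the profile's global scale because the drug acts on the
  neuropathic state: the duloxetine-like profile zeroes the gain at
  0–5 °C and inverts it at 5–10 °C, leaving 10–20 °C untouched; the
  pregabalin-like profile zeroes 0–5 °C and inverts across 5–30 °C.
- **Cohorts**: per-subject biological variation is lognormal gain jitter
  (SD 0.2) and Gaussian optimum jitter (SD 1 °C). Cohort occupancy is
  drawn from the same crossing process as the full trajectory,
  discretized to frames (the spatial path adds only within-plate jitter,
  which cannot change the side between crossings); `spatial=True` runs
  the full path instead and is used in tests to confirm the two routes
  agree. All streams spawn deterministically from one seed.

What the simulator does **not** emulate: real body shape and posture
(the blob is a disk), rearing/grooming motion signatures, shadows and
reflections, cage-mate interference, thermal adaptation within a session,
and pharmacokinetic time courses. Passing tests therefore demonstrate
correctness of the algorithmic pipeline under controlled conditions, not
performance on arbitrary real footage.

## Statistics

Per session, `pct_colder` is modeled with the within-subject factor
timepoint (3 levels). The two plates' shares are complementary
(`pct_warmer = 100 − pct_colder`), so a two-factor plate × timepoint
model would be singular; the plate-vs-plate contrast within a timepoint
is instead the paired contrast of `pct_colder` against `pct_warmer` —
equivalently a one-sample t-test of `pct_colder` against 50 %.

- **Omnibus**: one-way repeated-measures ANOVA (pingouin), no sphericity
  correction by default (3 levels, small cohorts), Greenhouse–Geisser
  available. A session where every subject is constant across timepoints
  is degenerate and reported as p = 1 with a flag rather than an error.
- **Pairwise contrasts**: both comparison families use the studentized
  range with pair-specific paired SEs: `q = |t|·√2` referred to
  `Q(k, n−1)`. The plate family has k = 2 cells per contrast, where the
  adjustment reduces *exactly* to the two-sided paired t-test; the
  cross-timepoint (same-plate) family has k = 3. Degenerate zero-variance
  contrasts map to p = 1 (zero mean difference) or p = 0 (constant
  nonzero difference). Adjusted p-values are never smaller than the
  unadjusted paired t.
- **Stars**: strict inequalities at 0.05 / 0.01 / 0.001 / 0.0001.
- **Calls**: a timepoint's preference direction is warmer/colder when the
  adjusted plate contrast is significant at α = 0.05 and the cohort mean
  is on that side of 50 % (an exact 50 % mean has no direction). The
  drug-effect category compares pre-drug and post-drug directions:
  lost / reversed / maintained, or no-baseline when the pre-drug
  direction is none (such sessions support no analgesia claim).
  Families are corrected per session; analyses are run on percentages
  (tests on seconds are affine-equivalent).
- Missing cells are an error by default — silent imputation would change
  the test. Duplicate (subject, session, timepoint) keys are rejected.

## Calibration of the validation suite

- The **Type-I calibration** of the plate test uses gain-zero cohorts
  with the start side randomized. The protocol's start-on-colder rule by
  itself biases expected occupancy toward the cold plate (the first
  crossing attempt arrives ~10 s in), so a strictly per-protocol
  gain-zero cohort does not satisfy the null hypothesis of the plate test
  — the bias is real and the test correctly detects it with small power.
  Randomizing the start side yields E[`pct_colder`] = 50 exactly by
  symmetry, which is the correct null for measuring Type-I error.
- Problem sizes in tests and the reproduction script: ten 300 s videos
  for tracker fidelity, 500 cohorts (n = 10) for calibration, 200
  cohorts per drug profile for pattern recovery — sizes at which the
  Monte-Carlo error of each reported rate is a small fraction of the
  margin being checked.

## Known limitations

- Tracking assumes a single animal darker than both plate backgrounds and
  a fixed camera; no pose estimation or multi-animal support.
- The carry-forward rule is wrong in the (physically impossible under the
  model, rare in practice) case where an animal crosses plates while
  producing no differencing signal.
- Tukey adjustment for within-subject designs uses the standard
  studentized-range approximation with pair-specific variances; with
  strong sphericity violations and larger families its error control is
  approximate.
- The simulator's effect profiles are qualitative regime generators;
  recovering a published cohort's exact bar values is out of scope.
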