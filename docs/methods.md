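# Methods

This note documents the models, parameter choices, and numerical decisions
behind `gazeperim`, and what the synthetic validation does and does not show.

## Coordinate frames and units

Angular positions are per-axis flat-screen angles:
`θ = atan(offset_cm / distance_cm)` independently in x and y, with x positive
rightward in visual space and y positive upward, for both eyes (no
nasal/temporal mirroring of the measurement grid; only the two 27° nasal
points of the 24-2 reference lattice mirror with laterality). Retinal
(fixation-centered) positions are per-axis differences of screen-frame
angles. This is exact for a flat display and deviates from great-circle
offsets by well under 0.1° at the ≤ 21° eccentricities used here; we treat it
as approximate beyond ~15°. Degrees are the public unit everywhere; radians
appear only inside trig calls.

The decibel scale is the HFA attenuation convention: 0 dB ≡ 10,000 apostilb,
`asb = π·(cd/m²)`, so `dB = 10·log₁₀(10000/(π·L))`. A 300 cd/m² target is
10.26 dB — the fixed suprathreshold stimulus level used throughout.

## Measurement grid

The adapted grid keeps the 24-2 points with |x| ≤ 21°, |y| ≤ 15° (the unique
axis-aligned sub-box consistent with a 28.5° × 19.2° screen and a 44-point
total), drops the four points at (±3°, ±3°) — within the spatial imprecision
of a low-cost tracker — and adds (±10°, ±10°), giving 44 locations tested
four times each (176 presentations). The inclusion box is inferred rather
than printed anywhere; it is locked by test. Counting the four added points,
24 of the 44 locations lie in the paracentral |x| ≤ 15°, |y| ≤ 10° box.

## Trial engine

A trial scores a **hit** at the first valid gaze sample with Euclidean
angular distance ≤ 2.9° from the stimulus and `t − onset ≤ 1500 ms`; both
boundaries are inclusive (a tie-break we fixed by test, since "within" does
not specify open or closed). Distances are evaluated at each sample's own
viewing distance: the physical (cm) stimulus position is fixed at onset and
re-expressed in degrees per sample. A trial with no hit and fewer than two
valid samples in the window is **untrackable** — tracker dropout, not field
loss — and is counted separately and excluded from mapping.

The assumed fixation for placement is the most recent valid gaze sample at
onset; no saccade/fixation parsing is performed. The next trial begins one
sample (20 ms) after the previous trial resolves (hit time, or window
expiry). The engine never forces gaze: the anchor (last seen dot) is merely
left visible.

**Target scheduling.** The grid (42° × 30°) is wider than the screen
(~28° × 19°), so peripheral rows are only presentable from eccentric
fixations. Drawing uniformly among currently-placeable targets can starve
the session endgame (the last pending repetitions may need a fixation band
gaze no longer visits), so the draw is random *within the scarcest placeable
geometry class*: among placeable targets, those whose feasible fixation band
(`(W−|x|)·(H−|y|)`) is smallest are preferred. Hard-to-place peripheral
targets are thus taken whenever gaze happens to allow them. Presentations
that remain unplaceable are retried (each retry advances one sample) up to
`max_requeue_attempts = 8` times and then dropped with a warning; with
realistic observers a handful of peripheral repetitions per session are
dropped, which the convex-hull support masking downstream handles naturally.

## Eye-movement correction

After every scored trial the intended retinal location is replaced by
`stimulus − gaze(resolution − 200 ms)`, where resolution is the response time
for hits and the window expiry for misses (the look-back anchor for misses is
our choice; no response exists to anchor on). For hits, 200 ms before the
response predates the saccade — response latencies exceed 200 ms — so the
look-back recovers the pre-saccadic fixation. The lookup takes the nearest
valid sample; if none lies within ±60 ms (three samples at 50 Hz) the
intended location is retained and flagged rather than inventing a position.
Interpolation between samples is deliberately not used.

Why the correction matters even though placement is gaze-contingent: the
fixation estimate used for placement is the instantaneous gaze at onset,
which — right after the previous response saccade — is typically the
*undershot primary landing*, while the observer actually views the trial
from the settled, post-corrective fixation. The look-back lands on that
settled fixation; the intended location does not. In the simulation this is
exactly reproduced (see below), and disabling the correction measurably
worsens localization.

## Probability-of-seeing surface (ordinary kriging)

Corrected binary responses are interpolated by ordinary kriging. Defaults:
exponential semivariogram with range 6° (one grid spacing), partial sill
equal to the sample variance of the responses, nugget 0.05 (binomial
sampling noise of four-repetition binary data); all configurable, with
spherical and Gaussian families available. Numerical decisions:

* Sites closer than 0.25° are merged to their mean response before solving,
  keeping the system well conditioned when co-located binary responses
  disagree.
* The nugget is treated as measurement-error variance (*filtered kriging*):
  the prediction right-hand side uses γ → nugget as h → 0, so a positive
  nugget smooths at data sites and the estimate targets the noise-free
  probability field. With nugget = 0 this reduces to exact interpolation.
* Kriging is not range-respecting; predictions are clamped to [0, 1] after
  solving.
* The surface exists only inside the convex hull of the (merged) observation
  sites; lattice cells outside are masked. The default rendering lattice is
  0.5°, but all summaries evaluate the fitted model at exact coordinates,
  never by lattice lookup.
* A constant response set (all hits or all misses) degenerates the kriging
  system; it is special-cased to a constant surface.
* Singular systems after merging raise an error naming the offending sites.

The implementation is cross-checked in the tests against an independent
brute-force solve of the ordinary-kriging system (explicit per-point
assembly, `numpy.linalg.solve`) to 1e-8 on configurations of up to 12 sites.
One caveat: the "flipping a miss to a hit never lowers the surface" property
is checked numerically on seeded small configurations, but it is not a
theorem — ordinary-kriging weights can be negative (screening), so isolated
violations are possible in principle on other geometries.

**Mean Hit Rate** is the unweighted mean of the field evaluated at the 24-2
locations inside the support, with the included count reported alongside.

## Concordance with reference SAP fields

A 24-2 location inside the surface support is *concordant* when both tests
agree on defect status: `sensitivity < 25 dB` (reference) and
`hit rate < 0.5` (this test), or neither. Locations outside the hull are
excluded and counted; boundary locations are included iff they lie in the
closed hull (strict inside-hull inclusion is our rule — which boundary
handling the original analysis used is not stated anywhere). Both cutoffs
are parameters, and the cohort validation re-runs at (20 dB, 0.4) and
(28 dB, 0.6) to confirm the healthy/affected separation does not hinge on
them. The hit rate at a reference location is the kriged field evaluated at
that exact coordinate. Summary association uses the Pearson correlation and
the geometric-mean (standardized major axis) regression, the symmetric fit
appropriate when both axes carry error.

## The simulated observer

The simulator emulates the study conditions: a 25.4 × 16.9 cm screen at a
nominal 50 cm, monocular 50 Hz gaze with sub-0.6° precision, and a
fixed-luminance 300 cd/m² Goldmann III target.

* **Ground-truth field.** `sensitivity(x, y) = baseline − slope·eccentricity
  − Σ covering scotoma depths`, clipped to [0, 40] dB. Scotoma shapes: disk
  (center, radius), hemifield (direction), arcuate (an annular band of given
  arc radius and width on one side of fixation) — the canonical glaucomatous
  patterns.
* **Psychometric response.** `p = g + (1−g)·(1−λ)·Φ((S − S_stim)/σ)` with
  spread σ = 2 dB, lapse λ = 0.02, and guess floor g = 0.02 (false
  saccades). The probability is evaluated at the *fixation of record* — the
  settled fixation (base plus drift), excluding momentary saccadic
  transients — since the stimulus is viewed from there for the bulk of its
  1500 ms presentation.
* **Saccades.** Latency is truncated normal (mean 300 ms, SD 50 ms, floor
  220 ms; the floor guarantees gaze 200 ms before a response is still
  pre-saccadic, the same assumption the physical device makes). The primary
  saccade undershoots by 10% of its amplitude (classic hypometria) plus
  isotropic 0.75° landing noise; when it misses the target by more than
  0.5°, a corrective saccade follows 100 ms later and settles on the target
  (0.3° scatter). Saccades are modeled as instantaneous jumps at execution
  time — flight-path samples are not simulated, which at 50 Hz (one or two
  samples of flight) loses little.
* **Central fixation bias.** When a trial goes unseen, the observer gives up
  waiting with probability 0.6 late in the presentation (uniform
  1300–1480 ms after onset) and returns toward the screen center (3°
  scatter). Free-viewing observers re-center; without this the closed loop
  ratchets gaze toward the intact hemifield in eyes with hemifield loss and
  the opposite rows starve. The return is scheduled after the trial can no
  longer resolve (a response would exceed the window) and after the
  correction's look-back reference, so it alters neither outcomes nor
  corrected locations of the trial it ends.
* **Noise processes.** Tracker noise is isotropic Gaussian, σ = 0.3°/axis
  (within the < 0.6° device precision). Fixation drift and head distance are
  mean-reverting (Ornstein–Uhlenbeck) walks with 60 s time constants and
  stationary SDs of 1° and 2 cm around the fixation target and 50 cm
  respectively — slow postural/calibration wander that is quasi-stationary
  within a single trial, which is what makes the 200 ms look-back meaningful.
* **Synthetic reference fields** sample the ground-truth field at the 54
  24-2 locations with 1 dB measurement noise, clipped to [0, 50] dB. The
  mean deviation is computed against a flat 30 dB age-normal surrogate over
  the 52 non-nasal points. Real HFA MD uses an age-weighted normative model;
  only ordering/offset behavior matters for the synthetic comparisons, so
  the surrogate suffices.

All stochastic draws flow from one seeded generator per component (observer
and engine generators are spawned from the session seed); there is no hidden
global state, and identical seeds give byte-identical logs.

## Synthetic validation cohort

Twenty simulated eyes: ten healthy (central sensitivity 28–32 dB,
eccentricity decline 0.05–0.15 dB/°) and ten with scotomas of 20–30 dB depth
(three hemifield, three arcuate, four focal disks of 8–9° radius), each run
through the full pipeline against its synthetic reference field with
deterministic per-eye seeds. The validation asserts: median pointwise
concordance ≥ 90%, complete separation of the groups by Mean Hit Rate,
r² ≥ 0.8 between Mean Hit Rate and synthetic MD, and stability of the group
separation under the perturbed defect cutoffs. Sessions are ~170 trials and
the whole cohort runs in a few seconds.

What this does and does not show: the simulator reproduces the *mechanics*
of the test (closed-loop placement, saccadic scoring, look-back correction,
kriged mapping) under controlled ground truth. It does not reproduce
clinical variability — real patients show unstable fixation strategies,
media opacities, calibration failure (gaze-estimation *bias*, which neither
placement nor correction can observe), fatigue, and learning effects, none
of which are modeled. Synthetic concordance and correlation figures are
therefore cleaner than anything a clinical cohort would produce and are
checks of implementation correctness, not forecasts of clinical accuracy.

## File formats

CSV with a header row, UTF-8, "." decimal separator, floats serialized as
`%.12g` — a fixed dialect that makes write→read round-trips lossless to well
below 1e-9 at these magnitudes and outputs byte-stable for regression
testing. Provenance (config SHA-256 and seed) is embedded as `# key: value`
comment lines above the CSV header and as fields in JSON outputs. Reference
fields are accepted as JSON (laterality, md_db, 54 points) or CSV with the
laterality/MD carried in the comment header.

## Known limitations

* Per-axis flat-screen angles misstate great-circle eccentricity slightly
  beyond ~15°.
* Detection is decided once per fixation epoch, not continuously; gaze
  shifts in the last ~200 ms of a presentation cannot change an outcome (by
  design, matching the response-latency floor), but a mid-trial detection
  from a new fixation earlier than that is not modeled.
* The kriging variogram family and parameters of the original analysis are
  unknown; the exponential/6°/variance/0.05 defaults are our choice and all
  are configurable. Whether the original used a nugget (smoothing) or exact
  interpolation is likewise unknowable; both are supported.
* Dropped (never-placeable) peripheral repetitions shrink the surface
  support for severely impaired eyes; concordance is computed only over the
  locations present in both maps, mirroring how incomplete coverage is
  handled clinically.
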