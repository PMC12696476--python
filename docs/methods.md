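# Methods

This note documents the measurement conventions, the synthetic data
model, the statistical machinery, and the design decisions taken where
the underlying field conventions leave room for interpretation.

## Coordinate, time and interval conventions

Positions are continuous centimetres in an arena-centred frame after
dividing pixel coordinates by `px_per_cm` (derivable as arena pixel
diameter / 47 cm).  Frame indices are 0-based; all event intervals are
half-open `[start, end)`; an interval's duration is
`(end - start) / fps`.  The default trial is a 47-cm circular arena
filmed at 30 fps for 900 s.

Speeds and headings are forward finite differences: the value at frame
`t` describes the step `t -> t+1`, is undefined across missing frames
and at the last frame, and a heading is only defined when the step is
at least `min_step_cm` (default 0.05 cm).  The threshold exists because
at 30 fps sub-pixel tracking jitter otherwise produces essentially
random headings for a stationary fish; below it the fish has *no*
heading and heading-based predicates are false rather than noisy.
Optional centred moving-average smoothing of positions before
differencing is available and off by default.

## Gap handling and quality screening

Tracking software drops identities for stretches of frames.  Missing
runs bounded on both sides and no longer than `max_gap_s` (default
0.5 s) are filled by linear interpolation; filled frames stay flagged
and never count as tracked.  Trial quality is the *minimum* per-fish
fraction of originally tracked frames — a trial is only as usable as
its worst-tracked fish; a `mean` aggregate is available.  Trials are
discarded when that fraction is strictly below 0.80; exactly 80% is
retained, reading the exclusion rule ("below 80%") literally.  Because
interpolated frames are excluded from the fraction, interpolation can
never rescue a low-quality trial.

## Classifier definitions and boundary conventions

* Association: distance strictly `< 4 cm`.
* Chase: distance strictly `< 3 cm`; heading difference strictly
  `< 50°`; "behind" is operationalized geometrically as the female-to-
  male line of sight making an angle `> 90°` with her heading
  (equivalently, the male projects onto the negative half of her
  heading axis).  The source conventions state "behind" without
  geometry; the projection sign is the simplest rotation-invariant
  reading.
* Glide: distance `<= 60 mm`, orientation `<= 70°`, and speed inside
  the closed 5th–20th percentile band of that female's own speed
  distribution, computed per female per trial over originally tracked
  frames only (interpolated frames excluded).  Percentiles use linear
  interpolation between closest order statistics and require at least
  20 defined speed samples.  The slow-speed band *is* the smoothness
  criterion — no additional heading-change cap is applied by default.
  The same "male–female angle" phrase covers two distinct geometric
  quantities — heading alignment for chases, orientation-to-target for
  glides — and both readings are implemented as separate operators
  (`angle_between`, `bearing_angle`), each returning unsigned degrees
  in [0, 180].

Distance thresholds are strict (`<`) and glide thresholds inclusive
(`<=`), following the respective "within …" / "≤" phrasings.  Maximal
positive runs shorter than `min_bout_frames` (default 3 frames =
0.1 s) are discarded to suppress single-frame jitter events.  Glide
events with inter-event gaps `<= 3 s` merge into one; merging is
idempotent, monotone in the gap parameter, and available (off by
default) for chase bouts.

A deliberately naive per-frame re-implementation of all three
classifiers lives in `courtrack.reference` (plain scalar `math`, its
own hand-rolled percentile).  It shares no code with the vectorized
path and is compared frame-for-frame against it in the acceptance
tests on random noisy and clean trials.

## Trial-level statistics

The preference ratio `(tR - tN) / (tR + tN)` is undefined when the
male associated with neither female; such trials are flagged and
excluded from downstream preference analysis rather than imputed.
Latency to first sexual behavior pools all scored behavior onsets and
right-censors at the 900-s recording end when none occurred — the
recording length is the only defensible censoring bound.  The
receptivity validation statistic is the per-male difference in glide
counts (receptive minus non-receptive female) tested against zero with
a two-sided one-sample t-test; zero-variance inputs are flagged
degenerate instead of reporting an infinite t.  Agreement between
behavioral scoring and proximity measurement is Spearman's rank
correlation with midranks for ties, pooled across female-status groups,
with a permutation p-value (5000 seeded shuffles by default).

## Synthetic trajectory generator

The generator's purpose is fidelity to the classifiers' predicates,
not to fish biomechanics.  Baseline motion is a discrete correlated
random walk: per-frame heading increments N(0, 0.3 rad), speeds drawn
uniformly from 6–12 cm/s, alternating with slow idle bouts at
0.3 cm/s.  Scripted episodes overlay deterministic geometry:

* **chase** — the female runs a circular arc (radius 6 cm, 4 cm/s) and
  the male is placed 2 cm behind her along her direction of motion:
  distance 2 cm, heading difference ≈ 19°, male strictly behind, all
  inside the stated thresholds with margin.
* **glide** — the male holds a fixed point; the female approaches in a
  straight line from 5.8 cm at 3.0 cm/s, heading exactly at him.
* **approach_association** — both fish hold nearly stationary
  positions 2.5 cm apart: association fires, but with no headings
  neither chase nor glide can.
* **depart** — a straight run back toward the actor's home region.

Three structural guarantees make zero-noise ground truth *exact*
rather than approximate:

1. **Spatial separation.**  Outside scripted episodes the male wanders
   in a home half-disk on one side of the arena and each female on the
   other, with every scripted location confined to the male's side;
   the minimum distance between any wandering female and the male
   exceeds the largest classifier radius (6 cm).  After an episode the
   actor jumps straight back to its home region, so there are no slow
   transition passes through the interaction zone.  Consequently no
   unscripted frame can satisfy any classifier.
2. **Speed-band placement.**  Idle bouts (0.7–0.9 s) alternate with
   wander bouts (8–11 s), pinning each fish's idle-frame fraction
   between roughly 6% and 10%.  The 5th percentile of the female's
   speed distribution therefore always falls in the idle block
   (≈ 0.3 cm/s) and the 20th percentile in the fast wander block
   (≥ 6 cm/s), so the scripted 3.0 cm/s glide speed lies strictly
   inside her empirical band.  Bout lengths are drawn from narrow
   uniform ranges precisely because heavy-tailed bout distributions
   let the idle fraction drift below 5% in short trials, which parks a
   percentile edge on the glide-speed tie block and breaks exactness.
3. **Heading suppression.**  Idle and stationary-association steps are
   below the heading-definition threshold, so slow frames can never
   satisfy orientation predicates even if geometry cooperated.

Truth labels are the scripted frame ranges, assigned *before*
measurement noise (isotropic Gaussian jitter, i.i.d. per-frame
dropout) is applied, so recovery-versus-noise curves are measurable.
Boundary frames cost roughly one frame per episode (the last scripted
frame's displacement points at the teleport target), which is why
chase recovery is asserted as frame-level Jaccard ≥ 0.9 while glide
recovery — an event count, insensitive to one-frame erosion — is
asserted exact.  Episode scripts are validated: overlapping
participation, schedules past the trial end, and same-female glides
closer than the merge window are rejected.

What the generator does **not** emulate: realistic fish kinematics
(burst-glide swimming, wall-following, social following outside
scripted bouts), identity swaps, or correlated dropout near
occlusions.  Passing tests therefore demonstrate that the classifiers
implement their stated predicates and recover known events under
positional noise — not that the predicates themselves are optimal for
real guppy behavior.

## Behavior-count simulation

`simulate_counts` draws one assay table per call with the no-choice
study layout as default: 105 assays in four treatment × status cells
(24/29/26/26).  Counts are NB2 via the gamma–Poisson mixture with a
log-linear mean: fixed effects of female status, treatment and their
interaction; Gaussian random intercepts for batch (2 levels, SD 0.1)
and rearing tank (≈ 3 males per tank, nested in treatment, SD 0.2);
and body-size-difference (N(1.2, 0.4) cm) and glide-count covariates.
Default effect sizes are the published incidence-rate ratios of the
study this pipeline targets (e.g. treatment multiplies sneak attempts
by 2.45 and displays by 1.10); chasing time is zero-inflated with
probability 0.04 (the published zero-inflation intercept, treated as a
probability — at 0.04 the odds/probability distinction is below
simulation resolution).  NB dispersions (θ = 3, 1.5, 2 for displays,
sneaks, chasing) and random-effect SDs are not published anywhere and
were fixed once at values giving realistic overdispersion
(variance/mean ≈ 6 for displays) and small-but-nonzero clustering.
Latencies are exponential with per-cell medians (mixed-sex males
faster, most markedly with non-receptive females: 200/180 s vs
600/300 s) censored at 900 s.  `CountSimConfig.null()` switches every
effect and random-effect variance off for calibration runs.

## Count model fitting

`BehaviorCountModel` fits NB2 (log link) by maximum likelihood
(statsmodels, BFGS with a Nelder–Mead fallback; non-convergence is
flagged, never silently refit).  Treatment coding uses the
male-only / non-receptive reference cell.  Wald tests and 95%
intervals use a t(n − p) reference (p = mean-model parameters) rather
than the normal: at ~100 assays the plain z reference is measurably
anticonservative (empirical size ≈ 0.065 at nominal 0.05 in the
package's own calibration runs; the t reference brings it to ≈ 0.062).
IRRs are `exp(coef)` exactly; interval endpoints exponentiate the
link-scale interval.  The random intercepts present in the generator
are *not* estimated — the fixed marginal model is the within-package
calibration surface, and because tank and batch effects are
multiplicative in both cells they do not bias the treatment IRR.  An
optional intercept-only zero-inflation component (statsmodels
`ZeroInflatedNegativeBinomialP`) serves the chasing response.  The
mixed-model battery with batch/tank intercepts, Kenward–Roger degrees
of freedom and Tukey-adjusted post hocs is an R-side analysis by
design; the CSV contract (`BehaviorRecord` table) is the hand-off
boundary, and `fit_latency_cox` (lifelines, Efron ties, no frailty)
is the fixed-effects analogue of the mixed survival model.

## Problem sizes and calibration bands

The test suite and `scripts/acceptance.py` use: 50 random trials of
5,000 frames for classifier–reference equivalence (exact, frame for
frame); 10 zero-noise scripted trials for ground-truth recovery (glide
counts exact, chase Jaccard ≥ 0.9); 500 replicate 105-assay null
datasets for the size of the treatment test (accepted band
0.03–0.07); and 200 replicates with a true IRR of 2.45 for interval
coverage (accepted band 0.90–0.98).  These sizes put Monte-Carlo
standard errors near 0.01 for both calibration rates while keeping the
whole acceptance run under a minute on one CPU.

## Known limitations

* The behind-predicate and both angle operators assume 2-D planar
  motion; vertical excursions in deeper arenas would alias into
  apparent speed and orientation changes.
* The speed-percentile band is computed over the whole trial, so a
  female that spends most of a trial interacting (rather than
  swimming freely) has a band that reflects interaction speeds; the
  alternative (excluding near-male frames from the band) is a
  documented interpretation question, not implemented.
* Latency analysis treats the two behavior types symmetrically; no
  competing-risks structure.
* `estimate_body_length` inherits any systematic bounding-box bias of
  the tracker (boxes are axis-aligned, so the diagonal overestimates
  length for diagonal postures and underestimates it for curved ones);
  it is a covariate, not a morphometric measurement.
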