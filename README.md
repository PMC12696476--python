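# courtrack

Trajectory-derived quantification of fish courtship behavior.

Video tracking (e.g. idTracker) turns mate-choice trials into per-frame
position tables — one row per frame and individual.  `courtrack` turns
those tables into the behavioral measurements used in studies of male
mating tactics and mate preference in poeciliid fish such as the guppy
(*Poecilia reticulata*): male–female **association time**, **chase**
bouts, female **glide approaches** (a receptivity signal), the
**preference ratio** of dichotomous choice tests, and censored
**latencies** to first sexual behavior.  A synthetic-trial generator
with scripted, ground-truth-labelled episodes makes every classifier
testable end to end, and a negative-binomial count model supports
calibration and power analysis of the downstream behavior-count
statistics.

It is aimed at behavioral ecologists who already have tracking output
(this package does no video processing or identity assignment) and want
reproducible, scriptable event detection and trial summaries.

## The classifiers

All three operate on calibrated positions (cm, arena-centred, 30 fps by
default), with headings from frame-to-frame displacements.  Writing
$d_t$ for the male–female distance at frame $t$, $\theta^M_t,
\theta^F_t$ for their headings, and $\beta_t$ for the angle between the
female's heading and her line of sight to the male:

- **association**: frame $t$ counts iff $d_t < 4\,\mathrm{cm}$
  (roughly two body lengths).  Association time is the frame count
  over the frame rate.
- **chase**: $d_t < 3\,\mathrm{cm}$, nearly parallel motion
  $|\theta^M_t - \theta^F_t| < 50^\circ$, and the male *behind* the
  female — her line of sight to him makes more than $90^\circ$ with
  her heading.
- **glide** (slow female approach): $d_t \le 60\,\mathrm{mm}$, female
  speed inside the 5th–20th percentile band of her own within-trial
  speed distribution, and oriented toward the male,
  $\beta_t \le 70^\circ$.  Glide bouts separated by $\le 3$ s merge
  into one event.

Positive runs of at least 3 frames (0.1 s) become half-open
`EventInterval` bouts.  Trials in which any fish is tracked in fewer
than 80% of frames are flagged for exclusion (exactly 80% is retained).

From a dichotomous trial the preference for the receptive female is

$$\mathrm{ratio} = \frac{t_R - t_N}{t_R + t_N} \in [-1, 1],$$

with $t_R, t_N$ the association times with the receptive and
non-receptive female.

Behavior counts $y$ (displays, sneak attempts, chasing time in frames)
are modelled as NB2 with a log link,
$\log \mu = \beta_0 + \beta_S\,\mathrm{status} +
\beta_T\,\mathrm{treatment} + \beta_{S\times T} + \beta_b\,\Delta_{\rm size}
+ \beta_g\,n_{\rm glides}$, and effects reported as incidence-rate
ratios $e^{\beta}$ with $t_{(n-p)}$ Wald tests and intervals.

## Worked example

```python
import courtrack as ct

script = ct.make_standard_script("dichotomous", duration_s=300.0)
trial, truth = ct.simulate_trial(script, seed=42, trial_id="demo")

for fem in trial.females:
    _, assoc_s, _ = ct.association_frames(trial, fem)
    glides, n_glides = ct.detect_glides(trial, fem)
    chases = ct.detect_chase(trial, fem)
    print(f"{fem.role}: association {assoc_s:.1f} s, "
          f"{n_glides} glides (scripted {truth.expected_glide_counts[fem.individual_id]}), "
          f"{len(chases)} chase bouts")

t_r = ct.association_frames(trial, trial.track_for_role("female_receptive"))[1]
t_n = ct.association_frames(trial, trial.track_for_role("female_nonreceptive"))[1]
print(f"preference ratio: {ct.preference_ratio(t_r, t_n):+.3f}")
```

prints

```
female_receptive: association 15.4 s, 5 glides (scripted 5), 4 chase bouts
female_nonreceptive: association 4.7 s, 2 glides (scripted 2), 0 chase bouts
preference ratio: +0.529
```

Every scripted glide is recovered exactly, chases are detected only
toward the chased female, and the male's preference ratio is positive
because the script places him near the receptive female more often.

Fitting the count model to a simulated 105-assay study in which the
mixed-sex rearing treatment multiplies sneak attempts by 2.45:

```python
from courtrack import simulate_counts, BehaviorCountModel

df = simulate_counts(seed=7)
print(BehaviorCountModel(df, "sneaks").fit().summary())
```

```
Negative-binomial count model: sneaks
  n = 105, converged = True
       term     coef       se      irr  irr_low irr_high        z        p
  intercept   -0.187    0.480    0.829    0.320    2.148   -0.390    0.697
  treatment    0.801    0.322    2.228    1.175    4.225    2.484    0.015
     status    0.443    0.373    1.558    0.743    3.264    1.189    0.237
interaction   -0.692    0.455    0.501    0.203    1.236   -1.520    0.132
  body_size    0.214    0.319    1.239    0.657    2.336    0.671    0.504
     glides   -0.001    0.088    0.999    0.839    1.189   -0.014    0.989
```

The fitted treatment IRR (2.23, CI [1.18, 4.23]) recovers the simulated
2.45-fold effect within sampling error at this sample size.

## Command line

```sh
courtrack simulate  --out-dir sim --seed 7 --n-trials 3 --design dichotomous --duration-s 300
courtrack events    --input sim/sim000.csv --config sim/config_echo.yaml --out events.csv
courtrack summarize sim/sim*.csv --config sim/config_echo.yaml --out summary.csv
courtrack analyze   --counts sim/behavior_records.csv --out-dir models/
courtrack replicate --summary summary.csv --out glide_test.csv
```

Stages exchange plain CSV files; classifier thresholds can be
overridden per run (`--association-radius`, `--chase-angle`, …) and are
echoed to `config_echo.yaml` next to the outputs.  All stages are
deterministic given `--seed`.

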