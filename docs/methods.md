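# Methods

This note records the modeling choices behind `actibout`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic-data generator does and does not emulate, and the
numerical conventions at the edges.

## Signal model and epoching

Raw input is a triaxial acceleration trace in gravitational units with
strictly increasing timestamps (nominally 60 Hz for research-grade wrist
devices). The per-second summary is the *summed gravity-subtracted SVM*,
`Σ |√(x²+y²+z²) − 1|` over the samples of the second (units g·s). This is
the convention under which the bundled cut points are expressed; an
alternative without gravity subtraction (`subtract_gravity=False`) is
provided but off by default. Seconds inside the recording span with no
samples are kept as *missing* epochs — they carry no label, break bout runs,
and are excluded from wear fractions. Days are partitioned at local
midnight; all windows (analysis, non-wear, sleep exclusion) are clock-time
based.

## Cut points

Class bands are half-open: sedentary `[0, c₁)`, light `[c₁, c₂)`, MVPA
`[c₂, ∞)` — an epoch exactly at a cut belongs to the more intense class.
Defaults (`c₁ = 11.40`, `c₂ = 18.84` g·s per 1-s epoch) derive from the
youth wrist GENEActiv calibration of Schaefer et al. (2014) — mean
gravity-subtracted SVM of 0.190 g and 0.314 g per second — multiplied by
the 60 Hz sampling rate to match the summed convention. Cut points are
configuration (`data/default_config.yaml`), not code: studies using other
devices, wear sites, or age groups should substitute their own validated
values. Every downstream result in this package is conditional on the cut
points; the synthetic round-trip guarantee holds for any valid pair.

## Wear protocol

Per day, in order: fewer than 10 h of non-missing epochs → `invalid_short`;
otherwise, if the sedentary share of classified epochs inside 06:00–21:00
strictly exceeds 80% → `nonwear`; otherwise `valid`. A participant-period
needs ≥3 valid days. Non-wear detection is per-day (the protocol's "within
1 day" reading), and non-wear days are excluded exactly like short days.
The comparisons are strict (`<10 h`, `>80%`), so days at exactly 10 h or
exactly 80% are valid — the threshold fixtures in the tests pin this.

## Bout features

A bout is a maximal run of same-class seconds; missing seconds break runs
and are bridged by no tolerance (none is part of the protocol). The eight
daily factors are time and frequency of MVPA bouts at ≥3 s and ≥30 s and of
sedentary bouts at ≥60 s and ≥300 s, computed inside 07:00–22:00. The ≥3 s
MVPA floor reflects that shorter excursions at the wrist are predominantly
device agitation rather than activity. Thresholds are *cumulative*: a run
counts at every threshold it meets, which keeps time-at-threshold and
frequency-at-threshold monotone non-increasing in the threshold — the
orderings the behavior archetypes rely on. Daily summaries report MVPA
min/day from ≥3 s bouts and sedentary h/day from ≥60 s bouts; because
features are computed in the daytime window, the sedentary summary already
excludes sleep time (22:00–07:00). Guideline compliance uses an inclusive
60 min/day MVPA boundary.

## Clustering chain

Daily 8-factor vectors from *both* periods are pooled into one fit — labels
are then comparable across periods, which the movement matrix requires.
Standardization uses the sample SD (ddof = 1); constant columns map to
zeros with a warning rather than NaNs. PCA retains an explicit `fixed_m`
when given, else the smallest m whose cumulative explained variance reaches
0.90. k-means (scikit-learn, k-means++ initialization, best of `n_init=50`
by WSS, seed mandatory) runs in PC-score space; scikit-learn's internal
empty-cluster relocation stands in for explicit farthest-point re-seeding.
The elbow selects k over 2–10 by maximum perpendicular distance from
(k, WSS(k)) to the chord joining the endpoints of the WSS curve, ties to
the smaller k; WSS(k) is the best of `replicates=10` fits. Clusters are
renumbered by decreasing member-mean MVPA time (≥3 s), ties by increasing
sedentary time (≥60 s), so cluster 1 is always the most active group.
Participant-periods are assigned their modal day cluster (ties toward the
more active cluster); a mean-feature-vector mode is available. In the k×k
movement matrix (rows pre, columns post) below-diagonal cells are moves to
a more active cluster.

## Synthetic cohorts

The generator emulates children's daytime free-living behavior as
alternating intensity bouts over a 15 h (07:00–22:00) window. An archetype
fixes per-class daily minutes (summing to the window) and a
truncated-normal bout-length law (minimum 1 s) per class; a day is built by
drawing each class's bouts to its (integer-rounded) second target and
interleaving them randomly while avoiding same-class adjacency where
possible. Two jitters make days realistically non-identical: class totals
vary with CV 0.04 (renormalized to the window; realized totals stay well
inside ±10% of target), and each day rescales the bout-length laws per
class with CV 0.15 — children fragment a similar activity volume
differently from day to day, which is what gives the frequency and
sustained-bout features within-archetype spread.

The five default archetypes span guideline-meeting (70 MVPA min/day, many
short MVPA bouts) down to highly sedentary (21 MVPA min/day, >500 sedentary
minutes in long runs), with a "moderately active" profile distinguished by
sustained ≥30 s MVPA bouts and an "active" profile with the least sedentary
accumulation. They are designed to be *well separated* as 8-factor
distributions — separation is part of the generator's contract (planted
membership must be recoverable, ARI ≥ 0.9, and the elbow must find k = 5
on defaults) — while preserving the qualitative orderings that define the
archetypes. One fine point is knowingly approximate: a single
truncated-normal law cannot give the moderately-active profile both ~100
short sedentary bouts and the largest sustained-sedentary time, so its
≥300 s sedentary time ranks below the most-active profile's.

Raw-signal synthesis draws, per second, a target SVM uniformly inside the
label's cut-point band (2% margins; the MVPA band capped at twice the MVPA
cut) and emits `rate` isotropically-oriented samples of magnitude
`1 + target/rate`, so the per-second aggregate equals the target to
floating-point accuracy and the round trip is exact by construction —
independent of any noise model. Samples sit on an integer-microsecond grid
so CSV round trips are lossless. Scheduled wear gaps either drop samples
(`gap_mode="missing"`, exercising the <10 h rule) or emit resting
unit-gravity samples (`"rest"`, exercising the sedentary-fraction rule).

What the generator does **not** emulate: physiologically realistic
waveforms (frequency content, device noise spectra, autocorrelation),
sleep, posture, heavy-tailed real bout-length distributions, or
between-child variation within an archetype. Passing tests therefore
demonstrate the *pipeline's* correctness and the recoverability of planted
structure — not that real cohorts separate this cleanly; real accelerometer
data are far noisier and cluster structure in them is an empirical
question.

## Trial metrics

Feasibility rates follow pilot-report conventions: opt-in over reachable
invitees, retention over baseline completers, completion and module
completion over program commencers, tracker compliance over intervention
completers. Percentages are rounded half-up to integers for report parity;
exact fractions are always retained. Score summaries use the
linear-interpolation quantile convention. Pre/post contrasts are
complete-case paired t statistics (mean difference, t-based CI, two-sided
p) — a deliberate simplification of random-intercept mixed modeling;
participants missing either period are excluded and counted, and
zero-variance differences are flagged as degenerate rather than given a
spurious interval. Youth HRQoL profiles dichotomize to "any problems"
(level ≥ 2) per dimension; index values come from a user-supplied value-set
table (these are licensed artifacts and are not bundled), with the
all-ones profile anchored at 1.0. 6MWT percentiles interpolate linearly
between the bracketing quantiles of a user-supplied `sex × age × quantile`
normative table and clamp to [1, 99] outside it; the normative equations
themselves are consumed as data, not reimplemented.

## Problem sizes used in validation

The validation harness runs at desk scale, chosen to exercise every code
path with comfortable statistical margins: the round-trip check uses 1,000
random label sequences of 60–300 s at 60 Hz (~180,000 classified seconds);
the bout oracle 1,000 random strings up to 400 s; archetype recovery 20
simulated cohorts of 5 archetypes × 10 participants × 7 days (350 daily
vectors each). Full-day round trips (15 h at 60 Hz) are covered by the unit
tests at smaller counts; exactness does not depend on sequence length.

## Known limitations

- Cut points, and therefore every intensity-dependent quantity, are
  device-, site-, and population-specific; the bundled defaults are for
  children's wrist-worn accelerometry under the summed-SVM convention.
- Epoch lengths other than integer seconds, device calibration,
  idle-sleep-mode artifacts, and temperature/light channels are out of
  scope.
- The elbow criterion is the only k-selection rule offered (by design);
  silhouette or gap statistics are not implemented.
- The paired-contrast helper assumes exchangeable complete cases; it does
  not model missingness or within-participant correlation beyond pairing.
- `assign_periods` requires the model to have been fitted on pooled
  pre+post days; fitting per period would make cluster labels
  incomparable.
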