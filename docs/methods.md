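# Methods

This note records the model behind `crowdtrace`, the conventions and
numerical choices that were genuinely open, and what the synthetic cohorts
do and do not establish about real tracing data.

## Geometry and scoring

Templates are closed planar curves in mm, screen coordinates (origin
top-left, y down; every statistic is invariant to this choice). The five
built-in families are an ellipse (semi-axes 55 × 35 mm), a thinner ellipse
(60 × 20 mm), three- and four-petal polar roses r(θ) = 35 + 20·cos(kθ)
(k = 3, 4; scaled isotropically so the k-fold symmetry survives), and a
Bernoulli lemniscate (half-width 55 mm), all centred in the 216 × 135 mm
drawing area and sampled as 2000-point polylines. Any closed curve can be
supplied as a `custom` template, which is the hook for exact replication of
a particular study's shapes.

The curve is cut into `n_ref` segments of equal arc length (50 for the two
ellipses, 100 otherwise — enough to represent the shape while keeping
several touch samples per bin), starting at the polyline's first point.
Each segment's **reference point** is the coordinate-wise (marginal) median
of its polyline points. "Median centre of mass" admits a geometric-median
reading too; the marginal median is the simpler reading, is
permutation-stable, and every downstream statistic is defined relative to
whichever convention is used. For even counts the midpoint of the two
middle values is used. Note one subtlety discovered in testing: on a thin
arc whose x and y are not both monotone, the marginal median can land
marginally *outside* the (degenerate-thin) convex hull of the arc — it is
always inside the bounding box and within a fraction of a mm of the arc, so
this has no practical consequence, but "inside the hull" is not an
invariant of the construction.

Errors are per-bin Euclidean distances to the reference points, summarised
by their arithmetic mean over non-missing bins; coverage (fraction of bins
present) is always reported alongside.

## Cleaning

Three per-trace filters: duration < 25 s; standard deviation in either axis
below half the template polyline's; any consecutive-sample jump exceeding a
quarter of the screen in either dimension ("dimensions" read per axis — a
Euclidean-jump variant would differ only for diagonal glitches). Verdicts
are per trace, so cleaning is idempotent and order-independent. Template
spread is computed over the dense polyline; the trace is used raw (no
resampling before cleaning).

## Splicing and subsampling

Each trace is cut into 8 slices of equal *wall-clock* duration (robust to
irregular sampling; the final sample joins the last slice), with 5 and 12
supported for robustness analyses. No attempt is made to detect true
single passes — slices typically contain about one lap, sometimes more.
Each slice is binned against the template by nearest reference point (ties
to the lowest index) and collapsed to per-bin marginal medians. Bins with
no samples stay missing (NaN) end to end; nothing is interpolated, and
aggregation and scoring run over available bins with counts recorded.

## Aggregation and the crowd

The crowd trajectory aggregates one individual trajectory per subject —
each subject's first slice by default; a seeded random slice or a per-subject
pooled aggregate are options, and no statistic in this package is sensitive
to the choice beyond Monte-Carlo noise. Aggregation is the per-bin marginal
median (mean optional). Mean aggregation obeys an exact convexity (Jensen)
bound — per bin, over exactly the inputs present there, the aggregate's
error cannot exceed the inputs' average error — which the pipeline verifies
on every run as an internal consistency check.

Within-subject aggregation curves enumerate all C(8, k) subsets of each
subject's slices exactly, averaging errors over subsets then subjects.
Between-subject curves are Monte Carlo (default 10 000 draws): n *distinct*
subjects per draw — a crowd of n means n different people — one random
slice each. Confidence intervals everywhere are subject-level bootstrap:
virtual experiments redraw subjects with replacement up to the cohort size,
all of a subject's trajectories travelling together; intervals are the
central 95% of 500 replicates. For the between-subject curve the bootstrap
re-runs a reduced-rep Monte Carlo per resample (full-rep bootstrap is
quadratic cost for no statistical gain); it is off by default in the raw
function and enabled where the model fit needs it.

The skill-selection sweep asks how accurately a recruiter must estimate
individual skill before a selected individual beats the crowd: subjects'
true skills (per-subject mean errors) are corrupted with Gaussian noise of
a given level (in SDs of the skill spread), the apparent best is selected,
and the expectation of their true error is estimated by Monte Carlo. The
crossover percentile is the empirical fraction of subjects whose error is
below the crowd's.

## The synthetic cohort generator

The generator produces the statistical structure a tracing crowd exhibits,
each component tied to an observable signature:

| component | model | default | signature |
|---|---|---|---|
| subject bias | K = 3 sinusoidal normal-offset modes per lap, Gaussian amplitudes, uniform phases; zero-mean across subjects | 2.5 mm RMS at age 10.5 | within-subject curves plateau at E\|bias\| = √(2/π)·2.5 ≈ 2.0 mm while between-subject curves keep falling |
| trial noise | stationary Ornstein–Uhlenbeck process in arc length | 1.5 mm, correlation length 20 mm | independent deviations on successive laps; within-subject aggregation averages it down as ~1/√k |
| sensor jitter | isotropic per-sample Gaussian | 0.3 mm | averaged away inside bins |
| age skill | bias and noise scaled by (age/10.5)^−1, ages uniform on 6–18 | — | individual error falls roughly from 4 to 1.9 mm across ages |
| population bias | one shared sinusoidal field per template, realized RMS pinned to the configured value | 1.0 mm | crowd error saturates near 0.8 mm as the crowd grows instead of falling as 1/√n indefinitely |
| outliers | larger bias field (12 mm) plus a constant one-sided 8 mm normal drift | 2% of subjects | inflates mean aggregation but not the median |

The pen moves at constant speed, completing 7–11 laps per 30 s trace
(uniform per trace), sampled at 85 Hz; kinematic realism such as the
speed–curvature power law is deliberately omitted, since binning by nearest
reference point makes aggregation statistics insensitive to time course.
The population field's realized amplitude is pinned (not drawn) because it
is a singleton realization: drawing it would make each simulated cohort's
systematic floor a lottery around the configured value rather than the
configured condition itself. Per-subject fields keep random amplitudes —
across-subject variability of skill is part of what is being modelled.

Outliers deserve a note. Large *zero-mean* deviations, of any amplitude,
barely perturb a 200-subject crowd under either estimator — and
nearest-point binning additionally folds excursions beyond ~10 mm back onto
other parts of the curve, capping their influence. The case in which the
median genuinely protects the crowd is *one-sided* outliers (subjects
tracing a systematically displaced copy of the shape), so outlier subjects
carry a constant normal drift. Even so, on thin or multi-lobed templates
the folding largely neutralises them; the inflation of mean aggregation is
demonstrated on the wide ellipse, where geometry lets the drift through.
That binning acts as an implicit robustifier is itself a finding worth
knowing about the method.

What passing tests on these cohorts shows: the pipeline's accounting,
estimators, resampling and the qualitative crowd signatures (i)–(iv) are
correct under a generative model with the right correlation structure. What
they do not show: that real tracing data match the generator's particular
spectra, age law, or outlier shapes — real bias fields are presumably
neither purely low-frequency nor sinusoidal, real sampling is irregular
with occasional dropouts, and real crowds' systematic floor (the population
bias here) has structure this model only caricatures.

## Numerical choices and problem sizes

Medians are numpy conventions (midpoint of middle pair); nearest-bin ties
break to the lowest index; all Monte-Carlo procedures take explicit seeds
and are bit-reproducible; aggregation is NaN-aware throughout, and a bin is
missing only if missing in every input. Cohort CSVs are written at full
precision and read with round-trip float parsing, so storage is bit-exact.
Enumeration of within-subject subsets and the between-subject Monte Carlo
are vectorised with memory-bounded chunking (a few million array elements
per block).

The test suite and the acceptance script run on scaled problem sizes chosen
to keep statistical margins wide: 200-subject cohorts for the headline
signatures (10 seeds where averaging across seeds is asserted), 60-subject
single-template cohorts for parameter recovery, 150 subjects for the 1/√n
scaling fit (mean aggregation, for which the slope is exactly −1/2; the
median's small-crowd variance inefficiency tilts the fitted slope to about
−0.45), 1 500–2 000 Monte-Carlo draws per curve point, and 200 replicate
cohorts × 500 bootstrap resamples for coverage. Those sizes leave every
asserted margin several standard errors wide.

## Known limitations

* The analytic template shapes are stand-ins; exact replication of a given
  study requires loading its curves via the `custom` template path.
* The within-subject curve is exact but exponential in k; it is intended
  for the 8-slice design (at most 70 subsets per subject), not for large
  slice counts.
* Binning by nearest reference point assigns stray samples near curve
  crossings (lemniscate) or adjacent lobes (roses) to the wrong bin; this
  is inherent to the method, affects individuals and crowd alike, and is
  one reason aggregate errors do not vanish even for careful tracers.
* `bootstrap_ci` re-validates a full cohort per resample; it is meant for
  subject-level statistics, not per-sample ones.
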