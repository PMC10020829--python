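# Methods

This note records the models, estimators, parameter choices and known
limitations behind the package, at the level of detail a maintainer or
reviewer needs to judge what a passing test suite does and does not show.

## Units of analysis

Observations and identifications are day-granular calendar events; project
start/end are naive timestamps assumed local to the event. An observation
belongs to a project-event when its `project_id` matches **and** its date
falls inside the event window (platforms let projects accrue records outside
the event; those are counted separately and reported). Activity metrics use
**all** of a user's observations, not only the focal project's: engagement is
about platform use generally.

## Bioblitz qualification

A project qualifies when it has at least `min_observers` (default 2 — the
strict reading of "more than one observer"), at least `min_identifiers`
(default 1; identifiers who are also observers count), and a duration of at
most `max_duration_hours`. The duration cutoff is genuinely a judgement
call: most bioblitzes run under 72 h but longer events exist, so the default
is 336 h (14 days) with a documented 72 h preset (`STRICT_72H`). Relaxing
any threshold can only grow the qualified set (tested property).

## Weekly devoted days and paired-week differencing

Weekly devoted days = distinct active days in a 7-day block, in [0, 7].
Post-event week *w* ≥ 1 covers days `end + 1 + 7(w−1) … end + 7w`; its
seasonal control is the block exactly **364** days earlier (52 whole weeks,
not 365 — the pairing only cancels weekday effects if the paired blocks
start on the same weekday). The difference series runs over post weeks
1…50, leaving a 2-week guard band before the pairing would wrap into the
event window itself.

Event-window days are excluded from both the difference series and the
prior/posterior activity checks, so the boost estimate cannot absorb
event-day activity and participation is judged purely on in-event records.

Participant categories come from platform-wide activity in the 364 days
before the event start and after the event end: `only_during` (neither),
`lapsed` (prior only), `continuing_new` (posterior only),
`continuing_veteran` (both). Only continuing users enter the difference
panel: the decay model conditions on continuation.

Weeks whose pre- or post-block falls outside the span the log covers are
reported as missing, never as zero — an absence of data is not an absence of
activity.

## The decay model and its estimator

Panel rows (user, project, week *x*, difference *y*) are modelled as
y = a·exp(−b·x) with project-level heterogeneity in the amplitude and a
shared decay rate. The default `two_stage` estimator:

1. **Row weights.** Each user's rows are weighted by the inverse variance
   of that user's own difference series. This matters because roughly half
   of continuing users are new users whose differences carry almost no
   baseline noise, while veterans contribute the same boost signal plus the
   variance of two years of baseline recording. The variance is
   **cross-fitted by week parity** — the weight applied to odd weeks is
   estimated from the even weeks and vice versa — so weights are
   independent of the errors they multiply. (Weights estimated on the same
   rows they scale shrink the amplitude severely: users whose noise
   happened to realize small get upweighted, and their small realizations
   drag the curve down. Measured on the generator at the default design,
   same-sample weights biased the amplitude by roughly −25%; cross-fitting
   removes this.) Variances are floored at 0.02 days² to keep weights
   finite for near-silent users. `weighting="uniform"` disables all of
   this.
2. **Rate fit.** A single (a, b) is fitted to the pooled weighted mean
   curve by least squares; given b the amplitude is linear and is profiled
   out, leaving a one-dimensional problem in b. The profiled objective can
   be multimodal on noisy curves, so a coarse geometric grid over
   b ∈ [1e−5, 5] (80 points) locates the basin and a bounded scalar
   minimization refines it (xatol 1e−12). Fitting one shared b matters:
   per-project exponential fits at a handful of users per project are close
   to unidentifiable, and pooling such fits (however weighted) is strongly
   biased — measured at the default design, a per-project-NLS-then-pool
   estimator overestimated b by ~14% with 2·SE coverage of 25%.
3. **Project effects.** Per-project amplitudes are recovered at the fitted
   rate (linear least squares per project); projects with fewer than
   `min_users_per_project` (default 3) continuing users are merged into a
   single pseudo-project first. Non-positive amplitudes are flagged and
   listed, never silently dropped.
4. **Uncertainty.** Standard errors for (a, b) come from a nonparametric
   bootstrap over projects (B = 200, seeded), which is honest about
   between-project heterogeneity. Calibration, measured over 40 generator
   replicates at the default design: b̂ mean error −0.0001, sd 0.0023,
   mean SE 0.0024, and the generating b inside b̂ ± 2·SE in 40/40
   replicates.

The `pooled` fallback is a plain nonlinear least squares of all user-week
rows on a·exp(−b·x) (SciPy `curve_fit`, jittered restarts on
non-convergence); on a single-project panel it coincides with the uniform-
weight two-stage fit. Its reported SEs assume independent rows and should
not be trusted for clustered panels.

Degenerate inputs: an all-zero panel yields a declared-degenerate fit with
a = 0 and undefined b (no silent numbers); an empty panel is an error.
`n_points` counts user-week rows — the natural sample size for this design.

With the default weighting, the population amplitude is a precision-
weighted mean across users and projects; under amplitude heterogeneity it
sits slightly below the arithmetic mean of project amplitudes (a few
percent at the default heterogeneity). The decay rate is unaffected. The
parity-alternating weights also mean a noiseless *heterogeneous* panel is
recovered only to ~0.5% (a mixture of unequal amplitudes with alternating
weights is no longer an exact exponential); noiseless homogeneous panels
are recovered exactly.

Derived quantities: half-life = ln 2 / b; cumulative boost = a/b
(infinite horizon) or a/b·(1 − exp(−b·W)) for a finite horizon of W weeks.
Both require b > 0. Report-layer rounding is one decimal for half-life and
cumulative boost, three decimals for the decay constant.

## Platform extrapolation

additional observations = participants × continuing fraction × cumulative
extra days × observations per extra day; the share divides by the total
observations recorded during the events. With one observation per extra
day, 113,076 participants, a 21.5% continuing rate and 7.4 cumulative days,
this gives ≈179,900 additional observations, ~10% of a 1,851,444-record
corpus. The operation reports the computed product; no attempt is made to
reverse-engineer unrounded inputs from published roundings.

## Observer–identifier network

One node per user, role `observer` / `identifier` / `both`; one edge per
(observer, identifier) pair weighted by the identifications the identifier
made on that observer's event records. Self-identifications count by
default (they are what creates `both` nodes); a flag excludes them for
analyses of purely external engagement. Identifications that do not resolve
to an event record are excluded and reported. Node "size" (identifications
made) counts event records only, not the identifier's platform-wide
activity. Total edge weight always equals the retained identification count
(tested conservation property).

## Aim ratings

Long-format scores (item × rater × five aims, integers 1–5). Aims may be
scored independently; a strict validator enforces a 1–5 permutation per
item where a forced ranking is wanted. For items scored by several raters
the first-listed rater is tallied (double scoring exists to measure
agreement, not to average). Agreement between two raters is the Jaccard
coefficient over (item, aim, score) triples, restricted to the items both
raters scored — differing item coverage is a workload fact, not a
disagreement; raters sharing no items are an error.

## The synthetic generator

`bioblitz.synthdata.generate` emulates the statistical structure the
engagement analysis assumes, with every generating quantity recorded in a
truth table:

* **Design defaults** (the study conditions): 100 projects, ~34
  participants each (Poisson), category mix (0.77, 0.015, 0.116, 0.099) —
  the published 21.5% continuing share split between new and veteran users
  in proportion to the two reported panel sizes (20,950 of 38,850
  user-weeks ⇒ 53.9% new); boost a = 0.4 days/week (the cumulative 7.4
  days × b), b = 0.054 per week.
* **Heterogeneity**: per-project lognormal multiplier on the boost
  amplitude (σ = 0.3, median 1).
* **Baseline activity**: veterans and lapsed users draw a Gamma(2) baseline
  with mean 0.5 devoted days/week — a deliberately modest "hobbyist"
  level — modulated by a sinusoidal season (amplitude 0.3, spring peak)
  computed on the 52-week cycle aligned with the 364-day pairing lag, so a
  week and its control share the factor exactly and the expected difference
  is the boost alone.
* **Realization**: weekly devoted days are Binomial(7, μ/7) with
  μ = clamp(baseline·season + m_p·a·exp(−b·t), 0, 7); active-day
  identities are uniform within the week; observations per active day are
  1 + Poisson(0.3). Event participation is 1+ records on random event
  days. Identifications on event records come at Poisson(0.8) per record
  from a long-tailed pool of 40 external identifiers mixed (30%) with the
  participants themselves, which yields self-identifications and `both`
  roles naturally.
* **Timing**: starts roll to a Saturday with probability 0.6 and months
  are weighted toward April and September, mirroring typical event timing.

Everything derives from one `numpy` Generator, so identical parameters give
byte-identical CSV output.

What the generator does **not** emulate — and hence what passing tests do
not show about real exports: taxon-abundance realism beyond a long-tailed
label draw, spatial structure beyond jitter around a site, users attending
several events, within-user activity trends other than season + boost,
weekday structure inside a week, or identification timing dynamics. Decay
recovery results on the generator validate the estimator under the model's
own assumptions; they cannot certify the exponential form against real
behaviour.

## Problem sizes in the test and acceptance suites

The suites favour the smallest designs that still exercise each claim: the
study-scale design (100 projects) for single-fit recovery and the 20-seed
calibration; 440 projects (≥3,000 continuing users) for the large-design
coverage property; ~59 projects (≈2,000 participants) for the category-mix
recovery of the full pipeline; and 5–6 project corpora for everything
structural.
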