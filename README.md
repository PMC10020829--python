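# bioblitz

Analytics for **bioblitz** event logs — the rapid, place-based biodiversity
surveys run on recording platforms such as iNaturalist, where volunteers and
experts record as many species as possible in a short window (usually a
weekend or a single day).

The package is aimed at citizen-science researchers and event organizers who
have observation/identification exports and want to answer, quantitatively:

* Which candidate projects actually *are* bioblitzes (short-term, one place,
  more than one observer, at least one identifier), and what did each yield?
* Does taking part change how often participants record wildlife afterwards,
  and for how long does that boost last?
* How far beyond the physical attendees does an event reach through the
  online community identifying its records?
* When several raters score event reports on their aims, how well do they
  agree?

## The engagement-boost model

For each event participant, activity is measured as **weekly devoted days**:
the number of distinct days per 7-day block with at least one observation
(0–7). To cancel seasonal and weekday effects, post-event week *t* is
compared with the weekday-aligned week exactly 364 days earlier, giving the
paired difference *y* ∈ [−7, 7]. Over the 50 weeks after the event the mean
difference of continuing participants follows an exponential decay

  y = a · exp(−b·x),

with *a* the initial boost (devoted days/week), *b* the decay constant
(per week), *x* the weeks since the event. Derived quantities:

* half-life of the boost: ln 2 / b (weeks),
* cumulative extra recording days per continuing participant: a / b,
* platform-scale extrapolation: participants × continuing share ×
  cumulative days × observations per extra day.

Projects differ in boost strength, so the default estimator fits a shared
*b* with project-specific amplitudes and bootstraps projects for the
standard errors (see `docs/methods.md`).

Everything is exercised end to end on a seeded synthetic event-log
generator (`bioblitz.synthdata`) whose defaults encode the study design the
analysis targets: 100 projects of ~34 participants, a 77% / 1.5% / 21.5%
only-during / lapsed / continuing mix, and a boost of a = 0.4 days/week
decaying at b = 0.054 per week.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
corpus and write their tables under `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/02_qualify_summarize.py
python analysis/03_engagement.py
python analysis/04_fit_decay.py
python analysis/05_network.py
python analysis/06_ratings.py
```

Output of a full run (seed 42):

```
seed 42: wrote 35926 observations, 5369 identifications, 100 projects, 3423 participants -> results/analysis/data
100/100 candidate projects qualify as bioblitzes
mean per event: 67 observations of 24 taxa by 34 observers, 30 identifiers
most common start weekday: Saturday (69/100 events)
3423 participants: 77.6% only during, 2.0% lapsed, 20.5% continuing
difference panel: 35050 user-weeks from 701 continuing users; mean first-week difference +0.36 days
decay constant b = 0.051 (SE 0.002), n = 35050 user-weeks
initial boost a = 0.36 devoted days/week (SE 0.02)
half-life = 13.5 weeks; cumulative boost = 7.0 days per continuing participant
event P0045: 102 records, 72 users in the network (31 observer-only, 21 identifier-only, 20 both)
inter-rater Jaccard agreement: 0.62 (fraction of identical scoring decisions)
```

Reading this: the recovered decay constant 0.051 sits within sampling error
of the generating 0.054 (half-life 13.5 vs 12.8 weeks), the participant mix
matches the generator's 77 / 1.5 / 21.5 split up to binomial noise, and the
busiest event's identification network reaches 21 people who never attended.

The same stages are available as a CLI (`bioblitz simulate|qualify|summarize|
engagement|fit-decay|network|ratings|run-all`) for user-supplied CSV exports;
column names are mapped via a YAML config (see `bioblitz.eventlog.ColumnMap`).

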