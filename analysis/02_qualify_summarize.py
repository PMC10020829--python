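#!/usr/bin/env python
"""Qualify candidate projects against the bioblitz definition and summarize.

A bioblitz is a short-term event from a specific place with more than one
observer and at least one identifier.  This script applies that filter to the
simulated corpus, then reports the per-project headline numbers
(observations, taxa, observers, identifiers), the weekday/month timing
distributions, and the most frequent words in the project descriptions.

Run analysis/01_simulate.py first.
"""

from pathlib import Path

from bioblitz import eventlog, projects

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main() -> None:
    obs = eventlog.read_observations(DATA / "observations.csv").table
    ids = eventlog.read_identifications(DATA / "identifications.csv").table
    projs = eventlog.read_projects(DATA / "projects.csv").table

    qual = projects.qualify_all(projs, obs, ids)
    qual.to_csv(OUT / "qualification.csv", index=False)
    n_ok = int(qual["qualifies"].sum())
    print(f"{n_ok}/{len(qual)} candidate projects qualify as bioblitzes")

    qualified = projs[projs["project_id"].isin(qual.loc[qual["qualifies"], "project_id"])]
    summaries = projects.summarize_all(qualified, obs, ids)
    summaries.to_csv(OUT / "project_summaries.csv", index=False)
    print("mean per event: "
          f"{summaries['n_observations'].mean():.0f} observations of "
          f"{summaries['n_taxa'].mean():.0f} taxa by "
          f"{summaries['n_observers'].mean():.0f} observers, "
          f"{summaries['n_identifiers'].mean():.0f} identifiers")

    weekday, month = projects.timing_histograms(qualified)
    weekday.rename_axis("weekday").reset_index().to_csv(OUT / "timing_weekday.csv", index=False)
    month.rename_axis("month").reset_index().to_csv(OUT / "timing_month.csv", index=False)
    print(f"most common start weekday: {weekday.idxmax()} "
          f"({weekday.max()}/{weekday.sum()} events)")

    words = projects.word_frequencies(list(qualified["description"].dropna()))
    words.rename_axis("word").reset_index().to_csv(OUT / "word_frequencies.csv", index=False)
    print("top description words:", ", ".join(words.head(5).index))


if __name__ == "__main__":
    main()
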