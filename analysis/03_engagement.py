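#!/usr/bin/env python
"""Classify participants and build the paired-week difference panel.

For every event participant, platform-wide activity in the 364 days before
and after the event decides their category (only-during / lapsed /
continuing).  For continuing users, weekly devoted days in the 50 post-event
weeks are differenced against the weekday-aligned weeks one year earlier —
the seasonality-controlled response the decay model is fitted to.

Run analysis/01_simulate.py first.
"""

from pathlib import Path

from bioblitz import engagement, eventlog

DATA = Path("results/analysis/data")
OUT = Path("results/analysis")


def main() -> None:
    obs = eventlog.read_observations(DATA / "observations.csv").table
    projs = eventlog.read_projects(DATA / "projects.csv").table

    panel, cats = engagement.difference_panel(obs, projs)
    cats.to_csv(OUT / "participant_categories.csv", index=False)
    panel.to_csv(OUT / "difference_panel.csv", index=False)

    frac = cats["category"].value_counts(normalize=True)
    print(f"{cats['user_id'].nunique()} participants: "
          f"{frac.get('only_during', 0):.1%} only during, "
          f"{frac.get('lapsed', 0):.1%} lapsed, "
          f"{frac.get('continuing_new', 0) + frac.get('continuing_veteran', 0):.1%} "
          "continuing")
    print(f"difference panel: {len(panel)} user-weeks from "
          f"{panel['user_id'].nunique()} continuing users; "
          f"mean first-week difference "
          f"{panel.loc[panel['week_after'] == 1, 'diff'].mean():+.2f} days")


if __name__ == "__main__":
    main()
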