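#!/usr/bin/env python
"""Fit the exponential decay model and derive half-life, cumulative boost
and the platform-scale extrapolation.

The panel rows follow y = a*exp(-b*x) with x the weeks since the event.
The two-stage fit reports the population (a, b) with project-bootstrap
standard errors; ln(2)/b gives the boost's half-life and a/b the cumulative
extra recording days per continuing participant.

Run analysis/03_engagement.py first.
"""

import json
from pathlib import Path

import pandas as pd

from bioblitz import decay

OUT = Path("results/analysis")
SEED = 42


def main() -> None:
    panel = pd.read_csv(OUT / "difference_panel.csv")
    cats = pd.read_csv(OUT / "participant_categories.csv")

    fit = decay.fit_decay(panel, method="two_stage", seed=SEED)
    half = decay.half_life(fit.b_hat)
    cumulative = decay.cumulative_boost(fit.a_hat, fit.b_hat)
    print(f"decay constant b = {fit.b_hat:.3f} (SE {fit.se_b:.3f}), "
          f"n = {fit.n_points} user-weeks")
    print(f"initial boost a = {fit.a_hat:.2f} devoted days/week (SE {fit.se_a:.2f})")
    print(f"half-life = {half:.1f} weeks; cumulative boost = {cumulative:.1f} days "
          "per continuing participant")

    continuing = cats["category"].str.startswith("continuing").mean()
    n_participants = cats["user_id"].nunique()
    summaries = pd.read_csv(OUT / "project_summaries.csv")
    total_obs = int(summaries["n_observations"].sum())
    extra, share = decay.extrapolate(decay.ExtrapolationInput(
        n_participants=n_participants, continuation_rate=continuing,
        cumulative_days=cumulative, obs_per_day=1.0,
        total_observations=total_obs))
    print(f"at one observation per extra day, the {n_participants} participants "
          f"({continuing:.1%} continuing) would add ~{extra:.0f} observations "
          f"({share:.0%} of the {total_obs} made during the events)")

    report = {
        "a": fit.a_hat, "b": fit.b_hat, "se_a": fit.se_a, "se_b": fit.se_b,
        "n_points": fit.n_points, "half_life_weeks": round(half, 1),
        "cumulative_boost_days": round(cumulative, 1),
        "extrapolated_additional_observations": round(extra, 1),
        "extrapolated_share_of_event_total": round(share, 3),
    }
    with open(OUT / "decay_fit.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    if not fit.project_effects.empty:
        fit.project_effects.to_csv(OUT / "project_effects.csv", index=False)


if __name__ == "__main__":
    main()
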