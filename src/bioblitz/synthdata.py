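"""Seeded synthetic bioblitz corpora for end-to-end pipeline testing.

The generator emulates the statistical structure the engagement analysis
assumes, so every pipeline stage can be exercised (and its estimators
validated against known truth) without platform downloads:

* projects with realistic timing (weekend-heavy starts, spring/autumn peaks)
  and a per-project multiplier on the boost (between-project heterogeneity);
* a participant mix of only-during / lapsed / continuing users;
* per-user seasonal baseline recording activity, identical in expectation in
  the pre- and post-event year so it cancels in the paired-week differences;
* an event-triggered boost to weekly devoted days that decays exponentially,
  applied to continuing users only (the decay estimate conditions on
  continuation, so the generator mirrors that conditioning);
* identifications on event records from a pool of external identifiers plus
  the participants themselves.

Weekly devoted days are drawn as Binomial(7, mu/7) per week with
``mu = clamp(baseline*season + m_p*a*exp(-b t), 0, 7)``; day identities
within a week are assigned uniformly.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ratings import AIMS

__all__ = ["SynthParams", "SynthTables", "generate", "generate_ratings"]


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    The defaults are the study conditions of the engagement analysis this
    package reproduces: 100 projects of ~34 participants, category mix
    (77% only-during, 1.5% lapsed, 21.5% continuing — split 11.6% new /
    9.9% veteran in proportion to the reported panel sizes), boost
    a = 0.4 days/week decaying at b = 0.054 per week.
    """

    seed: int = 0
    n_projects: int = 100
    users_per_project: float = 34.0
    #: fractions (only_during, lapsed, continuing_new, continuing_veteran)
    category_mix: tuple[float, float, float, float] = (0.77, 0.015, 0.116, 0.099)
    #: mean weekly devoted days of veteran users' baseline activity
    baseline_rate: float = 0.5
    seasonal_amplitude: float = 0.3
    boost_a: float = 0.4
    boost_b: float = 0.054
    #: sd of log per-project multiplier on the boost amplitude (median 1)
    project_sd: float = 0.3
    event_duration_hours: float = 24.0
    obs_per_devoted_day: float = 1.3
    n_external_identifiers: int = 40
    #: mean identifications per event record
    id_rate: float = 0.8
    saturday_start_prob: float = 0.6
    horizon_weeks: int = 52
    start_years: tuple[int, int] = (2017, 2019)

    def __post_init__(self) -> None:
        mix = np.asarray(self.category_mix, dtype=float)
        if mix.size != 4 or (mix < 0).any():
            raise ValueError("category_mix must be 4 non-negative fractions")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if not self.boost_b > 0:
            raise ValueError("boost_b must be positive")
        for name in ("baseline_rate", "boost_a", "obs_per_devoted_day", "id_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SynthTables:
    """Generated corpus: the three canonical event-log tables plus the truth
    table recording every per-user generating quantity."""

    projects: pd.DataFrame
    observations: pd.DataFrame
    identifications: pd.DataFrame
    truth: pd.DataFrame
    params: SynthParams


_CATEGORY_NAMES = ("only_during", "lapsed", "continuing_new", "continuing_veteran")

# small pool of plausible taxon labels; sampling weights are long-tailed so
# distinct-taxon counts behave like real species-abundance data
_TAXA = [
    "Turdus merula", "Parus major", "Apis mellifera", "Pieris rapae",
    "Quercus robur", "Bellis perennis", "Vanessa atalanta", "Erithacus rubecula",
    "Taraxacum officinale", "Coccinella septempunctata", "Columba palumbus",
    "Urtica dioica", "Bombus terrestris", "Fringilla coelebs", "Hedera helix",
    "Pica pica", "Plantago lanceolata", "Sylvia atricapilla", "Achillea millefolium",
    "Aglais io", "Corvus corone", "Ranunculus repens", "Sturnus vulgaris",
    "Trifolium repens", "Lumbricus terrestris", "Passer domesticus",
    "Geranium robertianum", "Larus argentatus", "Rubus fruticosus",
    "Helix pomatia", "Anas platyrhynchos", "Crataegus monogyna",
    "Motacilla alba", "Papaver rhoeas", "Troglodytes troglodytes",
    "Cirsium arvense", "Ardea cinerea", "Lamium purpureum",
    "Phylloscopus collybita", "Silene dioica",
]

_MONTH_WEIGHTS = np.array([1, 1, 1, 2, 1, 1, 1, 1, 2, 1, 1, 1], dtype=float)


def _season_factor(week_day_start: np.ndarray, amplitude: float,
                   phase_weeks: float = 3.0) -> np.ndarray:
    """Seasonal multiplier for the weeks starting on the given day numbers.

    Uses the 52-week cycle aligned with the 364-day pairing lag, so a week
    and its seasonal control get an identical factor; peaks in spring.
    """
    woy = (week_day_start // 7) % 52
    return 1.0 + amplitude * np.sin(2.0 * math.pi * (woy - phase_weeks) / 52.0)


def _project_start(rng: np.random.Generator, params: SynthParams) -> pd.Timestamp:
    year = int(rng.integers(params.start_years[0], params.start_years[1] + 1))
    month = int(rng.choice(12, p=_MONTH_WEIGHTS / _MONTH_WEIGHTS.sum())) + 1
    day = int(rng.integers(1, 29))
    ts = pd.Timestamp(year=year, month=month, day=day, hour=9)
    if rng.random() < params.saturday_start_prob:
        ts += pd.Timedelta(days=(5 - ts.dayofweek) % 7)  # roll to next Saturday
    return ts


def _draw_week_days(rng: np.random.Generator, mu: np.ndarray,
                    block_starts: np.ndarray) -> np.ndarray:
    """Realize distinct active day numbers from weekly expectations."""
    counts = rng.binomial(7, np.clip(mu, 0.0, 7.0) / 7.0)
    out = []
    for k, start in zip(counts, block_starts):
        if k:
            out.append(start + rng.choice(7, size=k, replace=False))
    return np.concatenate(out) if out else np.array([], dtype=np.int64)


_EPOCH = np.datetime64("1970-01-01", "D")


def _to_dates(day_ints: np.ndarray) -> np.ndarray:
    return _EPOCH + day_ints.astype("timedelta64[D]")


def generate(params: SynthParams | None = None, **overrides) -> SynthTables:
    """Generate a synthetic bioblitz corpus.

    Keyword overrides are applied on top of ``params`` (or the defaults), so
    ``generate(seed=7, n_projects=20)`` works directly.
    """
    params = replace(params or SynthParams(), **overrides) if overrides else (params or SynthParams())
    rng = np.random.default_rng(params.seed)

    taxa_w = 1.0 / np.arange(1, len(_TAXA) + 1)
    taxa_w /= taxa_w.sum()
    mix = np.asarray(params.category_mix, dtype=float)
    mix = mix / mix.sum()
    ext_ids = [f"X{i:03d}" for i in range(1, params.n_external_identifiers + 1)]
    ext_w = 1.0 / np.arange(1, len(ext_ids) + 1)
    ext_w /= ext_w.sum()
    extra_obs = max(params.obs_per_devoted_day - 1.0, 0.0)

    proj_rows, truth_rows = [], []
    obs_cols: dict[str, list] = {k: [] for k in
                                 ("observation_id", "observer_id", "day", "project_id",
                                  "taxon", "latitude", "longitude")}
    id_rows: dict[str, list] = {k: [] for k in
                                ("identification_id", "observation_id", "identifier_id", "day")}
    obs_counter = id_counter = user_counter = 0
    weeks = np.arange(1, params.horizon_weeks + 1)

    for p in range(1, params.n_projects + 1):
        pid = f"P{p:04d}"
        start_ts = _project_start(rng, params)
        end_ts = start_ts + pd.Timedelta(hours=params.event_duration_hours)
        start_day = (start_ts.to_datetime64().astype("datetime64[D]") - _EPOCH).astype(int)
        end_day = (end_ts.to_datetime64().astype("datetime64[D]") - _EPOCH).astype(int)
        n_event_days = end_day - start_day + 1
        m_p = float(rng.lognormal(0.0, params.project_sd))
        lat = float(rng.uniform(-55.0, 65.0))
        lon = float(rng.uniform(-175.0, 175.0))
        n_users = max(2, int(rng.poisson(params.users_per_project)))
        proj_rows.append({
            "project_id": pid, "title": f"BioBlitz {pid}",
            "start": start_ts, "end": end_ts,
            "description": f"A 24-hour bioblitz survey of site {pid}: observing "
                           "wildlife, engaging volunteers, building a species inventory.",
            "place_label": f"Site {pid}",
        })

        post_block_starts = end_day + 1 + 7 * (weeks - 1)
        pre_block_starts = post_block_starts - 364
        season = _season_factor(post_block_starts, params.seasonal_amplitude)
        boost_mu = m_p * params.boost_a * np.exp(-params.boost_b * weeks)

        participants: list[str] = []
        proj_obs_start = obs_counter
        for _ in range(n_users):
            user_counter += 1
            uid = f"U{user_counter:05d}"
            participants.append(uid)
            cat_idx = int(rng.choice(4, p=mix))
            category = _CATEGORY_NAMES[cat_idx]
            has_baseline = category in ("lapsed", "continuing_veteran")
            continuing = category in ("continuing_new", "continuing_veteran")
            baseline = float(rng.gamma(2.0, params.baseline_rate / 2.0)) if has_baseline else 0.0

            # event-window records (participation)
            k = 1 + int(rng.binomial(n_event_days - 1, 0.5)) if n_event_days > 1 else 1
            ev_days = start_day + rng.choice(n_event_days, size=k, replace=False)
            user_days = [(ev_days, True)]

            pre_mu = baseline * season if has_baseline else np.zeros_like(season)
            post_mu = pre_mu.copy() if category == "continuing_veteran" else np.zeros_like(season)
            if category == "lapsed":
                post_mu = np.zeros_like(season)
            if continuing:
                post_mu = post_mu + boost_mu
            if pre_mu.any():
                d = _draw_week_days(rng, pre_mu, pre_block_starts)
                d = d[(d < start_day) | (d > end_day)]  # event window stays event-only
                user_days.append((d, False))
            if post_mu.any():
                user_days.append((_draw_week_days(rng, post_mu, post_block_starts), False))

            for day_arr, in_event in user_days:
                for day in np.sort(day_arr):
                    n_obs = 1 + int(rng.poisson(extra_obs))
                    for _ in range(n_obs):
                        obs_counter += 1
                        obs_cols["observation_id"].append(f"O{obs_counter:07d}")
                        obs_cols["observer_id"].append(uid)
                        obs_cols["day"].append(int(day))
                        obs_cols["project_id"].append(pid if in_event else pd.NA)
                        obs_cols["taxon"].append(_TAXA[int(rng.choice(len(_TAXA), p=taxa_w))])
                        obs_cols["latitude"].append(round(lat + float(rng.normal(0, 0.05)), 5))
                        obs_cols["longitude"].append(round(lon + float(rng.normal(0, 0.05)), 5))

            truth_rows.append({
                "user_id": uid, "project_id": pid, "category": category,
                "baseline_rate": baseline, "project_multiplier": m_p,
                "boost_a": m_p * params.boost_a if continuing else 0.0,
                "boost_b": params.boost_b if continuing else float("nan"),
            })

        # identifications on this event's records
        for i in range(proj_obs_start, obs_counter):
            oid = obs_cols["observation_id"][i]
            day = obs_cols["day"][i]
            proj = obs_cols["project_id"][i]
            if proj is pd.NA or proj != pid:
                continue
            for _ in range(int(rng.poisson(params.id_rate))):
                id_counter += 1
                if rng.random() < 0.3 and participants:
                    identifier = participants[int(rng.integers(len(participants)))]
                else:
                    identifier = ext_ids[int(rng.choice(len(ext_ids), p=ext_w))]
                id_rows["identification_id"].append(f"I{id_counter:07d}")
                id_rows["observation_id"].append(oid)
                id_rows["identifier_id"].append(identifier)
                id_rows["day"].append(day + int(rng.integers(0, 10)))

    projects = pd.DataFrame(proj_rows)
    projects["duration_hours"] = (projects["end"] - projects["start"]).dt.total_seconds() / 3600.0
    observations = pd.DataFrame({
        "observation_id": obs_cols["observation_id"],
        "observer_id": obs_cols["observer_id"],
        "observed_date": pd.to_datetime(_to_dates(np.array(obs_cols["day"], dtype=np.int64))),
        "project_id": obs_cols["project_id"],
        "taxon": obs_cols["taxon"],
        "latitude": obs_cols["latitude"],
        "longitude": obs_cols["longitude"],
    })
    identifications = pd.DataFrame({
        "identification_id": id_rows["identification_id"],
        "observation_id": id_rows["observation_id"],
        "identifier_id": id_rows["identifier_id"],
        "identified_date": pd.to_datetime(_to_dates(np.array(id_rows["day"], dtype=np.int64))),
    })
    truth = pd.DataFrame(truth_rows)
    return SynthTables(projects, observations, identifications, truth, params)


def generate_ratings(seed: int, n_items: int = 59, n_raters: int = 2,
                     disagreement_rate: float = 0.2) -> pd.DataFrame:
    """Synthetic multi-rater aim scores in long format.

    Rater 1 scores each (item, aim) uniformly in 1..5; every other rater
    copies those scores but, independently per cell with probability
    ``disagreement_rate``, replaces the score with a uniformly chosen
    *different* one — so the rate is the exact per-cell disagreement
    probability.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if not 0.0 <= disagreement_rate <= 1.0:
        raise ValueError("disagreement_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.integers(1, 6, size=(n_items, len(AIMS)))
    rows = []
    items = [f"R{i:03d}" for i in range(1, n_items + 1)]
    for r in range(1, n_raters + 1):
        if r == 1:
            scores = base
        else:
            flip = rng.random(base.shape) < disagreement_rate
            shift = rng.integers(1, 5, size=base.shape)  # 1..4 steps away
            scores = np.where(flip, (base - 1 + shift) % 5 + 1, base)
        for i, item in enumerate(items):
            for j, aim in enumerate(AIMS):
                rows.append((item, f"rater_{r}", aim, int(scores[i, j])))
    return pd.DataFrame(rows, columns=["item_id", "rater_id", "aim", "score"])
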