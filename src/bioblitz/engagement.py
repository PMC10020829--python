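"""Participant-level engagement metrics around a bioblitz event.

The engagement analysis asks whether taking part in a bioblitz changes how
often a person records wildlife afterwards.  Activity is measured as *weekly
devoted days*: the number of distinct calendar days in a 7-day block on which
the user made at least one observation (0–7).  To cancel seasonal and weekday
effects, post-event week ``t`` is compared against the weekday-aligned week
exactly 364 days (52 whole weeks) earlier — the paired-week difference
``diff_t = devoted_days(week t) − devoted_days(week −t)`` is the response the
decay model is fitted to.

Week blocks are anchored on the event end date: week ``w ≥ 1`` covers days
``anchor + 1 + 7(w−1) … anchor + 7w``; week ``−w`` covers the same block 364
days earlier.  Days inside the event window itself are excluded so the boost
estimate does not absorb event-day activity.

Participants are classified relative to the event from their platform-wide
records: ``only_during`` (no activity outside the event window within a year
either side), ``lapsed`` (prior but no posterior activity), ``continuing_new``
(posterior only) and ``continuing_veteran`` (both).  Only continuing users
enter the difference panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "PAIRING_DAYS",
    "ParticipationError",
    "weekly_devoted_days",
    "categorize",
    "paired_differences",
    "difference_panel",
]

#: lag between a post-event week and its seasonal control (52 whole weeks,
#: so the paired weeks start on the same weekday)
PAIRING_DAYS = 364

CATEGORIES = ("only_during", "lapsed", "continuing_new", "continuing_veteran")


class ParticipationError(ValueError):
    """Raised when a user has no observation inside the event window."""


_EPOCH = np.datetime64("1970-01-01")


def _day_ints(dates) -> np.ndarray:
    """Distinct calendar days as sorted integer day numbers."""
    arr = pd.to_datetime(pd.Series(dates)).dt.normalize().to_numpy()
    if arr.size == 0:
        return np.array([], dtype=np.int64)
    days = (arr.astype("datetime64[D]") - _EPOCH.astype("datetime64[D]")).astype(np.int64)
    return np.unique(days)


def _day_int(date) -> int:
    ts = pd.Timestamp(date).normalize()
    return int((ts.to_datetime64().astype("datetime64[D]")
                - _EPOCH.astype("datetime64[D]")).astype(np.int64))


def _block_counts(days: np.ndarray, anchor: int, horizon: int, shift: int) -> np.ndarray:
    """devoted-days count for weeks 1..horizon of blocks starting at
    ``anchor + 1 + shift`` (shift = 0 for post, −364 for the paired year)."""
    offset = days - anchor - shift
    sel = (offset >= 1) & (offset <= 7 * horizon)
    weeks = (offset[sel] - 1) // 7  # 0-based
    return np.bincount(weeks, minlength=horizon).astype(np.int64)[:horizon]


def weekly_devoted_days(events, anchor, horizon_weeks: int = 52) -> pd.DataFrame:
    """Per-week devoted days for one user around an anchor date.

    Parameters
    ----------
    events
        Dated observations of a single user (any datetime-like sequence);
        duplicated days count once.
    anchor
        The event end date; week 1 starts the day after it.
    horizon_weeks
        Number of weeks on each side.

    Returns
    -------
    DataFrame with ``week_index`` in ``−horizon…−1, 1…horizon`` and
    ``devoted_days`` in [0, 7].  A user with no events gets all zeros.
    """
    days = _day_ints(events)
    a = _day_int(anchor)
    post = _block_counts(days, a, horizon_weeks, 0)
    pre = _block_counts(days, a, horizon_weeks, -PAIRING_DAYS)
    idx = np.concatenate([-np.arange(horizon_weeks, 0, -1), np.arange(1, horizon_weeks + 1)])
    vals = np.concatenate([pre[::-1], post])
    return pd.DataFrame({"week_index": idx, "devoted_days": vals})


def _windows(project: pd.Series) -> tuple[int, int]:
    start = _day_int(project["start"])
    end = _day_int(project["end"])
    if end < start:
        raise ValueError("project end precedes start")
    return start, end


def categorize(events, project: pd.Series) -> str:
    """Classify an event participant from their platform-wide activity.

    Prior activity = any observation within 364 days before the event start;
    posterior = any within 364 days after the event end; event days are
    excluded from both.  Raises :class:`ParticipationError` if the user has
    no observation inside the event window.
    """
    days = _day_ints(events)
    start, end = _windows(project)
    if not ((days >= start) & (days <= end)).any():
        raise ParticipationError("user has no observation inside the event window")
    prior = bool(((days >= start - PAIRING_DAYS) & (days < start)).any())
    post = bool(((days > end) & (days <= end + PAIRING_DAYS)).any())
    if prior and post:
        return "continuing_veteran"
    if prior:
        return "lapsed"
    if post:
        return "continuing_new"
    return "only_during"


def paired_differences(events, project: pd.Series, horizon_weeks: int = 50,
                       log_start=None, log_end=None) -> pd.DataFrame:
    """Seasonality-paired weekly differences for one continuing user.

    For ``t = 1…horizon_weeks``: ``diff = devoted_days(week t) −
    devoted_days(week −t)`` with week −t the weekday-aligned block 364 days
    earlier.  Event-window days are excluded from both series.

    ``log_start`` / ``log_end`` bound the calendar span actually covered by
    the input log; weeks whose pre or post block falls partly outside the
    span are *missing* (omitted), not zero.
    """
    start, end = _windows(project)
    days = _day_ints(events)
    days = days[(days < start) | (days > end)]

    post = _block_counts(days, end, horizon_weeks, 0)
    pre = _block_counts(days, end, horizon_weeks, -PAIRING_DAYS)
    t = np.arange(1, horizon_weeks + 1)

    ok = np.ones(horizon_weeks, dtype=bool)
    if log_start is not None:
        pre_block_start = end + 1 + 7 * (t - 1) - PAIRING_DAYS
        ok &= pre_block_start >= _day_int(log_start)
    if log_end is not None:
        post_block_end = end + 7 * t
        ok &= post_block_end <= _day_int(log_end)

    return pd.DataFrame({"week_after": t[ok], "diff": (post - pre)[ok]})


def difference_panel(obs: pd.DataFrame, projects: pd.DataFrame,
                     horizon_weeks: int = 50,
                     categories: tuple[str, ...] = ("continuing_new", "continuing_veteran"),
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the event-study panel for a corpus of projects.

    For every project, event participants (users with an in-window record
    carrying the project id) are classified with :func:`categorize` over
    their platform-wide observations, and those in ``categories`` contribute
    one :class:`~bioblitz.engagement` difference series each.

    Returns
    -------
    (panel, participant_categories)
        ``panel``: user_id, project_id, week_after, diff — the decay model's
        (x, y) rows.  ``participant_categories``: user_id, project_id,
        category for every participant.
    """
    dates_all = pd.to_datetime(obs["observed_date"]).dt.normalize().to_numpy()
    day_all = (dates_all.astype("datetime64[D]")
               - _EPOCH.astype("datetime64[D]")).astype(np.int64)
    by_user: dict[str, np.ndarray] = {
        u: np.unique(day_all[idx])
        for u, idx in obs.groupby("observer_id", sort=False).indices.items()
    }

    cat_rows: list[tuple[str, str, str]] = []
    panel_parts: list[pd.DataFrame] = []
    for _, project in projects.iterrows():
        start, end = _windows(project)
        if "project_id" in obs.columns:
            mask = (obs["project_id"] == project["project_id"]).to_numpy()
        else:
            mask = np.ones(len(obs), dtype=bool)
        in_win = mask & (day_all >= start) & (day_all <= end)
        participants = pd.unique(obs.loc[in_win, "observer_id"])

        for user in participants:
            days = by_user[user]
            prior = bool(((days >= start - PAIRING_DAYS) & (days < start)).any())
            post = bool(((days > end) & (days <= end + PAIRING_DAYS)).any())
            cat = ("continuing_veteran" if prior and post else
                   "lapsed" if prior else
                   "continuing_new" if post else "only_during")
            cat_rows.append((user, str(project["project_id"]), cat))
            if cat not in categories:
                continue
            out = days[(days < start) | (days > end)]
            post_c = _block_counts(out, end, horizon_weeks, 0)
            pre_c = _block_counts(out, end, horizon_weeks, -PAIRING_DAYS)
            panel_parts.append(pd.DataFrame({
                "user_id": user,
                "project_id": str(project["project_id"]),
                "week_after": np.arange(1, horizon_weeks + 1),
                "diff": post_c - pre_c,
            }))

    cats = pd.DataFrame(cat_rows, columns=["user_id", "project_id", "category"])
    panel = (pd.concat(panel_parts, ignore_index=True) if panel_parts
             else pd.DataFrame(columns=["user_id", "project_id", "week_after", "diff"]))
    return panel, cats
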