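"""Bioblitz qualification and per-project / corpus-level summaries.

A *bioblitz* is a short-term biodiversity survey of a specific place with more
than one observer and at least one identifier.  :func:`qualify` applies that
definition (thresholds configurable via :class:`QualificationCriteria`) to a
candidate project; :func:`summarize_project` computes the headline numbers
(observations, distinct taxa, observers, identifiers, duration, timing).

An observation belongs to a project-event when its ``project_id`` matches AND
its date falls inside the event window — recording platforms let projects
accrue records outside the event, and those are counted separately.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "QualificationCriteria",
    "QualificationResult",
    "ProjectSummary",
    "STRICT_72H",
    "event_observations",
    "qualify",
    "qualify_all",
    "summarize_project",
    "summarize_all",
    "timing_histograms",
    "word_frequencies",
    "DEFAULT_STOPWORDS",
]


@dataclass(frozen=True)
class QualificationCriteria:
    """Definitional thresholds for a bioblitz.

    Defaults read the definition strictly: "more than one observer" → at
    least 2 observers; at least 1 identifier.  ``max_duration_hours``
    defaults to 336 h (14 days); most bioblitzes run under 72 h, and the
    :data:`STRICT_72H` preset applies that tighter cutoff.
    """

    min_observers: int = 2
    min_identifiers: int = 1
    max_duration_hours: float = 336.0

    def __post_init__(self) -> None:
        if self.min_observers < 1:
            raise ValueError("min_observers must be >= 1")
        if self.min_identifiers < 0:
            raise ValueError("min_identifiers must be >= 0")
        if self.max_duration_hours <= 0:
            raise ValueError("max_duration_hours must be > 0")


STRICT_72H = QualificationCriteria(max_duration_hours=72.0)


@dataclass
class QualificationResult:
    project_id: str
    qualifies: bool
    n_observers: int
    n_identifiers: int
    duration_hours: float
    failed_criteria: list[str] = field(default_factory=list)


@dataclass
class ProjectSummary:
    project_id: str
    n_observations: int
    n_taxa: int
    n_observers: int
    n_identifiers: int
    n_out_of_window: int
    duration_hours: float
    start_weekday: str
    start_month: int


def event_observations(project: pd.Series, obs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Observations belonging to a project-event.

    Returns ``(in_window, n_out_of_window)``: rows with the project's id and
    an observed date inside ``[start, end]`` (date-granular, inclusive), and
    the count of rows carrying the id but dated outside the window.
    """
    if "project_id" not in obs.columns:
        return obs.iloc[0:0], 0
    mine = obs[obs["project_id"] == project["project_id"]]
    start = pd.Timestamp(project["start"]).normalize()
    end = pd.Timestamp(project["end"]).normalize()
    dates = pd.to_datetime(mine["observed_date"])
    inside = (dates >= start) & (dates <= end)
    return mine[inside], int((~inside).sum())


def _event_identifiers(event_obs: pd.DataFrame, ids: pd.DataFrame) -> pd.Series:
    """Distinct identifiers of the event's observations (observers who also
    identify are included)."""
    if ids.empty or event_obs.empty:
        return pd.Series([], dtype=object)
    linked = ids[ids["observation_id"].isin(set(event_obs["observation_id"]))]
    return linked["identifier_id"].drop_duplicates()


def _duration_hours(project: pd.Series) -> float:
    if "duration_hours" in project.index and pd.notna(project.get("duration_hours")):
        return float(project["duration_hours"])
    return (pd.Timestamp(project["end"]) - pd.Timestamp(project["start"])).total_seconds() / 3600.0


def qualify(project: pd.Series, obs: pd.DataFrame, ids: pd.DataFrame,
            criteria: QualificationCriteria | None = None) -> QualificationResult:
    """Apply the bioblitz definition to one candidate project."""
    criteria = criteria or QualificationCriteria()
    event_obs, _ = event_observations(project, obs)
    n_observers = int(event_obs["observer_id"].nunique()) if not event_obs.empty else 0
    n_identifiers = int(_event_identifiers(event_obs, ids).nunique())
    duration = _duration_hours(project)

    failed = []
    if n_observers < criteria.min_observers:
        failed.append("min_observers")
    if n_identifiers < criteria.min_identifiers:
        failed.append("min_identifiers")
    if duration > criteria.max_duration_hours:
        failed.append("max_duration_hours")
    return QualificationResult(
        project_id=str(project["project_id"]),
        qualifies=not failed,
        n_observers=n_observers,
        n_identifiers=n_identifiers,
        duration_hours=duration,
        failed_criteria=failed,
    )


def qualify_all(projects: pd.DataFrame, obs: pd.DataFrame, ids: pd.DataFrame,
                criteria: QualificationCriteria | None = None) -> pd.DataFrame:
    """Qualification results for every project, one row each."""
    rows = [qualify(p, obs, ids, criteria) for _, p in projects.iterrows()]
    return pd.DataFrame(
        {
            "project_id": [r.project_id for r in rows],
            "qualifies": [r.qualifies for r in rows],
            "n_observers": [r.n_observers for r in rows],
            "n_identifiers": [r.n_identifiers for r in rows],
            "duration_hours": [r.duration_hours for r in rows],
            "failed_criteria": [";".join(r.failed_criteria) for r in rows],
        }
    )


_WEEKDAYS = ["Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday"]


def summarize_project(project: pd.Series, obs: pd.DataFrame,
                      ids: pd.DataFrame) -> ProjectSummary:
    """Headline numbers for one project-event.

    ``n_taxa`` counts distinct non-missing taxon labels; weekday/month come
    from the event start.
    """
    event_obs, n_out = event_observations(project, obs)
    taxa = event_obs["taxon"].dropna().nunique() if "taxon" in event_obs.columns else 0
    start = pd.Timestamp(project["start"])
    return ProjectSummary(
        project_id=str(project["project_id"]),
        n_observations=int(len(event_obs)),
        n_taxa=int(taxa),
        n_observers=int(event_obs["observer_id"].nunique()) if not event_obs.empty else 0,
        n_identifiers=int(_event_identifiers(event_obs, ids).nunique()),
        n_out_of_window=n_out,
        duration_hours=_duration_hours(project),
        start_weekday=_WEEKDAYS[start.dayofweek],
        start_month=int(start.month),
    )


def summarize_all(projects: pd.DataFrame, obs: pd.DataFrame,
                  ids: pd.DataFrame) -> pd.DataFrame:
    rows = [summarize_project(p, obs, ids) for _, p in projects.iterrows()]
    return pd.DataFrame([r.__dict__ for r in rows])


def timing_histograms(projects: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Counts of project starts by weekday and by month.

    Both tables are dense (every weekday / month present, zero-filled) and
    each sums to the number of projects.
    """
    if projects.empty:
        raise ValueError("timing_histograms requires at least one project")
    starts = pd.to_datetime(projects["start"])
    weekday = starts.dt.dayofweek.value_counts().reindex(range(7), fill_value=0)
    weekday.index = _WEEKDAYS
    weekday.name = "n_projects"
    month = starts.dt.month.value_counts().reindex(range(1, 13), fill_value=0)
    month.name = "n_projects"
    return weekday, month


DEFAULT_STOPWORDS = frozenset(
    """a an and are as at be by for from has have in is it of on or our that the
    this to was we will with you your""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def word_frequencies(descriptions: list[str], stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
                     min_length: int = 3) -> pd.Series:
    """Token counts over project descriptions (the word-cloud statistic).

    Tokens are lower-cased, punctuation-stripped; stopwords and tokens
    shorter than ``min_length`` are dropped.  Returns counts sorted
    descending, ties broken alphabetically.
    """
    counts: Counter[str] = Counter()
    for text in descriptions:
        if not isinstance(text, str):
            continue
        for tok in _TOKEN_RE.findall(text.lower()):
            if len(tok) >= min_length and tok not in stopwords:
                counts[tok] += 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series({k: v for k, v in items}, dtype=int, name="count")
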