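"""Reading, validation and canonicalization of bioblitz event-log tables.

Three delimited-text tables drive every downstream analysis:

* **observations** — one row per species observation: who recorded what, when,
  and (optionally) under which project;
* **identifications** — one row per identification act: who identified which
  observation, when;
* **projects** — one row per candidate bioblitz event: title, description and
  the event window.

Column names in the wild vary (iNaturalist exports, GBIF downloads, custom
spreadsheets), so every reader takes a :class:`ColumnMap` translating canonical
field names to source columns.  Validation is total: every input row is either
accepted into the canonical table or appears exactly once in the rejection
report with its row index and a reason.

Dates on observations and identifications are calendar dates (the analysis is
day-granular); project start/end are naive timestamps assumed local to the
event.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ColumnMap",
    "ReadResult",
    "read_observations",
    "read_identifications",
    "read_projects",
    "write_observations",
    "write_identifications",
    "write_projects",
]

#: canonical observation fields; values say whether the field is required
OBSERVATION_FIELDS: Mapping[str, bool] = {
    "observation_id": True,
    "observer_id": True,
    "observed_date": True,
    "project_id": False,
    "taxon": False,
    "latitude": False,
    "longitude": False,
}

IDENTIFICATION_FIELDS: Mapping[str, bool] = {
    "identification_id": True,
    "observation_id": True,
    "identifier_id": True,
    "identified_date": False,
}

PROJECT_FIELDS: Mapping[str, bool] = {
    "project_id": True,
    "title": True,
    "start": True,
    "end": True,
    "description": False,
    "place_label": False,
}


class ConfigurationError(ValueError):
    """A required column is missing or the column map is malformed."""


def _identity(fields: Mapping[str, bool]) -> dict[str, str]:
    return {name: name for name in fields}


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical field names to source column names per table.

    Unmapped optional fields are simply absent from the canonical table.
    Mapping keys outside the canonical schema are carried through untouched
    (e.g. an iNaturalist ``quality_grade`` column).
    """

    observations: Mapping[str, str] = field(default_factory=lambda: _identity(OBSERVATION_FIELDS))
    identifications: Mapping[str, str] = field(default_factory=lambda: _identity(IDENTIFICATION_FIELDS))
    projects: Mapping[str, str] = field(default_factory=lambda: _identity(PROJECT_FIELDS))
    date_format: str | None = None  # None = ISO-8601 / pandas-parseable
    delimiter: str = ","

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        """Load a column map from a YAML file with ``observations:``,
        ``identifications:`` and ``projects:`` sections."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for table in ("observations", "identifications", "projects"):
            if table in raw and raw[table]:
                kwargs[table] = dict(raw[table])
        if "date_format" in raw:
            kwargs["date_format"] = raw["date_format"]
        if "delimiter" in raw:
            kwargs["delimiter"] = raw["delimiter"]
        return cls(**kwargs)


@dataclass
class ReadResult:
    """A validated canonical table plus the rejection report.

    ``rejections`` has columns ``row_index`` (0-based position in the source
    file, header excluded) and ``reason``.  ``flags`` carries non-fatal
    issues (e.g. cross-validation misses) in the same shape.
    """

    table: pd.DataFrame
    rejections: pd.DataFrame
    flags: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["row_index", "reason"])
    )

    def write_rejections(self, path: str | Path) -> None:
        self.rejections.to_csv(path, index=False)


def _empty_result(fields: Mapping[str, bool], mapping: Mapping[str, str]) -> ReadResult:
    cols = [f for f in mapping if fields.get(f, False) or f in mapping]
    return ReadResult(
        table=pd.DataFrame(columns=list(cols)),
        rejections=pd.DataFrame(columns=["row_index", "reason"]),
    )


def _load_raw(path: str | Path, mapping: Mapping[str, str], fields: Mapping[str, bool],
              delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [src for canon, src in mapping.items()
               if fields.get(canon, False) and src not in df.columns]
    if missing:
        raise ConfigurationError(
            f"required column(s) missing from {path}: {', '.join(missing)}"
        )
    present = {canon: src for canon, src in mapping.items() if src in df.columns}
    out = df[[src for src in present.values()]].copy()
    out.columns = list(present.keys())
    return out


def _parse_dates(series: pd.Series, fmt: str | None) -> pd.Series:
    s = series.replace("", pd.NA)
    return pd.to_datetime(s, format=fmt, errors="coerce")


def _reject(mask: pd.Series, reason: str, rejections: list[tuple[int, str]]) -> None:
    for idx in mask.index[mask]:
        rejections.append((int(idx), reason))


def read_observations(path: str | Path, colmap: ColumnMap | None = None) -> ReadResult:
    """Read and validate an observation table.

    Rows with an unparseable ``observed_date``, coordinates out of range, or a
    duplicated ``observation_id`` (first occurrence kept) are rejected and
    listed in the report.  Row order is preserved.
    """
    colmap = colmap or ColumnMap()
    df = _load_raw(path, colmap.observations, OBSERVATION_FIELDS, colmap.delimiter)
    rejections: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)

    dates = _parse_dates(df["observed_date"], colmap.date_format)
    bad_date = dates.isna()
    _reject(bad_date & keep, "unparseable observed_date", rejections)
    keep &= ~bad_date
    df["observed_date"] = dates.dt.normalize()

    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        if col in df.columns:
            vals = pd.to_numeric(df[col].replace("", pd.NA), errors="coerce")
            bad = df[col].ne("") & (vals.isna() | (vals < lo) | (vals > hi))
            _reject(bad & keep, f"{col} out of range or non-numeric", rejections)
            keep &= ~bad
            df[col] = vals

    dup = df["observation_id"].duplicated(keep="first") & keep
    _reject(dup, "duplicate observation_id (first kept)", rejections)
    keep &= ~dup

    if "project_id" in df.columns:
        df["project_id"] = df["project_id"].replace("", pd.NA)
    if "taxon" in df.columns:
        df["taxon"] = df["taxon"].replace("", pd.NA)

    rej = pd.DataFrame(sorted(rejections), columns=["row_index", "reason"])
    return ReadResult(table=df[keep].reset_index(drop=True), rejections=rej)


def read_identifications(path: str | Path, colmap: ColumnMap | None = None,
                         observations: pd.DataFrame | None = None) -> ReadResult:
    """Read and validate an identification table.

    When ``observations`` is given, identifications whose ``observation_id``
    does not resolve against it are flagged (kept in the table, listed in
    ``flags``) — downstream stages decide whether to drop them.
    """
    colmap = colmap or ColumnMap()
    df = _load_raw(path, colmap.identifications, IDENTIFICATION_FIELDS, colmap.delimiter)
    rejections: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)

    if "identified_date" in df.columns:
        blank = df["identified_date"].eq("")
        dates = _parse_dates(df["identified_date"], colmap.date_format)
        bad = dates.isna() & ~blank
        _reject(bad & keep, "unparseable identified_date", rejections)
        keep &= ~bad
        df["identified_date"] = dates.dt.normalize()

    dup = df["identification_id"].duplicated(keep="first") & keep
    _reject(dup, "duplicate identification_id (first kept)", rejections)
    keep &= ~dup

    flags: list[tuple[int, str]] = []
    if observations is not None:
        known = set(observations["observation_id"])
        orphan = ~df["observation_id"].isin(known) & keep
        for idx in orphan.index[orphan]:
            flags.append((int(idx), "observation_id not found in observation table"))

    rej = pd.DataFrame(sorted(rejections), columns=["row_index", "reason"])
    flg = pd.DataFrame(sorted(flags), columns=["row_index", "reason"])
    return ReadResult(table=df[keep].reset_index(drop=True), rejections=rej, flags=flg)


def read_projects(path: str | Path, colmap: ColumnMap | None = None) -> ReadResult:
    """Read and validate a project/event table; events with ``end < start``
    or unparseable timestamps are rejected.  A ``duration_hours`` column is
    derived."""
    colmap = colmap or ColumnMap()
    df = _load_raw(path, colmap.projects, PROJECT_FIELDS, colmap.delimiter)
    rejections: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)

    for col in ("start", "end"):
        parsed = _parse_dates(df[col], colmap.date_format)
        bad = parsed.isna()
        _reject(bad & keep, f"unparseable {col}", rejections)
        keep &= ~bad
        df[col] = parsed

    reversed_ = keep & (df["end"] < df["start"])
    _reject(reversed_, "end before start", rejections)
    keep &= ~reversed_

    dup = df["project_id"].duplicated(keep="first") & keep
    _reject(dup, "duplicate project_id (first kept)", rejections)
    keep &= ~dup

    df["duration_hours"] = (df["end"] - df["start"]).dt.total_seconds() / 3600.0

    rej = pd.DataFrame(sorted(rejections), columns=["row_index", "reason"])
    return ReadResult(table=df[keep].reset_index(drop=True), rejections=rej)


def _invert(mapping: Mapping[str, str], columns: Sequence[str]) -> dict[str, str]:
    return {canon: mapping.get(canon, canon) for canon in columns}


def _fmt_dates(df: pd.DataFrame, cols: Sequence[str], fmt: str) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        if col in df.columns and pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime(fmt)
    return df


def write_observations(table: pd.DataFrame, path: str | Path,
                       colmap: ColumnMap | None = None) -> None:
    """Write a canonical observation table back to CSV (round-trip safe)."""
    colmap = colmap or ColumnMap()
    out = _fmt_dates(table, ["observed_date"], colmap.date_format or "%Y-%m-%d")
    out = out.rename(columns=_invert(colmap.observations, out.columns))
    out.to_csv(path, index=False, sep=colmap.delimiter)


def write_identifications(table: pd.DataFrame, path: str | Path,
                          colmap: ColumnMap | None = None) -> None:
    colmap = colmap or ColumnMap()
    out = _fmt_dates(table, ["identified_date"], colmap.date_format or "%Y-%m-%d")
    out = out.rename(columns=_invert(colmap.identifications, out.columns))
    out.to_csv(path, index=False, sep=colmap.delimiter)


def write_projects(table: pd.DataFrame, path: str | Path,
                   colmap: ColumnMap | None = None) -> None:
    colmap = colmap or ColumnMap()
    out = table.drop(columns=["duration_hours"], errors="ignore")
    out = _fmt_dates(out, ["start", "end"], "%Y-%m-%dT%H:%M:%S")
    out = out.rename(columns=_invert(colmap.projects, out.columns))
    out.to_csv(path, index=False, sep=colmap.delimiter)
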