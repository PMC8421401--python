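"""Canonical review-log data model, readers/writers, and preprocessing filters.

A review log is the atomic observation stream of a spaced-repetition trial:
one record per (learner, question) presentation inside a study session, with
a binary recall outcome and the trial-arm label of the learner.

Canonical on-disk schema (CSV header / JSONL keys)::

    learner_id, question_id, session_id, time, recall, arm

``time`` is seconds since epoch.  The stored seconds value is kept verbatim
in memory so that write -> read is an exact identity; a ``time_days`` column
(seconds / 86400) is derived once at construction and is the unit every
downstream computation uses, because forgetting rates are per-day quantities
and half-lives in days are human-readable.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86400.0

ARMS = ("select", "difficulty", "random")
#: arm labels accepted on input; "unknown" marks logs without arm metadata
VALID_ARMS = ARMS + ("unknown",)

COLUMNS = ["learner_id", "question_id", "session_id", "time", "recall", "arm"]


class SchemaError(ValueError):
    """The file header/keys do not match the canonical schema."""


class ValidationError(ValueError):
    """A row violates a field-level invariant (named by row number)."""


class IntegrityError(ValueError):
    """A log contradicts its recorded ground truth or internal invariants."""


@dataclass(frozen=True)
class ReviewEvent:
    """One (learner, question, session) observation."""

    learner_id: str
    question_id: str
    session_id: str
    time: float  # seconds since epoch
    recall: int  # 1 recalled, 0 forgot
    arm: str = "unknown"

    @property
    def time_days(self) -> float:
        return self.time / SECONDS_PER_DAY


@dataclass(frozen=True, order=True)
class SequenceKey:
    """Unique key of a per-pair review sequence."""

    learner_id: str
    question_id: str


class ReviewLog:
    """An ordered, validated collection of review events.

    Events are sorted by (learner_id, time, question_id); ties beyond that
    keep input order (stable sort), so pipelines are deterministic.
    """

    def __init__(self, frame: pd.DataFrame, metadata: Mapping | None = None,
                 _validated: bool = False):
        if not _validated:
            frame = _validate_frame(frame)
        self._df = frame
        self.metadata: dict = dict(metadata or {})

    # -- construction --------------------------------------------------

    @classmethod
    def from_events(cls, events: Iterable[ReviewEvent],
                    metadata: Mapping | None = None) -> "ReviewLog":
        rows = [(e.learner_id, e.question_id, e.session_id, e.time,
                 e.recall, e.arm) for e in events]
        df = pd.DataFrame(rows, columns=COLUMNS)
        return cls(df, metadata)

    @classmethod
    def empty(cls) -> "ReviewLog":
        return cls(pd.DataFrame(columns=COLUMNS))

    # -- basic protocol -------------------------------------------------

    @property
    def events(self) -> pd.DataFrame:
        """The event table (including the derived ``time_days`` column)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for row in self._df.itertuples(index=False):
            yield ReviewEvent(row.learner_id, row.question_id,
                              row.session_id, row.time, row.recall, row.arm)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReviewLog):
            return NotImplemented
        a = self._df[COLUMNS].reset_index(drop=True)
        b = other._df[COLUMNS].reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:
        return (f"ReviewLog({len(self)} events, "
                f"{self._df['learner_id'].nunique() if len(self) else 0} learners)")

    def learners(self) -> np.ndarray:
        return self._df["learner_id"].unique()

    def items(self) -> np.ndarray:
        return self._df["question_id"].unique()


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df = df[COLUMNS].copy()
    for col in ("learner_id", "question_id", "session_id", "arm"):
        df[col] = df[col].astype(str)

    recall = pd.to_numeric(df["recall"], errors="coerce")
    bad = ~recall.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"recall must be 0 or 1; first offending data row: {row} "
            f"(value {df['recall'].iloc[row - 1]!r})")
    df["recall"] = recall.astype(np.int8)

    time = pd.to_numeric(df["time"], errors="coerce").astype(float)
    bad = ~np.isfinite(time) | (time < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"time must be finite and non-negative; first offending data row: {row}")
    df["time"] = time

    bad = ~df["arm"].isin(VALID_ARMS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(
            f"arm must be one of {VALID_ARMS}; first offending data row: {row} "
            f"(value {df['arm'].iloc[row - 1]!r})")

    # events sharing a session id must share learner and time
    if len(df):
        g = df.groupby(["learner_id", "session_id"])["time"].nunique()
        if (g > 1).any():
            key = g[g > 1].index[0]
            raise ValidationError(
                f"session {key[1]!r} of learner {key[0]!r} spans multiple times")
        per_session = df.groupby("session_id")["learner_id"].nunique()
        if (per_session > 1).any():
            sid = per_session[per_session > 1].index[0]
            raise ValidationError(f"session {sid!r} is shared by multiple learners")

    df = df.sort_values(["learner_id", "time", "question_id"],
                        kind="stable").reset_index(drop=True)
    df["time_days"] = df["time"] / SECONDS_PER_DAY
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_review_log(path, format: str = "csv") -> ReviewLog:
    """Read a canonical review log from ``path``.

    Parameters
    ----------
    path : str or path-like
    format : {"csv", "jsonl"}

    Raises
    ------
    SchemaError
        If the header/keys do not match the canonical schema.
    ValidationError
        If a row violates a field invariant; the message names the first
        offending data row (1-based, excluding the header).
    """
    if format == "csv":
        df = pd.read_csv(path, dtype={c: str for c in COLUMNS
                                      if c not in ("time", "recall")},
                         keep_default_na=False, float_precision="round_trip")
    elif format == "jsonl":
        rows = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValidationError(f"malformed JSON on line {lineno}: {exc}")
        df = pd.DataFrame(rows, columns=COLUMNS if not rows else None)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing key(s): {', '.join(missing)}")
    else:
        raise ValueError(f"unknown format {format!r}")
    log = ReviewLog(df, metadata={"source": str(path), "format": format})
    return log


def write_review_log(log: ReviewLog, path, format: str = "csv") -> None:
    """Write ``log`` to ``path``; ``read_review_log`` inverts it exactly."""
    df = log.events[COLUMNS]
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_MINIMAL)
            writer.writerow(COLUMNS)
            for row in df.itertuples(index=False):
                writer.writerow([row.learner_id, row.question_id,
                                 row.session_id, repr(float(row.time)),
                                 int(row.recall), row.arm])
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in df.itertuples(index=False):
                fh.write(json.dumps({
                    "learner_id": row.learner_id,
                    "question_id": row.question_id,
                    "session_id": row.session_id,
                    "time": float(row.time),
                    "recall": int(row.recall),
                    "arm": row.arm,
                }, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_adapted_csv(path, column_map: Mapping[str, str],
                     time_unit: str = "seconds",
                     default_arm: str = "unknown") -> ReviewLog:
    """Adapter for third-party review-log exports.

    ``column_map`` maps canonical column names to the columns of the foreign
    file (e.g. ``{"learner_id": "user_id", ...}``).  Canonical columns absent
    from the map are filled with defaults where that is meaningful
    (``session_id`` from learner+time, ``arm`` from ``default_arm``).
    ``time_unit`` is "seconds", "milliseconds" or "days".
    """
    raw = pd.read_csv(path)
    df = pd.DataFrame()
    for canon in ("learner_id", "question_id", "time", "recall"):
        src = column_map.get(canon)
        if src is None or src not in raw.columns:
            raise SchemaError(f"no source column mapped for {canon!r}")
        df[canon] = raw[src]
    scale = {"seconds": 1.0, "milliseconds": 1e-3, "days": SECONDS_PER_DAY}
    if time_unit not in scale:
        raise ValueError(f"unknown time_unit {time_unit!r}")
    df["time"] = pd.to_numeric(df["time"]) * scale[time_unit]
    if "session_id" in column_map and column_map["session_id"] in raw.columns:
        df["session_id"] = raw[column_map["session_id"]]
    else:
        df["session_id"] = (df["learner_id"].astype(str) + "@"
                            + df["time"].astype(str))
    if "arm" in column_map and column_map["arm"] in raw.columns:
        df["arm"] = raw[column_map["arm"]]
    else:
        df["arm"] = default_arm
    return ReviewLog(df, metadata={"source": str(path), "adapter": dict(column_map)})


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterResult:
    log: "ReviewLog"
    removed_learners: int

    def __iter__(self):  # allow tuple-unpacking
        yield self.log
        yield self.removed_learners


def filter_arm_switchers(log: ReviewLog) -> FilterResult:
    """Drop every learner observed under more than one arm label.

    Learners who reinstall an app can be re-randomized into a different
    group; their data are not attributable to a single policy and are
    removed entirely.
    """
    df = log.events
    if not len(df):
        return FilterResult(log, 0)
    n_arms = df.groupby("learner_id")["arm"].nunique()
    keep = n_arms[n_arms <= 1].index
    removed = int((n_arms > 1).sum())
    out = df[df["learner_id"].isin(keep)].reset_index(drop=True)
    return FilterResult(ReviewLog(out, log.metadata, _validated=True), removed)


def filter_short_usage(log: ReviewLog, min_days: float = 2.0,
                       mode: str = "span") -> FilterResult:
    """Drop learners who used the app for less than ``min_days``.

    mode="span": usage is last event time minus first event time (days);
    learners with span >= min_days are retained (inclusive boundary).
    mode="active_days": usage is the number of distinct calendar days
    (floor of time in days) with at least one event.
    """
    if min_days < 0:
        raise ValueError("min_days must be >= 0")
    df = log.events
    if not len(df):
        return FilterResult(log, 0)
    if mode == "span":
        g = df.groupby("learner_id")["time_days"]
        usage = g.max() - g.min()
    elif mode == "active_days":
        days = np.floor(df["time_days"])
        usage = days.groupby(df["learner_id"]).nunique().astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = usage[usage >= min_days].index
    removed = int((usage < min_days).sum())
    out = df[df["learner_id"].isin(keep)].reset_index(drop=True)
    return FilterResult(ReviewLog(out, log.metadata, _validated=True), removed)


def build_sequences(log: ReviewLog) -> dict[SequenceKey, pd.DataFrame]:
    """Partition the log into per-(learner, question) review sequences.

    Each sequence preserves time order; the union of all sequences is the
    event set of the log (a partition).
    """
    out: dict[SequenceKey, pd.DataFrame] = {}
    df = log.events
    if not len(df):
        return out
    for (lid, qid), sub in df.groupby(["learner_id", "question_id"], sort=True):
        out[SequenceKey(lid, qid)] = sub.reset_index(drop=True)
    return out
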