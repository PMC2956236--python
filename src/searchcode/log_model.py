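"""Data model and I/O for clinician search-event logs.

A *search event* is one submitted search: the participant picked a profile
(an information resource, or a clinical task, depending on the study arm)
and entered free-text keywords under up to four categories (disease, drug,
symptom, other).  Events are grouped into *search sessions* — the sequence
of searches one participant submits while answering one clinical scenario
question — and sessions into a :class:`StudyLog`.

Two on-disk formats are supported and round-trip exactly:

* JSONL (canonical): one event object per line::

      {"participant_id": "...", "session_id": "...", "arm": "resource",
       "seq_index": 1, "profile": "PubMed",
       "keywords": {"disease": "asthma", "drug": "", "symptom": "", "other": ""}}

* CSV: flat dialect with columns ``participant_id, session_id, arm,
  seq_index, profile, kw_disease, kw_drug, kw_symptom, kw_other``.

Keyword text is stored raw; all normalization happens at coding time so
that coding decisions are reproducible from the original strings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Literal

from pydantic import BaseModel, Field, ValidationError as _PydanticError, field_validator, model_validator

__all__ = [
    "KEYWORD_CATEGORIES",
    "Arm",
    "SearchEvent",
    "SearchSession",
    "StudyLog",
    "LogError",
    "LogParseError",
    "LogValidationError",
    "LogSummary",
    "ArmSummary",
    "read_log",
    "write_log",
    "summarize_log",
]

#: The four keyword-entry categories offered by both study arms.
KEYWORD_CATEGORIES: tuple[str, ...] = ("disease", "drug", "symptom", "other")

_CSV_COLUMNS = (
    "participant_id",
    "session_id",
    "arm",
    "seq_index",
    "profile",
    "kw_disease",
    "kw_drug",
    "kw_symptom",
    "kw_other",
)


class LogError(ValueError):
    """Base class for log reading/validation failures."""


class LogParseError(LogError):
    """A record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LogValidationError(LogError):
    """Structurally parseable input violating a model invariant."""


class Arm(str, Enum):
    """Study arm: which kind of pre-query profile the system offered."""

    RESOURCE = "resource"
    TASK = "task"


class SearchEvent(BaseModel):
    """One submitted search within a session."""

    model_config = {"frozen": True}

    participant_id: str
    session_id: str
    arm: Arm
    seq_index: int = Field(ge=1, description="1-based submission order within the session")
    profile: str
    keywords: dict[str, str]

    @field_validator("profile")
    @classmethod
    def _profile_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("profile must be non-empty")
        return v

    @field_validator("keywords")
    @classmethod
    def _keyword_keys(cls, v: dict[str, str]) -> dict[str, str]:
        if set(v) != set(KEYWORD_CATEGORIES):
            raise ValueError(
                f"keywords must have exactly the keys {KEYWORD_CATEGORIES}, got {sorted(v)}"
            )
        return dict(v)


class SearchSession(BaseModel):
    """An ordered sequence of searches by one participant for one scenario."""

    model_config = {"frozen": True}

    session_id: str
    participant_id: str
    arm: Arm
    events: tuple[SearchEvent, ...]

    @model_validator(mode="after")
    def _check(self) -> "SearchSession":
        if not self.events:
            raise ValueError("a session must contain at least one event")
        for e in self.events:
            if (e.session_id, e.participant_id, e.arm) != (
                self.session_id,
                self.participant_id,
                self.arm,
            ):
                raise ValueError(
                    f"event {e.seq_index} of session {self.session_id!r} has inconsistent ids/arm"
                )
        indices = [e.seq_index for e in self.events]
        if indices != list(range(1, len(self.events) + 1)):
            raise ValueError(
                f"session {self.session_id!r}: seq_index must be contiguous 1..n, got {indices}"
            )
        return self

    def __len__(self) -> int:
        return len(self.events)


class StudyLog(BaseModel):
    """All sessions of a study (one or both arms)."""

    model_config = {"frozen": True}

    sessions: tuple[SearchSession, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "StudyLog":
        seen: set[str] = set()
        for s in self.sessions:
            if s.session_id in seen:
                raise ValueError(f"duplicate session_id {s.session_id!r}")
            seen.add(s.session_id)
        return self

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_searches(self) -> int:
        return sum(len(s) for s in self.sessions)

    def events(self) -> Iterator[SearchEvent]:
        for s in self.sessions:
            yield from s.events

    def arm_sessions(self, arm: Arm) -> list[SearchSession]:
        return [s for s in self.sessions if s.arm == arm]

    @property
    def arms(self) -> list[Arm]:
        """Arms present, resource first."""
        present = {s.arm for s in self.sessions}
        return [a for a in (Arm.RESOURCE, Arm.TASK) if a in present]


@dataclass(frozen=True)
class ArmSummary:
    sessions: int
    searches: int

    @property
    def transitions(self) -> int:
        """Codable consecutive-search transitions: searches − sessions."""
        return self.searches - self.sessions


@dataclass(frozen=True)
class LogSummary:
    sessions: int
    searches: int
    per_arm: dict[Arm, ArmSummary]

    @property
    def transitions(self) -> int:
        return self.searches - self.sessions


def _events_to_log(events: Iterable[tuple[int | None, SearchEvent]]) -> StudyLog:
    """Group parsed events into sessions, validating uniqueness and order."""
    by_session: dict[str, list[SearchEvent]] = {}
    seen: set[tuple[str, int]] = set()
    for line, ev in events:
        key = (ev.session_id, ev.seq_index)
        if key in seen:
            raise LogValidationError(
                f"duplicate (session_id, seq_index) = {key}"
                + (f" at line {line}" if line is not None else "")
            )
        seen.add(key)
        by_session.setdefault(ev.session_id, []).append(ev)
    sessions = []
    for sid, evs in by_session.items():
        evs.sort(key=lambda e: e.seq_index)
        try:
            sessions.append(
                SearchSession(
                    session_id=sid,
                    participant_id=evs[0].participant_id,
                    arm=evs[0].arm,
                    events=tuple(evs),
                )
            )
        except _PydanticError as exc:
            raise LogValidationError(str(exc)) from exc
    try:
        return StudyLog(sessions=tuple(sessions))
    except _PydanticError as exc:
        raise LogValidationError(str(exc)) from exc


def _parse_jsonl(path: Path) -> Iterator[tuple[int, SearchEvent]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LogParseError(f"invalid JSON: {exc.msg}", line=lineno) from exc
            try:
                yield lineno, SearchEvent(**obj)
            except (_PydanticError, TypeError) as exc:
                raise LogParseError(f"invalid record: {exc}", line=lineno) from exc


def _parse_csv(path: Path) -> Iterator[tuple[int, SearchEvent]]:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return
        if tuple(reader.fieldnames) != _CSV_COLUMNS:
            raise LogParseError(
                f"unexpected CSV header {reader.fieldnames}; expected {list(_CSV_COLUMNS)}",
                line=1,
            )
        for row in reader:
            lineno = reader.line_num
            try:
                yield lineno, SearchEvent(
                    participant_id=row["participant_id"],
                    session_id=row["session_id"],
                    arm=row["arm"],
                    seq_index=int(row["seq_index"]),
                    profile=row["profile"],
                    keywords={cat: row[f"kw_{cat}"] for cat in KEYWORD_CATEGORIES},
                )
            except (_PydanticError, TypeError, ValueError, KeyError) as exc:
                raise LogParseError(f"invalid record: {exc}", line=lineno) from exc


def read_log(path: str | Path, format: Literal["jsonl", "csv"] | None = None) -> StudyLog:
    """Read a search-event log file into a validated :class:`StudyLog`.

    ``format`` defaults to the file suffix (``.csv`` → csv, otherwise jsonl).
    Raises :class:`LogParseError` (with a line number) on malformed records
    and :class:`LogValidationError` on invariant violations such as a
    duplicated ``(session_id, seq_index)``.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    parser = _parse_csv if format == "csv" else _parse_jsonl
    return _events_to_log(parser(path))


def write_log(log: StudyLog, path: str | Path, format: Literal["jsonl", "csv"] | None = None) -> None:
    """Write a :class:`StudyLog`; ``read_log(write_log(x)) == x`` field-for-field."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for ev in log.events():
                fh.write(
                    json.dumps(
                        {
                            "participant_id": ev.participant_id,
                            "session_id": ev.session_id,
                            "arm": ev.arm.value,
                            "seq_index": ev.seq_index,
                            "profile": ev.profile,
                            "keywords": {c: ev.keywords[c] for c in KEYWORD_CATEGORIES},
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for ev in log.events():
                writer.writerow(
                    [
                        ev.participant_id,
                        ev.session_id,
                        ev.arm.value,
                        ev.seq_index,
                        ev.profile,
                        *[ev.keywords[c] for c in KEYWORD_CATEGORIES],
                    ]
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def summarize_log(log: StudyLog) -> LogSummary:
    """Session/search totals, overall and per arm.

    ``searches − sessions`` per arm equals the number of codable
    consecutive-search transitions in that arm.
    """
    per_arm: dict[Arm, ArmSummary] = {}
    for arm in log.arms:
        sess = log.arm_sessions(arm)
        per_arm[arm] = ArmSummary(sessions=len(sess), searches=sum(len(s) for s in sess))
    return LogSummary(sessions=log.n_sessions, searches=log.n_searches, per_arm=per_arm)
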