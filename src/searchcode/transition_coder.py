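"""Coding of consecutive-search transitions within sessions.

Every ordered pair of consecutive searches in a session is one *transition*
(*search action*): a session of k searches yields k−1 transitions.  Each
transition carries

* a profile code — ``same`` (repeat of the immediately preceding profile),
  ``previous`` (used earlier in the session but not immediately preceding),
  or ``new`` (first use in the session);
* a query code from :mod:`searchcode.query_coder`;
* the combined action category (did the profile change? did the query?);
* a position label: a session's first transition is ``first``, its final
  transition is ``last`` when there are at least two, everything between
  is ``middle``.  A single-transition session is labeled ``first``.

Profile history is session-scoped and profile comparison is exact string
equality after whitespace trimming (profiles are menu selections, not
typed text).  An identical resubmission codes as a ``no_change`` transition
rather than being discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .log_model import Arm, SearchSession, StudyLog
from .query_coder import (
    DEFAULT_CONFIG,
    CoderConfig,
    CodingError,
    QueryCode,
    ReformulationType,
    classify_query_reformulation,
)

__all__ = [
    "ProfileCode",
    "ActionCategory",
    "Position",
    "Transition",
    "code_profile_transition",
    "code_action_category",
    "enumerate_transitions",
    "label_positions",
    "consecutive_action_pairs",
    "action_pairs_by_session",
    "code_log",
    "transitions_to_frame",
    "write_transitions",
]


class ProfileCode(str, Enum):
    SAME = "same"
    PREVIOUS = "previous"
    NEW = "new"


class ActionCategory(str, Enum):
    NO_CHANGE = "no_change"
    CHANGE_QUERY_ONLY = "change_query_only"
    CHANGE_PROFILE_ONLY = "change_profile_only"
    CHANGE_QUERY_AND_PROFILE = "change_query_and_profile"


class Position(str, Enum):
    FIRST = "first"
    MIDDLE = "middle"
    LAST = "last"


@dataclass(frozen=True)
class Transition:
    """One coded consecutive-search transition."""

    session_id: str
    arm: Arm
    index: int  # 1-based among the session's transitions
    profile_code: ProfileCode
    query_code: QueryCode
    action: ActionCategory
    position: Position


def code_profile_transition(history: Sequence[str], current: str) -> ProfileCode:
    """Code the profile selection of the current search against the
    session's profile history (all profiles used before it, in order).

    Raises :class:`CodingError` on empty history: the session's first
    search has no transition to code.
    """
    if not history:
        raise CodingError("profile history is empty: the first search of a session has no transition")
    cur = current.strip()
    if cur == history[-1].strip():
        return ProfileCode.SAME
    if cur in {h.strip() for h in history}:
        return ProfileCode.PREVIOUS
    return ProfileCode.NEW


def code_action_category(profile_code: ProfileCode, query_code: QueryCode) -> ActionCategory:
    """Combined 4-way action category from the profile and query codes."""
    profile_changed = profile_code is not ProfileCode.SAME
    query_changed = query_code.value is not ReformulationType.NONE
    if profile_changed and query_changed:
        return ActionCategory.CHANGE_QUERY_AND_PROFILE
    if profile_changed:
        return ActionCategory.CHANGE_PROFILE_ONLY
    if query_changed:
        return ActionCategory.CHANGE_QUERY_ONLY
    return ActionCategory.NO_CHANGE


def label_positions(transitions: Sequence[Transition]) -> list[Transition]:
    """Assign first/middle/last positions to one session's ordered
    transitions.  A single transition is ``first``; with two or more, the
    final one is ``last`` and any between are ``middle``."""
    n = len(transitions)
    out = []
    for i, t in enumerate(transitions):
        if i == 0:
            pos = Position.FIRST
        elif i == n - 1:
            pos = Position.LAST
        else:
            pos = Position.MIDDLE
        out.append(replace(t, position=pos))
    return out


def enumerate_transitions(
    session: SearchSession, config: CoderConfig = DEFAULT_CONFIG
) -> list[Transition]:
    """Code every consecutive-search pair of a session.

    Returns ``len(session) − 1`` fully coded transitions (an empty list
    for a single-search session).
    """
    transitions: list[Transition] = []
    profiles = [e.profile for e in session.events]
    for i in range(1, len(session.events)):
        prev_ev, curr_ev = session.events[i - 1], session.events[i]
        pc = code_profile_transition(profiles[:i], curr_ev.profile)
        qc = classify_query_reformulation(prev_ev.keywords, curr_ev.keywords, config)
        transitions.append(
            Transition(
                session_id=session.session_id,
                arm=session.arm,
                index=i,
                profile_code=pc,
                query_code=qc,
                action=code_action_category(pc, qc),
                position=Position.FIRST,  # placeholder, set below
            )
        )
    return label_positions(transitions)


def code_log(log: StudyLog, config: CoderConfig = DEFAULT_CONFIG) -> list[Transition]:
    """Code all sessions of a log, in session order."""
    out: list[Transition] = []
    for session in log.sessions:
        out.extend(enumerate_transitions(session, config))
    return out


def consecutive_action_pairs(
    transitions: Sequence[Transition],
) -> list[tuple[ActionCategory, ActionCategory]]:
    """Adjacent (current, next) action pairs of one session's transitions.

    A session with k transitions yields k−1 pairs; each session's final
    transition contributes no pair because the next action was to stop
    searching.
    """
    return [
        (transitions[i].action, transitions[i + 1].action)
        for i in range(len(transitions) - 1)
    ]


def action_pairs_by_session(
    transitions: Iterable[Transition],
) -> list[tuple[Arm, ActionCategory, ActionCategory]]:
    """Adjacent action pairs across a whole coded log, grouped by session.

    Across a log the pair count equals total transitions minus the number
    of sessions having at least one transition.
    """
    by_session: dict[str, list[Transition]] = {}
    order: list[str] = []
    for t in transitions:
        if t.session_id not in by_session:
            by_session[t.session_id] = []
            order.append(t.session_id)
        by_session[t.session_id].append(t)
    pairs: list[tuple[Arm, ActionCategory, ActionCategory]] = []
    for sid in order:
        ts = sorted(by_session[sid], key=lambda t: t.index)
        for a, b in consecutive_action_pairs(ts):
            pairs.append((ts[0].arm, a, b))
    return pairs


def transitions_to_frame(transitions: Sequence[Transition]) -> pd.DataFrame:
    """Coded-transitions table with one row per transition."""
    rows = [
        {
            "session_id": t.session_id,
            "arm": t.arm.value,
            "index": t.index,
            "profile_code": t.profile_code.value,
            "query_code": t.query_code.value.value,
            "syntactic_subtypes": ";".join(sorted(s.value for s in t.query_code.subtypes)),
            "action": t.action.value,
            "position": t.position.value,
        }
        for t in transitions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "arm",
            "index",
            "profile_code",
            "query_code",
            "syntactic_subtypes",
            "action",
            "position",
        ],
    )


def write_transitions(transitions: Sequence[Transition], path) -> None:
    transitions_to_frame(transitions).to_csv(path, index=False)
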