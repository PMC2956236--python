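"""Synthetic two-arm search logs with controlled behavioral structure.

Two generators are provided:

* :func:`generate_study_log` samples logs from a :class:`BehaviorSpec` —
  a probability vector over the 12 (profile code × reformulation type)
  action combinations plus a session-length law — and *realizes* each
  sampled action as concrete profile selections and keyword edits whose
  pipeline coding is guaranteed to equal the sampled action (a closed
  loop with :mod:`searchcode.query_coder`).  The shipped presets emulate
  the two behavioral signatures of interest: "breadth-first" (explore new
  profiles, keep the query; the resource-arm signature) and "depth-first"
  (keep the profile, reformulate the query; the task-arm signature),
  with default action probabilities and session-length means taken from
  the published two-arm study this package models.

* :func:`fixture_from_counts` deterministically assembles a log whose
  coded 12-cell combination table and position-by-action table equal a
  :class:`FixtureSpec` cell-for-cell.  :data:`STUDY_FIXTURES` carries the
  published per-arm counts, so the full pipeline can be exercised against
  the printed tables without the original (unreleased) logs.

The keyword vocabulary ships as a list of clinical-flavored tokens
screened pairwise against the typographic-variant relation, so that a
semantic edit can never be mistaken for a syntactic one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .log_model import KEYWORD_CATEGORIES, Arm, SearchEvent, SearchSession, StudyLog
from .query_coder import (
    DEFAULT_CONFIG,
    CoderConfig,
    QueryCode,
    ReformulationType,
    SyntacticSubtype,
    classify_query_reformulation,
    is_typographic_variant,
    light_stem,
)
from .transition_coder import ActionCategory, Position, ProfileCode

__all__ = [
    "SpecError",
    "RealizationError",
    "FixtureConstructionError",
    "BehaviorSpec",
    "FixtureSpec",
    "CLINICAL_VOCABULARY",
    "RESOURCE_PROFILES",
    "TASK_PROFILES",
    "ACTION_COMBOS",
    "STUDY_FIXTURES",
    "STUDY_ACTION_PROBS",
    "breadth_first_spec",
    "depth_first_spec",
    "generate_study_log",
    "realize_query_edit",
    "fixture_from_counts",
    "study_fixture_log",
]


class SpecError(ValueError):
    """An infeasible or inconsistent generator specification."""


class RealizationError(ValueError):
    """A requested keyword edit is infeasible on the current keywords."""


class FixtureConstructionError(ValueError):
    """The exact-fixture builder could not satisfy the requested counts."""


#: The 12 profile-code x reformulation-type action combinations, in the
#: row order used by the combination table.
ACTION_COMBOS: tuple[tuple[ProfileCode, ReformulationType], ...] = tuple(
    (pc, rt)
    for pc in (ProfileCode.SAME, ProfileCode.PREVIOUS, ProfileCode.NEW)
    for rt in (
        ReformulationType.NONE,
        ReformulationType.SYNTACTIC_ONLY,
        ReformulationType.SEMANTIC_ONLY,
        ReformulationType.SYNTACTIC_AND_SEMANTIC,
    )
)

RESOURCE_PROFILES = (
    "PubMed",
    "MIMS",
    "Therapeutic Guidelines",
    "Merck Manual",
    "Harrisons",
    "HealthInsite",
)
TASK_PROFILES = (
    "diagnosis",
    "drug information",
    "etiology",
    "patient education",
    "treatment",
    "other",
)

#: Clinical-flavored keyword tokens, screened pairwise non-variant under
#: the default typographic-variant relation (asserted by validation).
CLINICAL_VOCABULARY = (
    "asthma",
    "spacer",
    "inhaler",
    "tympanostomy",
    "grommet",
    "otitis",
    "hearing",
    "nicotine",
    "patch",
    "infarction",
    "myocardial",
    "cancer",
    "breast",
    "cervical",
    "fertilization",
    "embryo",
    "sibling",
    "infant",
    "death",
    "syndrome",
    "anaerobic",
    "osteomyelitis",
    "diabetes",
    "bacteroides",
    "glucosamine",
    "osteoarthritis",
    "cartilage",
    "epinephrine",
    "antivenom",
    "anaphylaxis",
    "snakebite",
    "dosage",
    "pediatric",
    "guideline",
    "therapy",
    "etiology",
    "prognosis",
    "screening",
    "vaccine",
    "antibiotic",
    "steroid",
    "bronchodilator",
    "nebulizer",
    "oxygen",
    "ventilation",
    "sepsis",
    "fever",
    "wheeze",
)


def _screen_vocabulary(tokens: Sequence[str], config: CoderConfig) -> None:
    for i, a in enumerate(tokens):
        for b in tokens[i + 1 :]:
            if a == b or is_typographic_variant(a, b, config):
                raise SpecError(
                    f"keyword vocabulary tokens {a!r} and {b!r} are variants; "
                    "the closed-loop guarantee needs a pairwise non-variant vocabulary"
                )


def _action_of(pc: ProfileCode, rt: ReformulationType) -> ActionCategory:
    profile_changed = pc is not ProfileCode.SAME
    query_changed = rt is not ReformulationType.NONE
    if profile_changed and query_changed:
        return ActionCategory.CHANGE_QUERY_AND_PROFILE
    if profile_changed:
        return ActionCategory.CHANGE_PROFILE_ONLY
    if query_changed:
        return ActionCategory.CHANGE_QUERY_ONLY
    return ActionCategory.NO_CHANGE


# ---------------------------------------------------------------------------
# keyword-edit realization


def _chunks(text: str) -> list[str]:
    return text.split()


def _is_conj(chunk: str, config: CoderConfig) -> bool:
    return chunk.casefold() in config.conjunctions


def _chunk_key(chunk: str, config: CoderConfig) -> tuple[str, ...]:
    import re

    words = [w for w in re.split("[" + re.escape(config.spacing_punctuation) + "]", chunk) if w]
    return tuple(light_stem(w.casefold()) for w in words)


def _field_keys(text: str, config: CoderConfig) -> set[str]:
    keys: set[str] = set()
    for c in _chunks(text):
        if not _is_conj(c, config):
            keys.update(_chunk_key(c, config))
    return keys


def _apply_syntactic(field_text: str, subtype: SyntacticSubtype, config: CoderConfig) -> str:
    """Apply one syntactic edit to a keyword field, or raise
    :class:`RealizationError` if that edit is infeasible on it."""
    chunks = _chunks(field_text)
    content_idx = [i for i, c in enumerate(chunks) if not _is_conj(c, config)]

    if subtype is SyntacticSubtype.CAPITALIZATION:
        for i in content_idx:
            c = chunks[i]
            if c and c[0].isalpha():
                flipped = (c[0].lower() if c[0].isupper() else c[0].upper()) + c[1:]
                chunks[i] = flipped
                return " ".join(chunks)
        raise RealizationError("no alphabetic word to re-capitalize")

    if subtype is SyntacticSubtype.WORD_ORDER:
        for i, j in itertools.combinations(content_idx, 2):
            if _chunk_key(chunks[i], config) != _chunk_key(chunks[j], config):
                chunks[i], chunks[j] = chunks[j], chunks[i]
                return " ".join(chunks)
        raise RealizationError("word-order change needs two distinct content words")

    if subtype is SyntacticSubtype.CONJUNCTION:
        conj_idx = [i for i, c in enumerate(chunks) if _is_conj(c, config)]
        if conj_idx:
            del chunks[conj_idx[0]]
            return " ".join(chunks)
        if len(content_idx) >= 2:
            chunks.insert(content_idx[0] + 1, "AND")
            return " ".join(chunks)
        if content_idx:
            return " ".join(chunks + ["AND"])
        raise RealizationError("no content to conjoin")

    if subtype is SyntacticSubtype.SPACING:
        for i, c in enumerate(chunks):
            if "-" in c:
                chunks[i] = c.replace("-", " ", 1)
                return " ".join(chunks)
        for a, b in zip(content_idx, content_idx[1:]):
            if b == a + 1:  # adjacent content chunks
                chunks[a : b + 1] = [chunks[a] + "-" + chunks[b]]
                return " ".join(chunks)
        raise RealizationError("spacing change needs a hyphenated word or adjacent words")

    if subtype is SyntacticSubtype.TYPOGRAPHIC:
        for i in content_idx:
            c = chunks[i]
            if c.isalpha():
                toggled = c[:-1] if c.casefold().endswith("s") and len(c) > 4 else c + "s"
                if is_typographic_variant(c, toggled, config):
                    chunks[i] = toggled
                    return " ".join(chunks)
        raise RealizationError("no word admits a plural/stem toggle")

    raise ValueError(f"unknown subtype {subtype}")


def _fresh_token(
    vocabulary: Sequence[str],
    forbidden_keys: set[str],
    rng: np.random.Generator | None,
) -> str:
    candidates = [t for t in vocabulary if light_stem(t.casefold()) not in forbidden_keys]
    if not candidates:
        raise RealizationError("vocabulary exhausted: no token with a fresh base form")
    if rng is None:
        return candidates[0]
    return candidates[int(rng.integers(len(candidates)))]


def _apply_semantic(
    keywords: dict[str, str],
    vocabulary: Sequence[str],
    rng: np.random.Generator | None,
    config: CoderConfig,
) -> dict[str, str]:
    """Add, remove, or replace a keyword in the drug/symptom fields."""
    new = dict(keywords)
    ops: list[str] = []
    if new["drug"].strip():
        ops.append("replace_drug")
    if new["symptom"].strip():
        ops.append("remove_symptom")
    else:
        ops.append("add_symptom")
    if not ops:
        raise RealizationError("no feasible semantic edit")
    op = ops[0] if rng is None else ops[int(rng.integers(len(ops)))]
    if op == "replace_drug":
        forbidden = _field_keys(new["drug"], config)
        new["drug"] = _fresh_token(vocabulary, forbidden, rng)
    elif op == "remove_symptom":
        new["symptom"] = ""
    else:
        new["symptom"] = _fresh_token(vocabulary, _field_keys(new["symptom"], config), rng)
    return new


def realize_query_edit(
    current: Mapping[str, str],
    target: ReformulationType,
    subtype: SyntacticSubtype | None = None,
    *,
    vocabulary: Sequence[str] = CLINICAL_VOCABULARY,
    rng: np.random.Generator | None = None,
    config: CoderConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Produce a keywords map whose classification against ``current`` is
    exactly ``target`` (and exactly ``{subtype}`` when one is requested).

    Syntactic edits are applied to the disease field and semantic edits to
    the drug/symptom fields, so combined targets decompose cleanly across
    categories.  With ``rng=None`` all choices are deterministic (first
    feasible option).  Raises :class:`RealizationError` on infeasible
    requests; the result is verified by the classifier before returning.
    """
    current = {c: current[c] for c in KEYWORD_CATEGORIES}
    if target is ReformulationType.NONE:
        if subtype is not None:
            raise ValueError("no-change target cannot carry a syntactic subtype")
        return dict(current)

    new = dict(current)
    chosen: SyntacticSubtype | None = None
    if target in (ReformulationType.SYNTACTIC_ONLY, ReformulationType.SYNTACTIC_AND_SEMANTIC):
        candidates = [subtype] if subtype is not None else list(SyntacticSubtype)
        if rng is not None and subtype is None:
            candidates = [candidates[i] for i in rng.permutation(len(candidates))]
        last_err: RealizationError | None = None
        for cand in candidates:
            try:
                new["disease"] = _apply_syntactic(current["disease"], cand, config)
                chosen = cand
                break
            except RealizationError as exc:
                last_err = exc
        if chosen is None:
            raise last_err if last_err is not None else RealizationError("no feasible syntactic edit")
    elif subtype is not None:
        raise ValueError("a semantic-only target cannot carry a syntactic subtype")

    if target in (ReformulationType.SEMANTIC_ONLY, ReformulationType.SYNTACTIC_AND_SEMANTIC):
        new = _apply_semantic(new, vocabulary, rng, config)

    got = classify_query_reformulation(current, new, config)
    expected_subtypes = frozenset({chosen}) if chosen is not None else frozenset()
    if got.value is not target or got.subtypes != expected_subtypes:
        raise RealizationError(
            f"edit realization drifted: wanted {target.value}/{set(expected_subtypes)}, "
            f"classifier saw {got.value.value}/{set(got.subtypes)}"
        )
    return new


# ---------------------------------------------------------------------------
# behavioral sampler


@dataclass(frozen=True)
class BehaviorSpec:
    """Parameters of the behavioral log sampler.

    ``action_probs`` assigns probability to each of the 12 action
    combinations in :data:`ACTION_COMBOS`; at sampling time mass on
    history-infeasible actions (``previous`` before any revisitable
    profile exists, ``new`` once every profile has been used) is
    redistributed proportionally over the feasible ones.
    ``session_length_law`` is a named family with one parameter:
    ``("geometric", m)`` for a shifted geometric on {1, 2, ...} with mean
    m, or ``("fixed", k)``.
    """

    arm: Arm
    n_participants: int
    sessions_per_participant: int
    session_length_law: tuple[str, float]
    action_probs: Mapping[tuple[ProfileCode, ReformulationType], float]
    profile_vocabulary: tuple[str, ...]
    keyword_vocabulary: tuple[str, ...] = CLINICAL_VOCABULARY
    seed: int = 0
    config: CoderConfig = field(default=DEFAULT_CONFIG, compare=False)

    def validate(self) -> None:
        if self.n_participants < 1 or self.sessions_per_participant < 1:
            raise SpecError("need at least one participant and one session each")
        law, param = self.session_length_law
        if law not in ("geometric", "fixed") or param < 1:
            raise SpecError(f"unsupported session length law {self.session_length_law}")
        probs = np.array([self.action_probs.get(combo, 0.0) for combo in ACTION_COMBOS])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise SpecError("action_probs must be a probability vector over the 12 combinations")
        unknown = set(self.action_probs) - set(ACTION_COMBOS)
        if unknown:
            raise SpecError(f"unknown action combinations {unknown}")
        if len(self.profile_vocabulary) < 2:
            raise SpecError("need at least two profiles")
        if len(self.keyword_vocabulary) < 8:
            raise SpecError("keyword vocabulary too small to realize semantic edits")
        _screen_vocabulary(self.keyword_vocabulary, self.config)

    def prob_vector(self) -> np.ndarray:
        return np.array([self.action_probs.get(combo, 0.0) for combo in ACTION_COMBOS])


#: Per-arm action-combination probabilities matching the published study's
#: observed transition frequencies (combination counts / arm totals).
STUDY_ACTION_PROBS: dict[Arm, dict[tuple[ProfileCode, ReformulationType], float]] = {
    Arm.RESOURCE: {
        combo: cnt / 1398
        for combo, cnt in zip(
            ACTION_COMBOS, (67, 193, 203, 94, 120, 18, 36, 28, 401, 83, 87, 68)
        )
    },
    Arm.TASK: {
        combo: cnt / 585
        for combo, cnt in zip(ACTION_COMBOS, (74, 99, 123, 83, 16, 10, 17, 12, 54, 28, 39, 30))
    },
}


def breadth_first_spec(seed: int = 0) -> BehaviorSpec:
    """Resource-arm-like behavior: new profiles explored with an unchanged
    query dominate.  Defaults mirror the published resource arm: 39
    participants x 8 scenarios, mean session length 1708/310."""
    return BehaviorSpec(
        arm=Arm.RESOURCE,
        n_participants=39,
        sessions_per_participant=8,
        session_length_law=("geometric", 1708 / 310),
        action_probs=STUDY_ACTION_PROBS[Arm.RESOURCE],
        profile_vocabulary=RESOURCE_PROFILES,
        seed=seed,
    )


def depth_first_spec(seed: int = 0) -> BehaviorSpec:
    """Task-arm-like behavior: query reformulation within the same profile
    dominates.  Defaults mirror the published task arm: 36 participants x
    8 scenarios, mean session length 873/288."""
    return BehaviorSpec(
        arm=Arm.TASK,
        n_participants=36,
        sessions_per_participant=8,
        session_length_law=("geometric", 873 / 288),
        action_probs=STUDY_ACTION_PROBS[Arm.TASK],
        profile_vocabulary=TASK_PROFILES,
        seed=seed,
    )


def _sample_length(law: tuple[str, float], rng: np.random.Generator) -> int:
    name, param = law
    if name == "fixed":
        return int(param)
    return int(rng.geometric(1.0 / param))


def _initial_keywords(vocabulary: Sequence[str], rng: np.random.Generator) -> dict[str, str]:
    picks = rng.choice(len(vocabulary), size=3, replace=False)
    return {
        "disease": f"{vocabulary[int(picks[0])]} {vocabulary[int(picks[1])]}",
        "drug": vocabulary[int(picks[2])],
        "symptom": "",
        "other": "",
    }


def _next_profile(
    pc: ProfileCode,
    history: list[str],
    vocabulary: Sequence[str],
    rng: np.random.Generator | None,
) -> str:
    used = list(dict.fromkeys(history))  # preserve first-use order
    last = history[-1]
    if pc is ProfileCode.SAME:
        return last
    if pc is ProfileCode.PREVIOUS:
        options = [p for p in used if p != last]
        if not options:
            raise RealizationError("no previously used profile distinct from the last")
        return options[0] if rng is None else options[int(rng.integers(len(options)))]
    options = [p for p in vocabulary if p not in used]
    if not options:
        raise RealizationError("all profiles already used; 'new' is infeasible")
    return options[0] if rng is None else options[int(rng.integers(len(options)))]


def _feasible_mask(history: list[str], n_profiles: int) -> np.ndarray:
    distinct = len(set(history))
    can_prev = distinct >= 2
    can_new = distinct < n_profiles
    mask = np.ones(len(ACTION_COMBOS), dtype=bool)
    for i, (pc, _) in enumerate(ACTION_COMBOS):
        if pc is ProfileCode.PREVIOUS and not can_prev:
            mask[i] = False
        if pc is ProfileCode.NEW and not can_new:
            mask[i] = False
    return mask


def generate_study_log(spec: BehaviorSpec) -> StudyLog:
    """Sample a complete one-arm log from a :class:`BehaviorSpec`.

    Fully deterministic given ``spec.seed``: each session draws from its
    own PRNG substream seeded with (seed, session ordinal), so logs are
    stable under any generation order.
    """
    spec.validate()
    base_probs = spec.prob_vector()
    sessions: list[SearchSession] = []
    ordinal = 0
    for p in range(spec.n_participants):
        pid = f"{spec.arm.value}-p{p + 1:02d}"
        for q in range(spec.sessions_per_participant):
            rng = np.random.default_rng([spec.seed, ordinal])
            sid = f"{pid}-q{q + 1}"
            sessions.append(_generate_session(spec, base_probs, pid, sid, rng))
            ordinal += 1
    return StudyLog(sessions=tuple(sessions))


def _generate_session(
    spec: BehaviorSpec,
    base_probs: np.ndarray,
    participant_id: str,
    session_id: str,
    rng: np.random.Generator,
) -> SearchSession:
    length = _sample_length(spec.session_length_law, rng)
    profile = spec.profile_vocabulary[int(rng.integers(len(spec.profile_vocabulary)))]
    keywords = _initial_keywords(spec.keyword_vocabulary, rng)
    events = [
        SearchEvent(
            participant_id=participant_id,
            session_id=session_id,
            arm=spec.arm,
            seq_index=1,
            profile=profile,
            keywords=keywords,
        )
    ]
    history = [profile]
    for i in range(2, length + 1):
        mask = _feasible_mask(history, len(spec.profile_vocabulary))
        probs = base_probs * mask
        total = probs.sum()
        if total <= 0:
            raise SpecError(
                "action_probs places all mass on history-infeasible actions"
            )
        idx = int(rng.choice(len(ACTION_COMBOS), p=probs / total))
        pc, rt = ACTION_COMBOS[idx]
        profile = _next_profile(pc, history, spec.profile_vocabulary, rng)
        keywords = realize_query_edit(
            keywords, rt, vocabulary=spec.keyword_vocabulary, rng=rng, config=spec.config
        )
        events.append(
            SearchEvent(
                participant_id=participant_id,
                session_id=session_id,
                arm=spec.arm,
                seq_index=i,
                profile=profile,
                keywords=keywords,
            )
        )
        history.append(profile)
    return SearchSession(
        session_id=session_id,
        participant_id=participant_id,
        arm=spec.arm,
        events=tuple(events),
    )


# ---------------------------------------------------------------------------
# exact-fixture builder


@dataclass(frozen=True)
class FixtureSpec:
    """Target counts for the exact-fixture builder: the 12-cell combination
    table and the position-by-action table of one arm, plus the session
    and search totals they must be embedded in."""

    arm: Arm
    n_sessions: int
    n_searches: int
    combo_counts: Mapping[tuple[ProfileCode, ReformulationType], int]
    position_action_counts: Mapping[tuple[Position, ActionCategory], int]
    profile_vocabulary: tuple[str, ...] = RESOURCE_PROFILES
    keyword_vocabulary: tuple[str, ...] = CLINICAL_VOCABULARY

    def validate(self) -> None:
        combo = {c: int(self.combo_counts.get(c, 0)) for c in ACTION_COMBOS}
        if any(v < 0 for v in combo.values()):
            raise FixtureConstructionError("negative combination count")
        total = sum(combo.values())
        if total != self.n_searches - self.n_sessions:
            raise FixtureConstructionError(
                f"combination total {total} != searches - sessions = "
                f"{self.n_searches - self.n_sessions}"
            )
        pos = {
            (p, a): int(self.position_action_counts.get((p, a), 0))
            for p in Position
            for a in ActionCategory
        }
        if any(v < 0 for v in pos.values()):
            raise FixtureConstructionError("negative position-by-action count")
        for a in ActionCategory:
            combo_a = sum(v for (pc, rt), v in combo.items() if _action_of(pc, rt) is a)
            pos_a = sum(pos[(p, a)] for p in Position)
            if combo_a != pos_a:
                raise FixtureConstructionError(
                    f"action {a.value}: combination total {combo_a} != "
                    f"position marginal total {pos_a}"
                )
            first_a = pos[(Position.FIRST, a)]
            non_prev_a = sum(
                v
                for (pc, rt), v in combo.items()
                if _action_of(pc, rt) is a and pc is not ProfileCode.PREVIOUS
            )
            if first_a > non_prev_a:
                raise FixtureConstructionError(
                    f"action {a.value}: {first_a} first-position transitions but only "
                    f"{non_prev_a} non-'previous' combinations (a session's first "
                    "transition can never revisit a previous profile)"
                )
        first_tot = sum(pos[(Position.FIRST, a)] for a in ActionCategory)
        last_tot = sum(pos[(Position.LAST, a)] for a in ActionCategory)
        if last_tot > first_tot:
            raise FixtureConstructionError("more last than first transitions")
        if first_tot > self.n_sessions:
            raise FixtureConstructionError(
                "more first transitions than sessions: every session has at most one"
            )


#: Published per-arm counts: combination cells (12, in ACTION_COMBOS
#: order) and position-by-action cells, with the arm session/search totals.
STUDY_FIXTURES: dict[Arm, FixtureSpec] = {
    Arm.RESOURCE: FixtureSpec(
        arm=Arm.RESOURCE,
        n_sessions=310,
        n_searches=1708,
        combo_counts=dict(
            zip(ACTION_COMBOS, (67, 193, 203, 94, 120, 18, 36, 28, 401, 83, 87, 68))
        ),
        position_action_counts={
            (Position.FIRST, ActionCategory.NO_CHANGE): 9,
            (Position.FIRST, ActionCategory.CHANGE_QUERY_ONLY): 115,
            (Position.FIRST, ActionCategory.CHANGE_PROFILE_ONLY): 82,
            (Position.FIRST, ActionCategory.CHANGE_QUERY_AND_PROFILE): 57,
            (Position.MIDDLE, ActionCategory.NO_CHANGE): 47,
            (Position.MIDDLE, ActionCategory.CHANGE_QUERY_ONLY): 303,
            (Position.MIDDLE, ActionCategory.CHANGE_PROFILE_ONLY): 359,
            (Position.MIDDLE, ActionCategory.CHANGE_QUERY_AND_PROFILE): 204,
            (Position.LAST, ActionCategory.NO_CHANGE): 11,
            (Position.LAST, ActionCategory.CHANGE_QUERY_ONLY): 72,
            (Position.LAST, ActionCategory.CHANGE_PROFILE_ONLY): 80,
            (Position.LAST, ActionCategory.CHANGE_QUERY_AND_PROFILE): 59,
        },
        profile_vocabulary=RESOURCE_PROFILES,
    ),
    Arm.TASK: FixtureSpec(
        arm=Arm.TASK,
        n_sessions=288,
        n_searches=873,
        combo_counts=dict(
            zip(ACTION_COMBOS, (74, 99, 123, 83, 16, 10, 17, 12, 54, 28, 39, 30))
        ),
        position_action_counts={
            (Position.FIRST, ActionCategory.NO_CHANGE): 31,
            (Position.FIRST, ActionCategory.CHANGE_QUERY_ONLY): 100,
            (Position.FIRST, ActionCategory.CHANGE_PROFILE_ONLY): 24,
            (Position.FIRST, ActionCategory.CHANGE_QUERY_AND_PROFILE): 34,
            (Position.MIDDLE, ActionCategory.NO_CHANGE): 32,
            (Position.MIDDLE, ActionCategory.CHANGE_QUERY_ONLY): 144,
            (Position.MIDDLE, ActionCategory.CHANGE_PROFILE_ONLY): 34,
            (Position.MIDDLE, ActionCategory.CHANGE_QUERY_AND_PROFILE): 57,
            (Position.LAST, ActionCategory.NO_CHANGE): 11,
            (Position.LAST, ActionCategory.CHANGE_QUERY_ONLY): 61,
            (Position.LAST, ActionCategory.CHANGE_PROFILE_ONLY): 12,
            (Position.LAST, ActionCategory.CHANGE_QUERY_AND_PROFILE): 45,
        },
        profile_vocabulary=TASK_PROFILES,
    ),
}


class _Pool:
    """A position's multiset of pending (profile code, reformulation) items."""

    def __init__(self, items: Iterable[tuple[ProfileCode, ReformulationType]]):
        self.counts: dict[tuple[ProfileCode, ReformulationType], int] = {}
        for it in items:
            self.counts[it] = self.counts.get(it, 0) + 1

    def total(self, pc: ProfileCode | None = None) -> int:
        return sum(
            v for (p, _), v in self.counts.items() if pc is None or p is pc
        )

    def take(self, pc: ProfileCode) -> tuple[ProfileCode, ReformulationType]:
        """Remove and return the most numerous item with the given profile
        code (ties broken by combination order)."""
        best = None
        for combo in ACTION_COMBOS:
            if combo[0] is pc and self.counts.get(combo, 0) > 0:
                if best is None or self.counts[combo] > self.counts[best]:
                    best = combo
        if best is None:
            raise FixtureConstructionError(f"pool has no {pc.value} item left")
        self.counts[best] -= 1
        return best


def _draw(
    pool: _Pool,
    history: list[str],
    n_profiles: int,
    prev_remaining: int,
) -> tuple[ProfileCode, ReformulationType]:
    """Pick the next item from a position pool.

    Preference order: drain ``previous`` items as soon as the session can
    host them; place a ``new`` item early when undrained ``previous``
    items still need future hosts; otherwise balance across profile-code
    classes (largest remaining first) subject to history feasibility.
    """
    distinct = len(set(history))
    can_prev = distinct >= 2
    can_new = distinct < n_profiles
    if can_prev and pool.total(ProfileCode.PREVIOUS) > 0:
        return pool.take(ProfileCode.PREVIOUS)
    if prev_remaining > 0 and not can_prev and can_new and pool.total(ProfileCode.NEW) > 0:
        return pool.take(ProfileCode.NEW)
    candidates = [
        pc
        for pc in (ProfileCode.SAME, ProfileCode.NEW)
        if pool.total(pc) > 0 and (pc is not ProfileCode.NEW or can_new)
    ]
    if not candidates:
        raise FixtureConstructionError(
            "no feasible item left in pool (profile vocabulary exhausted for this session)"
        )
    pc = max(candidates, key=lambda c: pool.total(c))
    return pool.take(pc)


def fixture_from_counts(spec: FixtureSpec) -> StudyLog:
    """Deterministically assemble a log whose coded tables equal ``spec``.

    Sessions are laid out from the position marginals: ``first − last``
    single-transition sessions, ``last`` multi-transition sessions with
    middle transitions spread round-robin, and the remainder as
    single-search sessions.  Items are dealt from per-position pools with
    ``previous`` revisits scheduled after a ``new`` selection in the same
    session.  The result is verified by recoding before it is returned.
    """
    spec.validate()
    combo = {c: int(spec.combo_counts.get(c, 0)) for c in ACTION_COMBOS}
    pos = {
        (p, a): int(spec.position_action_counts.get((p, a), 0))
        for p in Position
        for a in ActionCategory
    }

    # Split each action's combination cells across positions: first
    # positions take new-profile cells (then same), middles absorb all
    # 'previous' cells, the rest fills middle then last.
    pool_items: dict[Position, list[tuple[ProfileCode, ReformulationType]]] = {
        p: [] for p in Position
    }
    for a in ActionCategory:
        cells = [c for c in ACTION_COMBOS if _action_of(*c) is a]
        expand = lambda pcs: [
            c for c in cells if c[0] in pcs for _ in range(combo[c])
        ]
        non_prev = expand({ProfileCode.NEW}) + expand({ProfileCode.SAME})
        prev_items = expand({ProfileCode.PREVIOUS})
        f, m, l = pos[(Position.FIRST, a)], pos[(Position.MIDDLE, a)], pos[(Position.LAST, a)]
        first_items = non_prev[:f]
        rest = non_prev[f:]
        take_mid = max(0, m - len(prev_items))
        middle_items = prev_items[:m] + rest[:take_mid]
        last_items = prev_items[m:] + rest[take_mid:]
        if len(last_items) != l:  # guaranteed by validate(), kept as a guard
            raise FixtureConstructionError(f"position split failed for action {a.value}")
        pool_items[Position.FIRST] += first_items
        pool_items[Position.MIDDLE] += middle_items
        pool_items[Position.LAST] += last_items

    pools = {p: _Pool(items) for p, items in pool_items.items()}

    first_tot = sum(pos[(Position.FIRST, a)] for a in ActionCategory)
    last_tot = sum(pos[(Position.LAST, a)] for a in ActionCategory)
    middle_tot = sum(pos[(Position.MIDDLE, a)] for a in ActionCategory)
    n_multi = last_tot
    n_single = first_tot - last_tot
    n_zero = spec.n_sessions - first_tot
    base_mid, extra_mid = (divmod(middle_tot, n_multi)) if n_multi else (0, 0)
    if n_multi == 0 and middle_tot > 0:
        raise FixtureConstructionError("middle transitions require multi-transition sessions")

    session_shapes: list[list[Position]] = []
    for s in range(n_multi):
        mids = base_mid + (1 if s < extra_mid else 0)
        session_shapes.append(
            [Position.FIRST] + [Position.MIDDLE] * mids + [Position.LAST]
        )
    session_shapes += [[Position.FIRST]] * n_single
    session_shapes += [[]] * n_zero

    subtype_cycle = itertools.cycle(list(SyntacticSubtype))
    rng = np.random.default_rng(0)  # fixed stream: builder output is deterministic
    sessions: list[SearchSession] = []
    for s_idx, shape in enumerate(session_shapes):
        pid = f"{spec.arm.value}-p{s_idx // 8 + 1:02d}"
        sid = f"{pid}-q{s_idx % 8 + 1}-{s_idx}"
        profile = spec.profile_vocabulary[0]
        keywords = {
            "disease": f"{spec.keyword_vocabulary[0]} {spec.keyword_vocabulary[1]}",
            "drug": spec.keyword_vocabulary[2],
            "symptom": "",
            "other": "",
        }
        events = [
            SearchEvent(
                participant_id=pid,
                session_id=sid,
                arm=spec.arm,
                seq_index=1,
                profile=profile,
                keywords=keywords,
            )
        ]
        history = [profile]
        for k, position in enumerate(shape):
            prev_remaining = sum(p.total(ProfileCode.PREVIOUS) for p in pools.values())
            pc, rt = _draw(pools[position], history, len(spec.profile_vocabulary), prev_remaining)
            profile = _next_profile(pc, history, spec.profile_vocabulary, None)
            if rt in (ReformulationType.SYNTACTIC_ONLY, ReformulationType.SYNTACTIC_AND_SEMANTIC):
                keywords = _realize_round_robin(
                    keywords, rt, subtype_cycle, spec.keyword_vocabulary, rng
                )
            else:
                keywords = realize_query_edit(
                    keywords, rt, vocabulary=spec.keyword_vocabulary, rng=rng
                )
            history.append(profile)
            events.append(
                SearchEvent(
                    participant_id=pid,
                    session_id=sid,
                    arm=spec.arm,
                    seq_index=k + 2,
                    profile=profile,
                    keywords=keywords,
                )
            )
        sessions.append(
            SearchSession(session_id=sid, participant_id=pid, arm=spec.arm, events=tuple(events))
        )

    log = StudyLog(sessions=tuple(sessions))
    _verify_fixture(log, combo, pos)
    return log


def _realize_round_robin(
    keywords: dict[str, str],
    rt: ReformulationType,
    subtype_cycle,
    vocabulary: Sequence[str],
    rng: np.random.Generator,
) -> dict[str, str]:
    """Realize a syntactic(-and-semantic) edit, choosing the subtype
    round-robin and skipping currently infeasible ones."""
    last_err: RealizationError | None = None
    for _ in range(len(SyntacticSubtype)):
        cand = next(subtype_cycle)
        try:
            return realize_query_edit(keywords, rt, cand, vocabulary=vocabulary, rng=rng)
        except RealizationError as exc:
            last_err = exc
    raise FixtureConstructionError(f"no syntactic subtype is feasible: {last_err}")


def _verify_fixture(log: StudyLog, combo: dict, pos: dict) -> None:
    from .transition_coder import code_log

    transitions = code_log(log)
    got_combo: dict = {c: 0 for c in combo}
    got_pos: dict = {k: 0 for k in pos}
    for t in transitions:
        got_combo[(t.profile_code, t.query_code.value)] += 1
        got_pos[(t.position, t.action)] += 1
    if got_combo != combo or got_pos != pos:
        bad = {k: (got_combo[k], combo[k]) for k in combo if got_combo[k] != combo[k]}
        bad.update({k: (got_pos[k], pos[k]) for k in pos if got_pos[k] != pos[k]})
        raise FixtureConstructionError(f"fixture self-check failed, (got, want) per cell: {bad}")


def study_fixture_log(arms: Sequence[Arm] = (Arm.RESOURCE, Arm.TASK)) -> StudyLog:
    """The two-arm fixture carrying the published counts, as one log."""
    sessions: list[SearchSession] = []
    for arm in arms:
        sessions.extend(fixture_from_counts(STUDY_FIXTURES[arm]).sessions)
    return StudyLog(sessions=tuple(sessions))
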