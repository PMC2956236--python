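"""Synthetic-log generator: closed-loop realization, determinism,
statistical recovery, and exact-fixture construction."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pytest

from searchcode import (
    Arm,
    Position,
    ProfileCode,
    ReformulationType,
    SyntacticSubtype,
    classify_query_reformulation,
)
from searchcode.synthetic import (
    ACTION_COMBOS,
    CLINICAL_VOCABULARY,
    STUDY_FIXTURES,
    BehaviorSpec,
    FixtureConstructionError,
    FixtureSpec,
    RealizationError,
    SpecError,
    breadth_first_spec,
    depth_first_spec,
    fixture_from_counts,
    generate_study_log,
    is_typographic_variant,
    realize_query_edit,
)
from searchcode.transition_coder import code_log, enumerate_transitions

from conftest import kw


class TestVocabulary:
    def test_tokens_pairwise_non_variant(self):
        toks = CLINICAL_VOCABULARY
        for i, a in enumerate(toks):
            for b in toks[i + 1 :]:
                assert a != b
                assert not is_typographic_variant(a, b), (a, b)


class TestRealizeQueryEdit:
    BASE = kw("asthma spacer", drug="nicotine")

    @pytest.mark.parametrize("subtype", list(SyntacticSubtype))
    def test_each_syntactic_subtype_realizes_exactly(self, subtype):
        new = realize_query_edit(self.BASE, ReformulationType.SYNTACTIC_ONLY, subtype)
        code = classify_query_reformulation(self.BASE, new)
        assert code.value is ReformulationType.SYNTACTIC_ONLY
        assert code.subtypes == {subtype}

    def test_semantic_add_realizes(self):
        new = realize_query_edit(self.BASE, ReformulationType.SEMANTIC_ONLY)
        assert classify_query_reformulation(self.BASE, new).value is ReformulationType.SEMANTIC_ONLY

    def test_combined_target_realizes(self):
        new = realize_query_edit(
            self.BASE, ReformulationType.SYNTACTIC_AND_SEMANTIC, SyntacticSubtype.WORD_ORDER
        )
        code = classify_query_reformulation(self.BASE, new)
        assert code.value is ReformulationType.SYNTACTIC_AND_SEMANTIC
        assert code.subtypes == {SyntacticSubtype.WORD_ORDER}

    def test_no_change_returns_equal_map(self):
        assert realize_query_edit(self.BASE, ReformulationType.NONE) == dict(self.BASE)

    def test_word_order_infeasible_on_single_token(self):
        with pytest.raises(RealizationError):
            realize_query_edit(
                kw("asthma"), ReformulationType.SYNTACTIC_ONLY, SyntacticSubtype.WORD_ORDER
            )


def _small_spec(**overrides):
    spec = depth_first_spec(seed=overrides.pop("seed", 0))
    return replace(spec, n_participants=4, **overrides)


class TestGenerator:
    def test_same_seed_reproduces_identical_log(self):
        spec = _small_spec(seed=9)
        assert generate_study_log(spec) == generate_study_log(spec)

    def test_different_seeds_differ(self):
        assert generate_study_log(_small_spec(seed=1)) != generate_study_log(_small_spec(seed=2))

    def test_degenerate_spec_yields_only_no_change(self):
        probs = {c: 0.0 for c in ACTION_COMBOS}
        probs[(ProfileCode.SAME, ReformulationType.NONE)] = 1.0
        spec = _small_spec(
            action_probs=probs,
            sessions_per_participant=1,
            session_length_law=("fixed", 3),
        )
        log = generate_study_log(spec)
        for session in log.sessions:
            for t in enumerate_transitions(session):
                assert t.profile_code is ProfileCode.SAME
                assert t.query_code.value is ReformulationType.NONE

    def test_invalid_probability_vector_rejected(self):
        probs = {c: 1.0 for c in ACTION_COMBOS}  # sums to 12
        with pytest.raises(SpecError):
            generate_study_log(_small_spec(action_probs=probs))

    def test_tiny_vocabulary_rejected(self):
        with pytest.raises(SpecError):
            generate_study_log(_small_spec(keyword_vocabulary=("asthma", "spacer")))

    def test_closed_loop_recovery_is_exact(self):
        """Pipeline codes equal generator-intended codes, transition for
        transition, on a session driven through the public realization API."""
        rng = np.random.default_rng(123)
        profiles = ["A", "B", "C", "D", "E", "F"]
        from searchcode import SearchEvent, SearchSession

        intended = []
        keywords = kw("asthma spacer", drug="nicotine")
        history = ["A"]
        events = [
            SearchEvent(
                participant_id="p",
                session_id="s",
                arm=Arm.RESOURCE,
                seq_index=1,
                profile="A",
                keywords=keywords,
            )
        ]
        for i in range(2, 40):
            distinct = set(history)
            feasible = [
                (pc, rt)
                for pc, rt in ACTION_COMBOS
                if (pc is not ProfileCode.PREVIOUS or len(distinct) >= 2)
                and (pc is not ProfileCode.NEW or len(distinct) < len(profiles))
            ]
            pc, rt = feasible[int(rng.integers(len(feasible)))]
            if pc is ProfileCode.SAME:
                profile = history[-1]
            elif pc is ProfileCode.PREVIOUS:
                profile = [p for p in history if p != history[-1]][0]
            else:
                profile = [p for p in profiles if p not in distinct][0]
            keywords = realize_query_edit(keywords, rt, rng=rng)
            intended.append((pc, rt))
            history.append(profile)
            events.append(
                SearchEvent(
                    participant_id="p",
                    session_id="s",
                    arm=Arm.RESOURCE,
                    seq_index=i,
                    profile=profile,
                    keywords=keywords,
                )
            )
        session = SearchSession(
            session_id="s", participant_id="p", arm=Arm.RESOURCE, events=tuple(events)
        )
        coded = [(t.profile_code, t.query_code.value) for t in enumerate_transitions(session)]
        assert coded == intended

    def test_high_new_profile_mass_makes_profile_change_modal_mid_session(self):
        probs = {c: 0.4 / 11 for c in ACTION_COMBOS}
        probs[(ProfileCode.NEW, ReformulationType.NONE)] = 0.6
        log = generate_study_log(replace(breadth_first_spec(seed=17), action_probs=probs))
        from searchcode import ActionCategory, build_table

        ts = code_log(log)
        mid = build_table(ts, "position_by_action")[Position.MIDDLE]
        counts = {lab: int(c) for lab, c in zip(mid.row_labels, mid.counts[:, 0])}
        assert max(counts, key=counts.get) == ActionCategory.CHANGE_PROFILE_ONLY.value

    def test_statistical_recovery_within_three_se(self):
        """Empirical action frequencies match spec probabilities at the
        fully feasible transitions (where no renormalization applies)."""
        spec = replace(
            breadth_first_spec(seed=3),
            n_participants=150,
            session_length_law=("fixed", 8),
        )
        log = generate_study_log(spec)
        observed = []
        for session in log.sessions:
            profiles = [e.profile for e in session.events]
            for t in enumerate_transitions(session):
                distinct = len(set(profiles[: t.index]))
                if 2 <= distinct < len(spec.profile_vocabulary):
                    observed.append((t.profile_code, t.query_code.value))
        n = len(observed)
        assert n >= 5000
        counts = Counter(observed)
        for combo in ACTION_COMBOS:
            p = spec.action_probs[combo]
            se = (p * (1 - p) / n) ** 0.5
            assert abs(counts[combo] / n - p) <= 3 * se, combo


class TestFixtureBuilder:
    def test_study_counts_reproduced_exactly(self, study_log):
        from searchcode import build_table

        ts = code_log(study_log)
        combo = build_table(ts, "combo")
        assert list(combo.column("resource")) == [67, 193, 203, 94, 120, 18, 36, 28, 401, 83, 87, 68]
        assert list(combo.column("task")) == [74, 99, 123, 83, 16, 10, 17, 12, 54, 28, 39, 30]
        pos = build_table(ts, "position_by_action")
        assert list(pos[Position.FIRST].column("resource")) == [9, 115, 82, 57]
        assert list(pos[Position.MIDDLE].column("resource")) == [47, 303, 359, 204]
        assert list(pos[Position.LAST].column("resource")) == [11, 72, 80, 59]
        assert list(pos[Position.FIRST].column("task")) == [31, 100, 24, 34]
        assert list(pos[Position.MIDDLE].column("task")) == [32, 144, 34, 57]
        assert list(pos[Position.LAST].column("task")) == [11, 61, 12, 45]

    def test_builder_is_deterministic(self):
        a = fixture_from_counts(STUDY_FIXTURES[Arm.TASK])
        b = fixture_from_counts(STUDY_FIXTURES[Arm.TASK])
        assert a == b

    def test_inconsistent_total_rejected(self):
        spec = STUDY_FIXTURES[Arm.TASK]
        bad = replace(spec, n_searches=spec.n_searches + 1)
        with pytest.raises(FixtureConstructionError):
            fixture_from_counts(bad)

    def test_position_marginal_mismatch_rejected(self):
        spec = STUDY_FIXTURES[Arm.TASK]
        pos = dict(spec.position_action_counts)
        from searchcode import ActionCategory

        pos[(Position.FIRST, ActionCategory.NO_CHANGE)] += 1
        with pytest.raises(FixtureConstructionError):
            fixture_from_counts(replace(spec, position_action_counts=pos))

    def test_small_handmade_fixture(self):
        """A tiny consistent spec builds and recodes exactly."""
        from searchcode import ActionCategory

        combo = {c: 0 for c in ACTION_COMBOS}
        combo[(ProfileCode.NEW, ReformulationType.NONE)] = 2
        combo[(ProfileCode.SAME, ReformulationType.SEMANTIC_ONLY)] = 2
        combo[(ProfileCode.PREVIOUS, ReformulationType.NONE)] = 1
        pos = {
            (Position.FIRST, ActionCategory.CHANGE_PROFILE_ONLY): 1,
            (Position.MIDDLE, ActionCategory.CHANGE_PROFILE_ONLY): 2,
            (Position.MIDDLE, ActionCategory.CHANGE_QUERY_ONLY): 1,
            (Position.LAST, ActionCategory.CHANGE_QUERY_ONLY): 1,
        }
        spec = FixtureSpec(
            arm=Arm.RESOURCE,
            n_sessions=2,
            n_searches=7,
            combo_counts=combo,
            position_action_counts=pos,
        )
        log = fixture_from_counts(spec)  # internal self-check recodes it
        assert log.n_sessions == 2 and log.n_searches == 7
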