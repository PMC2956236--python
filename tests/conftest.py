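import pytest

from searchcode import Arm, SearchEvent, SearchSession, StudyLog
from searchcode.synthetic import study_fixture_log


def kw(disease="", drug="", symptom="", other=""):
    return {"disease": disease, "drug": drug, "symptom": symptom, "other": other}


def make_session(profiles, keyword_maps, session_id="s1", participant_id="p1", arm=Arm.RESOURCE):
    """Build a session from parallel lists of profiles and keyword maps."""
    assert len(profiles) == len(keyword_maps)
    events = tuple(
        SearchEvent(
            participant_id=participant_id,
            session_id=session_id,
            arm=arm,
            seq_index=i + 1,
            profile=p,
            keywords=k,
        )
        for i, (p, k) in enumerate(zip(profiles, keyword_maps))
    )
    return SearchSession(
        session_id=session_id, participant_id=participant_id, arm=arm, events=events
    )


@pytest.fixture
def two_event_log():
    s = make_session(["PubMed", "PubMed"], [kw("asthma"), kw("asthma child")])
    return StudyLog(sessions=(s,))


@pytest.fixture(scope="session")
def study_log():
    """Two-arm fixture log carrying the published counts; built once."""
    return study_fixture_log()
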