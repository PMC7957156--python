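"""Outcome classification, biomarker labelling, and state-history building."""

import datetime as dt

import pytest

from conftest import REFERENCE_DATE, hand_traced_programs, program, trial
from trialpath.records import (
    BiomarkerLabel,
    OutcomeStatus,
    StateObservation,
    build_state_history,
    classify_biomarker_status,
    classify_phase_outcome,
    program_biomarker_flag,
)


@pytest.mark.parametrize(
    "prog,meta",
    hand_traced_programs(),
    ids=[p.drug_id for p, _ in hand_traced_programs()],
)
def test_phase_outcomes_match_hand_trace(prog, meta):
    for phase, expected in meta["expected"].items():
        out = classify_phase_outcome(prog, phase, REFERENCE_DATE)
        assert out.status is expected, (prog.drug_id, phase)


@pytest.mark.parametrize(
    "prog,meta",
    hand_traced_programs(),
    ids=[p.drug_id for p, _ in hand_traced_programs()],
)
def test_state_history_terminal_state(prog, meta):
    history = build_state_history(prog, REFERENCE_DATE)
    last = history[-1]
    if isinstance(meta["terminal"], frozenset):
        assert last.censor_set == meta["terminal"]
    else:
        assert last.state == meta["terminal"]
    # invariants: strictly increasing times, first observation at t=0
    times = [o.time for o in history]
    assert times == sorted(times) and len(set(times)) == len(times)
    assert times[0] == 0.0
    assert history[0].state == min(prog.states_attempted())


def test_history_roundtrips_phase_outcomes(traced_programs):
    """Reading the last transient state off the history reproduces the
    per-phase classification for every attempted phase."""
    for prog, meta in traced_programs:
        history = build_state_history(prog, REFERENCE_DATE)
        observed_states = [o.state for o in history if o.state is not None]
        for phase, expected in meta["expected"].items():
            if expected is OutcomeStatus.success and phase < 3:
                assert phase + 1 in observed_states
        if any(v is OutcomeStatus.failure for v in meta["expected"].values()):
            assert observed_states[-1] == 5
        if meta["expected"].get(3) is OutcomeStatus.success:
            assert observed_states[-1] == 4


def test_monotone_censoring(traced_programs):
    """Moving the data-collection date later can resolve an ongoing phase
    but never flips success<->failure."""
    later = REFERENCE_DATE + dt.timedelta(days=1500)
    for prog, meta in traced_programs:
        for phase in meta["expected"]:
            before = classify_phase_outcome(prog, phase, REFERENCE_DATE).status
            after = classify_phase_outcome(prog, phase, later).status
            if before is OutcomeStatus.success:
                assert after is OutcomeStatus.success
            elif before is OutcomeStatus.failure:
                assert after is OutcomeStatus.failure
            else:
                assert after in OutcomeStatus


def test_phase_absent_raises():
    prog = program("p", [trial("t", "I", "2010-01-01", "2011-01-01")])
    with pytest.raises(ValueError, match="no trial at phase"):
        classify_phase_outcome(prog, 3, REFERENCE_DATE)


def test_future_dated_trial_rejected():
    prog = program("p", [trial("t", "I", "2010-01-01", "2018-01-01")])
    with pytest.raises(ValueError, match="after reference_date"):
        classify_phase_outcome(prog, 1, REFERENCE_DATE)


def test_completion_before_start_rejected():
    with pytest.raises(ValueError, match="precedes"):
        trial("t", "I", "2012-01-01", "2011-01-01")


@pytest.mark.parametrize(
    "approval,usage,expected",
    [
        (None, "2014-01-01", BiomarkerLabel.exploratory),       # never approved
        ("2012-06-01", "2013-06-01", BiomarkerLabel.exploratory),  # 1 year after
        ("2008-01-01", "2013-01-01", BiomarkerLabel.validated),  # 5 years after
        ("2012-01-02", "2014-01-01", BiomarkerLabel.exploratory),  # 730 days: within
        ("2012-01-01", "2014-01-01", BiomarkerLabel.validated),  # 731 days: beyond
    ],
)
def test_biomarker_validation_window(approval, usage, expected):
    registry = {}
    if approval is not None:
        registry[("HER2", "breast")] = dt.date.fromisoformat(approval)
    status = classify_biomarker_status(
        "HER2", "breast", dt.date.fromisoformat(usage), registry
    )
    assert status.label is expected


def test_biomarker_none_and_indication_specific():
    registry = {("HER2", "breast"): dt.date(2000, 1, 1)}
    assert classify_biomarker_status(
        None, "breast", dt.date(2014, 1, 1), registry
    ).label is BiomarkerLabel.none
    # approval in another indication does not validate this one
    assert classify_biomarker_status(
        "HER2", "colorectal", dt.date(2014, 1, 1), registry
    ).label is BiomarkerLabel.exploratory


def test_drug_level_biomarker_rules():
    mixed = program("m", [
        trial("t1", "I", "2010-01-01", "2011-01-01", biomarker=True),
        trial("t2", "II", "2011-06-01", biomarker=False),
    ])
    assert program_biomarker_flag(mixed, "any") is True
    assert program_biomarker_flag(mixed, "all") is False


def test_observation_validation():
    with pytest.raises(ValueError):
        StateObservation("d", -1.0, state=1)
    with pytest.raises(ValueError):
        StateObservation("d", 1.0)  # neither state nor censor set
    with pytest.raises(ValueError):
        StateObservation("d", 1.0, state=1, censor_set=frozenset({2}))


def test_nonmonotone_dates_rejected():
    prog = program("p", [
        trial("t1", "I", "2012-01-01", "2013-01-01"),
        trial("t2", "II", "2012-01-01"),
    ])
    with pytest.raises(ValueError, match="strictly"):
        build_state_history(prog, REFERENCE_DATE)
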