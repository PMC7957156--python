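"""Shared fixtures: hand-constructed drug programs with hand-traced
expected classifications, and small helpers for building models."""

from __future__ import annotations

import datetime as dt
from typing import List, Optional, Tuple

import pytest

from trialpath.records import (
    DrugProgram,
    Indication,
    OutcomeStatus,
    Phase,
    TrialRecord,
)

REFERENCE_DATE = dt.date(2017, 1, 2)


def trial(
    tid: str,
    phase: str,
    start: str,
    completion: Optional[str] = None,
    indication: str = "breast",
    biomarker: bool = False,
    biomarker_ids: Tuple[str, ...] = (),
) -> TrialRecord:
    return TrialRecord(
        trial_id=tid,
        phase=Phase(phase),
        start_date=dt.date.fromisoformat(start),
        completion_date=dt.date.fromisoformat(completion) if completion else None,
        indication=Indication(indication),
        uses_biomarker_selection=biomarker,
        biomarker_ids=biomarker_ids,
    )


def program(drug_id: str, trials, **kw) -> DrugProgram:
    ind = trials[0].indication
    return DrugProgram(drug_id=drug_id, indication=ind, trials=tuple(trials), **kw)


def hand_traced_programs() -> List[Tuple[DrugProgram, dict]]:
    """Programs covering every classification rule, each with the expected
    status per attempted phase (worked out by hand from the rules) and the
    expected terminal state of the panel history (4, 5, or a censor set)."""
    S, F, O = OutcomeStatus.success, OutcomeStatus.failure, OutcomeStatus.ongoing
    cases = []

    # advanced I -> II, phase II trial still running (no completion date)
    cases.append((
        program("adv-ongoing", [
            trial("t1", "I", "2010-01-01", "2011-01-01"),
            trial("t2", "II", "2011-06-01"),
        ]),
        {"expected": {1: S, 2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    # full run to approval
    cases.append((
        program("approved", [
            trial("t1", "I", "2008-01-01", "2009-06-01"),
            trial("t2", "II", "2010-01-01", "2011-06-01"),
            trial("t3", "III", "2012-01-01", "2014-01-01"),
        ], fda_approved=True, approval_date=dt.date(2015, 3, 1)),
        {"expected": {1: S, 2: S, 3: S}, "terminal": 4},
    ))
    # two-year inactivity after the Phase II trial completed
    cases.append((
        program("inactive-II", [
            trial("t1", "I", "2009-01-01", "2010-01-01"),
            trial("t2", "II", "2010-06-01", "2013-01-01"),
        ]),
        {"expected": {1: S, 2: F}, "terminal": 5},
    ))
    # withdrawn by the manufacturer during Phase I (inside the 2-year window)
    cases.append((
        program("withdrawn-I", [
            trial("t1", "I", "2014-01-01", "2016-06-01"),
        ], withdrawn_by_manufacturer=True),
        {"expected": {1: F}, "terminal": 5},
    ))
    # missed primary endpoints in Phase III, no approval
    cases.append((
        program("endpoint-III", [
            trial("t1", "I", "2008-01-01", "2009-01-01"),
            trial("t2", "II", "2009-06-01", "2011-01-01"),
            trial("t3", "III", "2011-06-01", "2014-06-01"),
        ], failed_primary_endpoint=True),
        {"expected": {1: S, 2: S, 3: F}, "terminal": 5},
    ))
    # only trial completed six months before data collection: ongoing
    cases.append((
        program("recent-II", [
            trial("t1", "II", "2014-01-01", "2016-07-02"),
        ]),
        {"expected": {2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    # combined Phase I/II trial counts as Phase I; II exists so I succeeded
    cases.append((
        program("combined-I-II", [
            trial("t1", "I_II", "2011-01-01", "2012-06-01"),
            trial("t2", "II", "2013-01-01"),
        ]),
        {"expected": {1: S, 2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    # program entering mid-stream at Phase II
    cases.append((
        program("midstream-II", [
            trial("t1", "II", "2015-01-01"),
        ]),
        {"expected": {2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    # Phase III complete, awaiting an FDA decision: III ongoing, earlier success
    cases.append((
        program("awaiting-decision", [
            trial("t1", "I", "2009-01-01", "2010-01-01"),
            trial("t2", "II", "2010-06-01", "2012-01-01"),
            trial("t3", "III", "2012-06-01", "2016-01-02"),
        ]),
        {"expected": {1: S, 2: S, 3: O}, "terminal": frozenset({3, 4})},
    ))
    # inactivity boundary: completion exactly 730 days before the reference
    # date is still within the window -> ongoing
    cases.append((
        program("boundary-in", [
            trial("t1", "II", "2013-01-01", "2015-01-03"),
        ]),
        {"expected": {2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    # one day beyond the window -> failure
    cases.append((
        program("boundary-out", [
            trial("t1", "II", "2013-01-01", "2015-01-02"),
        ]),
        {"expected": {2: F}, "terminal": 5},
    ))
    # multiple trials in one phase: earliest start is the entry, latest
    # completion drives the inactivity clock (2016 completion -> ongoing)
    cases.append((
        program("multi-trial-II", [
            trial("t1", "I", "2009-01-01", "2010-01-01"),
            trial("t2", "II", "2010-06-01", "2012-01-01"),
            trial("t3", "II", "2011-01-01", "2016-06-01"),
        ]),
        {"expected": {1: S, 2: O}, "terminal": frozenset({2, 3, 4})},
    ))
    return cases


@pytest.fixture(scope="session")
def traced_programs():
    return hand_traced_programs()
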