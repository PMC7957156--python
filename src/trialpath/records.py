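"""Domain types for drug-development programs and the deterministic rules
that turn raw trial records into multi-state panel histories.

A drug's trajectory through clinical testing is summarised as movement
through five states:

    1 = Phase I    2 = Phase II    3 = Phase III
    4 = Approved   5 = Failed      (4 and 5 absorbing)

Outcome classification is rule-based and fully deterministic:

* a phase is *successful* if the drug has a trial record at the next
  phase (for Phase III: FDA approval);
* a phase is a *failure* if more than two years have passed since the
  last trial at that phase completed with no further development, or the
  manufacturer withdrew the drug, or the drug was declared to have
  missed its primary endpoints;
* otherwise the phase is *ongoing* and the drug's terminal state is
  right-censored over the states it could still occupy.

Predictive biomarkers used for patient enrolment or exclusion are
labelled ``exploratory`` until two years after the biomarker's first FDA
approval in the same indication, and ``validated`` afterwards.

Time is measured in years from the drug's first phase-entry date in the
indication; all intensities downstream are therefore per year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import FrozenSet, List, Mapping, Optional, Tuple, Union

__all__ = [
    "Phase",
    "Indication",
    "OutcomeStatus",
    "BiomarkerLabel",
    "TrialRecord",
    "DrugProgram",
    "PhaseOutcome",
    "BiomarkerStatus",
    "StateObservation",
    "STATE_PHASE_I",
    "STATE_PHASE_II",
    "STATE_PHASE_III",
    "STATE_APPROVED",
    "STATE_FAILED",
    "TRANSIENT_STATES",
    "ABSORBING_STATES",
    "DAYS_PER_YEAR",
    "INACTIVITY_WINDOW_DAYS",
    "VALIDATION_WINDOW_DAYS",
    "classify_phase_outcome",
    "classify_biomarker_status",
    "build_state_history",
    "program_biomarker_flag",
]

STATE_PHASE_I = 1
STATE_PHASE_II = 2
STATE_PHASE_III = 3
STATE_APPROVED = 4
STATE_FAILED = 5

TRANSIENT_STATES = (STATE_PHASE_I, STATE_PHASE_II, STATE_PHASE_III)
ABSORBING_STATES = (STATE_APPROVED, STATE_FAILED)

DAYS_PER_YEAR = 365.25
#: Calendar-exact two-year windows; a boundary date exactly on the window edge
#: counts as within the window.
INACTIVITY_WINDOW_DAYS = 730
VALIDATION_WINDOW_DAYS = 730


class Phase(str, Enum):
    """Trial phase. ``I_II`` combined-phase trials count as Phase I."""

    I = "I"
    I_II = "I_II"
    II = "II"
    III = "III"

    @property
    def state(self) -> int:
        """The model state this phase maps to (I/II counts as Phase I)."""
        return {"I": 1, "I_II": 1, "II": 2, "III": 3}[self.value]


class Indication(str, Enum):
    breast = "breast"
    colorectal = "colorectal"
    melanoma = "melanoma"
    nsclc = "nsclc"


class OutcomeStatus(str, Enum):
    success = "success"
    failure = "failure"
    ongoing = "ongoing"


class BiomarkerLabel(str, Enum):
    none = "none"
    exploratory = "exploratory"
    validated = "validated"


@dataclass(frozen=True)
class TrialRecord:
    """One registered clinical trial of a drug in one indication."""

    trial_id: str
    phase: Phase
    start_date: dt.date
    completion_date: Optional[dt.date]
    indication: Indication
    uses_biomarker_selection: bool = False
    biomarker_ids: Tuple[str, ...] = ()
    sponsor_industry: bool = True
    survival_endpoint: bool = True

    def __post_init__(self) -> None:
        if self.completion_date is not None and self.completion_date < self.start_date:
            raise ValueError(
                f"trial {self.trial_id}: completion_date {self.completion_date} "
                f"precedes start_date {self.start_date}"
            )


@dataclass(frozen=True)
class DrugProgram:
    """One drug's full development history in one indication.

    The sample unit throughout the package is the drug, not the trial.
    """

    drug_id: str
    indication: Indication
    trials: Tuple[TrialRecord, ...]
    fda_approved: bool = False
    approval_date: Optional[dt.date] = None
    withdrawn_by_manufacturer: bool = False
    failed_primary_endpoint: bool = False

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError(f"drug {self.drug_id}: program has no trials")
        if self.fda_approved and self.approval_date is None:
            raise ValueError(f"drug {self.drug_id}: approved but approval_date absent")

    def trials_at_state(self, state: int) -> Tuple[TrialRecord, ...]:
        return tuple(t for t in self.trials if t.phase.state == state)

    def states_attempted(self) -> Tuple[int, ...]:
        return tuple(sorted({t.phase.state for t in self.trials}))


@dataclass(frozen=True)
class PhaseOutcome:
    phase: int  # state 1, 2 or 3
    status: OutcomeStatus


@dataclass(frozen=True)
class BiomarkerStatus:
    label: BiomarkerLabel
    biomarker_id: Optional[str] = None


@dataclass(frozen=True)
class StateObservation:
    """A (drug, time, state-or-censoring-set) record for the panel likelihood.

    ``state`` is an exact state 1–5; a terminal observation of an ongoing
    program instead carries ``censor_set``, the set of states the drug may
    occupy at that time.
    """

    drug_id: str
    time: float
    state: Optional[int] = None
    censor_set: Optional[FrozenSet[int]] = None

    def __post_init__(self) -> None:
        if (self.state is None) == (self.censor_set is None):
            raise ValueError("exactly one of state / censor_set must be given")
        if self.time < 0:
            raise ValueError(f"negative observation time {self.time}")
        if self.state is not None and self.state not in range(1, 6):
            raise ValueError(f"state {self.state} outside 1..5")

    @property
    def is_censored(self) -> bool:
        return self.censor_set is not None


def _phase_name(state: int) -> str:
    return {1: "I", 2: "II", 3: "III"}[state]


def classify_phase_outcome(
    program: DrugProgram,
    phase: Union[int, Phase],
    reference_date: dt.date,
    inactivity_window_days: int = INACTIVITY_WINDOW_DAYS,
) -> PhaseOutcome:
    """Classify one development phase of a drug as success / failure / ongoing.

    Parameters
    ----------
    program
        The drug's development history.
    phase
        The phase to classify, as a state number (1–3) or :class:`Phase`.
    reference_date
        The data-collection date; the two-year inactivity clock and
        right-censoring are evaluated against it.
    inactivity_window_days
        Length of the no-further-development window after a trial's
        completion beyond which the drug is declared failed (calendar-exact;
        the boundary day still counts as within the window).

    Notes
    -----
    Success takes precedence (advancing to the next phase is observed
    directly); the drug-level failure flags and the inactivity rule are
    then checked; anything else is ongoing and contributes a censored
    terminal observation downstream.
    """
    state = phase.state if isinstance(phase, Phase) else int(phase)
    if state not in TRANSIENT_STATES:
        raise ValueError(f"phase must map to state 1..3, got {state}")

    here = program.trials_at_state(state)
    if not here:
        raise ValueError(
            f"drug {program.drug_id}: no trial at phase {_phase_name(state)}"
        )
    for t in here:
        for d in (t.start_date, t.completion_date):
            if d is not None and d > reference_date:
                raise ValueError(
                    f"drug {program.drug_id}: trial {t.trial_id} dated {d} "
                    f"after reference_date {reference_date}"
                )

    # Advancement: a later-phase trial exists (Phase III: FDA approval).
    if state == STATE_PHASE_III:
        if program.fda_approved:
            return PhaseOutcome(state, OutcomeStatus.success)
    else:
        later = [t for t in program.trials if t.phase.state > state]
        if later:
            return PhaseOutcome(state, OutcomeStatus.success)

    if program.withdrawn_by_manufacturer or program.failed_primary_endpoint:
        return PhaseOutcome(state, OutcomeStatus.failure)

    completions = [t.completion_date for t in here if t.completion_date is not None]
    if len(completions) < len(here):
        # A trial without a completion date is still running: ongoing.
        return PhaseOutcome(state, OutcomeStatus.ongoing)
    latest = max(completions)
    if (reference_date - latest).days > inactivity_window_days:
        return PhaseOutcome(state, OutcomeStatus.failure)
    return PhaseOutcome(state, OutcomeStatus.ongoing)


def classify_biomarker_status(
    biomarker_id: Optional[str],
    indication: Union[str, Indication],
    usage_date: dt.date,
    approval_registry: Mapping[Tuple[str, str], dt.date],
    validation_window_days: int = VALIDATION_WINDOW_DAYS,
) -> BiomarkerStatus:
    """Label a biomarker use as none / exploratory / validated.

    ``approval_registry`` maps ``(biomarker_id, indication)`` to the date of
    the biomarker's first FDA approval in that indication.  Use within the
    two-year window after that approval (inclusive of the boundary day), or
    with no approval on record, is exploratory; later use is validated.
    """
    if biomarker_id is None or biomarker_id == "":
        return BiomarkerStatus(BiomarkerLabel.none)
    ind = Indication(indication)
    approval = approval_registry.get((biomarker_id, ind.value))
    if approval is None:
        return BiomarkerStatus(BiomarkerLabel.exploratory, biomarker_id)
    if (usage_date - approval).days <= validation_window_days:
        return BiomarkerStatus(BiomarkerLabel.exploratory, biomarker_id)
    return BiomarkerStatus(BiomarkerLabel.validated, biomarker_id)


def program_biomarker_flag(program: DrugProgram, rule: str = "any") -> bool:
    """Drug-level biomarker indicator.

    ``rule='any'`` (default): the drug counts as biomarker-selected if any of
    its trials used a biomarker for enrolment or exclusion.  ``rule='all'``
    requires every trial to have done so.
    """
    flags = [t.uses_biomarker_selection for t in program.trials]
    if rule == "any":
        return any(flags)
    if rule == "all":
        return all(flags)
    raise ValueError(f"unknown biomarker rule {rule!r}")


def _years_between(later: dt.date, earlier: dt.date) -> float:
    return (later - earlier).days / DAYS_PER_YEAR


def build_state_history(
    program: DrugProgram,
    reference_date: dt.date,
    inactivity_window_days: int = INACTIVITY_WINDOW_DAYS,
) -> List[StateObservation]:
    """Translate a drug program into a panel-model state history.

    Emits one observation at each phase-entry date (the earliest start among
    the phase's trials), an Approved observation at the approval date, a
    Failed observation at the failing phase's last completion date, or — for
    programs still ongoing at ``reference_date`` — a terminal censored
    observation over {current phase, later transient phases, Approved}.

    The clock starts at the drug's first phase-entry date and runs in years.
    A drug first appearing at Phase II or III starts its history there.
    """
    attempted = program.states_attempted()
    entries = {}
    for s in attempted:
        entries[s] = min(t.start_date for t in program.trials_at_state(s))
    origin = min(entries.values())

    prev_date: Optional[dt.date] = None
    obs: List[StateObservation] = []
    for s in attempted:
        d = entries[s]
        if prev_date is not None and d <= prev_date:
            raise ValueError(
                f"drug {program.drug_id}: phase-entry dates not strictly "
                f"increasing ({prev_date} then {d})"
            )
        obs.append(StateObservation(program.drug_id, _years_between(d, origin), state=s))
        prev_date = d

    last = attempted[-1]
    outcome = classify_phase_outcome(
        program, last, reference_date, inactivity_window_days
    )

    if outcome.status is OutcomeStatus.success:
        # Only Phase III can be the last attempted phase and still succeed
        # (earlier successes imply a later-phase trial exists).
        assert last == STATE_PHASE_III and program.approval_date is not None
        end, end_state = program.approval_date, STATE_APPROVED
    elif outcome.status is OutcomeStatus.failure:
        completions = [
            t.completion_date
            for t in program.trials_at_state(last)
            if t.completion_date is not None
        ]
        # The failure event is pinned to the failing phase's last trial
        # completion; the two-year rule is a discovery delay, not an event
        # time.  Flag-based failures without any completion date fall back
        # to the reference date.
        end = max(completions) if completions else reference_date
        end_state = STATE_FAILED
    else:
        cset = frozenset(range(last, STATE_PHASE_III + 1)) | {STATE_APPROVED}
        t_cens = _years_between(reference_date, origin)
        if t_cens <= obs[-1].time:
            raise ValueError(
                f"drug {program.drug_id}: reference_date {reference_date} not "
                f"after the last phase entry"
            )
        obs.append(StateObservation(program.drug_id, t_cens, censor_set=cset))
        return obs

    t_end = _years_between(end, origin)
    if t_end <= obs[-1].time:
        raise ValueError(
            f"drug {program.drug_id}: terminal event date {end} not after the "
            f"last phase entry"
        )
    obs.append(StateObservation(program.drug_id, t_end, state=end_state))
    return obs
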