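"""Markov cycle machinery: replay pathways through cycles and tally occupancy.

The cohort model is a multistate transient model: every lymphadenopathy
starts cycle 1 in the state assigned by its first FNAC, and each
subsequent event (follow-up, repeat FNAC, surgical biopsy) closes one
cycle and opens the next.  Procedures move the node to the state of
their result; clinical follow-up leaves it where it is.  The engine is a
*replay* engine over recorded events — transition probabilities are
empirical counts, not sampled; sampling lives in :mod:`lnfnac.synth`.

Conclusion semantics
--------------------
The diagnostic process concludes at the cycle of the last *diagnostically
necessary* procedure:

* no procedures at all → concluded at cycle 1 (cytology sufficient for a
  malignant call; follow-up confirmed benignity otherwise);
* follow-up events never extend the process — they confirm a diagnosis
  already made, so a benign node that simply regresses under surveillance
  concludes at cycle 1;
* a *confirmatory* excision after an already-diagnostic malignant
  cytology (metastasis with identified primary, or relapse of a known
  lymphoma, with histology confirming malignancy) does not extend the
  process either: the diagnosis was available at cycle 1;
* otherwise the conclusion cycle is the cycle of the last repeat FNAC or
  surgical biopsy.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort import (
    CohortTallies,
    DiagnosticState,
    Event,
    EventKind,
    MalignantSubtype,
    PatientPathway,
    PROCEDURE_KINDS,
    StateLabel,
)

__all__ = [
    "TerminationRule",
    "ModelConfig",
    "ConclusionMode",
    "Trajectory",
    "advance",
    "run_model",
    "tally_cohort",
]


class TerminationRule(str, enum.Enum):
    """Diagnostic process ends on gold-standard histology, sufficient
    cytology, or follow-up-confirmed persistence in a benign state."""

    PERSIST_OR_GOLD = "persist_or_gold"


@dataclass(frozen=True)
class ModelConfig:
    max_cycles: int = 3
    termination_rule: TerminationRule = TerminationRule.PERSIST_OR_GOLD

    def __post_init__(self) -> None:
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


class ConclusionMode(str, enum.Enum):
    FNAC_SUFFICIENT = "fnac_sufficient"
    FOLLOW_UP_CONFIRMED = "follow_up_confirmed"
    HISTOLOGY = "histology"
    SECOND_FNAC = "second_fnac"


@dataclass(frozen=True)
class Trajectory:
    pathway_id: str
    states_per_cycle: tuple
    concluded_at_cycle: int
    conclusion_mode: ConclusionMode

    def __post_init__(self) -> None:
        if len(self.states_per_cycle) != self.concluded_at_cycle:
            raise ValueError("states_per_cycle must cover exactly the concluded cycles")


def advance(state: DiagnosticState, event: Event) -> DiagnosticState:
    """Apply one event to a state.

    Procedures (repeat FNAC, surgical biopsy) move the node to the state
    of their result; follow-up and no-event leave it unchanged.
    """
    if event.kind in PROCEDURE_KINDS:
        if event.result_state is None:  # Event validates this; belt and braces
            raise ValueError(f"{event.kind.value} event requires a result_state")
        return event.result_state
    return state


#: Malignant cytology subtypes for which FNAC (+ ancillary techniques) is a
#: sufficient final diagnosis, making any subsequent excision confirmatory.
_FNAC_SUFFICIENT_SUBTYPES = frozenset(
    {MalignantSubtype.METASTASIS_KNOWN_PRIMARY, MalignantSubtype.LYMPHOMA_RELAPSE}
)


def _is_confirmatory_course(pathway: PatientPathway) -> bool:
    """True when every recorded procedure is a biopsy confirming an
    already-sufficient malignant cytology diagnosis."""
    initial = pathway.initial_state
    if not initial.is_malignant:
        return False
    if initial.malignant_subtype not in _FNAC_SUFFICIENT_SUBTYPES:
        return False
    procedures = [e for e in pathway.events if e.kind in PROCEDURE_KINDS]
    return bool(procedures) and all(
        e.kind is EventKind.SURGICAL_BIOPSY and e.result_state.is_malignant
        for e in procedures
    )


def _conclude(pathway: PatientPathway) -> tuple:
    procedure_cycles = [
        cycle
        for cycle, e in enumerate(pathway.events, start=2)
        if e.kind in PROCEDURE_KINDS
    ]
    if not procedure_cycles or _is_confirmatory_course(pathway):
        if pathway.initial_state.is_malignant:
            return 1, ConclusionMode.FNAC_SUFFICIENT
        return 1, ConclusionMode.FOLLOW_UP_CONFIRMED
    last_cycle = procedure_cycles[-1]
    last_proc = pathway.events[last_cycle - 2]
    if last_proc.kind is EventKind.SURGICAL_BIOPSY:
        return last_cycle, ConclusionMode.HISTOLOGY
    return last_cycle, ConclusionMode.SECOND_FNAC


def run_model(
    cohort: Sequence[PatientPathway], config: ModelConfig = ModelConfig()
) -> list:
    """Replay every pathway through its cycles.

    Raises if any pathway carries more events than ``max_cycles − 1``
    post-initial cycles allow: the model has no semantics for a node
    still undiagnosed after the last cycle.
    """
    trajectories = []
    for p in cohort:
        if len(p.events) > config.max_cycles - 1:
            raise ValueError(
                f"pathway {p.id}: {len(p.events)} events exceed "
                f"max_cycles={config.max_cycles}"
            )
        states = [p.initial_state]
        for ev in p.events:
            states.append(advance(states[-1], ev))
        concluded_at, mode = _conclude(p)
        trajectories.append(
            Trajectory(
                pathway_id=p.id,
                states_per_cycle=tuple(states[:concluded_at]),
                concluded_at_cycle=concluded_at,
                conclusion_mode=mode,
            )
        )
    return trajectories


def tally_cohort(
    trajectories: Sequence[Trajectory], cohort: Sequence[PatientPathway]
) -> CohortTallies:
    """Aggregate a replayed cohort into machine-readable tallies.

    Trajectories and pathways must be aligned one-to-one by id.
    """
    if [t.pathway_id for t in trajectories] != [p.id for p in cohort]:
        raise ValueError("trajectories and cohort must be aligned by id")

    initial_counts: Counter = Counter()
    final_counts: Counter = Counter()
    sb_by_state: Counter = Counter()
    fnac_by_state: Counter = Counter()
    cycle_counts: Counter = Counter()
    n_repeat = n_sb_patients = n_sb_procedures = 0
    n_hist_mal = n_hist_ben = n_quiet = 0

    for t, p in zip(trajectories, cohort):
        label = p.initial_state.label
        initial_counts[label] += 1
        final_counts[p.final_state.label] += 1
        fnac_by_state[label] += p.n_fnac
        n_repeat += p.n_fnac - 1
        cycle_counts[t.concluded_at_cycle] += 1
        if p.n_sb_patient:
            n_sb_patients += 1
            n_sb_procedures += p.n_sb_procedures
            sb_by_state[label] += 1
            if p.sb_events[-1].result_state.is_malignant:
                n_hist_mal += 1
            else:
                n_hist_ben += 1
        if p.n_fnac == 1 and not p.n_sb_patient:
            n_quiet += 1

    n = len(cohort)
    return CohortTallies(
        n_lymphadenopathies=n,
        n_first_fnac=n,
        n_repeat_fnac=n_repeat,
        n_total_fnac=n + n_repeat,
        n_sb_patients=n_sb_patients,
        n_sb_procedures=n_sb_procedures,
        n_sb_histology_malignant=n_hist_mal,
        n_sb_histology_benign=n_hist_ben,
        n_no_escalation=n_quiet,
        initial_state_counts=dict(initial_counts),
        final_state_counts=dict(final_counts),
        per_state_sb_counts=dict(sb_by_state),
        per_state_fnac_counts=dict(fnac_by_state),
        conclusion_cycle_counts=dict(cycle_counts),
    )
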