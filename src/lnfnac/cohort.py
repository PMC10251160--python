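"""Domain types for lymph-node FNAC diagnostic pathways.

The unit of analysis throughout the package is the *lymphadenopathy* (a
single investigated lymph node), not the patient-person: one person can
contribute more than one node, and the procedure arithmetic (first
aspirates + repeats, biopsy counts) only closes at the node level.

A :class:`PatientPathway` records one lymphadenopathy's ordered sequence
of diagnostic procedures across model cycles: the first fine-needle
aspiration cytology (FNAC) result places the node in one of the four
Sydney System states (benign, ALUS, suspicious, malignant), and each
subsequent cycle may bring clinical follow-up, a repeat FNAC, or a
surgical excisional biopsy (SB).  The adjudicated truth is histology when
the node was excised and clinical follow-up otherwise (the composite
reference standard).

The module also ships :func:`reference_cohort`, a built-in cohort of 535
consecutive clinically suspicious lymphadenopathies (545 FNACs, 131
surgical biopsies) whose pathway-level disaggregation reproduces every
published tally of the series it encodes; it is the worked dataset used
by the documentation, the test-suite and the reproduction script.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "StateLabel",
    "MalignantSubtype",
    "DiagnosticState",
    "EventKind",
    "Event",
    "TruthLabel",
    "TruthSource",
    "PatientPathway",
    "CostSchedule",
    "CohortTallies",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "reference_cohort",
    "BENIGN",
    "ALUS",
    "SUSPICIOUS",
]


class StateLabel(str, enum.Enum):
    """Sydney System reporting category of a cytology/histology result."""

    BENIGN = "benign"
    ALUS = "alus"
    SUSPICIOUS = "suspicious"
    MALIGNANT = "malignant"


class MalignantSubtype(str, enum.Enum):
    """Subtype detail carried by malignant diagnoses.

    Metastases with an identified primary (clinically known or pinned
    down by immunocytochemistry) and relapses of a known lymphoma are the
    situations in which cytology alone is a sufficient final diagnosis;
    primary NHL/HL and metastases of unknown origin require histology.
    """

    METASTASIS_KNOWN_PRIMARY = "metastasis_known_primary"
    METASTASIS_UNKNOWN_PRIMARY = "metastasis_unknown_primary"
    NHL = "nhl"
    HL = "hl"
    LYMPHOMA_RELAPSE = "lymphoma_relapse"


@dataclass(frozen=True)
class DiagnosticState:
    """One of the four transient model states, with malignant subtype detail.

    ``malignant_subtype`` is present exactly when ``label`` is MALIGNANT.
    """

    label: StateLabel
    malignant_subtype: Optional[MalignantSubtype] = None

    def __post_init__(self) -> None:
        if self.label is StateLabel.MALIGNANT:
            if self.malignant_subtype is None:
                raise ValueError("malignant state requires a malignant_subtype")
        elif self.malignant_subtype is not None:
            raise ValueError(
                f"state {self.label.value!r} cannot carry a malignant_subtype"
            )

    @property
    def is_malignant(self) -> bool:
        return self.label is StateLabel.MALIGNANT

    @property
    def is_cytology_positive(self) -> bool:
        """Suspicious and malignant categories count as a positive call."""
        return self.label in (StateLabel.SUSPICIOUS, StateLabel.MALIGNANT)

    def token(self) -> str:
        """Serialise to the CSV token (``malignant:nhl``, ``benign`` ...)."""
        if self.malignant_subtype is not None:
            return f"{self.label.value}:{self.malignant_subtype.value}"
        return self.label.value

    @classmethod
    def from_token(cls, token: str) -> "DiagnosticState":
        head, _, sub = token.strip().lower().partition(":")
        try:
            label = StateLabel(head)
        except ValueError:
            raise ValueError(f"unknown state label {head!r}") from None
        subtype = None
        if sub:
            try:
                subtype = MalignantSubtype(sub)
            except ValueError:
                raise ValueError(f"unknown malignant subtype {sub!r}") from None
        elif label is StateLabel.MALIGNANT:
            raise ValueError(
                "malignant state token must carry a subtype, e.g. 'malignant:nhl'"
            )
        return cls(label, subtype)


#: Convenience singletons for the three subtype-free states.
BENIGN = DiagnosticState(StateLabel.BENIGN)
ALUS = DiagnosticState(StateLabel.ALUS)
SUSPICIOUS = DiagnosticState(StateLabel.SUSPICIOUS)


def malignant(subtype: MalignantSubtype) -> DiagnosticState:
    """Build a malignant state with the given subtype."""
    return DiagnosticState(StateLabel.MALIGNANT, subtype)


class EventKind(str, enum.Enum):
    FOLLOW_UP = "follow_up"
    REPEAT_FNAC = "repeat_fnac"
    SURGICAL_BIOPSY = "surgical_biopsy"
    NONE = "none"


#: Event kinds that produce a new diagnostic result (and hence may move
#: the node to a new state).
PROCEDURE_KINDS = (EventKind.REPEAT_FNAC, EventKind.SURGICAL_BIOPSY)


@dataclass(frozen=True)
class Event:
    """One per-cycle event: follow-up, repeat FNAC, or surgical biopsy.

    Repeat FNAC and SB carry the resulting diagnostic state; clinical
    follow-up carries none — the node remains in its current state.
    """

    kind: EventKind
    result_state: Optional[DiagnosticState] = None

    def __post_init__(self) -> None:
        if self.kind in PROCEDURE_KINDS:
            if self.result_state is None:
                raise ValueError(f"{self.kind.value} event requires a result_state")
        elif self.result_state is not None:
            raise ValueError(f"{self.kind.value} event cannot carry a result_state")


class TruthLabel(str, enum.Enum):
    MALIGNANT = "malignant"
    BENIGN = "benign"


class TruthSource(str, enum.Enum):
    HISTOLOGY = "histology"
    CLINICAL_FOLLOW_UP = "clinical_follow_up"


@dataclass(frozen=True)
class PatientPathway:
    """One lymphadenopathy's diagnostic course and adjudicated truth.

    ``events`` holds one entry per completed cycle after the first (the
    first cycle is always the initial FNAC).  ``n_sb_procedures`` may
    exceed the number of biopsy events when a biopsy had to be repeated
    for technical reasons (wrong node excised); the repeat confirms the
    same result and is not a separate diagnostic step.
    """

    id: str
    initial_state: DiagnosticState
    events: tuple = ()
    truth_label: TruthLabel = TruthLabel.BENIGN
    truth_source: TruthSource = TruthSource.CLINICAL_FOLLOW_UP
    n_sb_procedures: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        for ev in self.events:
            if not isinstance(ev, Event):
                raise TypeError("events must be Event instances")
            if ev.kind is EventKind.NONE:
                raise ValueError("NONE events are implicit; omit them from events")
        sb_events = self.sb_events
        if self.n_sb_procedures is None:
            object.__setattr__(self, "n_sb_procedures", len(sb_events))
        if self.n_sb_procedures < len(sb_events):
            raise ValueError("n_sb_procedures cannot be below the number of SB events")
        if (self.n_sb_procedures > 0) != bool(sb_events):
            raise ValueError("n_sb_procedures inconsistent with recorded SB events")
        biopsied = bool(sb_events)
        if biopsied != (self.truth_source is TruthSource.HISTOLOGY):
            raise ValueError(
                "truth_source must be histology exactly for biopsied pathways"
            )
        if biopsied:
            histology_malignant = sb_events[-1].result_state.is_malignant
            if histology_malignant != (self.truth_label is TruthLabel.MALIGNANT):
                raise ValueError("truth_label contradicts the final biopsy result")

    # -- derived procedure counts ------------------------------------

    @property
    def sb_events(self) -> tuple:
        return tuple(e for e in self.events if e.kind is EventKind.SURGICAL_BIOPSY)

    @property
    def n_fnac(self) -> int:
        """FNAC procedures performed: the first plus any repeats."""
        return 1 + sum(1 for e in self.events if e.kind is EventKind.REPEAT_FNAC)

    @property
    def n_sb_patient(self) -> int:
        """0/1 flag: was this lymphadenopathy ever excised."""
        return 1 if self.sb_events else 0

    @property
    def last_fnac_state(self) -> DiagnosticState:
        """The final cytology category (initial FNAC or last repeat)."""
        repeats = [e for e in self.events if e.kind is EventKind.REPEAT_FNAC]
        return repeats[-1].result_state if repeats else self.initial_state

    @property
    def final_state(self) -> DiagnosticState:
        """State after replaying all events (procedures move the state)."""
        state = self.initial_state
        for e in self.events:
            if e.kind in PROCEDURE_KINDS:
                state = e.result_state
        return state


@dataclass(frozen=True)
class CostSchedule:
    """Unit reimbursements and repeat-counting rules for the cost model.

    Defaults are the Italian NHS regional reimbursements used throughout
    the documentation: EUR 129.50 per FNAC (US guidance, ROSE, processing,
    reporting) and EUR 1666.64 per surgical biopsy (day-surgery admission,
    excision, histology).  Repeat FNACs are additional billed procedures
    and are counted; a technically repeated biopsy on the same node is
    reimbursed once, hence ``count_sb_repeats`` defaults to False.
    """

    fnac_unit_cost: float = 129.50
    sb_unit_cost: float = 1666.64
    count_fnac_repeats: bool = True
    count_sb_repeats: bool = False

    def __post_init__(self) -> None:
        if self.fnac_unit_cost <= 0 or self.sb_unit_cost <= 0:
            raise ValueError("unit costs must be positive")

    def fnac_procedures(self, pathway: PatientPathway) -> int:
        return pathway.n_fnac if self.count_fnac_repeats else 1

    def sb_procedures(self, pathway: PatientPathway) -> int:
        return pathway.n_sb_procedures if self.count_sb_repeats else pathway.n_sb_patient


@dataclass(frozen=True)
class CohortTallies:
    """Aggregate per-state / per-event counts of a replayed cohort."""

    n_lymphadenopathies: int
    n_first_fnac: int
    n_repeat_fnac: int
    n_total_fnac: int
    n_sb_patients: int
    n_sb_procedures: int
    n_sb_histology_malignant: int
    n_sb_histology_benign: int
    n_no_escalation: int
    initial_state_counts: Mapping[StateLabel, int]
    final_state_counts: Mapping[StateLabel, int]
    per_state_sb_counts: Mapping[StateLabel, int]
    per_state_fnac_counts: Mapping[StateLabel, int]
    conclusion_cycle_counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if sum(self.initial_state_counts.values()) != self.n_lymphadenopathies:
            raise ValueError("initial_state_counts must sum to n_lymphadenopathies")
        if self.n_total_fnac != self.n_first_fnac + self.n_repeat_fnac:
            raise ValueError("n_total_fnac must equal first + repeat FNACs")
        if sum(self.per_state_sb_counts.values()) != self.n_sb_patients:
            raise ValueError("per_state_sb_counts must sum to n_sb_patients")


class CohortValidationError(ValueError):
    """Raised by load_cohort with row-level diagnostics."""


# ---------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------

CSV_COLUMNS = [
    "id",
    "initial_state",
    "malignant_subtype",
    "cycle2_event",
    "cycle2_result",
    "cycle3_event",
    "cycle3_result",
    "truth_label",
    "truth_source",
    "n_sb_procedures",
]


def _parse_event(kind_token: str, result_token: str, where: str) -> Optional[Event]:
    if not kind_token:
        if result_token:
            raise ValueError(f"{where}: result given without an event")
        return None
    try:
        kind = EventKind(kind_token.strip().lower())
    except ValueError:
        raise ValueError(f"{where}: unknown event kind {kind_token!r}") from None
    if kind is EventKind.NONE:
        return None
    if kind in PROCEDURE_KINDS:
        if not result_token:
            raise ValueError(f"{where}: {kind.value} requires a result state")
        return Event(kind, DiagnosticState.from_token(result_token))
    if result_token:
        raise ValueError(f"{where}: {kind.value} cannot carry a result state")
    return Event(kind)


def _pathway_from_row(row: Mapping[str, str]) -> PatientPathway:
    label_token = str(row["initial_state"]).strip().lower()
    try:
        label = StateLabel(label_token)
    except ValueError:
        raise ValueError(f"unknown state label {label_token!r}") from None
    subtype_token = str(row.get("malignant_subtype", "") or "").strip().lower()
    try:
        subtype = MalignantSubtype(subtype_token) if subtype_token else None
    except ValueError:
        raise ValueError(f"unknown malignant subtype {subtype_token!r}") from None
    initial = DiagnosticState(label, subtype)

    events = []
    for cycle in (2, 3):
        ev = _parse_event(
            str(row.get(f"cycle{cycle}_event", "") or ""),
            str(row.get(f"cycle{cycle}_result", "") or ""),
            f"cycle {cycle}",
        )
        if ev is None:
            if cycle == 2 and str(row.get("cycle3_event", "") or "").strip():
                raise ValueError("cycle 3 event recorded without a cycle 2 event")
            break
        events.append(ev)

    n_sb_raw = str(row.get("n_sb_procedures", "") or "").strip()
    n_sb = int(n_sb_raw) if n_sb_raw else None
    return PatientPathway(
        id=str(row["id"]),
        initial_state=initial,
        events=tuple(events),
        truth_label=TruthLabel(str(row["truth_label"]).strip().lower()),
        truth_source=TruthSource(str(row["truth_source"]).strip().lower()),
        n_sb_procedures=n_sb,
    )


def load_cohort(source: Union[str, Path, pd.DataFrame]) -> list:
    """Read pathway records from CSV (or a DataFrame) into validated pathways.

    Malformed rows are collected and reported together with their row
    number; a single bad row fails the whole load.
    """
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {', '.join(missing)}")

    pathways, problems = [], []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            pathways.append(_pathway_from_row(row))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i + 2} (id={row.get('id', '?')}): {exc}")
    if problems:
        raise CohortValidationError(
            "invalid cohort records:\n  " + "\n  ".join(problems)
        )
    ids = [p.id for p in pathways]
    if len(set(ids)) != len(ids):
        raise CohortValidationError("duplicate pathway ids")
    return pathways


def write_cohort(cohort: Sequence[PatientPathway], path: Union[str, Path]) -> None:
    """Write pathways to the cohort CSV schema (lossless round-trip)."""
    rows = []
    for p in cohort:
        if len(p.events) > 2:
            raise ValueError("CSV schema records at most two post-initial cycles")
        row = {c: "" for c in CSV_COLUMNS}
        row["id"] = p.id
        row["initial_state"] = p.initial_state.label.value
        if p.initial_state.malignant_subtype is not None:
            row["malignant_subtype"] = p.initial_state.malignant_subtype.value
        for cycle, ev in zip((2, 3), p.events):
            row[f"cycle{cycle}_event"] = ev.kind.value
            if ev.result_state is not None:
                row[f"cycle{cycle}_result"] = ev.result_state.token()
        row["truth_label"] = p.truth_label.value
        row["truth_source"] = p.truth_source.value
        row["n_sb_procedures"] = p.n_sb_procedures
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------
# Built-in reference cohort
# ---------------------------------------------------------------------


def reference_cohort() -> list:
    """The built-in 535-lymphadenopathy reference cohort.

    Pathway-level disaggregation of a consecutive series of clinically
    suspicious lymphadenopathies worked up FNAC-first over 18 months:

    * 275 malignant first FNACs (167 metastases, 98 NHL, 10 HL): 160
      metastases diagnosed by FNAC+ICC alone, 7 with confirmatory SB;
      94 lymphomas biopsied (one needing a technically repeated SB) and
      14 relapsed/SB-contraindicated lymphomas concluded on cytology.
    * 240 benign first FNACs: 220 regressed on follow-up; 10 repeated
      FNAC (9 benign — one of which was nevertheless excised, benign;
      1 suspicious — excised, benign, i.e. the series' false positive);
      10 excised directly on clinical/US suspicion (3 malignant at
      histology — false negatives — and 7 benign).
    * 15 suspicious first FNACs: all excised, all malignant.
    * 5 ALUS first FNACs: 2 resolved on follow-up, 3 excised
      (1 metastasis — false negative — and 2 benign).

    Totals: 545 FNAC procedures, 131 biopsied nodes (120 malignant / 11
    benign at histology), 132 SB procedures.
    """
    pathways: list = []
    counter = 0

    def add(n, initial, events=(), truth=TruthLabel.MALIGNANT,
            source=TruthSource.HISTOLOGY, n_sb=None):
        nonlocal counter
        for _ in range(n):
            counter += 1
            pathways.append(
                PatientPathway(
                    id=f"LN-{counter:04d}",
                    initial_state=initial,
                    events=events,
                    truth_label=truth,
                    truth_source=source,
                    n_sb_procedures=n_sb,
                )
            )

    met_known = malignant(MalignantSubtype.METASTASIS_KNOWN_PRIMARY)
    met_unknown = malignant(MalignantSubtype.METASTASIS_UNKNOWN_PRIMARY)
    nhl = malignant(MalignantSubtype.NHL)
    hl = malignant(MalignantSubtype.HL)
    sb = lambda result: Event(EventKind.SURGICAL_BIOPSY, result)
    repeat = lambda result: Event(EventKind.REPEAT_FNAC, result)
    follow_up = Event(EventKind.FOLLOW_UP)

    # --- malignant first FNAC (275) ---
    # metastases, primary identified by ICC/clinic: cytology is final
    add(160, met_known, (), TruthLabel.MALIGNANT, TruthSource.CLINICAL_FOLLOW_UP)
    # metastases with confirmatory excision
    add(7, met_known, (sb(met_known),))
    # primary NHL requiring histological confirmation; one needed the
    # biopsy repeated because the wrong node was first excised
    add(83, nhl, (sb(nhl),))
    add(1, nhl, (sb(nhl),), n_sb=2)
    add(10, hl, (sb(hl),))
    # lymphoma relapses / surgery contraindicated: cytology is final
    add(14, nhl, (), TruthLabel.MALIGNANT, TruthSource.CLINICAL_FOLLOW_UP)

    # --- benign first FNAC (240) ---
    add(220, BENIGN, (follow_up,), TruthLabel.BENIGN, TruthSource.CLINICAL_FOLLOW_UP)
    # repeat FNAC for persisting symptoms: 9 benign (1 then excised), 1 suspicious
    add(8, BENIGN, (repeat(BENIGN),), TruthLabel.BENIGN, TruthSource.CLINICAL_FOLLOW_UP)
    add(1, BENIGN, (repeat(BENIGN), sb(BENIGN)), TruthLabel.BENIGN)
    add(1, BENIGN, (repeat(SUSPICIOUS), sb(BENIGN)), TruthLabel.BENIGN)
    # excised directly on clinical/US suspicion
    add(3, BENIGN, (sb(nhl),), TruthLabel.MALIGNANT)
    add(7, BENIGN, (sb(BENIGN),), TruthLabel.BENIGN)

    # --- suspicious first FNAC (15): all excised, all malignant ---
    add(15, SUSPICIOUS, (sb(nhl),))

    # --- ALUS first FNAC (5) ---
    add(2, ALUS, (follow_up,), TruthLabel.BENIGN, TruthSource.CLINICAL_FOLLOW_UP)
    add(1, ALUS, (sb(met_unknown),))
    add(2, ALUS, (sb(BENIGN),), TruthLabel.BENIGN)

    assert len(pathways) == 535
    return pathways
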