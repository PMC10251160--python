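"""Seeded synthetic-cohort generator.

Samples lymphadenopathy pathways with the same statistical structure the
replay model assumes: a multinomial initial cytology state, per-state
event probabilities for the second cycle (nothing further / follow-up /
repeat FNAC / surgical biopsy), conditional second-cycle results, and
planted ground truth.  Truth is planted for *every* node — including the
ones the composite reference standard can only adjudicate by follow-up —
so reference-standard bias itself can be measured: the composite
standard recovers the planted mislabel rates exactly, while scoring only
the biopsied subset does not.  Note that biopsy selection here is
independent of the planted truth, a simplification discussed in the
methods note: real escalation targets the nodes clinicians distrust.

Defaults are the empirical conditionals of the built-in reference cohort
(e.g. after a benign first FNAC: follow-up 220/240, repeat FNAC 10/240,
direct biopsy 10/240).  Mislabel rates are defined against the *final*
cytology call: a call-negative node is truly malignant with probability
``fnac_false_negative_rate`` and a call-positive node truly benign with
probability ``fnac_false_positive_rate``; biopsy results always report
the planted truth (histology is gold).

A single :class:`numpy.random.Generator` seeded from ``params.seed`` is
threaded through all sampling — same seed, same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import (
    ALUS,
    BENIGN,
    SUSPICIOUS,
    DiagnosticState,
    Event,
    EventKind,
    MalignantSubtype,
    PatientPathway,
    StateLabel,
    TruthLabel,
    TruthSource,
    malignant,
)

__all__ = ["GeneratorParams", "simulate_cohort", "estimate_params"]


def _default_initial_probs() -> dict:
    return {
        StateLabel.MALIGNANT: 275 / 535,
        StateLabel.BENIGN: 240 / 535,
        StateLabel.SUSPICIOUS: 15 / 535,
        StateLabel.ALUS: 5 / 535,
    }


def _default_event_probs() -> dict:
    return {
        StateLabel.MALIGNANT: {
            EventKind.NONE: 174 / 275,
            EventKind.SURGICAL_BIOPSY: 101 / 275,
        },
        StateLabel.BENIGN: {
            EventKind.FOLLOW_UP: 220 / 240,
            EventKind.REPEAT_FNAC: 10 / 240,
            EventKind.SURGICAL_BIOPSY: 10 / 240,
        },
        StateLabel.SUSPICIOUS: {EventKind.SURGICAL_BIOPSY: 1.0},
        StateLabel.ALUS: {
            EventKind.FOLLOW_UP: 2 / 5,
            EventKind.SURGICAL_BIOPSY: 3 / 5,
        },
    }


def _default_repeat_result_probs() -> dict:
    # second-FNAC result given the initial state that triggered the repeat
    return {StateLabel.BENIGN: {StateLabel.BENIGN: 0.9, StateLabel.SUSPICIOUS: 0.1}}


def _default_post_repeat_sb_probs() -> dict:
    # probability that a biopsy follows, given the second-FNAC result
    return {StateLabel.BENIGN: 1 / 9, StateLabel.SUSPICIOUS: 1.0}


def _default_sufficient_subtypes() -> dict:
    # malignant cytology that needs no histology: identified-primary
    # metastases and lymphoma relapses
    return {
        MalignantSubtype.METASTASIS_KNOWN_PRIMARY: 160 / 174,
        MalignantSubtype.LYMPHOMA_RELAPSE: 14 / 174,
    }


def _default_biopsied_subtypes() -> dict:
    # malignant cytology sent to histology: primary lymphomas and
    # unknown-primary metastases
    return {
        MalignantSubtype.METASTASIS_UNKNOWN_PRIMARY: 7 / 101,
        MalignantSubtype.NHL: 84 / 101,
        MalignantSubtype.HL: 10 / 101,
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Sampling parameters; all probability maps must sum to one."""

    n: int = 535
    initial_probs: Mapping[StateLabel, float] = field(
        default_factory=_default_initial_probs
    )
    event_probs: Mapping[StateLabel, Mapping[EventKind, float]] = field(
        default_factory=_default_event_probs
    )
    repeat_result_probs: Mapping[StateLabel, Mapping[StateLabel, float]] = field(
        default_factory=_default_repeat_result_probs
    )
    post_repeat_sb_probs: Mapping[StateLabel, float] = field(
        default_factory=_default_post_repeat_sb_probs
    )
    fnac_false_negative_rate: float = 4 / 244
    fnac_false_positive_rate: float = 1 / 291
    sufficient_malignant_subtypes: Mapping[MalignantSubtype, float] = field(
        default_factory=_default_sufficient_subtypes
    )
    biopsied_malignant_subtypes: Mapping[MalignantSubtype, float] = field(
        default_factory=_default_biopsied_subtypes
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        maps = [
            ("initial_probs", self.initial_probs),
            ("sufficient_malignant_subtypes", self.sufficient_malignant_subtypes),
            ("biopsied_malignant_subtypes", self.biopsied_malignant_subtypes),
        ]
        maps += [(f"event_probs[{s.value}]", m) for s, m in self.event_probs.items()]
        maps += [
            (f"repeat_result_probs[{s.value}]", m)
            for s, m in self.repeat_result_probs.items()
        ]
        for name, mapping in maps:
            probs = list(mapping.values())
            if any(p < 0 or p > 1 for p in probs):
                raise ValueError(f"{name}: probabilities must lie in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ValueError(f"{name}: probabilities must sum to 1")
        for rate in (self.fnac_false_negative_rate, self.fnac_false_positive_rate):
            if rate < 0 or rate > 1:
                raise ValueError("mislabel rates must lie in [0, 1]")
        for p in self.post_repeat_sb_probs.values():
            if p < 0 or p > 1:
                raise ValueError("post-repeat biopsy probabilities must lie in [0, 1]")


def _sampler(mapping: Mapping):
    items = list(mapping.items())
    cum = np.cumsum([p for _, p in items])

    def pick(rng: np.random.Generator):
        u = rng.random()
        for (item, _), c in zip(items, cum):
            if u < c:
                return item
        return items[-1][0]

    return pick


def simulate_cohort(params: GeneratorParams = GeneratorParams()) -> list:
    """Sample ``params.n`` pathways; deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    pick_initial = _sampler(params.initial_probs)
    pick_event = {s: _sampler(m) for s, m in params.event_probs.items()}
    pick_repeat = {s: _sampler(m) for s, m in params.repeat_result_probs.items()}
    pick_sufficient = _sampler(params.sufficient_malignant_subtypes)
    pick_biopsied = _sampler(params.biopsied_malignant_subtypes)
    plain = {
        StateLabel.BENIGN: BENIGN,
        StateLabel.ALUS: ALUS,
        StateLabel.SUSPICIOUS: SUSPICIOUS,
    }

    pathways = []
    for i in range(params.n):
        label = pick_initial(rng)
        kind = pick_event[label](rng) if label in pick_event else EventKind.NONE

        will_biopsy = kind is EventKind.SURGICAL_BIOPSY
        repeat_label: Optional[StateLabel] = None
        if kind is EventKind.REPEAT_FNAC:
            repeat_label = pick_repeat[label](rng) if label in pick_repeat else label
            will_biopsy = rng.random() < params.post_repeat_sb_probs.get(
                repeat_label, 0.0
            )

        # initial state, with subtype detail for malignant cytology
        if label is StateLabel.MALIGNANT:
            subtype = pick_biopsied(rng) if will_biopsy else pick_sufficient(rng)
            initial = malignant(subtype)
        else:
            initial = plain[label]

        # final cytology call, then planted truth conditional on the call
        call_label = repeat_label if repeat_label is not None else label
        call_positive = call_label in (StateLabel.SUSPICIOUS, StateLabel.MALIGNANT)
        if call_positive:
            truly_malignant = rng.random() >= params.fnac_false_positive_rate
        else:
            truly_malignant = rng.random() < params.fnac_false_negative_rate

        if truly_malignant:
            if initial.is_malignant:
                truth_state = initial
            else:
                truth_state = malignant(pick_biopsied(rng))
        else:
            truth_state = BENIGN

        events = []
        if kind is EventKind.FOLLOW_UP:
            events.append(Event(EventKind.FOLLOW_UP))
        elif kind is EventKind.REPEAT_FNAC:
            if repeat_label is StateLabel.MALIGNANT:
                repeat_state = malignant(pick_biopsied(rng))
            else:
                repeat_state = plain[repeat_label]
            events.append(Event(EventKind.REPEAT_FNAC, repeat_state))
        if will_biopsy:
            events.append(Event(EventKind.SURGICAL_BIOPSY, truth_state))

        pathways.append(
            PatientPathway(
                id=f"SIM-{i:06d}",
                initial_state=initial,
                events=tuple(events),
                truth_label=(
                    TruthLabel.MALIGNANT if truly_malignant else TruthLabel.BENIGN
                ),
                truth_source=(
                    TruthSource.HISTOLOGY if will_biopsy else TruthSource.CLINICAL_FOLLOW_UP
                ),
            )
        )
    return pathways


def estimate_params(cohort: Sequence[PatientPathway]) -> GeneratorParams:
    """Point estimates of the generator parameters from a cohort.

    Empirical frequencies of initial states, second-cycle events,
    second-FNAC results, post-repeat biopsy decisions, and mislabel
    rates (P(malignant | call-negative), P(benign | call-positive)).
    Conditionals with no observations keep their defaults; states never
    observed get probability zero.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    n = len(cohort)

    initial_counts = {s: 0 for s in StateLabel}
    event_counts: dict = {}
    repeat_counts: dict = {}
    post_repeat = {}  # result label -> [n_sb, n_total]
    n_neg = n_neg_mal = n_pos = n_pos_ben = 0

    for p in cohort:
        label = p.initial_state.label
        initial_counts[label] += 1
        first = p.events[0].kind if p.events else EventKind.NONE
        event_counts.setdefault(label, {}).setdefault(first, 0)
        event_counts[label][first] += 1
        if first is EventKind.REPEAT_FNAC:
            result = p.events[0].result_state.label
            repeat_counts.setdefault(label, {}).setdefault(result, 0)
            repeat_counts[label][result] += 1
            tot = post_repeat.setdefault(result, [0, 0])
            tot[1] += 1
            tot[0] += p.n_sb_patient
        malignant_truth = p.truth_label is TruthLabel.MALIGNANT
        if p.last_fnac_state.is_cytology_positive:
            n_pos += 1
            n_pos_ben += not malignant_truth
        else:
            n_neg += 1
            n_neg_mal += malignant_truth

    defaults = GeneratorParams()
    return replace(
        defaults,
        n=n,
        initial_probs={s: c / n for s, c in initial_counts.items()},
        event_probs={
            s: {k: c / sum(m.values()) for k, c in m.items()}
            for s, m in event_counts.items()
        },
        repeat_result_probs=(
            {
                s: {r: c / sum(m.values()) for r, c in m.items()}
                for s, m in repeat_counts.items()
            }
            or defaults.repeat_result_probs
        ),
        post_repeat_sb_probs=(
            {r: k / t for r, (k, t) in post_repeat.items()}
            or defaults.post_repeat_sb_probs
        ),
        fnac_false_negative_rate=(n_neg_mal / n_neg if n_neg else 0.0),
        fnac_false_positive_rate=(n_pos_ben / n_pos if n_pos else 0.0),
    )
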