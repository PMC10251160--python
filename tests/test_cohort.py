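"""Domain types, CSV round-trip, and the built-in reference cohort."""

from collections import Counter

import pandas as pd
import pytest

from lnfnac import (
    ALUS,
    BENIGN,
    SUSPICIOUS,
    CohortValidationError,
    DiagnosticState,
    Event,
    EventKind,
    MalignantSubtype,
    PatientPathway,
    StateLabel,
    TruthLabel,
    TruthSource,
    load_cohort,
    malignant,
    write_cohort,
)
from lnfnac.cohort import CSV_COLUMNS


class TestDiagnosticState:
    def test_subtype_required_iff_malignant(self):
        with pytest.raises(ValueError):
            DiagnosticState(StateLabel.MALIGNANT)
        with pytest.raises(ValueError):
            DiagnosticState(StateLabel.BENIGN, MalignantSubtype.NHL)
        assert malignant(MalignantSubtype.NHL).is_malignant

    @pytest.mark.parametrize(
        "token,label,subtype",
        [
            ("benign", StateLabel.BENIGN, None),
            ("alus", StateLabel.ALUS, None),
            ("malignant:hl", StateLabel.MALIGNANT, MalignantSubtype.HL),
        ],
    )
    def test_token_round_trip(self, token, label, subtype):
        s = DiagnosticState.from_token(token)
        assert (s.label, s.malignant_subtype) == (label, subtype)
        assert s.token() == token

    def test_bad_tokens_rejected(self):
        with pytest.raises(ValueError, match="unknown state label"):
            DiagnosticState.from_token("benignn")
        with pytest.raises(ValueError, match="subtype"):
            DiagnosticState.from_token("malignant")


class TestEvent:
    def test_procedures_require_result(self):
        with pytest.raises(ValueError):
            Event(EventKind.SURGICAL_BIOPSY)
        with pytest.raises(ValueError):
            Event(EventKind.FOLLOW_UP, BENIGN)
        assert Event(EventKind.FOLLOW_UP).result_state is None


class TestPatientPathway:
    def test_truth_source_must_match_biopsy(self):
        with pytest.raises(ValueError, match="truth_source"):
            PatientPathway(
                id="x",
                initial_state=BENIGN,
                truth_label=TruthLabel.BENIGN,
                truth_source=TruthSource.HISTOLOGY,
            )

    def test_truth_label_must_match_histology(self):
        with pytest.raises(ValueError, match="truth_label"):
            PatientPathway(
                id="x",
                initial_state=BENIGN,
                events=(Event(EventKind.SURGICAL_BIOPSY, BENIGN),),
                truth_label=TruthLabel.MALIGNANT,
                truth_source=TruthSource.HISTOLOGY,
            )

    def test_derived_counts(self):
        p = PatientPathway(
            id="x",
            initial_state=BENIGN,
            events=(
                Event(EventKind.REPEAT_FNAC, SUSPICIOUS),
                Event(EventKind.SURGICAL_BIOPSY, BENIGN),
            ),
            truth_label=TruthLabel.BENIGN,
            truth_source=TruthSource.HISTOLOGY,
        )
        assert p.n_fnac == 2
        assert p.n_sb_patient == 1
        assert p.n_sb_procedures == 1
        assert p.last_fnac_state == SUSPICIOUS
        assert p.final_state == BENIGN

    def test_final_state_identity_under_follow_up_only(self, cohort):
        for p in cohort:
            if all(e.kind is EventKind.FOLLOW_UP for e in p.events):
                assert p.final_state == p.initial_state


class TestReferenceCohort:
    def test_headline_counts(self, cohort):
        assert len(cohort) == 535
        assert sum(p.n_fnac for p in cohort) == 545
        assert sum(p.n_sb_patient for p in cohort) == 131
        assert sum(p.n_sb_procedures for p in cohort) == 132

    def test_initial_state_distribution(self, cohort):
        counts = Counter(p.initial_state.label for p in cohort)
        assert counts == {
            StateLabel.MALIGNANT: 275,
            StateLabel.BENIGN: 240,
            StateLabel.SUSPICIOUS: 15,
            StateLabel.ALUS: 5,
        }

    def test_malignant_cytology_subtypes(self, cohort):
        subtypes = Counter(
            p.initial_state.malignant_subtype
            for p in cohort
            if p.initial_state.is_malignant
        )
        metastases = (
            subtypes[MalignantSubtype.METASTASIS_KNOWN_PRIMARY]
            + subtypes[MalignantSubtype.METASTASIS_UNKNOWN_PRIMARY]
        )
        assert metastases == 167
        assert subtypes[MalignantSubtype.NHL] == 98
        assert subtypes[MalignantSubtype.HL] == 10

    def test_benign_arm_disaggregation(self, cohort):
        benign = [p for p in cohort if p.initial_state == BENIGN]
        repeats = [p for p in benign if p.n_fnac == 2]
        direct_sb = [p for p in benign if p.n_fnac == 1 and p.n_sb_patient]
        quiet = [p for p in benign if p.n_fnac == 1 and not p.n_sb_patient]
        assert (len(quiet), len(repeats), len(direct_sb)) == (220, 10, 10)
        # repeat results: 9 benign (one then excised) and 1 suspicious
        repeat_results = Counter(p.last_fnac_state.label for p in repeats)
        assert repeat_results == {StateLabel.BENIGN: 9, StateLabel.SUSPICIOUS: 1}
        assert sum(p.n_sb_patient for p in repeats) == 2
        # direct excisions: 3 malignant at histology, 7 benign
        truths = Counter(p.truth_label for p in direct_sb)
        assert truths == {TruthLabel.MALIGNANT: 3, TruthLabel.BENIGN: 7}

    def test_one_repeated_biopsy(self, cohort):
        doubles = [p for p in cohort if p.n_sb_procedures == 2]
        assert len(doubles) == 1
        assert doubles[0].initial_state.malignant_subtype in (
            MalignantSubtype.NHL,
            MalignantSubtype.HL,
        )
        assert doubles[0].n_sb_patient == 1

    def test_final_malignant_diagnoses(self, cohort):
        assert sum(p.truth_label is TruthLabel.MALIGNANT for p in cohort) == 294


class TestCsvIO:
    def test_round_trip_lossless(self, cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        assert load_cohort(path) == cohort

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(CSV_COLUMNS) + "\n")
        assert load_cohort(path) == []

    def test_minimal_well_formed_record(self):
        frame = pd.DataFrame(
            [
                {
                    "id": "a",
                    "initial_state": "benign",
                    "malignant_subtype": "",
                    "cycle2_event": "follow_up",
                    "cycle2_result": "",
                    "cycle3_event": "",
                    "cycle3_result": "",
                    "truth_label": "benign",
                    "truth_source": "clinical_follow_up",
                    "n_sb_procedures": "",
                }
            ]
        )
        (p,) = load_cohort(frame)
        assert p.n_fnac == 1
        assert p.n_sb_patient == 0
        assert p.events == (Event(EventKind.FOLLOW_UP),)

    @pytest.mark.parametrize(
        "patch,message",
        [
            ({"initial_state": "weird"}, "unknown state label"),
            ({"cycle2_event": "surgical_biopsy", "cycle2_result": ""}, "requires a result"),
            ({"truth_source": "histology"}, "truth_source"),
            ({"cycle2_event": "repeat_fnac", "cycle2_result": "malignant"}, "subtype"),
        ],
    )
    def test_malformed_rows_rejected_with_row_diagnostics(self, patch, message):
        row = {
            "id": "a",
            "initial_state": "benign",
            "malignant_subtype": "",
            "cycle2_event": "",
            "cycle2_result": "",
            "cycle3_event": "",
            "cycle3_result": "",
            "truth_label": "benign",
            "truth_source": "clinical_follow_up",
            "n_sb_procedures": "",
        }
        row.update(patch)
        with pytest.raises(CohortValidationError, match=message) as err:
            load_cohort(pd.DataFrame([row]))
        assert "row 2" in str(err.value)

    def test_duplicate_ids_rejected(self, cohort):
        import pandas as pd

        with pytest.raises(CohortValidationError, match="duplicate"):
            frame = pd.DataFrame(
                [
                    {
                        "id": "a",
                        "initial_state": "benign",
                        "malignant_subtype": "",
                        "cycle2_event": "",
                        "cycle2_result": "",
                        "cycle3_event": "",
                        "cycle3_result": "",
                        "truth_label": "benign",
                        "truth_source": "clinical_follow_up",
                        "n_sb_procedures": "",
                    }
                ]
                * 2
            )
            load_cohort(frame)
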