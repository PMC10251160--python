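# lnfnac

Cost-minimization and diagnostic-accuracy analysis of fine-needle
aspiration cytology (FNAC) as the first-line work-up of clinically
suspicious lymphadenopathy.

## The problem

When a suspicious lymph node persists, two diagnostic strategies
compete: excise it straight away (surgical biopsy, SB — the traditional
gold standard, invasive and expensive) or triage it first with
lymph-node FNAC (LN-FNAC), reserving surgery for the cases cytology
cannot settle. This package implements the cohort model that compares
the two strategies on cost, assuming equal diagnostic effectiveness
(a cost-minimization analysis), and tabulates how accurate the cytology
triage actually is.

The package is for health-economics and pathology researchers who want
to replay the analysis on the built-in reference cohort, stress its
assumptions (reimbursement levels, biopsy rates, counting rules), or run
the identical pipeline on their own pathway-level data or on synthetic
cohorts.

## The model

Each lymphadenopathy moves through discrete cycles of a Markov cohort
model with four transient states given by the Sydney System cytology
categories: *benign*, *ALUS* (atypical lymphoid cells of uncertain
significance), *suspicious*, *malignant*. Cycle 1 is always the first
FNAC; each later cycle is opened by one event — clinical follow-up
(state unchanged), repeat FNAC, or surgical biopsy (state moves to the
new result). The model is a *replay* engine over recorded pathways, so
transition probabilities are empirical; a seeded generator
(`lnfnac.synth`) provides the sampling counterpart.

Costs per patient under the two strategies, with unit reimbursements
c_f (FNAC) and c_s (SB):

* FNAC-first: `(c_f · #FNACs + c_s · #biopsied) / n` — repeats of FNAC
  are billed, a technically repeated excision of the same node is not;
* SB-only: `c_s` by construction.

Cytology accuracy uses the node's final FNAC category (suspicious or
malignant = positive call; benign or ALUS = negative) cross-tabulated
against either the **composite** reference standard (histology when
biopsied, clinical follow-up otherwise; all n nodes evaluable) or
**histology only** (the biopsied subset, which suffers
partial-verification bias).

## Worked example

```python
from lnfnac import (reference_cohort, run_model, tally_cohort,
                    compare_strategies, confusion_matrix, metrics, Reference)

cohort = reference_cohort()                  # 535 lymphadenopathies
tallies = tally_cohort(run_model(cohort), cohort)
print(tallies.n_total_fnac, tallies.n_sb_patients)   # 545 131

cmp = compare_strategies(cohort)
print(round(cmp.fnac_first.cost_per_patient, 2))     # 540.01
print(round(cmp.saving_per_patient, 2))              # 1126.63

m = metrics(confusion_matrix(cohort, Reference.COMPOSITE))
print(round(100 * m.sensitivity, 1))                 # 98.6
```

545 FNACs and 131 excisions give an average diagnostic cost of
€540.01 per patient, €1126.63 (about two-thirds) less than excising
every node upfront at €1666.64 — while cytology keeps a 98.6%
sensitivity against the composite reference standard. The
`examples/` scripts print the full analysis with commentary:

* `examples/reference_analysis.py` — tallies, cost comparison, accuracy;
* `examples/cost_sensitivity.py` — one-way sensitivity and break-even points;
* `examples/synthetic_recovery.py` — simulate a cohort, recover its parameters.

## Data in and out

Cohorts are plain CSV, one row per lymphadenopathy
(`id, initial_state, malignant_subtype, cycle2_event, cycle2_result,
cycle3_event, cycle3_result, truth_label, truth_source,
n_sb_procedures`); see `lnfnac.load_cohort` / `lnfnac.write_cohort`.
The built-in `reference_cohort()` needs no files.

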