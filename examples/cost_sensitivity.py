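"""One-way sensitivity of the per-patient saving.

Scans the surgical-biopsy reimbursement and the biopsy rate, printing
the saving of the FNAC-first strategy at each value and the break-even
point where the two strategies cost the same.
"""

import numpy as np

from lnfnac import CostSchedule, one_way_sensitivity, reference_cohort

cohort = reference_cohort()
schedule = CostSchedule()

print("== Saving vs surgical-biopsy reimbursement (EUR) ==")
table = one_way_sensitivity(
    cohort, schedule, "sb_unit_cost", np.linspace(0, 2000, 6)
)
for _, row in table.iterrows():
    marker = "  <- break-even" if abs(row.saving_per_patient) < 1e-9 else ""
    print(f"  SB cost {row.value:8.2f}  ->  saving {row.saving_per_patient:9.2f}{marker}")
print("-> below the break-even reimbursement, pre-screening every node with")
print("   cytology would cost more than excising everything upfront.\n")

print("== Saving vs fraction of nodes biopsied ==")
table = one_way_sensitivity(
    cohort, schedule, "biopsy_rate", np.linspace(0, 1, 6)
)
for _, row in table.iterrows():
    marker = "  <- break-even" if abs(row.saving_per_patient) < 1e-9 else ""
    print(f"  biopsy rate {row.value:5.3f}  ->  saving {row.saving_per_patient:9.2f}{marker}")
print("-> the observed rate is 131/535 = 0.245; even a far less selective")
print("   triage would still save money at the default reimbursements.")
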