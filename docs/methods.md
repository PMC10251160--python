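# Methods

## Model

The analysis treats the diagnostic work-up of a clinically suspicious
lymphadenopathy as a discrete-cycle Markov cohort model with four
transient states — the Sydney System cytology categories benign, ALUS,
suspicious and malignant. Cycle 1 is always the first FNAC, which
assigns the initial state. Each subsequent cycle is opened by exactly
one event:

* **clinical follow-up** — no new specimen; the node remains in its
  state (follow-up is how a benign cytology call is confirmed without
  surgery);
* **repeat FNAC** — the node moves to the state of the new cytology
  result;
* **surgical biopsy (SB)** — the node moves to the state given by
  histology, the gold standard.

The engine *replays* recorded pathways rather than sampling transitions:
the cohort defines its own empirical transition structure, which is the
appropriate use of the framework for a retrospective series. All
pathways must conclude within `max_cycles` (default 3); a pathway with
more recorded events raises an error rather than being truncated,
because the model assigns no meaning to an unconcluded node.

The unit of analysis is the lymphadenopathy, not the person: the
procedure arithmetic (first FNACs + repeats, biopsied nodes) only closes
at node level.

### Conclusion semantics

The diagnostic process concludes at the cycle of the last
*diagnostically necessary* procedure:

* no procedures → cycle 1 (cytology sufficient for malignant calls,
  follow-up-confirmed benignity otherwise);
* follow-up never extends the process — it confirms a diagnosis already
  made;
* a **confirmatory** excision after an already-diagnostic malignant
  cytology — a metastasis whose primary is identified (clinically or by
  immunocytochemistry) or a relapse of a known lymphoma, with histology
  confirming malignancy — does not extend the process; the diagnosis
  was available at cycle 1 and the excision served clinical management;
* otherwise the conclusion cycle is the cycle of the last repeat FNAC
  or biopsy.

This rule is a genuine design choice: a plain "cycle of the last event"
rule would date those confirmatory excisions to cycle 2. We adopted the
necessary-procedure reading because it reflects when the *diagnosis*
was in hand, and it is the reading under which the reference cohort's
cycle progression (403 / 130 / 2 nodes concluded at cycles 1–3) is
internally consistent with its escalation counts.

### The reference cohort

`reference_cohort()` encodes 535 consecutive lymphadenopathies as
disaggregated pathway rows (not marginal counts), so the same structure
feeds the replay engine, the cost model and the accuracy tabulations.
The disaggregation is uniquely determined by the series' narrative
counts; the package's tests assert every reported tally against it.
Two details are worth flagging:

* the escalation-free count computed from the pathway rows is **396**
  (535 − 131 biopsied − 10 re-aspirated + 2 nodes in both groups); the
  series' own summary prints 395 alongside a breakdown (174 + 222) that
  also sums to 396, so the package reports the arithmetic from the rows;
* the one technically repeated excision (wrong node removed first) is
  encoded as `n_sb_procedures = 2` on a single lymphoma pathway; it is
  one biopsied node, and by default one reimbursed excision.

Subtypes of malignancies discovered only at histology (three nodes with
benign cytology, one ALUS) are not reported at source; the fixture
assigns fixed, arbitrary subtypes to them, which no computed quantity
depends on.

## Costs

A cost-minimization comparison: the two strategies are assumed equally
effective, so only cost matters. Unit reimbursements default to
€129.50 per FNAC (ultrasound guidance, rapid on-site evaluation, basic
processing, reporting) and €1666.64 per SB (day-surgery admission,
excision, histology) — Italian NHS regional rates; both are plain
configuration in `CostSchedule` and carry no retrieval logic.

Counting rules, exposed as `CostSchedule` flags:

* repeat FNACs are billed (`count_fnac_repeats=True`): 545 procedures
  in the reference cohort;
* the technically repeated SB is not billed twice
  (`count_sb_repeats=False`): 131 reimbursed excisions, not 132.

Follow-up visits and ancillary techniques carry zero cost: follow-up
costs are hard to attribute, and ancillary work-ups are assumed
equivalent in kind and number between the two strategies. Quality-of-life
effects, complications and diagnostic-delay costs are out of scope.

Per-stratum costs attribute all of a node's procedures (repeats and any
biopsy) to the state assigned by its *first* FNAC. On the reference
cohort this yields €218.23 (benign), €741.61 (malignant), €1796.14
(suspicious — every node exactly one FNAC plus one excision) and
€1129.48 (ALUS). Note the suspicious/ALUS figures follow from the
stratum compositions and are computed, never hard-coded.

All arithmetic is carried unrounded; `round_currency` rounds half-up to
the cent for presentation. Derived percentages (e.g. the biopsy share of
the FNAC-first cost, 75.57%) are computed on unrounded values.

`one_way_sensitivity` scans one of {FNAC unit cost, SB unit cost, biopsy
rate}; the saving is linear in each, and the break-even value is
inserted into the table when it falls inside the scanned range. The
biopsy-rate scan holds the cohort's mean FNACs per node fixed.

## Diagnostic accuracy

A node's cytology call is its **final** FNAC category — the initial
result unless a repeat FNAC revised it (so the one benign→suspicious
revision counts as a positive call). Suspicious and malignant are
positive; benign and **ALUS count as negative** (the indeterminate
category is managed, not treated as a diagnosis of malignancy).

Two reference standards:

* **composite** — histology when biopsied, clinical follow-up
  otherwise; all 535 nodes evaluable; reference cells (290, 1, 240, 4);
* **histology-only** — the 131 biopsied nodes; cells (116, 1, 10, 4).

Metrics are exact fractions internally; undefined metrics (zero
denominator) are reported as `None`, never as 0. The false-negative
rate is `fn / (tp + fn) = 1 − sensitivity`. The histology-only subset
is a selected sample (partial-verification bias): on the reference
cohort it nearly triples the apparent false-negative rate (3.3% vs
1.4%) because clinicians biopsy precisely the nodes they distrust.

## Synthetic cohorts

`simulate_cohort` samples pathways with the structure the replay model
assumes: multinomial initial states (defaults 275/240/15/5 out of 535),
per-state second-cycle event tables (e.g. benign: follow-up 220/240,
repeat FNAC 10/240, direct SB 10/240), a conditional second-FNAC result
table (benign repeat: 9/10 benign, 1/10 suspicious), and post-repeat
biopsy probabilities (1/9 after a benign repeat, 1 after a suspicious
one). Ground truth is planted *conditional on the final cytology call*:
a call-negative node is truly malignant with probability
`fnac_false_negative_rate` (default 4/244) and a call-positive node
truly benign with probability `fnac_false_positive_rate` (default
1/291); biopsy results always report the planted truth. A single
`numpy.random.Generator` seeded from `params.seed` drives all sampling;
identical seeds give identical cohorts.

What the generator deliberately does **not** emulate:

* escalation is independent of the planted truth, whereas real
  clinicians biopsy the nodes they distrust — so the *direction* of the
  histology-only bias differs between simulated and real cohorts
  (dilution vs inflation of the false-negative fraction); passing
  recovery tests therefore shows the pipeline's internal consistency,
  not the clinical selection mechanism;
* no covariates (age, node size, ultrasound features) and no
  person-level linkage of multi-node patients;
* event probabilities are fixed conditionals, not fitted with
  uncertainty.

`estimate_params` returns empirical point estimates (initial and event
frequencies; mislabel rates as P(malignant | negative call) and
P(benign | positive call)); conditional tables with no observations keep
their defaults. Recovery at n = 50,000 lands initial probabilities
within 0.01 of truth and mislabel rates within 3 binomial standard
errors; rare conditional strata (ALUS, ~0.9% of nodes) carry
proportionally wider error bars and are tested at 3 SE of their realized
stratum size.

## Problem sizes and determinism

The reference-cohort analysis is exact and runs in milliseconds. The
stochastic checks use 50,000-node simulations (sub-second) and
1,000 small random cohorts for the cost-oracle property; every random
test and the reproduction script are seeded, so reruns are bit-identical
for a given seed.

## Known limitations

* The cost comparison inherits the series' assumption that an SB would
  have been feasible in every node under the SB-only strategy.
* The reference cohort's summary statistics contain two small internal
  inconsistencies at source (395 vs 396 escalation-free nodes; a
  "54.58% finally malignant" figure vs 294 enumerable malignant
  diagnoses). The package always reports what the pathway rows imply.
* Confidence intervals for the accuracy metrics are out of scope, as is
  ROC analysis; the metrics are descriptive fractions of a fixed cohort.
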