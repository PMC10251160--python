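"""Generate a synthetic cohort and recover its generating parameters.

Simulates 50,000 pathways with the default (reference-cohort) parameters,
re-estimates the parameters from the simulated data, and shows that the
composite reference standard recovers the planted mislabel rates while
the histology-only standard overstates the false-negative fraction.
"""

from lnfnac import Reference, confusion_matrix, estimate_params, metrics, simulate_cohort
from lnfnac.synth import GeneratorParams

params = GeneratorParams(n=50_000, seed=42)
cohort = simulate_cohort(params)
est = estimate_params(cohort)

print("== Initial-state probability recovery (n = 50,000) ==")
for state, true_p in params.initial_probs.items():
    print(f"  {state.value:>10}: true {true_p:.4f}  estimated {est.initial_probs[state]:.4f}")

print("\n== Planted vs recovered mislabel rates ==")
print(f"  false-negative: planted {params.fnac_false_negative_rate:.4f}  "
      f"recovered {est.fnac_false_negative_rate:.4f}")
print(f"  false-positive: planted {params.fnac_false_positive_rate:.4f}  "
      f"recovered {est.fnac_false_positive_rate:.4f}")

print("\n== Reference-standard comparison on the same simulated cohort ==")
for ref in Reference:
    m = metrics(confusion_matrix(cohort, ref))
    print(f"  {ref.value:>14}: false-negative rate {100 * m.fn_rate:.2f}%")
print("-> truth is planted for every node, so the composite standard")
print("   recovers the planted rate. The histology-only rate differs because")
print("   it scores a selected subset; here the generator biopsies negatives")
print("   at random, diluting false negatives among the many confirmed true")
print("   positives. In the reference cohort the direction reverses (3.3%")
print("   vs 1.4%): clinicians biopsy exactly the nodes they distrust.")
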