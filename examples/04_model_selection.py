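"""Decide which halves of the reaction an inhibitor competes with.

Runs the nested-model ladder (no inhibition -> single-half competitive ->
both halves) on two simulated datasets: a succinate-like one, which inhibits
only the NADPH half of NfsA, and an NfsB-like one, where 1 mM of either acid
has no effect.  Selection uses extra-sum-of-squares F-tests at alpha 0.05.
"""

from nitrokin import REFERENCE_PARAMETERS, default_designs, detect_inhibition, simulate_rates

designs = default_designs(replicates=3, noise_cv=0.05, seed=11)

for case in ("succinate_nfsa", "nfsb"):
    dataset = simulate_rates(REFERENCE_PARAMETERS[case], designs[case])
    report = detect_inhibition(dataset, alpha=0.05)
    print(f"{case}: selected variant = {report.selected.value}")
    for cmp in report.comparisons:
        print(f"  {cmp.reduced.variant.value:>18} vs {cmp.full.variant.value:<18}"
              f" F = {cmp.f_stat:9.3g}  p = {cmp.p_value:.3g}")
    best = report.best_fit.params
    if best.ki_b is not None:
        print(f"  Ki(NADPH) = {best.ki_b / 1000:.2f} mM")
    print()

print("The succinate-like data should select competitive_vs_B with Ki near 4.3 mM;")
print("the NfsB-like data should return no_inhibition: its F-tests find no")
print("significant improvement from any Ki term.")
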