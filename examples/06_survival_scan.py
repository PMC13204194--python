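"""Scan-mode Kaplan-Meier cutoff analysis on a simulated cohort.

Simulates a 127-patient cohort where above-median expression triples the
event hazard, then compares the single median split with scan mode, which
tests every admissible split (both groups >= 8 patients) and Bonferroni-
adjusts the winning p-value for the number of cutoffs tested.
"""

from mircargo import gen_survival, km_curve, scan_cutoff

cohort, truth = gen_survival(n_patients=127, hazard_ratio=3.0,
                             censor_rate=0.3, seed=6)

for mode in ("median", "scan"):
    res = scan_cutoff(cohort, min_group=8, mode=mode)
    adj = f", adjusted p = {res.p_adjusted:.3g}" if res.p_adjusted is not None else ""
    print(f"{mode:>6}: cutoff {res.cutoff:+.3f}, groups {res.n_low}/{res.n_high}, "
          f"chi2 {res.chi_square:.2f}, p = {res.p_nominal:.3g}{adj} "
          f"({res.n_cutoffs_tested} cutoffs tested)")

res = scan_cutoff(cohort, min_group=8, mode="scan")
high = cohort[cohort["expression"] > res.cutoff]
km = km_curve(high)
print(f"high-expression group: survival falls to {km['survival'].iloc[-1]:.2f} "
      f"by t = {km['time'].iloc[-1]:.0f}")
# Scan mode always reaches a p at most that of the median split (it scans a
# superset), which is why the Bonferroni adjustment over tested cutoffs is
# reported alongside.
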