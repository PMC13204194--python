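"""Differential expression on a simulated two-group TPM matrix.

Simulates a 3-vs-3 experiment with planted 4-fold effects, applies the
TPM < 10 low-expression filter, tests each transcript with a Welch t-test
on log2(TPM + 1), and calls up/down-regulated transcripts with the strict
p < 0.01, |logFC| > 0.5 rule.
"""

from mircargo import (
    classify_drgs,
    differential_expression,
    filter_low_tpm,
    gen_expression_matrix,
)

matrix, truth = gen_expression_matrix(
    n_transcripts=5000, n_per_group=3, de_fraction=0.05,
    effect_log2fc=2.0, dispersion=0.3, seed=1, low_fraction=0.5,
)
filtered, removed = filter_low_tpm(matrix, threshold=10, min_low_samples=2)
deg = differential_expression(filtered)
calls = classify_drgs(deg, p_cut=0.01, lfc_cut=0.5)

called = set(calls.up.index) | set(calls.down.index)
tp = called & truth.de_transcripts
print(f"transcripts: {matrix.n_transcripts}, removed by TPM filter: {len(removed)}")
print(f"called: {len(calls.up)} up, {len(calls.down)} down")
print(f"planted effects recovered: {len(tp)}/{len(truth.de_transcripts)} "
      f"(false discoveries: {len(called) - len(tp)})")
# The filter removes the planted low-expression transcripts; most of the
# planted 4-fold effects are recovered at n=3 with few false positives.
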