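# Methods

This note records the statistical models, conventions and design choices
behind each module, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Differential expression

The pipeline starts from TPM, not counts, so no count model is fitted.
Transcripts are removed when, in at least one experimental group
(`scope="either_group"`, the default), at least `min_low_samples = 2`
samples lie strictly below `threshold = 10` TPM. The phrase "in either one
or both groups" admits two readings; both are implemented
(`either_group` / `both_groups`) with the stricter one as default. The
filter is idempotent.

The per-transcript test is a two-sided Welch t-test on log2(TPM + 1) — the
simplest defensible location test at n = 3 vs 3 when the upstream vendor's
engine is unknown. Consequences worth knowing:

* With Satterthwaite degrees of freedom at n = 3, the test runs
  conservative in the far tail (true size ≈ 0.005 at nominal 0.01 on
  normal data). The null-calibration tests bound the empirical false-positive
  rate in [0.005, 0.02] over ≥ 10⁵ pooled tests.
* A transcript with zero variance in both groups gets p = 1 by convention
  (the location test is undefined there); its fold change is still
  reported.
* The pseudocount is 1 for both the fold change and the log transform,
  configurable via `pseudocount`.

Calling uses strict inequalities on raw p (p < 0.01) and |log2 FC| > 0.5,
so boundary records stay `ns`; a Benjamini–Hochberg column is emitted for
information only. Gene collapse averages member-transcript log-fold-changes
(arithmetic mean); equal gene scores are ordered lexicographically so the
ranking is deterministic.

Global differential-expression counts from any particular experiment are
not reproducible from this package alone — they depend on the raw matrix
and the upstream engine — and are not asserted anywhere.

## Pre-ranked GSEA

ES is the maximal deviation from zero of the running sum over the
descending-ranked list: hits increment by |score|^w normalised over the
set's hits (w = 1 default; w = 0 gives the classic Kolmogorov–Smirnov
form), misses decrement by 1/(N − k). Positive deviations peak immediately
after a hit and negative ones immediately before, which is how the
implementation evaluates them in closed form; magnitude ties (possible with
rational steps at w = 0) resolve to the positive side within a 1e-12
tolerance. If every member score is zero at w > 0 the hit increments fall
back to uniform.

The null is gene-label permutation — the only null available to a
pre-ranked analysis — sharing one permutation pool across sets so results
do not depend on set iteration order. NES divides ES by the mean |null ES|
of matching sign; p is the add-one-smoothed matching-sign tail, hence
p ≥ 1/(n_perm + 1). Default n_perm = 1000. Sets are filtered to an overlap
of [5, 500] genes with the ranked list. Selection of top terms filters at
raw p < 0.05 and ranks by NES (descending for enriched, ascending for
depleted), truncated to 10 per side.

ORA is the upper-tail hypergeometric probability of at least the observed
overlap; the gene list must be a subset of the declared universe, and each
set is intersected with the universe before testing.

## qPCR cards

Non-detects are the reserved token `Undetermined` on disk and NaN in
memory — never a numeric sentinel such as Ct 40. Normalisation subtracts
the spike-in (or housekeeping) Ct per preparation; a non-detected reference
in any preparation is a hard error naming the preparation. ΔΔCt uses means
over detected wells; RQ = 2^−ΔΔCt, so RQ(a,b)·RQ(b,a) = 1.

Expression calling conventions, where the published rule leaves room:

* "Clean negative control" is implemented as the NTC being a non-detect or
  Ct > 35 (configurable `ntc_ct_floor`); targets without NTC wells are
  treated as clean.
* The medium background is summarised per target as the mean Ct over
  detected medium wells; each EV preparation is compared against that mean
  (the medium is a background condition, not a paired preparation). A
  medium non-detect satisfies the ≥ 4-cycle separation by definition; an
  EV non-detect fails the call regardless of the medium.
* The high-abundance rule (Ct < 27.5, strict) applies per preparation when
  replicate-level data exist — the call table carries the worst
  (largest) EV Ct for this — and to the mean when only summary data are
  available, as with the shipped published table.
* The cross-species identity filter on the panel (which miRNAs are
  comparable between the EV donor and recipient species) is an input
  property of the panel file, not computed: it would require external
  sequence databases.

## Target integration

A gene belongs to a miRNA's consensus set when at least `min_db = 2` of
the declared databases predict it; an empty prediction from a database
still counts as one of the databases consulted. Consensus is anti-monotone
in `min_db`. Combined family rows (e.g. `miR-30b-5p/miR-30c-5p`) stay
single rows for consensus — matching how prediction tools report them —
but expand to their mature members for multiplicity counting, so a gene in
the consensus of one combined row plus one single row has multiplicity 3.
Gene symbols compare case-sensitively after whitespace trimming; no alias
resolution is attempted, so all inputs must share a symbol namespace.

## Pathway convergence

Both result lists are matched by exact pathway name after case-folding and
whitespace collapse; fuzzy matching is deliberately avoided because silent
mismatches are worse than loud ones (unmatched significant names are
logged). A term is convergent when p < 0.05 on both sides; the output is
ordered by ascending transcriptome-side p. Venn counts are emitted as JSON;
no figure is produced.

## Survival

The log-rank statistic uses the standard counting-process form: at each
distinct event time, observed minus expected events in one group under the
hypergeometric model, variance d(n−d)·n₁n₂/(n²(n−1)), χ² with 1 df. It is
implemented directly (the scan loop evaluates it up to ~10⁵ times in the
test battery, and the degenerate no-comparable-events case must return
p = 1 with a warning rather than NaN); `lifelines.statistics.logrank_test`
serves as an independent cross-check in the tests. Kaplan–Meier curves come
from lifelines.

Cutoff selection supports both modes because the source analysis names
both: a single median split (ties to the low group) and "scan" mode, the
default, which tests every split between distinct expression values
leaving both groups ≥ 8 patients and keeps the smallest nominal p (ties
resolve to the smaller cutoff). The minimal-p cutoff is anti-conservative
by construction, so a Bonferroni adjustment over the number of cutoffs
actually tested is always reported; it is conservative under the null. The
platform that inspired this analysis does not document its internal
correction, so Bonferroni was chosen as the transparent upper bound.

## Synthetic data

The generators emulate the study conditions end to end; all randomness
flows from one explicit seed (`numpy.random.default_rng`), and a fixed seed
reproduces every output bit for bit.

* **Expression**: per-transcript log-normal TPM baselines (log2 mean
  uniform on a well-expressed range ≈ 23–2048 TPM), with a configurable
  fraction drawn below the TPM-10 floor (default pipeline value 0.7,
  emulating the heavy transcript attrition of the filter step at a
  tractable scale of 20,000 transcripts — the package's own problem-size
  choice), per-sample log2 noise of sd 0.3, and planted effects of
  ±`effect_log2fc` placed among well-expressed transcripts so they survive
  filtering. Three samples per group, as in the study design. Not
  emulated: count noise (mean–variance coupling), transcript-length
  effects, correlated transcripts, batch structure — so passing recovery
  tests show the pipeline's rules behave as specified, not that the Welch
  test is optimal for real RNA-seq.
* **Ct cards**: a 136-miRNA panel with 20% expressed and half of those
  high-abundance by default (emulating 136 → 27 expressed → 13 high),
  spike-in at Ct 23.852 on every card, expressed miRNAs detected in every
  preparation with a medium background ≥ 6 cycles away or absent, and
  non-expressed miRNAs split between EV non-detects, sub-threshold
  separation (< 4 cycles), and occasional dirty NTCs. Amplification
  curves, efficiency differences and well-level outliers are not
  simulated.
* **Target databases**: `consensus_overlap` is the fraction of each
  database's per-miRNA prediction budget planted into ≥ 2 databases; all
  remaining predictions are drawn from database-exclusive pools, so the
  generated consensus equals the planted truth exactly for any overlap
  value. Real databases of course overlap by chance; this design trades
  that realism for an exact, independently checkable truth.
* **Gene sets**: uniform random sets, with the first `n_planted_sets`
  drawing 80% of their members from a planted gene list for power tests.
* **Survival**: exponential event times with the hazard multiplied by
  `hazard_ratio` for above-median expression (default 3 at n = 127, the
  cohort scale of the motivating analysis); censoring flags each record
  independently and truncates its time uniformly. No competing risks or
  time-varying hazards.

## Numerical conventions

* Strict inequalities at every published threshold (TPM < 10, p < 0.01,
  |logFC| > 0.5, ΔCt ≥ 4 meaning `medium − EV ≥ 4`, Ct < 27.5, p < 0.05).
* Deterministic sorts everywhere a ranking is emitted (mergesort with
  explicit tie-break keys), so outputs are byte-reproducible.
* Writers use the shortest round-trippable float representation; file
  round-trips are lossless.
* The pipeline derives one child seed per stochastic stage from the master
  seed via `numpy.random.SeedSequence`.

## Limitations

* The Welch-on-log2 substitute for the unknown upstream DE engine means
  absolute DEG counts from the original experiment are not recoverable;
  only the classification rules and their boundary behaviour are.
* The published summary of regulated transcripts contains rows whose
  printed p-values exceed the stated p < 0.01 calling threshold; under
  this package's strict rule those rows classify `ns`. The classifier
  follows the stated rule rather than the table.
* GSEA here replaces a web tool whose permutation count, weighting and
  FDR handling are unpublished; NES and p-values are comparable in spirit,
  not numerically.
* Pathway-level p-values for predicted miRNA targets are consumed as
  inputs (or produced by the in-package ORA on synthetic annotations);
  external prediction services and their database snapshots are not
  reproduced.
* Survival analysis is validated on synthetic cohorts only; no external
  patient dataset ships with the package.
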