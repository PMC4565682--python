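# Methods

`mircross` implements a cross-platform analysis pipeline for circulating
small-RNA biomarkers: discovery by small-RNA sequencing and validation by
RT-qPCR absolute quantification, with the standardisation steps (isomiR
tolerance, multi-normalisation consensus testing, small-RNA enrichment,
spike-in recovery normalisation) that make the two platforms comparable.
This note records the models, the parameters that matter, and the design
choices that were genuinely open.

## Read processing and isomiR counting

Small-RNA inserts (18–25 nt) are shorter than the read, so each read runs
into the 3' sequencing adapter. Trimming removes the leftmost occurrence of
an adapter prefix of length ≥ `min_overlap` (default 7 nt) allowing
mismatches at ≤ `max_mismatch_rate` (default 0.1); reads with no hit are
kept, because a full-length insert can fill the read, and the subsequent
length filter (18–25 nt inclusive) is the real gate. Quality-based trimming
is deliberately omitted: the pipeline's inputs carry no informative quality
model, and the length filter dominates. Cleaned reads are collapsed to
unique tags with per-sample counts; collapse conserves read totals exactly.

A tag is assigned to a mature miRNA when some ungapped placement puts both
tag ends within ±2 nt of the mature ends with ≤ 1 mismatch. The two-base
tolerance is interpreted **per end** (so a +2/−2 combination is legal), and
the single mismatch may fall in an extension. Bases extending past the
mature sequence are compared against precursor context when a precursor is
supplied; without it, an extension base is indistinguishable from a
non-templated addition and is charged as a mismatch. Ties between equally
good placements resolve by fewest mismatches, then smallest
|offset5|+|offset3|, then smallest offset5; ties between references add a
lexicographic ref-id tie-break. A tag matching k references contributes its
**full** count to each of the k rows — no fractional splitting — so library
sizes for normalisation are the per-sample cleaned-read totals, not column
sums, which would double-count multi-mapped tags.

## Filtering, normalisation and the consensus test

Transcripts enter testing only with ≥ 1 count per million in ≥ 3 samples.
Three normalisations are computed on the filtered matrix:

* **RPKM** `count·10⁹/(L·N)`, with L the mature reference length in nt. L is
  a per-transcript constant, so it cancels out of fold changes and
  t-statistics; it matters only for cross-transcript comparisons.
* **Quantile** — default `full`: each sample's order statistics are replaced
  by the cross-sample mean order statistics (ties averaged). The
  `upper_quartile` mode (each sample scaled so its 75th percentile of
  nonzero counts equals the geometric mean of those percentiles) is
  first-class because the two are often conflated in practice; which one a
  given study used is frequently ambiguous. Column means are exactly equal
  after full quantile normalisation only for tie-free data; tie averaging
  perturbs them slightly.
* **TMM** — for each sample against a reference sample (the one whose 75th
  percentile of count/library-size is closest to the mean), M-values
  (log2 expression ratios) and A-values (average log2 expression) are
  computed over transcripts nonzero in both; the top and bottom 30% of M and
  5% of A are discarded and the rest averaged with inverse delta-method
  variances as weights; factors are centred to geometric mean 1. These are
  the method's original trims and weighting. If fewer than 10 transcripts
  survive the double trim the untrimmed weighted mean is used with a
  warning. The implementation tracks the reference R implementation to well
  under 1% on negative-binomial data (checked in the test suite via
  `edgeR::calcNormFactors` through Rscript).

Differential expression uses Welch's unequal-variance t-test per transcript
under each normalisation, Benjamini–Hochberg step-up adjustment **within
each method across the filtered transcript set** (the adjustment universe
was an open choice; per-method adjustment keeps the three analyses
symmetric), 1-based p-value ranks (ties by |t| descending then id), and a
consensus verdict: significant iff q < α (default 0.05) under all three
methods. The intersection trades sensitivity for specificity; on null
simulations its false-positive rate is far below that of any single method.
Transcripts with all-zero counts in one group bypass the t-test and are
reported as group-exclusive only with ≥ 10 reads in total, an
artifact guard.

## Effect size and power

Cohen's d uses the **simple average of the two group SDs** as denominator,
`d = (x̄₁−x̄₂)/((s₁+s₂)/2)`, not the classical n-weighted pooled SD: the
average-SD form reproduces the published effect-size columns this pipeline
is benchmarked against exactly, while classical pooling does not
(classical pooling remains available via `pooling="classical"`). Power is
the exact two-sided two-sample t-test power from the noncentral t
distribution with `ncp = d·√(n₁n₂/(n₁+n₂))` and `df = n₁+n₂−2` — the
equal-variance df convention standard in power software, even though the
test itself is Welch.

## qPCR absolute quantification

Standard curves are ordinary least squares of Cq on log10(copies) over a
dilution series (≥ 3 distinct concentrations required; < 6 warns).
Efficiency `E = 10^(−1/slope)` must lie in [1.8, 2.1] to pass QC; failures
warn and require an explicit override rather than aborting, since observed
efficiencies are a property of the assay, not a hard gate. Triplicate Cq
are averaged **in the Cq domain** before conversion (log-domain averaging,
the conventional choice) and `copies = 10^((Cq−intercept)/slope)`; values
outside the curve's dilution range are flagged as extrapolated.

The spike-in normalisation factor is reconstructed as
`NF_s = E_spike^(Cq_spike,s − median Cq_spike)` with medians taken **per RNA
fraction** (total vs enriched): a sample whose spike Cq is one cycle above
the median lost roughly half its material and is scaled up by E. The
exponential-in-E form is the standard Cq→quantity relation (exactly
doublings at E = 2); taking medians per fraction means the factor corrects
within-fraction recovery variation while leaving the systematic enrichment
loss visible to the enrichment-impact comparison, which measures it
deliberately as `mean(total copies)/mean(enriched copies)` with a Welch t.
Group comparisons report a signed fold change: `+(case/control)` when cases
are higher, `−(control/case)` when lower, so magnitude is always ≥ 1 and
decreases print negative.

## Synthetic study generator

The generator emulates the structure of whole-blood small-RNA profiles from
a two-group cohort so every stage can be exercised offline:

* **Cohort**: 23 controls vs 14 cases by default (the sequenced-study
  design); one target miRNA truly 2.3-fold down in cases
  (control mean / case mean = 2.3).
* **Abundances**: the top three miRNAs take 60%, 13% and 3% of the pool
  (the observed dominance hierarchy in blood); the rest share the remainder
  log-normally.
* **Counts**: negative binomial with mean μ and dispersion φ = 0.1
  (var = μ + φμ²).
* **isomiRs**: each count is emitted as the canonical sequence (83.1%), the
  canonical with a 3'-appended A (13.8%), or a single random substitution
  (3.1%), with the 3' adapter appended and the read truncated to 32 nt.
* **qPCR**: Cq = intercept + slope·log10(effective copies) + N(0, cq_sd),
  triplicates. In total RNA the mature assay also detects a fraction
  (default 0.5) of a non-dysregulated precursor pool (~2× the mature mean);
  in enriched RNA only recovery × mature copies remain. Per-sample
  processing losses are log-normal (σ = 0.3 log10) and apply to every
  assay including the spike-in, which is what spike normalisation removes.
  Slope −3.3219 (E = 2.0) and intercept 50.9 put the spike-in's total-RNA
  Cq at the observed median 27.4 for 1.2 × 10⁷ copies/µl; the default
  enrichment recovery 0.048 makes the spike's between-fraction Cq shift
  4.38 cycles (27.4 → 31.78). The true precursor:mature ratio in blood
  total RNA is not known; both the detected fraction and the pool size are
  explicit parameters rather than asserted values. Note a consequence: with
  these defaults the simulated total→enriched fold decrease (~40–60×) is
  larger than the 4–12× range reported for real assays, because the
  recovery implied by the spike Cq shift and the contamination pool are set
  independently; the qualitative contrast the pipeline tests (attenuated
  total-RNA fold change, cleaner enriched fold change) does not depend on
  this scale.

All randomness descends from one seed through named SeedSequence streams
(reference, abundances, counts/reads, qPCR copy pools, Cq noise), so
outputs are byte-identical per seed and stages can be re-run independently.

**Scale.** Simulated libraries default to 2 × 10⁴ reads/sample over 30
reference miRNAs — far below real depth (millions of reads, ~10³ annotated
miRNAs). At this depth per-miRNA counts sit in the tens-to-thousands range,
the same regime as real filtered miRNA matrices, so the CPM filter, the
normalisations and the tests behave as at full scale; what the reduced
scale does **not** probe is the long tail of near-threshold transcripts and
rare isomiRs. Passing tests therefore demonstrate correctness of the
computations and recovery of strong signals, not sensitivity at real-data
depth.

## What the generator does not model

Sequencing error beyond single substitutions, quality scores, GC and
ligation bias, tRNA fragments and other non-miRNA small RNAs, multi-mapping
across near-identical miRNA families (references are random sequences, so
cross-matching is rare), and inhibition or melt-curve artefacts in qPCR.
Conclusions about those phenomena cannot be drawn from these simulations.

## Numerical and degenerate-input choices

* Welch test: both group variances zero is an error for the scalar API; in
  the vectorised matrix test such transcripts get t = 0, p = 1 (no
  evidence) rather than aborting a whole run.
* BH: computed by the step-up closed form with a stable sort; verified
  against the brute-force definition and an independent library
  implementation.
* TMM zero handling: transcripts zero in either sample of a pair are
  excluded before M/A computation (log-ratios undefined).
* Standard curves with non-negative slope fail QC with a warning instead of
  raising, so a batch with one bad assay still reports the others.
* Cq rows with non-positive effective copies are omitted with a warning
  (a sample can genuinely drop below detection).
* All parsers reject malformed records with the offending line rather than
  skipping.

## Problem sizes used by the checks

The acceptance script reconstructs the published summary-table statistics
from their printed group summaries (n = 26/15), runs 300 null simulations
(30 transcripts × 16 samples) for consensus-test calibration, and 10
independent end-to-end studies at the default scale above for the
cross-platform recovery signature. These sizes are the package's chosen
operating point for routine verification; all of them scale up by changing
`SimSpec` fields.
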