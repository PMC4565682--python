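# mircross

Cross-platform analysis pipeline for circulating small-RNA biomarkers.

MicroRNAs measured in whole blood are promising disease biomarkers, but
candidates discovered by small-RNA sequencing frequently fail RT-qPCR
validation: the two platforms see different RNA pools (a qPCR assay for a
mature miRNA also detects its precursor in total RNA, while sequencing
libraries are size-selected), and results depend on the normalisation
chosen. `mircross` implements the computational side of a standardised
discovery-to-validation pipeline for researchers comparing the two
platforms:

* **isomiR-tolerant counting** — adapter trimming, 18–25 nt length filter,
  collapsing to unique tags, and assignment to mature miRNAs allowing ±2 nt
  end shifts and ≤ 1 mismatch, with precursor-aware extension matching;
* **consensus differential expression** — Welch's t-test with
  Benjamini–Hochberg FDR under three normalisations (RPKM, quantile, TMM);
  a transcript counts as dysregulated only if significant under all three;
* **effect size and power** — Cohen's d (average-SD denominator) and exact
  two-sample t-test power via the noncentral t distribution;
* **RT-qPCR absolute quantification** — standard-curve fitting with
  efficiency QC (E = 10^(−1/slope) ∈ [1.8, 2.1]), Cq → copies conversion,
  spike-in recovery normalisation NF = E^(ΔCq vs per-fraction median),
  enrichment-impact and group-comparison statistics;
* **a synthetic study generator** — seeded, negative-binomial two-group
  cohorts with realistic isomiR mixtures and Cq data with precursor
  contamination and enrichment recovery loss, so the whole pipeline runs
  and is testable offline.

See `docs/methods.md` for the models and parameter choices.

## Worked example

The `analysis/` scripts run a complete synthetic study end to end:

```sh
python analysis/01_simulate.py --seed 1     # FASTQ + Cq data -> results/sim/
python analysis/02_sequencing_de.py         # counts + consensus DE -> results/seq/
python analysis/03_qpcr_quant.py            # curves + copies + folds -> results/qpcr/
python analysis/04_concordance.py           # cross-platform join -> results/concordance.tsv
```

With seed 1 this prints:

```
simulated 37 samples, 754066 reads, 30 miRNAs (target mir010 at fold change 2.3)
...
30 annotated miRNAs, 30 tested after CPM filter
1 consensus-significant: mir010
  mir010: fold change 1.98, d=1.37, power=0.98
...
standard curves:
  mir010: slope -3.328, E=2.00, R2=0.9989, QC pass
  spike-mir159: slope -3.263, E=2.03, R2=0.9975, QC pass
enrichment impact mir010: 53.2-fold decrease (p=3.2e-08)
group comparison mir010 [enriched]: fold change -2.02 (p=8.7e-07)
group comparison mir010 [total]: fold change -1.31 (p=0.0092)
...
mir010: sequencing consensus=True, qPCR enriched -2.02 vs total -1.31 -> agree
```

Reading this: the one miRNA simulated as truly 2.3-fold down in cases is
the only transcript flagged by the three-normalisation consensus test
(estimated fold change 1.98). On the qPCR side, the total-RNA assay —
contaminated by a non-dysregulated precursor pool — sees only a −1.31-fold
change, while the enriched small-RNA fraction recovers −2.02-fold with a
far smaller p-value. Both platforms agree in direction, and enrichment
makes the dysregulation more pronounced — the behaviour the pipeline is
designed to expose.

The same stages are available as one CLI (`mircross simulate|reads|
annotate|normalise|detest|power|qpcr|concord|run`) for use on real FASTQ /
Cq inputs.

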