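"""Cross-platform concordance: do sequencing and qPCR agree?

Joins the consensus DE verdicts (results/seq/) with the qPCR group
comparisons (results/qpcr/) and reports, per shared target, the fold
changes from each platform/fraction and whether their directions
agree.  Writes results/concordance.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mircross.pipeline import concordance

parser = argparse.ArgumentParser()
parser.add_argument("--seq", type=Path, default=Path("results/seq"))
parser.add_argument("--qpcr", type=Path, default=Path("results/qpcr"))
parser.add_argument("--out", type=Path, default=Path("results/concordance.tsv"))
args = parser.parse_args()

de = pd.read_csv(args.seq / "de.tsv", sep="\t", comment="#", index_col=0)
effect = pd.read_csv(args.seq / "effect_power.tsv", sep="\t", comment="#", index_col=0)
comparison = pd.read_csv(args.qpcr / "comparison.tsv", sep="\t", comment="#")

# signed sequencing fold change from the RPKM effect table
seq_fold = effect["fold_change"].apply(lambda f: -f if f >= 1 else 1 / f)
report = concordance(de, comparison, seq_fold=seq_fold)
report.to_csv(args.out, sep="\t")

print(report.to_string())
for tid, row in report.iterrows():
    verdict = "agree" if row["direction_agree"] else "DISAGREE"
    print(f"{tid}: sequencing consensus={bool(row['seq_consensus'])}, "
          f"qPCR enriched {row['qpcr_fold_enriched']:.2f} vs total {row['qpcr_fold_total']:.2f} -> {verdict}")
print(f"wrote {args.out}")
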