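"""Sequencing arm: reads -> isomiR counts -> consensus DE -> power.

Reads the simulated FASTQ libraries from results/sim/, runs adapter
trimming, length filtering, tag collapsing, isomiR-tolerant annotation,
CPM filtering and the three-normalisation consensus Welch test, then
computes effect sizes and power for every tested transcript from its
group summaries.  Tables land in results/seq/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mircross.de import effect_and_power
from mircross.io_formats import RunConfig, read_reads, read_reference, read_sample_sheet
from mircross.pipeline import sequencing_arm, write_outputs

parser = argparse.ArgumentParser()
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results/seq"))
args = parser.parse_args()

sheet = read_sample_sheet(args.sim / "samples.tsv")
reference = read_reference(args.sim / "reference.fasta")
reads = {s.sample_id: read_reads(args.sim / f"{s.sample_id}.fastq") for s in sheet.samples}
config = RunConfig()

results = sequencing_arm(reads, reference, sheet, config)
de = results["de"]

# per-transcript effect size and power from the RPKM group summaries
from mircross.normalise import rpkm

values = rpkm(results["filtered"]).values
groups = results["filtered"].groups
rows = []
for tid in values.index:
    control = values.loc[tid, groups == "control"]
    case = values.loc[tid, groups == "case"]
    if control.std(ddof=1) > 0 and case.std(ddof=1) > 0 and case.mean() > 0:
        ep = effect_and_power(control.mean(), control.std(ddof=1), case.mean(),
                              case.std(ddof=1), len(control), len(case))
        rows.append({"transcript_id": tid, "fold_change": ep.fold_change,
                     "d": ep.d, "power": ep.power})
power_table = pd.DataFrame(rows).set_index("transcript_id")
results["effect_power"] = power_table

write_outputs(results, args.out, config)

n_cons = int(de["consensus"].sum())
print(f"{len(results['matrix'].counts)} annotated miRNAs, {len(de)} tested after CPM filter")
print(f"{n_cons} consensus-significant:", ", ".join(de.index[de["consensus"]]))
for tid in de.index[de["consensus"]]:
    if tid in power_table.index:
        row = power_table.loc[tid]
        print(f"  {tid}: fold change {row['fold_change']:.2f}, d={row['d']:.2f}, power={row['power']:.2f}")
print(f"outputs in {args.out}")
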