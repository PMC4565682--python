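"""End-to-end orchestration and the cross-platform concordance report.

The sequencing arm runs reads -> annotate -> filter -> consensus DE;
the qPCR arm runs curves -> quantify -> spike-in normalise ->
enrichment impact -> group comparison.  The concordance report joins
the two arms on transcript/assay id and flags whether every reported
fold change points the same way.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import consensus_test, exclusive_rule
from .io_formats import (
    CountMatrix,
    ReferenceSet,
    RunConfig,
    SampleSheet,
    write_count_matrix,
)
from .isomir import annotate
from .normalise import cpm_filter
from .qpcr import (
    enrichment_impact,
    fit_curves_from_table,
    group_compare,
    quantify,
    spikein_control,
    spikein_normalise,
)
from .reads import merge_tags, process_sample

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def provenance(config: RunConfig) -> str:
    return f"mircross {__version__} config={config.config_hash()} seed={config.seed}"


def sequencing_arm(
    reads_by_sample: dict[str, list],
    reference: ReferenceSet,
    sheet: SampleSheet,
    config: RunConfig,
) -> dict[str, object]:
    """Reads through consensus DE; returns the intermediate tables."""
    tags_per_sample = []
    lib_sizes = {}
    try:
        for sample_id, reads in reads_by_sample.items():
            tags, n_clean = process_sample(
                reads,
                sample_id,
                config.adapter,
                config.min_len,
                config.max_len,
                config.min_overlap,
                config.max_mismatch_rate,
            )
            tags_per_sample.append(tags)
            lib_sizes[sample_id] = n_clean
    except Exception as exc:
        raise StageError("reads", str(exc)) from exc

    try:
        tags = merge_tags(tags_per_sample)
        matrix, unannotated, composition = annotate(
            tags,
            reference,
            sample_ids=list(reads_by_sample),
            max_shift=config.isomir_max_shift,
            max_mismatch=config.isomir_max_mismatch,
        )
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc

    matrix.groups = sheet.groups.reindex(matrix.counts.columns)
    matrix.lib_sizes = pd.Series(lib_sizes).reindex(matrix.counts.columns).astype(float)

    try:
        filtered = cpm_filter(matrix, config.cpm_threshold, config.cpm_min_samples)
        de = consensus_test(filtered, config)
        exclusive = exclusive_rule(matrix, config.exclusive_min_reads)
    except Exception as exc:
        raise StageError("detest", str(exc)) from exc

    return {
        "matrix": matrix,
        "filtered": filtered,
        "de": de,
        "exclusive": exclusive,
        "unannotated": unannotated,
        "composition": composition,
    }


def qpcr_arm(
    cq_table: pd.DataFrame,
    standards: pd.DataFrame,
    sheet: SampleSheet,
    spike_assay: str,
    allow_qc_fail: bool = False,
) -> dict[str, pd.DataFrame]:
    """Cq data through curves, quantification, spike-in normalisation,
    enrichment impact and group comparison."""
    try:
        curves = fit_curves_from_table(standards)
    except Exception as exc:
        raise StageError("curves", str(exc)) from exc
    try:
        quant = quantify(cq_table, curves, allow_qc_fail=allow_qc_fail)
        spike = spikein_control(quant, spike_assay)
        quant = spikein_normalise(quant, spike, curves[spike_assay].efficiency)
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    try:
        impact = enrichment_impact(quant, exclude_assays=(spike_assay,))
        comparison = group_compare(quant, sheet, exclude_assays=(spike_assay,))
    except Exception as exc:
        raise StageError("group_compare", str(exc)) from exc
    curve_table = pd.DataFrame(
        [
            {
                "assay_id": c.assay_id,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency": c.efficiency,
                "qc_pass": c.qc_pass,
            }
            for c in curves.values()
        ]
    )
    return {
        "curves": curve_table,
        "quant": quant,
        "impact": impact,
        "comparison": comparison,
    }


def concordance(
    de: pd.DataFrame, qpcr_comparison: pd.DataFrame, seq_fold: pd.Series | None = None
) -> pd.DataFrame:
    """Cross-platform concordance, ranked by |enriched qPCR fold change|.

    Joins DE results and qPCR group comparisons on transcript/assay id.
    ``seq_fold`` optionally supplies signed sequencing fold changes;
    direction_agree is true iff every reported fold change shares one
    sign.  An empty join yields an empty report with a warning.
    """
    wide = qpcr_comparison.pivot_table(
        index="assay_id", columns="fraction", values="fold_change"
    )
    shared = de.index.intersection(wide.index)
    if shared.empty:
        logger.warning("no shared identifiers between platforms; empty concordance report")
        return pd.DataFrame(
            columns=["seq_consensus", "seq_fold", "qpcr_fold_total", "qpcr_fold_enriched", "direction_agree"]
        )
    report = pd.DataFrame(index=shared)
    report["seq_consensus"] = de.loc[shared, "consensus"]
    report["seq_fold"] = seq_fold.reindex(shared) if seq_fold is not None else pd.NA
    report["qpcr_fold_total"] = wide.reindex(shared).get("total")
    report["qpcr_fold_enriched"] = wide.reindex(shared).get("enriched")
    folds = report[["seq_fold", "qpcr_fold_total", "qpcr_fold_enriched"]].apply(
        pd.to_numeric, errors="coerce"
    )
    signs = folds.apply(lambda row: set(np.sign(v) for v in row.dropna()), axis=1)
    report["direction_agree"] = signs.apply(lambda s: len(s) == 1)
    report = report.sort_values("qpcr_fold_enriched", key=lambda s: s.abs(), ascending=False)
    report.index.name = "id"
    return report


def write_outputs(results: dict, out_dir, config: RunConfig) -> list[Path]:
    """Write every table in a result bundle as TSV with a provenance header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = provenance(config)
    written = []
    for name, obj in results.items():
        path = out_dir / f"{name}.tsv"
        if isinstance(obj, CountMatrix):
            write_count_matrix(obj, path, header_comment=header)
        elif isinstance(obj, pd.DataFrame):
            with open(path, "w") as handle:
                handle.write(f"# {header}\n")
                obj.to_csv(handle, sep="\t")
        elif isinstance(obj, list):  # unannotated tags
            with open(path, "w") as handle:
                handle.write(f"# {header}\nsequence\ttotal_count\n")
                for tag in obj:
                    handle.write(f"{tag.sequence}\t{tag.total}\n")
        else:
            continue
        written.append(path)
    return written
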