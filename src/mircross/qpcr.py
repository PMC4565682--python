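"""RT-qPCR absolute quantification and spike-in enrichment normalisation.

A standard curve (ordinary least squares of Cq on log10 copies over a
dilution series) converts quantification cycles into absolute copy
numbers; amplification efficiency E = 10^(-1/slope) should sit between
1.8 and 2.1 for a well-behaved assay.  An exogenous spike-in miRNA
added before size selection tracks per-sample recovery: samples are
rescaled by E_spike^(Cq_spike - median Cq_spike within the fraction),
so a sample with poorer recovery (higher spike Cq) is scaled up.
Medians are taken per fraction (total vs enriched RNA) so the factor
corrects within-fraction recovery variation, not the enrichment loss
itself — the loss is measured deliberately by the enrichment-impact
comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FRACTIONS, SampleSheet
from .de import welch_t

logger = logging.getLogger(__name__)

EFFICIENCY_RANGE = (1.8, 2.1)


@dataclass
class StandardCurve:
    assay_id: str
    slope: float  # cycles per log10(copies)
    intercept: float  # Cq at 1 copy
    r_squared: float
    efficiency: float  # fold amplification per cycle, 10^(-1/slope)
    qc_pass: bool
    copies_range: tuple[float, float] | None = None


@dataclass
class SpikeInControl:
    assay_id: str
    median_cq_total: float
    median_cq_enriched: float
    per_sample_cq: pd.DataFrame  # columns sample_id, fraction, cq

    def median(self, fraction: str) -> float:
        return self.median_cq_total if fraction == "total" else self.median_cq_enriched


def fit_standard_curve(dilution_points, assay_id: str = "") -> StandardCurve:
    """Fit Cq = intercept + slope * log10(copies) by ordinary least squares.

    ``dilution_points`` is an iterable of (copies, cq) pairs; at least
    3 distinct concentrations are required (a warning is issued below
    the conventional 6).  QC passes when efficiency lies in [1.8, 2.1].
    """
    points = [(float(c), float(q)) for c, q in dilution_points]
    copies = np.array([c for c, _ in points])
    cq = np.array([q for _, q in points])
    if (copies <= 0).any():
        raise ValueError("standard-curve copies must be positive")
    distinct = np.unique(copies)
    if distinct.size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if distinct.size < 6:
        warnings.warn(
            f"standard curve {assay_id or '?'} has {distinct.size} dilutions; 6+ recommended",
            stacklevel=2,
        )
    result = stats.linregress(np.log10(copies), cq)
    slope, intercept = float(result.slope), float(result.intercept)
    if slope >= 0:
        warnings.warn(f"standard curve {assay_id or '?'} has non-negative slope", stacklevel=2)
        efficiency = float("nan")
        qc = False
    else:
        efficiency = float(10 ** (-1.0 / slope))
        qc = EFFICIENCY_RANGE[0] <= efficiency <= EFFICIENCY_RANGE[1]
    return StandardCurve(
        assay_id=assay_id,
        slope=slope,
        intercept=intercept,
        r_squared=float(result.rvalue**2),
        efficiency=efficiency,
        qc_pass=qc,
        copies_range=(float(distinct.min()), float(distinct.max())),
    )


def fit_curves_from_table(standards: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one curve per assay from a table with columns
    assay_id, copies, cq (replicate rows allowed)."""
    return {
        assay: fit_standard_curve(zip(sub["copies"], sub["cq"]), assay_id=assay)
        for assay, sub in standards.groupby("assay_id")
    }


def quantify(
    cq_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    allow_qc_fail: bool = False,
) -> pd.DataFrame:
    """Convert Cq replicates to absolute copies per (sample, assay, fraction).

    Replicates are averaged to mean Cq before conversion (log-domain
    averaging); raw_copies = 10^((mean_cq - intercept)/slope).  Rows
    whose mean Cq falls outside the curve's dilution range are flagged
    ``extrapolated``.
    """
    rows = []
    grouped = cq_table.groupby(["sample_id", "assay_id", "fraction"], sort=True)
    for (sample_id, assay_id, fraction), sub in grouped:
        if assay_id not in curves:
            raise KeyError(f"no standard curve for assay {assay_id!r}")
        curve = curves[assay_id]
        if not curve.qc_pass and not allow_qc_fail:
            raise ValueError(
                f"curve for {assay_id!r} failed efficiency QC "
                f"(E={curve.efficiency:.3g}); pass allow_qc_fail to override"
            )
        mean_cq = float(sub["cq"].mean())
        raw_copies = float(10 ** ((mean_cq - curve.intercept) / curve.slope))
        extrapolated = False
        if curve.copies_range is not None:
            lo, hi = curve.copies_range
            extrapolated = not (lo <= raw_copies <= hi)
        rows.append(
            {
                "sample_id": sample_id,
                "assay_id": assay_id,
                "fraction": fraction,
                "mean_cq": mean_cq,
                "raw_copies": raw_copies,
                "extrapolated": extrapolated,
            }
        )
    return pd.DataFrame(rows)


def spikein_control(quant: pd.DataFrame, spike_assay: str) -> SpikeInControl:
    """Summarise the spike-in assay: per-fraction median Cq across samples."""
    spike = quant.loc[quant["assay_id"] == spike_assay]
    if spike.empty:
        raise ValueError(f"no rows for spike assay {spike_assay!r}")
    medians = spike.groupby("fraction")["mean_cq"].median()
    return SpikeInControl(
        assay_id=spike_assay,
        median_cq_total=float(medians.get("total", np.nan)),
        median_cq_enriched=float(medians.get("enriched", np.nan)),
        per_sample_cq=spike[["sample_id", "fraction", "mean_cq"]].rename(columns={"mean_cq": "cq"}),
    )


def spikein_normalise(
    quant: pd.DataFrame,
    spike: SpikeInControl,
    efficiency_spike: float,
) -> pd.DataFrame:
    """Apply per-sample spike-in normalisation factors.

    NF_s = E_spike^(Cq_spike,s - median Cq_spike within the fraction);
    normalised_copies = raw_copies * NF_s.  Samples missing a spike
    measurement are flagged (normalised_copies = NaN), never silently
    passed through.
    """
    if efficiency_spike <= 1:
        raise ValueError("spike efficiency must exceed 1")
    spike_cq = spike.per_sample_cq.set_index(["sample_id", "fraction"])["cq"]
    out = quant.copy()
    factors = []
    missing = []
    for _, row in out.iterrows():
        key = (row["sample_id"], row["fraction"])
        if key not in spike_cq.index:
            factors.append(np.nan)
            missing.append(key)
            continue
        delta = spike_cq.loc[key] - spike.median(row["fraction"])
        factors.append(float(efficiency_spike**delta))
    if missing:
        logger.warning("no spike-in measurement for %s; flagged NaN", sorted(set(missing)))
    out["spike_factor"] = factors
    out["normalised_copies"] = out["raw_copies"] * out["spike_factor"]
    return out


def fold_decrease(mean_total: float, mean_enriched: float) -> float:
    """Fold decrease of detected copies after small-RNA enrichment."""
    if mean_enriched <= 0:
        raise ValueError("enriched mean must be positive")
    return mean_total / mean_enriched


def enrichment_impact(
    quant: pd.DataFrame, value_col: str = "raw_copies", exclude_assays=()
) -> pd.DataFrame:
    """Per-assay fold decrease from total to enriched RNA, with Welch t p.

    Assays present in only one fraction are skipped with a warning.
    """
    rows = []
    for assay, sub in quant.groupby("assay_id"):
        if assay in exclude_assays:
            continue
        total = sub.loc[sub["fraction"] == "total", value_col].to_numpy(dtype=float)
        enriched = sub.loc[sub["fraction"] == "enriched", value_col].to_numpy(dtype=float)
        if total.size == 0 or enriched.size == 0:
            warnings.warn(f"assay {assay!r} missing a fraction; skipped", stacklevel=2)
            continue
        t, _, p = welch_t(total, enriched)
        rows.append(
            {
                "assay_id": assay,
                "mean_total": total.mean(),
                "sd_total": total.std(ddof=1) if total.size > 1 else np.nan,
                "mean_enriched": enriched.mean(),
                "sd_enriched": enriched.std(ddof=1) if enriched.size > 1 else np.nan,
                "fold_decrease": fold_decrease(total.mean(), enriched.mean()),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def signed_fold_change(mean_control: float, mean_case: float) -> float:
    """Signed fold change, negative when cases are lower than controls.

    +(case/control) when case >= control, else -(control/case); the
    magnitude is always >= 1.
    """
    if mean_control <= 0 or mean_case <= 0:
        raise ValueError("group means must be positive")
    if mean_case >= mean_control:
        return mean_case / mean_control
    return -(mean_control / mean_case)


def group_compare(
    quant: pd.DataFrame,
    sheet: SampleSheet,
    value_col: str = "normalised_copies",
    fractions=FRACTIONS,
    exclude_assays=(),
) -> pd.DataFrame:
    """Per-assay, per-fraction control/case comparison of copy numbers.

    Welch t-test on copies plus the signed fold change (negative for a
    decrease in cases).
    """
    groups = sheet.groups
    rows = []
    for (assay, fraction), sub in quant.groupby(["assay_id", "fraction"]):
        if assay in exclude_assays or fraction not in fractions:
            continue
        sub = sub.dropna(subset=[value_col])
        labels = groups.reindex(sub["sample_id"]).to_numpy()
        control = sub.loc[labels == "control", value_col].to_numpy(dtype=float)
        case = sub.loc[labels == "case", value_col].to_numpy(dtype=float)
        if control.size < 2 or case.size < 2:
            warnings.warn(f"{assay}/{fraction}: <2 samples in a group; skipped", stacklevel=2)
            continue
        if control.mean() <= 0 or case.mean() <= 0:
            raise ValueError(f"{assay}/{fraction}: non-positive group mean")
        t, _, p = welch_t(control, case)
        rows.append(
            {
                "assay_id": assay,
                "fraction": fraction,
                "mean_control": control.mean(),
                "sd_control": control.std(ddof=1),
                "se_control": control.std(ddof=1) / np.sqrt(control.size),
                "mean_case": case.mean(),
                "sd_case": case.std(ddof=1),
                "se_case": case.std(ddof=1) / np.sqrt(case.size),
                "n_control": control.size,
                "n_case": case.size,
                "t": t,
                "p": p,
                "fold_change": signed_fold_change(control.mean(), case.mean()),
            }
        )
    return pd.DataFrame(rows)
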