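"""Consensus differential expression, effect size and power.

A transcript is called differentially expressed only when the Welch
t-test with Benjamini-Hochberg correction is significant under *all
three* normalisations (RPKM, quantile, TMM) — an intersection rule that
trades sensitivity for specificity.  Group-exclusive transcripts
(all-zero in one group) are reported separately and must carry at
least 10 reads in total to exclude sequencing artifacts.

Effect sizes are Cohen's d with the average-of-SDs denominator
(d = Δmean / ((sd1 + sd2)/2)); power is the exact two-sided two-sample
t-test power from the noncentral t distribution with
ncp = d * sqrt(n1 n2 / (n1 + n2)) and df = n1 + n2 - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, RunConfig
from . import normalise as norm

METHODS = ("rpkm", "quantile", "tmm")


def welch_t(values_control, values_case) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, p two-tailed).

    t is positive when the control mean exceeds the case mean.
    """
    x = np.asarray(values_control, dtype=float)
    y = np.asarray(values_case, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both group variances are zero")
    return welch_t_from_stats(x.mean(), np.sqrt(vx), x.size, y.mean(), np.sqrt(vy), y.size)


def welch_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df and two-tailed p from summaries."""
    se2_1 = sd1**2 / n1
    se2_2 = sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(se2_1 + se2_2)
    df = (se2_1 + se2_2) ** 2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; order-preserving.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _welch_matrix(values: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    control = values.loc[:, groups == "control"].to_numpy(dtype=float)
    case = values.loc[:, groups == "case"].to_numpy(dtype=float)
    n1, n2 = control.shape[1], case.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    m1, m2 = control.mean(axis=1), case.mean(axis=1)
    v1, v2 = control.var(axis=1, ddof=1), case.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    # zero-variance transcripts with equal means carry no evidence
    t = np.where(se2 == 0, 0.0, t)
    df = np.where(se2 == 0, n1 + n2 - 2, df)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    p = np.where(t == 0, 1.0, p)
    return pd.DataFrame({"t": t, "df": df, "p": p}, index=values.index)


def consensus_test(
    matrix: CountMatrix,
    config: RunConfig | None = None,
    methods=METHODS,
) -> pd.DataFrame:
    """Welch + BH under each normalisation, with the consensus verdict.

    ``matrix`` must already be CPM-filtered and carry group labels.
    Returns one row per transcript with, per method, t, p, BH q and the
    1-based p-value rank (ties broken by |t| descending then id), plus
    ``consensus`` = q < alpha under all methods.
    """
    if config is None:
        config = RunConfig()
    if matrix.groups is None:
        raise ValueError("count matrix needs group labels")
    normalised = {}
    for method in methods:
        if method == "rpkm":
            normalised[method] = norm.rpkm(matrix).values
        elif method == "quantile":
            normalised[method] = norm.quantile_normalise(matrix, config.quantile_mode).values
        elif method == "tmm":
            normalised[method] = norm.tmm(matrix, config.tmm_trim_m, config.tmm_trim_a).values
        else:
            raise ValueError(f"unknown method {method!r}")

    out = pd.DataFrame(index=matrix.counts.index)
    consensus = np.ones(len(out), dtype=bool)
    for method, values in normalised.items():
        res = _welch_matrix(values, matrix.groups)
        q = bh_adjust(res["p"].to_numpy())
        rank_key = pd.DataFrame(
            {"p": res["p"], "negabs_t": -res["t"].abs(), "id": res.index}
        )
        rank = rank_key.sort_values(["p", "negabs_t", "id"]).index
        ranks = pd.Series(np.arange(1, len(rank) + 1), index=rank).reindex(res.index)
        out[f"{method}_t"] = res["t"]
        out[f"{method}_p"] = res["p"]
        out[f"{method}_q"] = q
        out[f"{method}_rank"] = ranks.astype(int)
        consensus &= q < config.alpha
    out["consensus"] = consensus
    return out


def exclusive_rule(matrix: CountMatrix, min_total: int = 10) -> pd.DataFrame:
    """Group-exclusive transcripts passing the artifact threshold.

    A transcript with all-zero raw counts in one group is reported iff
    its total count across samples is >= min_total.
    """
    if matrix.groups is None:
        raise ValueError("count matrix needs group labels")
    counts = matrix.counts
    control_sum = counts.loc[:, matrix.groups == "control"].sum(axis=1)
    case_sum = counts.loc[:, matrix.groups == "case"].sum(axis=1)
    total = control_sum + case_sum
    exclusive = ((control_sum == 0) ^ (case_sum == 0)) & (total >= min_total)
    report = pd.DataFrame(
        {
            "present_in": np.where(control_sum > 0, "control", "case"),
            "total_count": total,
        }
    )
    return report.loc[exclusive]


@dataclass
class EffectPower:
    mean_control: float
    sd_control: float
    mean_case: float
    sd_case: float
    n_control: int
    n_case: int
    fold_change: float  # control / case
    d: float
    power: float


def cohens_d(
    mean_control: float, sd_control: float, mean_case: float, sd_case: float,
    pooling: str = "average",
) -> float:
    """Standardised mean difference.

    pooling="average" divides by the simple mean of the two group SDs;
    pooling="classical" uses the n-weighted pooled SD (needs ns via
    :func:`effect_and_power`).
    """
    if pooling != "average":
        raise ValueError("classical pooling is handled by effect_and_power")
    return (mean_control - mean_case) / ((sd_control + sd_case) / 2.0)


def t_test_power(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Exact two-sided two-sample t-test power via the noncentral t."""
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1 - alpha / 2.0, df)
    power = stats.nct.sf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp)
    return float(power)


def effect_and_power(
    mean_control: float,
    sd_control: float,
    mean_case: float,
    sd_case: float,
    n_control: int,
    n_case: int,
    alpha: float = 0.05,
    pooling: str = "average",
) -> EffectPower:
    """Fold change, Cohen's d and power from group summaries."""
    if n_control < 2 or n_case < 2:
        raise ValueError("need >= 2 samples per group")
    if sd_control <= 0 or sd_case <= 0:
        raise ValueError("group SDs must be positive")
    if mean_case == 0:
        raise ValueError("fold change undefined for zero case mean")
    if pooling == "average":
        d = cohens_d(mean_control, sd_control, mean_case, sd_case)
    elif pooling == "classical":
        pooled = np.sqrt(
            ((n_control - 1) * sd_control**2 + (n_case - 1) * sd_case**2)
            / (n_control + n_case - 2)
        )
        d = (mean_control - mean_case) / pooled
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return EffectPower(
        mean_control=mean_control,
        sd_control=sd_control,
        mean_case=mean_case,
        sd_case=sd_case,
        n_control=n_control,
        n_case=n_case,
        fold_change=mean_control / mean_case,
        d=float(d),
        power=t_test_power(d, n_control, n_case, alpha),
    )
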