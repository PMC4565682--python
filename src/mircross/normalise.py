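"""Expression filtering and the three between/within-sample normalisations.

The consensus differential-expression test requires the same filtered
matrix normalised three ways:

* RPKM — within-sample scaling by library size and transcript length;
* quantile — full order-statistic replacement (or upper-quartile
  scaling, both offered because the two are often conflated);
* TMM — trimmed mean of M-values: a per-sample scale factor from
  doubly-trimmed, precision-weighted log-ratios against a reference
  sample, geometric-mean centred.

Library sizes are the per-sample cleaned-read totals; transcripts must
reach 1 count per million in at least 3 samples to be tested.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalisedMatrix:
    method: str  # rpkm | quantile | tmm
    values: pd.DataFrame
    scale_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("normalised values must be non-negative")


def cpm_filter(
    matrix: CountMatrix, threshold: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep transcripts with CPM >= threshold in >= min_samples samples."""
    lib_sizes = matrix.effective_lib_sizes()
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    cpm = matrix.counts.div(lib_sizes, axis=1) * 1e6
    keep = (cpm >= threshold).sum(axis=1) >= min_samples
    return matrix.subset_transcripts(matrix.counts.index[keep])


def rpkm(matrix: CountMatrix) -> NormalisedMatrix:
    """Reads per kilobase (of mature sequence) per million cleaned reads."""
    if matrix.lengths is None:
        raise ValueError("RPKM needs transcript lengths")
    lib_sizes = matrix.effective_lib_sizes()
    if (lib_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    values = (
        matrix.counts.mul(1e9)
        .div(matrix.lengths, axis=0)
        .div(lib_sizes, axis=1)
    )
    return NormalisedMatrix("rpkm", values)


def quantile_normalise(matrix: CountMatrix, mode: str = "full") -> NormalisedMatrix:
    """Quantile normalisation of the count matrix.

    mode="full": each sample's order statistics are replaced by the
    cross-sample mean order statistics, ties receiving the mean of
    their would-be values.  mode="upper_quartile": each sample is
    scaled so its 75th percentile of nonzero counts equals the
    geometric mean of those percentiles across samples.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("a sample with all-zero counts has no quantiles")
    if mode == "full":
        arr = counts.to_numpy(dtype=float)
        order_means = np.sort(arr, axis=0).mean(axis=1)
        out = np.empty_like(arr)
        for j in range(arr.shape[1]):
            ranks = rankdata(arr[:, j], method="average")  # 1-based, ties averaged
            out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), order_means)
        values = pd.DataFrame(out, index=counts.index, columns=counts.columns)
        return NormalisedMatrix("quantile", values)
    if mode == "upper_quartile":
        q75_map = {}
        for col in counts.columns:
            nonzero = counts[col].to_numpy(dtype=float)
            nonzero = nonzero[nonzero > 0]
            if nonzero.size == 0:
                raise ValueError(f"upper-quartile undefined for all-zero sample {col!r}")
            q75_map[col] = np.percentile(nonzero, 75)
        q75 = pd.Series(q75_map)
        geo = float(np.exp(np.log(q75).mean()))
        factors = geo / q75
        values = counts.mul(factors, axis=1)
        return NormalisedMatrix("quantile", values, scale_factors=factors)
    raise ValueError(f"unknown quantile mode {mode!r}")


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference sample.

    M = log2 expression ratio, A = average log2 expression; the top and
    bottom trim_m of M and trim_a of A are discarded and the remaining
    M are averaged with inverse delta-method (binomial) variances as
    weights.
    """
    use = (obs > 0) & (ref > 0)
    obs, ref = obs[use].astype(float), ref[use].astype(float)
    if obs.size == 0:
        return 1.0
    log_obs = np.log2(obs / n_obs)
    log_ref = np.log2(ref / n_ref)
    m = log_obs - log_ref
    a = (log_obs + log_ref) / 2.0
    weights = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < 10:
        logger.warning("fewer than 10 transcripts survive TMM trimming; using untrimmed mean")
        keep = np.ones(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / weights[keep]
    f = np.sum(m[keep] * inv_w) / np.sum(inv_w)
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Per-sample TMM scale factors, geometric mean 1.

    The reference sample is the one whose 75th percentile of
    count/library-size is closest to the mean of those percentiles.
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib_sizes = matrix.effective_lib_sizes().to_numpy(dtype=float)
    arr = counts.to_numpy(dtype=float)
    f75 = np.array(
        [np.percentile(arr[:, j], 75) / lib_sizes[j] for j in range(arr.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair(arr[:, j], arr[:, ref_idx], lib_sizes[j], lib_sizes[ref_idx], trim_m, trim_a)
            for j in range(arr.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm(matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> NormalisedMatrix:
    """TMM-normalised expression: count / (library size x factor) x 1e6."""
    factors = tmm_factors(matrix, trim_m, trim_a)
    lib_sizes = matrix.effective_lib_sizes()
    values = matrix.counts.div(lib_sizes * factors, axis=1) * 1e6
    return NormalisedMatrix("tmm", values, scale_factors=factors)
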