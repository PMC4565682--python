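"""Synthetic study generator: reference sets, read libraries, Cq data.

Emulates the statistical structure of a circulating small-RNA study of
whole blood so every pipeline stage has deterministic, seedable
fixtures:

* a few miRNAs dominate the profile (the most abundant species takes
  ~60% of reads, the runner-up ~13%);
* each miRNA is emitted as an isomiR mixture (canonical sequence
  ~83.1%, the canonical plus a 3' A ~13.8%, other variants ~3.1%);
* between-sample count variation is negative binomial;
* differentially expressed targets have the case-group mean divided by
  the specified fold change;
* Cq data follow Cq = intercept + slope*log10(effective copies) with
  Gaussian replicate noise; the mature assay cross-detects a fraction
  of the precursor pool in total RNA, while the enriched fraction keeps
  only recovery x mature copies; an exogenous spike-in is measured in
  both fractions with the same per-sample processing losses.

All randomness descends from ``SimSpec.seed`` via SeedSequence
spawning, so outputs are byte-identical under a fixed spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    PRECURSOR_SUFFIX,
    Read,
    RefEntry,
    ReferenceSet,
    Sample,
    SampleSheet,
)

BASES = np.array(list("ACGT"))
READ_LENGTH = 32


@dataclass(frozen=True)
class IsomirVariant:
    """One isomiR class: end offsets, optional mismatch, mixture fraction."""

    offset5: int = 0
    offset3: int = 0
    mismatch: bool = False
    fraction: float = 1.0
    extension_base: str = "A"  # non-templated 3' addition default


@dataclass(frozen=True)
class QPCRSpec:
    """Cq-generation parameters.

    Defaults place the spike-in total-RNA Cq at the observed median
    27.4 for 1.2e7 copies/µl, and set the enrichment recovery so the
    spike's Cq shift between fractions is 4.38 cycles (27.4 -> 31.78)
    at slope -3.3219 (efficiency 2.0).
    """

    slope: float = -3.3219  # cycles per log10(copies)
    intercept: float = 50.9  # cycles at 1 copy
    cq_sd: float = 0.25  # replicate noise, cycles
    precursor_fraction_total: float = 0.5  # precursor pool detected in total RNA
    enrichment_recovery: float = 0.048  # mature fraction surviving size selection
    spike_copies: float = 1.2e7  # copies/µl
    proc_sd_log10: float = 0.3  # per-sample processing loss spread
    n_replicates: int = 3


@dataclass(frozen=True)
class SimSpec:
    """Study design of one synthetic experiment.

    The cohort defaults to the sequenced study design: 23 controls vs
    14 cases, one target dysregulated at fold change 2.3
    (control/case), negative-binomial counts with dispersion 0.1, and
    the observed isomiR mixture of a dominant canonical sequence.
    Library size defaults to 2e4 reads/sample, a scaled-down depth that
    keeps per-miRNA counts in the regime where the filters and tests
    behave as at full depth.
    """

    n_mirnas: int = 30
    n_control: int = 23
    n_case: int = 14
    lib_size_mean: float = 20_000
    nb_dispersion: float = 0.1
    de_targets: tuple[tuple[str, float], ...] = (("mir010", 2.3),)
    isomir_profile: tuple[IsomirVariant, ...] = (
        IsomirVariant(0, 0, False, 0.831),
        IsomirVariant(0, 1, False, 0.138),
        IsomirVariant(0, 0, True, 0.031),
    )
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    mature_length: int = 22
    precursor_length: int = 60
    qpcr: QPCRSpec = field(default_factory=QPCRSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(v.fraction for v in self.isomir_profile)
        if not np.isclose(total, 1.0):
            raise ValueError(f"isomir_profile fractions sum to {total}, not 1")
        for _, fc in self.de_targets:
            if fc <= 0:
                raise ValueError("fold changes must be positive")
        if not (0 < self.qpcr.enrichment_recovery <= 1):
            raise ValueError("enrichment_recovery must lie in (0, 1]")


def mirna_id(i: int) -> str:
    return f"mir{i:03d}"


def _rng(spec: SimSpec, stream: int) -> np.random.Generator:
    """Stage-specific generator: stream 0 reference, 1 abundances,
    2 counts/reads, 3 qPCR copy pools, 4 Cq noise."""
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(stream + 1)[stream])


def simulate_reference(spec: SimSpec) -> ReferenceSet:
    """Random mature sequences plus precursors for the DE targets.

    Each precursor contains its mature sequence as an exact substring,
    flanked by random hairpin context.
    """
    rng = _rng(spec, 0)
    target_ids = {t for t, _ in spec.de_targets}
    entries = []
    seen = set()
    for i in range(spec.n_mirnas):
        while True:
            mature = "".join(rng.choice(BASES, size=spec.mature_length))
            if mature not in seen:
                seen.add(mature)
                break
        rid = mirna_id(i)
        entries.append(RefEntry(rid, mature, "mature"))
        if rid in target_ids:
            flank = spec.precursor_length - spec.mature_length
            left = flank // 2
            pre = (
                "".join(rng.choice(BASES, size=left))
                + mature
                + "".join(rng.choice(BASES, size=flank - left))
            )
            entries.append(RefEntry(rid + PRECURSOR_SUFFIX, pre, "precursor"))
    return ReferenceSet(entries)


def baseline_abundances(spec: SimSpec) -> pd.Series:
    """Relative abundances dominated by a few species.

    The first miRNA takes 60% of the pool, the second 13%, the third
    3% (the observed whole-blood hierarchy); the rest share the
    remainder log-normally.
    """
    rng = _rng(spec, 1)
    rel = np.empty(spec.n_mirnas)
    head = [0.60, 0.13, 0.03][: spec.n_mirnas]
    rel[: len(head)] = head
    rest = spec.n_mirnas - len(head)
    if rest > 0:
        tail = rng.lognormal(mean=0.0, sigma=1.0, size=rest)
        rel[len(head) :] = tail / tail.sum() * (1.0 - sum(head))
    return pd.Series(rel, index=[mirna_id(i) for i in range(spec.n_mirnas)], name="rel_abundance")


def sample_sheet(spec: SimSpec) -> SampleSheet:
    samples = [Sample(f"ctrl{i:02d}", "control") for i in range(spec.n_control)]
    samples += [Sample(f"case{i:02d}", "case") for i in range(spec.n_case)]
    return SampleSheet(samples)


def true_counts(spec: SimSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial true counts, transcripts x samples.

    Mean for transcript g in sample s is lib_size_mean x relative
    abundance, divided by the fold change for DE targets in cases.
    NB is parameterised by mean mu and dispersion phi (var = mu +
    phi mu^2).
    """
    if rng is None:
        rng = _rng(spec, 2)
    rel = baseline_abundances(spec)
    sheet = sample_sheet(spec)
    fold = dict(spec.de_targets)
    counts = {}
    for s in sheet.samples:
        mu = rel * spec.lib_size_mean
        if s.group == "case":
            for target, fc in fold.items():
                if target in mu.index:
                    mu[target] = mu[target] / fc
        if spec.nb_dispersion > 0:
            size = 1.0 / spec.nb_dispersion
            p = size / (size + mu)
            counts[s.sample_id] = rng.negative_binomial(size, p)
        else:
            counts[s.sample_id] = rng.poisson(mu)
    df = pd.DataFrame(counts, index=rel.index)
    df.index.name = "transcript_id"
    return df


def _make_variant(
    mature: str,
    precursor: str | None,
    variant: IsomirVariant,
    rng: np.random.Generator,
) -> str:
    seq = mature
    mat_at = precursor.find(mature) if precursor else -1
    # 5' end
    if variant.offset5 < 0:
        ext = ""
        for k in range(-variant.offset5, 0, -1):
            pos = mat_at - k if mat_at >= 0 else -1
            ext += precursor[pos] if precursor and pos >= 0 else variant.extension_base
        seq = ext + seq
    elif variant.offset5 > 0:
        seq = seq[variant.offset5 :]
    # 3' end
    if variant.offset3 > 0:
        for k in range(variant.offset3):
            pos = mat_at + len(mature) + k if mat_at >= 0 else -1
            seq = seq + (
                precursor[pos]
                if precursor and 0 <= pos < len(precursor)
                else variant.extension_base
            )
    elif variant.offset3 < 0:
        seq = seq[: variant.offset3]
    if variant.mismatch:
        pos = int(rng.integers(1, len(seq) - 1))
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq = seq[:pos] + alternatives[int(rng.integers(3))] + seq[pos + 1 :]
    return seq


def simulate_reads(
    spec: SimSpec, reference: ReferenceSet
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Per-sample read libraries plus the truth count table.

    Each true count is emitted as reads drawn from the isomiR profile,
    with the 3' adapter appended and the read truncated to the
    sequencing read length.  The non-templated 3' addition uses an A
    unless precursor context supplies the templated base.
    """
    rng = _rng(spec, 2)
    truth = true_counts(spec, rng)
    fractions = np.array([v.fraction for v in spec.isomir_profile])
    reads: dict[str, list[Read]] = {}
    for sample_id in truth.columns:
        sample_reads: list[Read] = []
        idx = 0
        for ref_id, count in truth[sample_id].items():
            if count == 0:
                continue
            mature = reference[ref_id].sequence
            pre_entry = reference.precursor_of(ref_id)
            precursor = pre_entry.sequence if pre_entry else None
            split = rng.multinomial(int(count), fractions)
            for variant, n_var in zip(spec.isomir_profile, split):
                for _ in range(int(n_var)):
                    insert = _make_variant(mature, precursor, variant, rng)
                    full = (insert + spec.adapter)[:READ_LENGTH]
                    sample_reads.append(Read(f"{sample_id}_r{idx:07d}", full))
                    idx += 1
        order = rng.permutation(len(sample_reads))
        reads[sample_id] = [sample_reads[i] for i in order]
    return reads, truth


def mature_copy_numbers(
    spec: SimSpec,
    assays: tuple[str, ...] = ("mir010",),
    mean_copies: float = 1.0e6,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample true mature and precursor copy pools for qPCR assays.

    Mature copies are log-normal around ``mean_copies`` (cases divided
    by the target's fold change); the precursor pool is log-normal
    around 2x the mature mean and is *not* dysregulated, mirroring a
    contaminating species the mature assay cross-detects.
    """
    if rng is None:
        rng = _rng(spec, 3)
    sheet = sample_sheet(spec)
    fold = dict(spec.de_targets)
    mature_rows, pre_rows = {}, {}
    for assay in assays:
        fc = fold.get(assay, 1.0)
        mature, pre = {}, {}
        for s in sheet.samples:
            mu = mean_copies / (fc if s.group == "case" else 1.0)
            mature[s.sample_id] = mu * rng.lognormal(0.0, 0.35)
            pre[s.sample_id] = 2.0 * mean_copies * rng.lognormal(0.0, 0.35)
        mature_rows[assay] = mature
        pre_rows[assay] = pre
    return pd.DataFrame(mature_rows), pd.DataFrame(pre_rows)


def standard_dilution_series(
    spec: SimSpec, assay_id: str, rng: np.random.Generator, lo: float = 1e3, hi: float = 1e9
) -> pd.DataFrame:
    """Noisy dilution series (decade steps) for one assay."""
    q = spec.qpcr
    rows = []
    copies = 10.0 ** np.arange(np.log10(lo), np.log10(hi) + 0.5)
    for c in copies:
        for rep in range(1, q.n_replicates + 1):
            cq = q.intercept + q.slope * np.log10(c) + rng.normal(0.0, q.cq_sd)
            rows.append({"assay_id": assay_id, "copies": c, "replicate": rep, "cq": cq})
    return pd.DataFrame(rows)


def simulate_cq(
    spec: SimSpec,
    mature_copies: pd.DataFrame,
    precursor_copies: pd.DataFrame | None = None,
    spike_assay: str = "spike-mir159",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq table (samples + spike-in, both fractions) and standard curves.

    Effective copies per (sample, assay): in total RNA, mature +
    precursor_fraction_total x precursor; in enriched RNA,
    enrichment_recovery x mature only.  Per-sample processing factors
    (log-normal) apply to every assay including the spike, which is
    what the spike-in normalisation later removes.  Rows with
    non-positive effective copies are omitted with a warning.
    """
    q = spec.qpcr
    if q.slope >= 0:
        raise ValueError("qPCR slope must be negative")
    rng = _rng(spec, 4)  # distinct stream from the copy-pool draws
    samples = list(mature_copies.index)
    proc_total = {s: 10 ** rng.normal(0.0, q.proc_sd_log10) for s in samples}
    proc_enriched = {
        s: q.enrichment_recovery * 10 ** rng.normal(0.0, q.proc_sd_log10) for s in samples
    }
    rows = []

    def emit(sample_id: str, assay_id: str, fraction: str, eff_copies: float) -> None:
        if eff_copies <= 0:
            import warnings

            warnings.warn(
                f"non-positive effective copies for {sample_id}/{assay_id}/{fraction}; row omitted",
                stacklevel=3,
            )
            return
        for rep in range(1, q.n_replicates + 1):
            cq = q.intercept + q.slope * np.log10(eff_copies) + rng.normal(0.0, q.cq_sd)
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": assay_id,
                    "fraction": fraction,
                    "replicate": rep,
                    "cq": cq,
                }
            )

    for sample_id in samples:
        for assay_id in mature_copies.columns:
            mature = float(mature_copies.at[sample_id, assay_id])
            pre = (
                float(precursor_copies.at[sample_id, assay_id])
                if precursor_copies is not None and assay_id in precursor_copies.columns
                else 0.0
            )
            emit(
                sample_id,
                assay_id,
                "total",
                proc_total[sample_id] * (mature + q.precursor_fraction_total * pre),
            )
            emit(sample_id, assay_id, "enriched", proc_enriched[sample_id] * mature)
        emit(sample_id, spike_assay, "total", proc_total[sample_id] * q.spike_copies)
        emit(sample_id, spike_assay, "enriched", proc_enriched[sample_id] * q.spike_copies)

    assays = list(mature_copies.columns) + [spike_assay]
    standards = pd.concat(
        [standard_dilution_series(spec, a, rng) for a in assays], ignore_index=True
    )
    return pd.DataFrame(rows), standards


def with_seed(spec: SimSpec, seed: int) -> SimSpec:
    return replace(spec, seed=seed)
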