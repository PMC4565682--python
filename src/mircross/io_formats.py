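"""Readers, writers and shared domain types.

Every other stage of the pipeline consumes and produces the types defined
here: the sample sheet, the mature/precursor reference set, the
transcripts x samples count matrix, the Cq table and the run
configuration.  All on-disk formats are plain text (FASTA/FASTQ for
sequences, TSV/CSV for tables, YAML for the configuration) and every
reader rejects malformed input rather than silently skipping records.

Conventions
-----------
* RNA ``U`` is normalised to ``T`` at ingestion so all downstream
  matching happens in DNA space.
* isomiR offsets are 0-based relative to the mature reference 5' end:
  ``offset5 = read start - reference start`` (negative = 5' extension),
  ``offset3 = read end - reference end`` (positive = 3' extension).
* A precursor entry for mature ``X`` carries the reference id ``X-pre``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

PRECURSOR_SUFFIX = "-pre"

GROUPS = ("control", "case")
FRACTIONS = ("total", "enriched")


class ParseError(ValueError):
    """Raised when an input file is malformed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str
    fraction: str | None = None  # qPCR only
    file_path: str | None = None


@dataclass
class SampleSheet:
    """Per-sample metadata: group label and, for qPCR, the RNA fraction."""

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for s in self.samples:
            if s.group not in GROUPS:
                raise ValueError(f"unknown group {s.group!r} for {s.sample_id}")
            if s.fraction is not None and s.fraction not in FRACTIONS:
                raise ValueError(f"unknown fraction {s.fraction!r} for {s.sample_id}")

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s.sample_id: s.group for s in self.samples}, name="group")

    def require_min_per_group(self, n: int = 2) -> None:
        counts = self.groups.value_counts()
        for g in GROUPS:
            if counts.get(g, 0) < n:
                raise ValueError(f"need >= {n} samples in group {g!r}, have {counts.get(g, 0)}")


@dataclass(frozen=True)
class RefEntry:
    ref_id: str
    sequence: str
    kind: str = "mature"  # mature | precursor


@dataclass
class ReferenceSet:
    """Mature miRNA references, optionally with precursor context.

    Mature lengths are constrained to the miRNA range 16-30 nt.  The
    precursor of mature ``X`` (when available) is the entry ``X-pre``
    and must contain the mature sequence as an exact substring.
    """

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        ids = [e.ref_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        for e in self.entries:
            if e.kind not in ("mature", "precursor"):
                raise ValueError(f"unknown reference kind {e.kind!r}")
            if e.kind == "mature" and not (16 <= len(e.sequence) <= 30):
                raise ValueError(
                    f"mature reference {e.ref_id} has length {len(e.sequence)}, outside [16, 30]"
                )
        self._by_id = {e.ref_id: e for e in self.entries}

    def matures(self) -> list[RefEntry]:
        return [e for e in self.entries if e.kind == "mature"]

    def precursor_of(self, mature_id: str) -> RefEntry | None:
        entry = self._by_id.get(mature_id + PRECURSOR_SUFFIX)
        if entry is not None and entry.kind != "precursor":
            return None
        return entry

    def __getitem__(self, ref_id: str) -> RefEntry:
        return self._by_id[ref_id]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CountMatrix:
    """Transcripts x samples integer counts with optional annotations.

    ``lengths`` are mature-reference lengths in nt (used by RPKM);
    ``groups`` maps sample_id to control/case; ``lib_sizes`` are the
    total cleaned reads per sample.  Library sizes are carried
    separately from the matrix because multi-mapping tags contribute to
    several rows, so column sums double-count reads.
    """

    counts: pd.DataFrame  # index: transcript_id, columns: sample_id
    lengths: pd.Series | None = None
    groups: pd.Series | None = None
    lib_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate transcript ids")
        self.counts = self.counts.rename_axis("transcript_id")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                missing = self.lengths[self.lengths.isna()].index.tolist()
                raise ValueError(f"missing transcript lengths for {missing}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.counts.columns)
            if self.groups.isna().any():
                missing = self.groups[self.groups.isna()].index.tolist()
                raise ValueError(f"missing group labels for {missing}")
        if self.lib_sizes is not None:
            self.lib_sizes = self.lib_sizes.reindex(self.counts.columns).astype(float)
            if self.lib_sizes.isna().any():
                raise ValueError("missing library sizes for some samples")

    def effective_lib_sizes(self) -> pd.Series:
        """Library sizes for normalisation; column sums if none supplied."""
        if self.lib_sizes is not None:
            return self.lib_sizes
        return self.counts.sum(axis=0).astype(float)

    def subset_transcripts(self, transcript_ids) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts.loc[transcript_ids],
            lengths=None if self.lengths is None else self.lengths.loc[transcript_ids],
            groups=self.groups,
            lib_sizes=self.lib_sizes,
        )


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run.

    Defaults: reads of 18-25 nt are retained after trimming; isomiR
    matching tolerates a +/-2 nt shift at each end and one mismatch;
    transcripts need >= 1 count per million in >= 3 samples to be
    tested; group-exclusive transcripts need >= 10 reads in total; the
    consensus test uses alpha = 0.05 on BH-adjusted two-tailed p-values;
    quantile normalisation defaults to the full (order-statistic) mode;
    TMM trims 30% of M-values and 5% of A-values.
    """

    adapter: str = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
    min_len: int = 18
    max_len: int = 25
    isomir_max_shift: int = 2
    isomir_max_mismatch: int = 1
    cpm_threshold: float = 1.0
    cpm_min_samples: int = 3
    exclusive_min_reads: int = 10
    alpha: float = 0.05
    quantile_mode: str = "full"  # full | upper_quartile
    tmm_trim_m: float = 0.30
    tmm_trim_a: float = 0.05
    min_overlap: int = 7
    max_mismatch_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quantile_mode not in ("full", "upper_quartile"):
            raise ValueError(f"unknown quantile_mode {self.quantile_mode!r}")
        self.adapter = normalise_sequence(self.adapter)

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# sequence ingestion
# ---------------------------------------------------------------------------


def normalise_sequence(seq: str) -> str:
    """Upper-case and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    quality: str | None = None


def _iter_fastq(handle, path) -> Iterable[Read]:
    # hand-rolled record framing so errors can name the offending line;
    # sequence semantics (upper-case, U->T) match the FASTA path
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ParseError(f"{path}:{lineno}: FASTQ header must start with '@'")
        seq = handle.readline().rstrip("\n")
        plus = handle.readline().rstrip("\n")
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise ParseError(f"{path}:{lineno}: truncated FASTQ record")
        lineno += 3
        rid = header[1:].split()[0] if len(header) > 1 else ""
        if not plus.startswith("+") or (len(plus) > 1 and plus[1:] != rid and plus[1:] != header[1:]):
            raise ParseError(f"{path}:{lineno - 1}: '+' line does not match record {rid!r}")
        if len(qual) != len(seq):
            raise ParseError(f"{path}:{lineno}: quality length != sequence length for {rid!r}")
        yield Read(rid, normalise_sequence(seq), qual)


def read_reads(path, fmt: str | None = None) -> list[Read]:
    """Read a FASTA or FASTQ file into a list of reads.

    Sequences are upper-cased with U mapped to T; record order is
    preserved.  ``fmt`` is inferred from the file extension when not
    given.  Malformed records raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "fastq" if suffix in (".fastq", ".fq") else "fasta"
    fmt = fmt.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    with open(path) as handle:
        if fmt == "fastq":
            return list(_iter_fastq(handle, path))
        try:
            return [
                Read(rec.id, normalise_sequence(str(rec.seq)))
                for rec in SeqIO.parse(handle, "fasta")
            ]
        except ValueError as exc:  # Biopython parse failure
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_reference(path) -> ReferenceSet:
    """Load a reference FASTA.

    The kind is taken from the second whitespace token of the FASTA
    description (``mature`` by default); an entry whose id ends in
    ``-pre`` is a precursor regardless.
    """
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.description.split()
        kind = tokens[1] if len(tokens) > 1 and tokens[1] in ("mature", "precursor") else None
        if kind is None:
            kind = "precursor" if rec.id.endswith(PRECURSOR_SUFFIX) else "mature"
        entries.append(RefEntry(rec.id, normalise_sequence(str(rec.seq)), kind))
    return ReferenceSet(entries)


def write_reference(reference: ReferenceSet, path) -> None:
    with open(path, "w") as handle:
        for e in reference.entries:
            handle.write(f">{e.ref_id} {e.kind}\n{e.sequence}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_count_matrix(matrix: CountMatrix, path, header_comment: str | None = None) -> None:
    """Write counts as TSV: first column transcript_id, then one column
    per sample.  ``header_comment`` lines (prefixed ``#``) carry
    provenance and are ignored on read."""
    if matrix.counts.empty:
        raise ValueError("refusing to write an empty count matrix")
    with open(path, "w") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        out = matrix.counts.copy()
        out.index.name = "transcript_id"
        out.to_csv(handle, sep="\t")


def read_count_matrix(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate transcript ids {dups}")
    for col in df.columns:
        values = df[col]
        if not (values == values.astype(int)).all():
            raise ParseError(f"{path}: non-integer count in column {col!r}")
    return CountMatrix(counts=df.astype(int))


CQ_COLUMNS = ["sample_id", "assay_id", "fraction", "replicate", "cq"]


def validate_cq_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"Cq table missing columns {missing}")
    df = df[CQ_COLUMNS].copy()
    if (df["cq"] <= 0).any():
        bad = df.loc[df["cq"] <= 0].iloc[0]
        raise ParseError(f"non-positive Cq for {bad['sample_id']}/{bad['assay_id']}")
    unknown = set(df["fraction"]) - set(FRACTIONS)
    if unknown:
        raise ParseError(f"unknown fractions {sorted(unknown)}")
    return df


def read_cq_table(path) -> pd.DataFrame:
    return validate_cq_table(pd.read_csv(path, comment="#"))


def write_cq_table(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    validate_cq_table(df)
    with open(path, "w") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        df.to_csv(handle, index=False)


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs sample_id and group columns")
    samples = [
        Sample(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            fraction=str(row["fraction"]) if "fraction" in df.columns and pd.notna(row.get("fraction")) else None,
            file_path=str(row["file_path"]) if "file_path" in df.columns and pd.notna(row.get("file_path")) else None,
        )
        for _, row in df.iterrows()
    ]
    return SampleSheet(samples)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "fraction": s.fraction,
            "file_path": s.file_path,
        }
        for s in sheet.samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unspecified keys take defaults.

    Unknown keys are an error (anti-typo contract).  The effective
    configuration is logged.
    """
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    config = RunConfig(**data)
    logger.info("effective config: %s", config)
    return config


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(dict(config.__dict__), handle, sort_keys=True)
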