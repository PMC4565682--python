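"""Raw-read cleanup: 3' adapter trimming, length filtering, collapsing.

Small-RNA inserts (18-25 nt) are shorter than the read length, so each
read runs into the 3' sequencing adapter.  Trimming removes the
leftmost adapter occurrence and everything 3' of it; reads without a
detectable adapter are kept unchanged because a full-length insert may
simply fill the read.  Cleaned reads are then length-filtered and
collapsed to unique sequence tags with per-sample counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Read


@dataclass
class UniqueTag:
    """One distinct cleaned sequence with its count in each sample."""

    sequence: str
    count_per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.count_per_sample.values())


def _mismatches_exceed(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return True
    return False


def trim_adapter(
    sequence: str,
    adapter: str,
    min_overlap: int = 7,
    max_mismatch_rate: float = 0.1,
) -> str:
    """Remove the 3' adapter from one read.

    The leftmost position where a prefix of ``adapter`` of length
    >= ``min_overlap`` matches (with at most ``max_mismatch_rate`` x
    overlap mismatches) is found; that suffix is removed.  Reads with
    no hit are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    for i in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - i)
        if _mismatches_exceed(sequence[i : i + overlap], adapter[:overlap], int(max_mismatch_rate * overlap)):
            continue
        return sequence[:i]
    return sequence


def length_filter(
    sequences: Iterable[str], min_len: int = 18, max_len: int = 25
) -> list[str]:
    """Keep sequences with min_len <= length <= max_len (bounds inclusive)."""
    return [s for s in sequences if min_len <= len(s) <= max_len]


def collapse(sequences: Iterable[str], sample_id: str) -> list[UniqueTag]:
    """Collapse cleaned reads to unique tags for one sample.

    The sum of tag counts equals the number of input reads.  Ordering
    is deterministic: by count descending, then sequence.
    """
    counter = Counter(sequences)
    tags = [
        UniqueTag(seq, {sample_id: count})
        for seq, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return tags


def merge_tags(tag_sets: Sequence[Sequence[UniqueTag]]) -> list[UniqueTag]:
    """Merge per-sample tag lists into multi-sample tags."""
    merged: dict[str, dict[str, int]] = {}
    for tags in tag_sets:
        for tag in tags:
            per_sample = merged.setdefault(tag.sequence, {})
            for sid, count in tag.count_per_sample.items():
                per_sample[sid] = per_sample.get(sid, 0) + count
    out = [UniqueTag(seq, counts) for seq, counts in merged.items()]
    out.sort(key=lambda t: (-t.total, t.sequence))
    return out


def clean_reads(
    reads: Iterable[Read],
    adapter: str,
    min_len: int = 18,
    max_len: int = 25,
    min_overlap: int = 7,
    max_mismatch_rate: float = 0.1,
) -> list[str]:
    """Trim and length-filter a read list, returning cleaned sequences."""
    trimmed = (trim_adapter(r.sequence, adapter, min_overlap, max_mismatch_rate) for r in reads)
    return length_filter(trimmed, min_len, max_len)


def process_sample(
    reads: Iterable[Read],
    sample_id: str,
    adapter: str,
    min_len: int = 18,
    max_len: int = 25,
    min_overlap: int = 7,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[UniqueTag], int]:
    """Clean and collapse one sample; returns (tags, cleaned-read count).

    The cleaned-read count is the sample's library size for
    normalisation (raw read totals, not count-matrix column sums).
    """
    cleaned = clean_reads(reads, adapter, min_len, max_len, min_overlap, max_mismatch_rate)
    return collapse(cleaned, sample_id), len(cleaned)
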