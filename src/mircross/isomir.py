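"""isomiR-tolerant assignment of unique tags to mature miRNAs.

Mature miRNAs circulate as families of length/sequence variants
(isomiRs).  A tag is assigned to a mature reference if some ungapped
placement puts both of its ends within +/-2 nt of the mature ends with
at most one mismatch.  Bases extending beyond the mature sequence are
compared against the precursor context when a precursor is available;
without that context an extension base cannot be distinguished from a
non-templated addition and is charged as a mismatch.

A tag matching several references contributes its full count to every
matched row (no fractional splitting); library sizes for normalisation
therefore come from raw cleaned-read totals, not column sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import CountMatrix, RefEntry, ReferenceSet
from .reads import UniqueTag


@dataclass(frozen=True)
class IsomiRAssignment:
    """Placement of a tag on one mature reference.

    offset5 = tag start - mature start (negative: 5' extension);
    offset3 = tag end - mature end (positive: 3' extension).
    """

    sequence: str
    ref_id: str
    offset5: int
    offset3: int
    mismatches: int

    @property
    def is_canonical(self) -> bool:
        return self.offset5 == 0 and self.offset3 == 0 and self.mismatches == 0


def match_tag(
    tag: str,
    mature: RefEntry,
    precursor: RefEntry | None = None,
    max_shift: int = 2,
    max_mismatch: int = 1,
) -> IsomiRAssignment | None:
    """Best placement of ``tag`` on one mature reference, or None.

    All ungapped placements with |offset5| <= max_shift and
    |offset3| <= max_shift are scored by mismatch count; the placement
    with fewest mismatches wins (ties: smallest |offset5| + |offset3|,
    then smallest offset5).  Returns None when no placement has
    <= max_mismatch mismatches.
    """
    mat = mature.sequence
    m = len(mat)
    length = len(tag)
    pre = precursor.sequence if precursor is not None else None
    mat_at = pre.find(mat) if pre is not None else -1
    if mat_at == -1:
        pre = None

    best: tuple[int, int, int] | None = None  # (mismatches, |o5|+|o3|, o5)
    for offset5 in range(-max_shift, max_shift + 1):
        offset3 = offset5 + length - m
        if abs(offset3) > max_shift:
            continue
        mismatches = 0
        for i in range(length):
            j = offset5 + i  # coordinate on the mature reference
            if 0 <= j < m:
                match = tag[i] == mat[j]
            elif pre is not None and 0 <= mat_at + j < len(pre):
                match = tag[i] == pre[mat_at + j]
            else:
                match = False
            if not match:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        if mismatches > max_mismatch:
            continue
        key = (mismatches, abs(offset5) + abs(offset3), offset5)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    mismatches, _, offset5 = best
    return IsomiRAssignment(tag, mature.ref_id, offset5, offset5 + length - m, mismatches)


def match_tag_all(
    tag: str,
    reference: ReferenceSet,
    max_shift: int = 2,
    max_mismatch: int = 1,
) -> list[IsomiRAssignment]:
    """All references a tag matches, best-first.

    Ordered by fewest mismatches, then smallest |offset5| + |offset3|,
    then lexicographic ref_id, so the head is the canonical assignment
    for reporting.
    """
    hits = []
    for entry in reference.matures():
        assignment = match_tag(
            tag, entry, reference.precursor_of(entry.ref_id), max_shift, max_mismatch
        )
        if assignment is not None:
            hits.append(assignment)
    hits.sort(key=lambda a: (a.mismatches, abs(a.offset5) + abs(a.offset3), a.ref_id))
    return hits


def annotate(
    tags: Sequence[UniqueTag],
    reference: ReferenceSet,
    sample_ids: Sequence[str] | None = None,
    max_shift: int = 2,
    max_mismatch: int = 1,
) -> tuple[CountMatrix, list[UniqueTag], pd.DataFrame]:
    """Assign tags to mature references and build the count matrix.

    Returns ``(matrix, unannotated, composition)``: the transcripts x
    samples matrix over all mature references, the tags matching
    nothing, and a per-reference isoform composition report with the
    count-weighted canonical/variant fractions.
    """
    matures = reference.matures()
    if not matures:
        raise ValueError("reference has no mature entries")
    if sample_ids is None:
        seen: dict[str, None] = {}
        for tag in tags:
            for sid in tag.count_per_sample:
                seen.setdefault(sid)
        sample_ids = list(seen)

    ref_ids = [e.ref_id for e in matures]
    counts = pd.DataFrame(0, index=pd.Index(ref_ids, name="transcript_id"), columns=list(sample_ids))
    canonical = dict.fromkeys(ref_ids, 0)
    variant = dict.fromkeys(ref_ids, 0)
    unannotated: list[UniqueTag] = []

    for tag in tags:
        hits = match_tag_all(tag.sequence, reference, max_shift, max_mismatch)
        if not hits:
            unannotated.append(tag)
            continue
        for hit in hits:
            assert abs(hit.offset5) <= max_shift and abs(hit.offset3) <= max_shift
            assert hit.mismatches <= max_mismatch
            for sid, count in tag.count_per_sample.items():
                counts.at[hit.ref_id, sid] += count
            if hit.is_canonical:
                canonical[hit.ref_id] += tag.total
            else:
                variant[hit.ref_id] += tag.total

    composition = pd.DataFrame(
        {
            "canonical_count": pd.Series(canonical),
            "variant_count": pd.Series(variant),
        }
    )
    totals = composition.sum(axis=1)
    composition["canonical_fraction"] = (
        composition["canonical_count"] / totals.where(totals > 0)
    )
    composition.index.name = "transcript_id"

    lengths = pd.Series({e.ref_id: len(e.sequence) for e in matures}, name="length")
    matrix = CountMatrix(counts=counts, lengths=lengths)
    return matrix, unannotated, composition
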