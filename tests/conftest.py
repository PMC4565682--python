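import numpy as np
import pandas as pd
import pytest

from mircross import synthetic
from mircross.io_formats import CountMatrix, RefEntry, ReferenceSet


def brute_force_isomir_hits(tag, reference, max_shift=2, max_mismatch=1):
    """Independent isomiR matcher used as an oracle: pad each mature
    with its (possibly unknown) precursor context and slide the tag
    over the padded template, counting mismatches directly."""
    hits = {}
    for entry in reference.matures():
        mature = entry.sequence
        pre = reference.precursor_of(entry.ref_id)
        left = right = "?" * max_shift
        if pre is not None:
            at = pre.sequence.find(mature)
            if at != -1:
                left = ("?" * max_shift + pre.sequence[:at])[-max_shift:]
                tail = pre.sequence[at + len(mature):] + "?" * max_shift
                right = tail[:max_shift]
        template = left + mature + right
        best = None
        for start in range(0, len(template) - 1):
            offset5 = start - max_shift
            offset3 = offset5 + len(tag) - len(mature)
            if abs(offset5) > max_shift or abs(offset3) > max_shift:
                continue
            window = template[start : start + len(tag)]
            if len(window) < len(tag):
                continue
            mm = sum(1 for a, b in zip(tag, window) if b == "?" or a != b)
            if mm <= max_mismatch and (best is None or mm < best):
                best = mm
        if best is not None:
            hits[entry.ref_id] = best
    return hits


@pytest.fixture
def small_spec():
    """A small but complete synthetic study: 12 miRNAs, 6 vs 6 samples,
    one target at fold change 2.3."""
    return synthetic.SimSpec(
        n_mirnas=12,
        n_control=6,
        n_case=6,
        lib_size_mean=4000,
        de_targets=(("mir005", 2.3),),
        seed=11,
    )


@pytest.fixture
def toy_reference():
    mature = "TACCACAGGGTAGAACCACGGA"  # 22 nt
    precursor = "GGCTG" + mature + "CTGGGTTGAG"
    other = "AAAAGCTGGGTTGAGAGGGCTA"
    return ReferenceSet(
        [
            RefEntry("mirA", mature, "mature"),
            RefEntry("mirA-pre", precursor, "precursor"),
            RefEntry("mirB", other, "mature"),
        ]
    )


@pytest.fixture
def nb_matrix():
    """Random negative-binomial count matrix with group labels."""
    rng = np.random.default_rng(7)
    mu = rng.lognormal(4.0, 1.0, size=(40, 1))
    counts = rng.negative_binomial(10, 10 / (10 + mu * np.ones((40, 12))))
    samples = [f"s{i}" for i in range(12)]
    groups = pd.Series(["control"] * 6 + ["case"] * 6, index=samples)
    lengths = pd.Series(22, index=[f"g{i}" for i in range(40)])
    return CountMatrix(
        counts=pd.DataFrame(counts, index=lengths.index, columns=samples),
        lengths=lengths,
        groups=groups,
    )
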