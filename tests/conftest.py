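from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pirnakit.align import AlignedRead
from pirnakit.annotation import (
    GenomeAnnotation,
    GenomicInterval,
    OtherFeature,
    PiRNALocus,
    StructuralLocus,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_annotation() -> GenomeAnnotation:
    """Two type-1 loci (one per strand), a tRNA, and a same-strand miRNA
    overlapping a third locus."""
    return GenomeAnnotation(
        pirna_loci=[
            PiRNALocus("21ur-a", GenomicInterval("chr1", 999, 1020, "+")),
            PiRNALocus("21ur-b", GenomicInterval("chr1", 2000, 2021, "-")),
            PiRNALocus("21ur-c", GenomicInterval("chr1", 3000, 3021, "+")),
        ],
        structural_loci=[
            StructuralLocus(GenomicInterval("chr1", 5000, 5100, "+"), "tRNA"),
        ],
        other_features=[
            OtherFeature(GenomicInterval("chr1", 2990, 3005, "+"), "miRNA"),
        ],
        chrom_sizes={"chr1": 10_000},
    )


def make_read(
    chrom="chr1",
    start=999,
    length=21,
    strand="+",
    first_base="T",
    read_id="r1",
    mismatches=0,
):
    """Build an AlignedRead whose *sequenced* 5' base is `first_base`.

    The stored sequence is the forward-strand projection (SAM convention),
    so for minus-strand reads the requested base lands complemented at the
    forward sequence's end.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        seq = first_base + "G" * (length - 1)
    else:
        seq = "G" * (length - 1) + comp[first_base]
    return AlignedRead(
        read_id=read_id,
        interval=GenomicInterval(chrom, start, start + length, strand),
        strand=strand,
        sequence=seq,
        mismatches=mismatches,
    )


@pytest.fixture
def read_factory():
    return make_read
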