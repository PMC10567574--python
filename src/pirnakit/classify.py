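"""Partition aligned small-RNA reads into structural / mature / precursor /
other classes, count them per locus, and normalize to reads per million
non-structural 18-35-nt reads.

Category rules (stringent mode):

* structural  -- >=1 bp sense overlap with an rRNA/tRNA/snRNA/snoRNA locus;
  takes precedence over everything and removes the read from all further
  counting and from the normalization denominator.
* mature      -- exactly 21 nt, 5' base of the read *as sequenced* is T
  (forward-projected sequence starts with T on +, ends with A on -),
  read fully contained in a piRNA locus, same strand.
* precursor   -- 23-35 nt, 5'-most genomic base exactly at the single-base
  window 2 nt upstream of a locus 5' end, same strand; the 3' end is
  unconstrained.
* other_nonstructural -- everything else.

Relaxed mode replaces the mature/precursor tests by any >=1 bp sense
overlap with the locus (mature) or the window (precursor) for any
18-35-nt read.  Multi-assignment across overlapping loci is allowed in
both modes; the denominator counts each read once.

The 5'-base test inspects the sequenced bases, not the reference, so a
read whose single alignment mismatch sits at base 1 is judged by its own
sequence.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator

import pysam

from .align import AlignedRead
from .annotation import (
    GenomeAnnotation,
    GenomicInterval,
    PiRNALocus,
    PrecursorWindow,
)

__all__ = [
    "ReadCategory",
    "CountTable",
    "Classifier",
    "NormalizationError",
    "MIN_READ_LEN",
    "MAX_READ_LEN",
    "is_structural",
    "is_mature",
    "is_precursor",
    "classify_read",
    "count_by_locus",
    "compute_denominator",
    "normalize_rpm",
    "iter_sam",
    "classify_sample",
]

MIN_READ_LEN = 18
MAX_READ_LEN = 35
MATURE_LEN = 21
PRECURSOR_MIN_LEN = 23
PRECURSOR_MAX_LEN = 35


class ReadCategory(str, Enum):
    STRUCTURAL = "structural"
    MATURE_TYPE1 = "mature_type1"
    MATURE_TYPE2 = "mature_type2"
    PRECURSOR_TYPE1 = "precursor_type1"
    PRECURSOR_TYPE2 = "precursor_type2"
    OTHER = "other_nonstructural"


_MATURE_BY_TYPE = {"type1": ReadCategory.MATURE_TYPE1, "type2": ReadCategory.MATURE_TYPE2}
_PRECURSOR_BY_TYPE = {
    "type1": ReadCategory.PRECURSOR_TYPE1,
    "type2": ReadCategory.PRECURSOR_TYPE2,
}


class NormalizationError(ValueError):
    """Raised when RPM normalization is attempted with a zero denominator."""


@dataclass
class CountTable:
    """Per-locus raw counts for one category in one sample; RPM values are
    attached by :func:`normalize_rpm`."""

    sample_id: str
    category: ReadCategory
    mode: str  # "stringent" | "relaxed"
    counts: dict[str, int]
    denominator: int | None = None
    rpm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("stringent", "relaxed"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.denominator is not None and self.denominator < 0:
            raise ValueError("denominator must be >= 0")

    @property
    def total_raw(self) -> int:
        return sum(self.counts.values())

    @property
    def total_rpm(self) -> float:
        return sum(self.rpm.values())

    def write_tsv(self, stream) -> None:
        stream.write("locus_id\tcategory\traw\trpm\n")
        for locus_id in sorted(self.counts):
            rpm = self.rpm.get(locus_id, float("nan"))
            stream.write(
                f"{locus_id}\t{self.category.value}\t{self.counts[locus_id]}\t{rpm:.10g}\n"
            )


# ---------------------------------------------------------------------------
# Elementary predicates (contract surface; the Classifier below is the fast
# indexed path used by the pipeline)
# ---------------------------------------------------------------------------

def _in_size_range(read: AlignedRead) -> bool:
    return MIN_READ_LEN <= read.length <= MAX_READ_LEN


def is_structural(read: AlignedRead, annotation: GenomeAnnotation) -> bool:
    """Sense overlap (>=1 bp) with any structural RNA locus."""
    if not read.mapped:
        return False
    return any(
        read.interval.overlaps(s.interval, same_strand=True)
        for s in annotation.structural_loci
    )


def _five_prime_is_t(read: AlignedRead) -> bool:
    # SAM keeps the forward projection: a minus-strand read starting with U/T
    # in sequencing orientation ends with A on the forward strand.
    if read.strand == "+":
        return read.sequence.startswith("T")
    return read.sequence.endswith("A")


def is_mature(read: AlignedRead, locus: PiRNALocus) -> bool:
    """21 nt, sequenced 5' base T, fully contained in the locus, sense."""
    return (
        read.mapped
        and read.length == MATURE_LEN
        and read.strand == locus.interval.strand
        and locus.interval.contains(read.interval)
        and _five_prime_is_t(read)
    )


def is_precursor(read: AlignedRead, window: PrecursorWindow) -> bool:
    """23-35 nt with the 5'-most genomic base exactly on the window, sense."""
    return (
        read.mapped
        and PRECURSOR_MIN_LEN <= read.length <= PRECURSOR_MAX_LEN
        and read.strand == window.position.strand
        and read.interval.chrom == window.position.chrom
        and read.interval.five_prime == window.position.start
    )


# ---------------------------------------------------------------------------
# Indexed classifier
# ---------------------------------------------------------------------------

class Classifier:
    """Pre-indexed read classifier over one annotation + window set."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        windows: Iterable[PrecursorWindow],
        mode: str = "stringent",
    ):
        if mode not in ("stringent", "relaxed"):
            raise ValueError(f"invalid mode {mode!r}")
        self.annotation = annotation
        self.windows = list(windows)
        self.mode = mode
        self._structural: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for s in annotation.structural_loci:
            iv = s.interval
            self._structural.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        for ivs in self._structural.values():
            ivs.sort()
        self._loci: dict[tuple[str, str], list[PiRNALocus]] = {}
        for locus in annotation.pirna_loci:
            iv = locus.interval
            self._loci.setdefault((iv.chrom, iv.strand), []).append(locus)
        for loci in self._loci.values():
            loci.sort(key=lambda l: l.interval.start)
        self._locus_starts = {
            key: [l.interval.start for l in loci] for key, loci in self._loci.items()
        }
        self._max_locus_len = max(
            (len(l.interval) for l in annotation.pirna_loci), default=0
        )
        self._window_at: dict[tuple[str, str, int], list[PrecursorWindow]] = {}
        self._window_iv: dict[tuple[str, str], list[tuple[int, PrecursorWindow]]] = {}
        for w in self.windows:
            p = w.position
            self._window_at.setdefault((p.chrom, p.strand, p.start), []).append(w)
            self._window_iv.setdefault((p.chrom, p.strand), []).append((p.start, w))
        for lst in self._window_iv.values():
            lst.sort(key=lambda t: t[0])

    # -- helpers ------------------------------------------------------------

    def _overlapping_structural(self, read: AlignedRead) -> bool:
        ivs = self._structural.get((read.interval.chrom, read.strand))
        if not ivs:
            return False
        s, e = read.interval.start, read.interval.end
        # candidate structural loci can start well before the read; sizes are
        # small here, so scan from the first locus ending after read start
        for start, end in ivs:
            if start >= e:
                break
            if end > s:
                return True
        return False

    def _candidate_loci(self, read: AlignedRead) -> Iterator[PiRNALocus]:
        key = (read.interval.chrom, read.strand)
        loci = self._loci.get(key)
        if not loci:
            return
        starts = self._locus_starts[key]
        lo = bisect_left(starts, read.interval.start - self._max_locus_len)
        hi = bisect_right(starts, read.interval.end)
        for locus in loci[lo:hi]:
            yield locus

    # -- classification -----------------------------------------------------

    def classify(self, read: AlignedRead) -> set[tuple[ReadCategory, str | None]]:
        """Category assignments for one read; structural short-circuits."""
        if not read.mapped or not _in_size_range(read):
            return set()
        if self._overlapping_structural(read):
            return {(ReadCategory.STRUCTURAL, None)}
        out: set[tuple[ReadCategory, str | None]] = set()
        if self.mode == "stringent":
            for locus in self._candidate_loci(read):
                if is_mature(read, locus):
                    out.add((_MATURE_BY_TYPE[locus.pirna_type], locus.locus_id))
            for w in self._window_at.get(
                (read.interval.chrom, read.strand, read.interval.five_prime), ()
            ):
                if is_precursor(read, w):
                    out.add((_PRECURSOR_BY_TYPE[w.pirna_type], w.locus_id))
        else:
            for locus in self._candidate_loci(read):
                if read.interval.overlaps(locus.interval, same_strand=True):
                    out.add((_MATURE_BY_TYPE[locus.pirna_type], locus.locus_id))
            for pos, w in self._window_iv.get((read.interval.chrom, read.strand), ()):
                if read.interval.start <= pos < read.interval.end:
                    out.add((_PRECURSOR_BY_TYPE[w.pirna_type], w.locus_id))
        if not out:
            out.add((ReadCategory.OTHER, None))
        return out


def classify_read(
    read: AlignedRead,
    annotation: GenomeAnnotation,
    windows: Iterable[PrecursorWindow],
    mode: str = "stringent",
) -> set[tuple[ReadCategory, str | None]]:
    """One-shot wrapper around :class:`Classifier` for a single read."""
    return Classifier(annotation, windows, mode).classify(read)


# ---------------------------------------------------------------------------
# Counting and normalization
# ---------------------------------------------------------------------------

def _locus_universe(annotation: GenomeAnnotation, category: ReadCategory) -> list[str]:
    if category in (ReadCategory.MATURE_TYPE1, ReadCategory.PRECURSOR_TYPE1):
        return [l.locus_id for l in annotation.type1_loci()]
    if category in (ReadCategory.MATURE_TYPE2, ReadCategory.PRECURSOR_TYPE2):
        return [l.locus_id for l in annotation.type2_loci()]
    raise ValueError(f"category {category} has no locus universe")


def count_by_locus(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    windows: Iterable[PrecursorWindow],
    mode: str,
    category: ReadCategory,
    sample_id: str = "sample",
) -> CountTable:
    """Raw per-locus counts of one category (all loci present, zeros kept)."""
    classifier = Classifier(annotation, windows, mode)
    counts = {locus_id: 0 for locus_id in _locus_universe(annotation, category)}
    for read in reads:
        for cat, locus_id in classifier.classify(read):
            if cat is category:
                if locus_id not in counts:
                    raise KeyError(f"unknown locus_id {locus_id!r}")
                counts[locus_id] += 1
    return CountTable(sample_id=sample_id, category=category, mode=mode, counts=counts)


def compute_denominator(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
) -> int:
    """Number of mapped non-structural 18-35-nt reads (each counted once)."""
    classifier = Classifier(annotation, [], "stringent")
    n = 0
    for read in reads:
        if read.mapped and _in_size_range(read) and not classifier._overlapping_structural(read):
            n += 1
    return n


def normalize_rpm(table: CountTable, denominator: int) -> CountTable:
    """Attach reads-per-million values: rpm = raw / denominator * 1e6."""
    if denominator <= 0:
        raise NormalizationError(
            f"sample {table.sample_id}: denominator is {denominator}; "
            "RPM normalization is undefined"
        )
    rpm = {k: v / denominator * 1e6 for k, v in table.counts.items()}
    return replace(table, denominator=denominator, rpm=rpm)


# ---------------------------------------------------------------------------
# SAM ingestion and one-pass sample classification
# ---------------------------------------------------------------------------

def iter_sam(path: str) -> Iterator[AlignedRead]:
    """Yield mapped reads from a SAM/BAM file as :class:`AlignedRead`."""
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            seq = rec.query_sequence or ""
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            yield AlignedRead(
                read_id=rec.query_name,
                interval=GenomicInterval(
                    rec.reference_name, rec.reference_start,
                    rec.reference_start + len(seq), strand,
                ),
                strand=strand,
                sequence=seq,
                mismatches=int(nm),
            )


@dataclass
class SampleResult:
    sample_id: str
    mode: str
    denominator: int
    tables: dict[ReadCategory, CountTable]
    category_totals: dict[ReadCategory, int]
    n_mapped_in_range: int


def classify_sample(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    windows: Iterable[PrecursorWindow],
    mode: str = "stringent",
    sample_id: str = "sample",
) -> SampleResult:
    """Single pass over a sample: per-locus tables for every piRNA category,
    the normalization denominator, and per-category read tallies."""
    classifier = Classifier(annotation, windows, mode)
    categories = [
        ReadCategory.MATURE_TYPE1,
        ReadCategory.PRECURSOR_TYPE1,
    ]
    if annotation.type2_loci():
        categories += [ReadCategory.MATURE_TYPE2, ReadCategory.PRECURSOR_TYPE2]
    counts = {
        cat: {locus_id: 0 for locus_id in _locus_universe(annotation, cat)}
        for cat in categories
    }
    totals = {cat: 0 for cat in ReadCategory}
    denominator = 0
    n_in_range = 0
    for read in reads:
        if not read.mapped or not _in_size_range(read):
            continue
        n_in_range += 1
        assignments = classifier.classify(read)
        structural = any(cat is ReadCategory.STRUCTURAL for cat, _ in assignments)
        if not structural:
            denominator += 1
        seen_cats = {cat for cat, _ in assignments}
        for cat in seen_cats:
            totals[cat] += 1
        for cat, locus_id in assignments:
            if cat in counts:
                counts[cat][locus_id] += 1
    tables = {}
    for cat in categories:
        table = CountTable(sample_id=sample_id, category=cat, mode=mode, counts=counts[cat])
        if denominator > 0:
            table = normalize_rpm(table, denominator)
        tables[cat] = table
    return SampleResult(
        sample_id=sample_id,
        mode=mode,
        denominator=denominator,
        tables=tables,
        category_totals=totals,
        n_mapped_in_range=n_in_range,
    )
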