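"""A small exact/1-mismatch aligner for short inserts on small genomes.

Designed for simulated genomes up to a few megabases.  Uses a pigeonhole
seed index: every alignment of an >=18-nt read with at most one mismatch
contains at least one exact 9-mer at read offset 0 or 9, so candidate
placements come from two hash lookups per strand and are then verified
base-by-base.  One best alignment is reported; among equal-mismatch hits
ties break deterministically by (chromosome, start, then + before -).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation import GenomicInterval

__all__ = [
    "Genome",
    "AlignedRead",
    "AlignmentInputError",
    "load_genome",
    "build_index",
    "align_read",
    "align_fastq",
    "write_sam",
]

_SEED_K = 9
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlignmentInputError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    chroms: dict[str, str]
    _index: dict[str, list[tuple[str, int]]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.chroms:
            raise AlignmentInputError("empty genome")
        for name, seq in self.chroms.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise AlignmentInputError(
                    f"chromosome {name}: non-IUPAC characters {sorted(bad)}"
                )

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}


def load_genome(path_or_stream) -> Genome:
    """Read a FASTA genome (upper-cased)."""
    chroms = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(path_or_stream, "fasta")
    }
    return Genome(chroms)


def build_index(genome: Genome, k: int = _SEED_K) -> Genome:
    """Attach a k-mer position index (forward strand only; reverse-strand
    queries look up the reverse complement of the read)."""
    index: dict[str, list[tuple[str, int]]] = {}
    for name in sorted(genome.chroms):
        seq = genome.chroms[name]
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((name, pos))
    genome._index = index
    return genome


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    interval: GenomicInterval
    strand: str
    sequence: str  # forward-strand projection, SAM convention
    mismatches: int
    mapped: bool = True

    def __post_init__(self) -> None:
        if self.mapped and len(self.sequence) != len(self.interval):
            raise ValueError("sequence length must equal interval length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def sequence_as_sequenced(self) -> str:
        """The read's own bases in sequencing orientation (5'->3')."""
        return self.sequence if self.strand == "+" else revcomp(self.sequence)


def _mismatch_count(a: str, b: str, limit: int) -> int:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidates(query: str, genome: Genome, k: int) -> set[tuple[str, int]]:
    assert genome._index is not None
    if len(query) < 2 * k:
        # pigeonhole needs two disjoint seeds; fall back to a full scan
        return {
            (chrom, start)
            for chrom, seq in genome.chroms.items()
            for start in range(len(seq) - len(query) + 1)
        }
    cands: set[tuple[str, int]] = set()
    for offset in (0, k):
        seed = query[offset : offset + k]
        for chrom, pos in genome._index.get(seed, ()):
            start = pos - offset
            if start >= 0 and start + len(query) <= len(genome.chroms[chrom]):
                cands.add((chrom, start))
    return cands


def align_read(insert: str, genome: Genome, read_id: str = "read") -> AlignedRead | None:
    """Best-hit placement with at most one mismatch; None when unmapped.

    A 0-mismatch hit always beats a 1-mismatch hit (strata); within a
    stratum the hit with the lexicographically smallest (chromosome, start)
    wins, with + preferred over - at an identical position.
    """
    if not insert:
        raise AlignmentInputError("empty insert")
    bad = set(insert) - set("ACGTN")
    if bad:
        raise AlignmentInputError(f"non-IUPAC characters in insert: {sorted(bad)}")
    if genome._index is None:
        build_index(genome)
    hits: list[tuple[int, str, int, int, str]] = []  # (mm, chrom, start, strand_rank, query)
    for strand, query in (("+", insert), ("-", revcomp(insert))):
        for chrom, start in _candidates(query, genome, _SEED_K):
            ref = genome.chroms[chrom][start : start + len(query)]
            mm = 0 if ref == query else _mismatch_count(query, ref, 1)
            if mm <= 1:
                hits.append((mm, chrom, start, 0 if strand == "+" else 1, query))
    if not hits:
        return None
    mm, chrom, start, strand_rank, query = min(hits)
    strand = "+" if strand_rank == 0 else "-"
    return AlignedRead(
        read_id=read_id,
        interval=GenomicInterval(chrom, start, start + len(query), strand),
        strand=strand,
        sequence=query,
        mismatches=mm,
    )


def align_fastq(
    trimmed: IO[str] | Iterable[tuple[str, str]],
    genome: Genome,
) -> tuple[list[AlignedRead], list[tuple[str, str]]]:
    """Align a trimmed FASTQ stream (or (read_id, insert) pairs).

    Returns coordinate-sorted mapped reads and a list of unmapped
    (read_id, insert) pairs.
    """
    if hasattr(trimmed, "read"):
        pairs: Iterator[tuple[str, str]] = (
            (title.split()[0], seq.upper())
            for title, seq, _q in FastqGeneralIterator(trimmed)
        )
    else:
        pairs = iter(trimmed)
    if genome._index is None:
        build_index(genome)
    mapped: list[AlignedRead] = []
    unmapped: list[tuple[str, str]] = []
    for read_id, insert in pairs:
        hit = align_read(insert, genome, read_id=read_id)
        if hit is None:
            unmapped.append((read_id, insert))
        else:
            mapped.append(hit)
    mapped.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.strand, r.read_id))
    return mapped, unmapped


def write_sam(
    mapped: Iterable[AlignedRead],
    unmapped: Iterable[tuple[str, str]],
    chrom_sizes: dict[str, int],
    stream: IO[str],
) -> None:
    """Emit a coordinate-sorted SAM file with <len>M CIGARs and NM tags."""
    stream.write("@HD\tVN:1.6\tSO:coordinate\n")
    for name in sorted(chrom_sizes):
        stream.write(f"@SQ\tSN:{name}\tLN:{chrom_sizes[name]}\n")
    for r in mapped:
        flag = 0 if r.strand == "+" else 16
        stream.write(
            f"{r.read_id}\t{flag}\t{r.interval.chrom}\t{r.interval.start + 1}\t255\t"
            f"{len(r.sequence)}M\t*\t0\t0\t{r.sequence}\t*\tNM:i:{r.mismatches}\n"
        )
    for read_id, insert in unmapped:
        stream.write(f"{read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{insert}\t*\n")
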