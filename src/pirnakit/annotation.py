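"""Genome annotation handling for piRNA quantification.

Coordinates are internally 0-based, half-open.  GTF input/output converts
to/from the 1-based inclusive convention at the I/O boundary and nowhere
else.  piRNA genes are recognised by a ``gene_biotype "piRNA"`` attribute;
rRNA/tRNA/snRNA/snoRNA genes form the structural class whose sense-mapping
reads are excluded from all downstream counting; everything else is kept as
a generic feature so that ambiguous piRNA loci (same-strand overlap with
miRNAs, snoRNAs or other exons) can be removed before counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

__all__ = [
    "GenomicInterval",
    "PiRNALocus",
    "StructuralLocus",
    "OtherFeature",
    "PrecursorWindow",
    "GenomeAnnotation",
    "AnnotationError",
    "GtfParseError",
    "STRUCTURAL_CLASSES",
    "AMBIGUOUS_BIOTYPES",
    "load_annotation",
    "load_chrom_sizes",
    "load_type2_bed",
    "exclude_ambiguous_loci",
    "derive_precursor_windows",
    "write_gtf",
]

STRUCTURAL_CLASSES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})

#: biotypes whose same-strand overlap disqualifies a type-1 locus
AMBIGUOUS_BIOTYPES = frozenset({"miRNA", "snoRNA", "exon"})


class AnnotationError(ValueError):
    """Invalid annotation content (bad coordinates, duplicate ids, ...)."""


class GtfParseError(AnnotationError):
    """Malformed GTF input; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        """True if the intervals share >=1 bp (optionally requiring equal strand)."""
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5'-most base in transcription direction."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class PiRNALocus:
    locus_id: str
    interval: GenomicInterval
    pirna_type: str = "type1"  # "type1" | "type2"

    def __post_init__(self) -> None:
        if self.pirna_type not in ("type1", "type2"):
            raise AnnotationError(f"invalid pirna_type {self.pirna_type!r}")
        if self.pirna_type == "type1" and len(self.interval) != 21:
            raise AnnotationError(
                f"type-1 locus {self.locus_id} must span 21 nt, "
                f"got {len(self.interval)}"
            )


@dataclass(frozen=True)
class StructuralLocus:
    interval: GenomicInterval
    rna_class: str

    def __post_init__(self) -> None:
        if self.rna_class not in STRUCTURAL_CLASSES:
            raise AnnotationError(f"invalid structural class {self.rna_class!r}")


@dataclass(frozen=True)
class OtherFeature:
    interval: GenomicInterval
    biotype: str


@dataclass(frozen=True)
class PrecursorWindow:
    """The single genomic base 2 nt upstream (in transcription direction) of
    a locus 5' end; precursor reads must place their 5' end exactly here."""

    locus_id: str
    position: GenomicInterval
    pirna_type: str = "type1"

    def __post_init__(self) -> None:
        if len(self.position) != 1:
            raise AnnotationError("precursor window must span exactly 1 base")

    @property
    def strand(self) -> str:
        return self.position.strand


@dataclass
class GenomeAnnotation:
    pirna_loci: list[PiRNALocus] = field(default_factory=list)
    structural_loci: list[StructuralLocus] = field(default_factory=list)
    other_features: list[OtherFeature] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for locus in self.pirna_loci:
            if locus.locus_id in seen:
                raise AnnotationError(f"duplicate locus_id {locus.locus_id!r}")
            seen.add(locus.locus_id)
        if self.chrom_sizes:
            for iv in self._all_intervals():
                size = self.chrom_sizes.get(iv.chrom)
                if size is None:
                    raise AnnotationError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > size:
                    raise AnnotationError(
                        f"interval [{iv.start}, {iv.end}) exceeds {iv.chrom} "
                        f"length {size}"
                    )

    def _all_intervals(self) -> Iterable[GenomicInterval]:
        for locus in self.pirna_loci:
            yield locus.interval
        for s in self.structural_loci:
            yield s.interval
        for o in self.other_features:
            yield o.interval

    def type1_loci(self) -> list[PiRNALocus]:
        return [l for l in self.pirna_loci if l.pirna_type == "type1"]

    def type2_loci(self) -> list[PiRNALocus]:
        return [l for l in self.pirna_loci if l.pirna_type == "type2"]


# ---------------------------------------------------------------------------
# GTF / BED / chrom.sizes I/O
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_chrom_sizes(stream: IO[str] | Iterable[str]) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, length = line.split()[:2]
        sizes[chrom] = int(length)
    return sizes


def load_annotation(
    gtf_stream: IO[str] | Iterable[str],
    chrom_sizes: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Parse a GTF stream into a :class:`GenomeAnnotation`.

    Features with ``gene_biotype "piRNA"`` become type-1 loci; biotypes in
    :data:`STRUCTURAL_CLASSES` become structural loci; everything else is
    retained as an :class:`OtherFeature` keyed by its biotype (falling back
    to the feature column, so plain ``exon`` lines are preserved as such).
    """
    pirna: list[PiRNALocus] = []
    structural: list[StructuralLocus] = []
    other: list[OtherFeature] = []
    anon = 0
    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
        if strand not in ("+", "-"):
            raise GtfParseError(lineno, f"invalid strand {strand!r}")
        if start1 < 1 or end1 < start1:
            raise GtfParseError(lineno, f"invalid 1-based range {start1}..{end1}")
        interval = GenomicInterval(chrom, start1 - 1, end1, strand)
        attrs = _parse_attributes(attr_s)
        biotype = attrs.get("gene_biotype", feature)
        if biotype in ("piRNA", "piRNA_type2"):
            locus_id = attrs.get("gene_id")
            if locus_id is None:
                raise GtfParseError(lineno, "piRNA feature lacks gene_id")
            ptype = "type1" if biotype == "piRNA" else "type2"
            pirna.append(PiRNALocus(locus_id, interval, ptype))
        elif biotype in STRUCTURAL_CLASSES:
            structural.append(StructuralLocus(interval, biotype))
        else:
            if "gene_id" not in attrs:
                anon += 1
            other.append(OtherFeature(interval, biotype))
    return GenomeAnnotation(
        pirna_loci=pirna,
        structural_loci=structural,
        other_features=other,
        chrom_sizes=dict(chrom_sizes or {}),
    )


def load_type2_bed(
    stream: IO[str] | Iterable[str],
    annotation: GenomeAnnotation | None = None,
) -> list[PiRNALocus]:
    """Read type-2 loci from BED (0-based half-open, columns 1-6).

    If *annotation* is given the loci are appended to it in place.
    """
    loci: list[PiRNALocus] = []
    for i, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise AnnotationError(f"BED line {i}: need 6 columns, got {len(fields)}")
        chrom, start, end, name, _score, strand = fields[:6]
        iv = GenomicInterval(chrom, int(start), int(end), strand)
        loci.append(PiRNALocus(name, iv, "type2"))
    if annotation is not None:
        annotation.pirna_loci.extend(loci)
    return loci


def write_gtf(
    obj: GenomeAnnotation | Iterable[PrecursorWindow],
    stream: IO[str],
    source: str = "pirnakit",
) -> None:
    """Emit a 1-based inclusive GTF for an annotation or for precursor windows."""
    if isinstance(obj, GenomeAnnotation):
        for locus in obj.pirna_loci:
            _write_line(
                stream, locus.interval, source, "gene",
                f'gene_id "{locus.locus_id}"; gene_biotype "piRNA";'
                if locus.pirna_type == "type1"
                else f'gene_id "{locus.locus_id}"; gene_biotype "piRNA_type2";',
            )
        for s in obj.structural_loci:
            _write_line(
                stream, s.interval, source, "gene",
                f'gene_id "struct_{s.interval.chrom}_{s.interval.start}"; '
                f'gene_biotype "{s.rna_class}";',
            )
        for o in obj.other_features:
            feature = "exon" if o.biotype == "exon" else "gene"
            attr = (
                f'gene_id "feat_{o.interval.chrom}_{o.interval.start}"; '
                + (f'gene_biotype "{o.biotype}";' if o.biotype != "exon" else "")
            ).strip()
            _write_line(stream, o.interval, source, feature, attr)
    else:
        for w in obj:
            _write_line(
                stream, w.position, source, "precursor_window",
                f'gene_id "{w.locus_id}";',
            )


def _write_line(stream: IO[str], iv: GenomicInterval, source: str,
                feature: str, attributes: str) -> None:
    stream.write(
        f"{iv.chrom}\t{source}\t{feature}\t{iv.start + 1}\t{iv.end}\t.\t"
        f"{iv.strand}\t.\t{attributes}\n"
    )


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def exclude_ambiguous_loci(
    annotation: GenomeAnnotation,
    biotypes: frozenset[str] | set[str] = AMBIGUOUS_BIOTYPES,
) -> tuple[GenomeAnnotation, float]:
    """Drop type-1 loci with a same-strand overlap against miRNA/snoRNA/exon
    features; return the filtered annotation and the removed fraction of
    type-1 loci (0.0 for an empty annotation)."""
    confounders = [f.interval for f in annotation.other_features if f.biotype in biotypes]
    kept: list[PiRNALocus] = []
    n_type1 = 0
    removed = 0
    for locus in annotation.pirna_loci:
        if locus.pirna_type != "type1":
            kept.append(locus)
            continue
        n_type1 += 1
        if any(locus.interval.overlaps(c, same_strand=True) for c in confounders):
            removed += 1
        else:
            kept.append(locus)
    fraction = removed / n_type1 if n_type1 else 0.0
    filtered = replace(annotation, pirna_loci=kept)
    return filtered, fraction


def derive_precursor_windows(
    annotation: GenomeAnnotation,
    include_type2: bool = False,
) -> list[PrecursorWindow]:
    """One single-base window per locus, 2 nt upstream of its 5' end.

    Plus strand: window start = locus.start - 2.  Minus strand: upstream
    means larger coordinates, so window start = locus.end + 1.  Loci whose
    window would fall off the chromosome are dropped with a warning.
    """
    windows: list[PrecursorWindow] = []
    for locus in annotation.pirna_loci:
        if locus.pirna_type == "type2" and not include_type2:
            continue
        iv = locus.interval
        if iv.strand == "+":
            pos = iv.start - 2
        else:
            pos = iv.end + 1
        size = annotation.chrom_sizes.get(iv.chrom)
        if pos < 0 or (size is not None and pos >= size):
            warnings.warn(
                f"locus {locus.locus_id}: precursor window off chromosome, dropped",
                stacklevel=2,
            )
            continue
        windows.append(
            PrecursorWindow(
                locus_id=locus.locus_id,
                position=GenomicInterval(iv.chrom, pos, pos + 1, iv.strand),
                pirna_type=locus.pirna_type,
            )
        )
    return windows
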