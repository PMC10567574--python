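"""Synthetic genomes, annotations and genotype-specific read sets.

The simulator plants 21-nt piRNA loci whose sense sequence starts with T
(so mature reads carry the 5'-U bias), biases the base 2 nt upstream
toward A/G (the precursor position-1 preference), places structural RNA
loci of the four filtered classes, and emits NEXTflex-style raw reads:
4 random bases + insert + 4 random bases + 3' adapter.

Read composition is modeled in "transcript units": a fixed background
pool, a fixed structural pool, and per-locus mature/precursor units set
by the genotype profile (mature_fraction * expression for mature reads,
baseline_precursor_fraction * precursor_multiplier * expression for
precursors).  Sequencing a pool at fixed depth is a multinomial draw over
these units, so losing mature piRNAs shrinks the library's piRNA share
exactly as it would in a real library dominated by other small RNAs.

Every output is deterministic given the config seed; each stage draws
from its own spawned generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd

from .align import Genome, revcomp
from .annotation import (
    GenomeAnnotation,
    GenomicInterval,
    OtherFeature,
    PiRNALocus,
    PrecursorWindow,
    StructuralLocus,
    derive_precursor_windows,
)
from .preprocess import DEFAULT_ADAPTER

__all__ = [
    "SimulationConfig",
    "GenotypeProfile",
    "SimulatedRead",
    "genotype_profiles",
    "simulate_genome",
    "simulate_reads",
    "truth_frame",
    "write_fasta",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))
_STRUCTURAL_CYCLE = ("rRNA", "tRNA", "snRNA", "snoRNA")
_AMBIGUOUS_CYCLE = ("miRNA", "exon")  # snoRNA avoided: it would also be structural


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeProfile:
    """Direction-level phenotype preset.

    mature_fraction scales mature piRNA output per locus; the
    precursor_multiplier scales precursor abundance relative to the
    wild-type baseline.  Values are free modeling choices consistent with
    the observed directions, not measured parameters.
    """

    name: str
    mature_fraction: float
    precursor_multiplier: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mature_fraction <= 1.0):
            raise ConfigError("mature_fraction must lie in [0, 1]")
        if self.precursor_multiplier < 0:
            raise ConfigError("precursor_multiplier must be >= 0")


def genotype_profiles() -> dict[str, GenotypeProfile]:
    """The five built-in presets.

    wild_type: 90% of locus output is mature, baseline precursors.
    tofu2_E216A: catalytically dead nuclease - no mature piRNAs, strong
        precursor accumulation.
    slfl34_null: near-total mature loss with precursor accumulation.
    slfl3_dTM_slfl4: strong mature reduction, precursor levels unchanged.
    tofu2_pid1: mature absent, precursor accumulation reduced relative to
        the single nuclease-dead mutant (precursors destabilized).
    """
    profiles = [
        GenotypeProfile("wild_type", 0.90, 1.0),
        GenotypeProfile("tofu2_E216A", 0.0, 5.0),
        GenotypeProfile("slfl34_null", 0.02, 4.0),
        GenotypeProfile("slfl3_dTM_slfl4", 0.05, 1.0),
        GenotypeProfile("tofu2_pid1", 0.0, 2.0),
    ]
    return {p.name: p for p in profiles}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_type1_loci: int = 40
    n_type2_loci: int = 0
    n_structural_loci: int = 8
    n_ambiguous_overlaps: int = 0
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    genotype: str = "wild_type"
    n_reads: int = 50_000
    sequencing_error_rate: float = 0.0
    structural_fraction: float = 0.15
    background_fraction: float = 0.80
    pirna_fraction: float = 0.05
    baseline_precursor_fraction: float = 0.1
    offset_noise_rate: float = 0.0
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length", "n_type1_loci", "n_type2_loci",
            "n_structural_loci", "n_ambiguous_overlaps", "n_reads",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "sequencing_error_rate", "structural_fraction", "background_fraction",
            "pirna_fraction", "offset_noise_rate",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.baseline_precursor_fraction <= 1.0):
            raise ConfigError("baseline_precursor_fraction must lie in (0, 1]")
        if self.n_ambiguous_overlaps > self.n_type1_loci:
            raise ConfigError("cannot plant more ambiguous overlaps than loci")
        if self.n_chromosomes == 0 or self.chrom_length < 200:
            raise ConfigError("genome too small")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str  # full raw read: randoms + insert + randoms + adapter
    insert: str
    category: str  # mature | precursor | structural | background
    locus_id: str | None
    offset: int  # precursor 5' displacement from the -2 window (0, +1, -1)
    n_errors: int


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

_MARGIN = 40  # clearance between planted features, covers windows + 35-nt reads


def _place_intervals(
    rng: np.random.Generator,
    chrom_names: list[str],
    chrom_length: int,
    lengths: list[int],
) -> list[tuple[str, int, int]]:
    """Greedy non-overlapping placement with `_MARGIN` clearance."""
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    placed: list[tuple[str, int, int]] = []
    for length in lengths:
        for _attempt in range(10_000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            start = int(rng.integers(_MARGIN, chrom_length - length - _MARGIN))
            lo, hi = start - _MARGIN, start + length + _MARGIN
            if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                placed.append((chrom, start, start + length))
                break
        else:
            raise ConfigError("loci do not fit in genome; enlarge chromosomes")
    return placed


def _set_base(chroms: dict[str, list[str]], chrom: str, pos: int,
              base_sense: str, strand: str) -> None:
    chroms[chrom][pos] = base_sense if strand == "+" else revcomp(base_sense)


def simulate_genome(
    cfg: SimulationConfig,
) -> tuple[Genome, GenomeAnnotation, dict]:
    """Random genome plus planted annotation and a ground-truth record."""
    rng = np.random.default_rng([cfg.seed, 1])
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chroms = {
        name: list(rng.choice(_BASES, size=cfg.chrom_length))
        for name in chrom_names
    }
    n_pirna = cfg.n_type1_loci + cfg.n_type2_loci
    lengths = [21] * n_pirna + [
        int(rng.integers(90, 151)) for _ in range(cfg.n_structural_loci)
    ]
    placed = _place_intervals(rng, chrom_names, cfg.chrom_length, lengths)

    pirna_loci: list[PiRNALocus] = []
    other_features: list[OtherFeature] = []
    for i in range(n_pirna):
        chrom, start, end = placed[i]
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, end, strand)
        # sense sequence starts with T (mature 5'-U)
        _set_base(chroms, chrom, iv.five_prime, "T", strand)
        # precursor position 1 (2 nt upstream) biased toward A/G
        pos1 = start - 2 if strand == "+" else end + 1
        base1 = str(rng.choice(_BASES, p=[0.45, 0.05, 0.45, 0.05]))
        _set_base(chroms, chrom, pos1, base1, strand)
        ptype = "type1" if i < cfg.n_type1_loci else "type2"
        prefix = "21ur" if ptype == "type1" else "t2"
        pirna_loci.append(PiRNALocus(f"{prefix}-{i + 1}", iv, ptype))

    # plant same-strand confounders over the first n_ambiguous type-1 loci
    for j in range(cfg.n_ambiguous_overlaps):
        locus = pirna_loci[j]
        iv = locus.interval
        feat = GenomicInterval(
            iv.chrom, max(0, iv.start - 10), iv.start + 5, iv.strand
        )
        other_features.append(
            OtherFeature(feat, _AMBIGUOUS_CYCLE[j % len(_AMBIGUOUS_CYCLE)])
        )

    structural_loci = []
    for j in range(cfg.n_structural_loci):
        chrom, start, end = placed[n_pirna + j]
        strand = "+" if rng.random() < 0.5 else "-"
        structural_loci.append(
            StructuralLocus(
                GenomicInterval(chrom, start, end, strand),
                _STRUCTURAL_CYCLE[j % len(_STRUCTURAL_CYCLE)],
            )
        )

    genome = Genome({name: "".join(seq) for name, seq in chroms.items()})
    annotation = GenomeAnnotation(
        pirna_loci=pirna_loci,
        structural_loci=structural_loci,
        other_features=other_features,
        chrom_sizes=genome.chrom_sizes,
    )
    truth = {
        "seed": cfg.seed,
        "ambiguous_locus_ids": [l.locus_id for l in pirna_loci[: cfg.n_ambiguous_overlaps]],
        "type1_locus_ids": [l.locus_id for l in pirna_loci if l.pirna_type == "type1"],
    }
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _sense_sequence(genome: Genome, chrom: str, start: int, end: int, strand: str) -> str:
    frag = genome.chroms[chrom][start:end]
    return frag if strand == "+" else revcomp(frag)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate == 0.0:
        return seq, 0
    chars = list(seq)
    n_err = 0
    for i in range(len(chars)):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != chars[i]]
            chars[i] = alternatives[int(rng.integers(3))]
            n_err += 1
    return "".join(chars), n_err


def simulate_reads(
    cfg: SimulationConfig,
    genome: Genome,
    annotation: GenomeAnnotation,
    profile: GenotypeProfile | None = None,
) -> list[SimulatedRead]:
    """Draw a full raw-read set for one sample of the configured genotype."""
    if profile is None:
        profiles = genotype_profiles()
        if cfg.genotype not in profiles:
            raise ConfigError(f"unknown genotype preset {cfg.genotype!r}")
        profile = profiles[cfg.genotype]
    rng = np.random.default_rng([cfg.seed, 2])
    loci = annotation.type1_loci() + annotation.type2_loci()
    windows = {
        w.locus_id: w
        for w in derive_precursor_windows(annotation, include_type2=True)
    }
    n_loci = len(loci)
    if n_loci == 0:
        raise ConfigError("annotation has no piRNA loci")

    # expression weights and per-cell transcript units
    weights = rng.lognormal(cfg.expression_mu, cfg.expression_sigma, size=n_loci)
    weights /= weights.sum()
    f = profile.mature_fraction
    p = cfg.baseline_precursor_fraction * profile.precursor_multiplier
    units = np.concatenate(
        [
            cfg.pirna_fraction * weights * f,          # mature cells
            cfg.pirna_fraction * weights * p,          # precursor cells
            [cfg.structural_fraction if annotation.structural_loci else 0.0],
            [cfg.background_fraction],
        ]
    )
    total = units.sum()
    if total <= 0:
        raise ConfigError("no read sources configured")
    counts = rng.multinomial(cfg.n_reads, units / total)
    mature_counts = counts[:n_loci]
    precursor_counts = counts[n_loci : 2 * n_loci]
    n_structural = counts[2 * n_loci]
    n_background = counts[2 * n_loci + 1]

    reads: list[SimulatedRead] = []

    def emit(insert: str, category: str, locus_id: str | None, offset: int) -> None:
        seq, n_err = _apply_errors(rng, insert, cfg.sequencing_error_rate)
        full = _random_bases(rng, 4) + seq + _random_bases(rng, 4) + cfg.adapter
        reads.append(
            SimulatedRead(
                read_id=f"sim_{len(reads)}_{category}",
                sequence=full,
                insert=seq,
                category=category,
                locus_id=locus_id,
                offset=offset,
                n_errors=n_err,
            )
        )

    for locus, n_mat, n_pre in zip(loci, mature_counts, precursor_counts):
        iv = locus.interval
        mature_insert = _sense_sequence(genome, iv.chrom, iv.start, iv.end, iv.strand)
        for _ in range(int(n_mat)):
            emit(mature_insert, "mature", locus.locus_id, 0)
        window = windows.get(locus.locus_id)
        if window is None:
            continue
        wpos = window.position.start
        for _ in range(int(n_pre)):
            offset = 0
            if cfg.offset_noise_rate and rng.random() < cfg.offset_noise_rate:
                offset = 1 if rng.random() < 0.5 else -1
            length = int(rng.integers(27, 30))
            # genomic 5' start, shifted downstream by `offset` in
            # transcription direction
            if iv.strand == "+":
                start = wpos + offset
                end = start + length
            else:
                end = wpos - offset + 1
                start = end - length
            insert = _sense_sequence(genome, iv.chrom, start, end, iv.strand)
            emit(insert, "precursor", locus.locus_id, offset)

    structural = annotation.structural_loci
    for _ in range(int(n_structural)):
        s = structural[int(rng.integers(len(structural)))]
        iv = s.interval
        length = int(rng.integers(18, 36))
        length = min(length, len(iv))
        start = int(rng.integers(iv.start, iv.end - length + 1))
        insert = _sense_sequence(genome, iv.chrom, start, start + length, iv.strand)
        emit(insert, "structural", None, 0)

    # background reads must not sense-overlap any planted piRNA locus,
    # window or structural locus, so they always classify as "other"
    forbidden: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for locus in annotation.pirna_loci:
        iv = locus.interval
        zone = (iv.start - 3, iv.end) if iv.strand == "+" else (iv.start, iv.end + 3)
        forbidden.setdefault((iv.chrom, iv.strand), []).append(zone)
    for s in structural:
        iv = s.interval
        forbidden.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    chrom_names = sorted(genome.chroms)
    for _ in range(int(n_background)):
        for _attempt in range(1000):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(18, 36))
            start = int(rng.integers(0, len(genome.chroms[chrom]) - length))
            zones = forbidden.get((chrom, strand), ())
            if all(e <= start or s >= start + length for s, e in zones):
                break
        else:  # pragma: no cover - placement failure is a config problem
            raise ConfigError("could not place background reads")
        insert = _sense_sequence(genome, chrom, start, start + length, strand)
        emit(insert, "background", None, 0)

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


# ---------------------------------------------------------------------------
# ground truth + I/O
# ---------------------------------------------------------------------------

def truth_frame(reads: list[SimulatedRead]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": r.read_id,
            "category": r.category,
            "locus_id": r.locus_id if r.locus_id is not None else "",
            "offset": r.offset,
            "insert_length": len(r.insert),
            "n_errors": r.n_errors,
        }
        for r in reads
    )


def truth_count_table(
    reads: list[SimulatedRead], category: str, locus_ids: list[str]
) -> dict[str, int]:
    """Planted per-locus counts (precursors displaced by offset noise are
    not counted: their 5' end is no longer at the -2 window)."""
    counts = {locus_id: 0 for locus_id in locus_ids}
    for r in reads:
        if r.category == category and r.locus_id in counts and r.offset == 0:
            counts[r.locus_id] += 1
    return counts


def write_fasta(genome: Genome, stream: IO[str]) -> None:
    for name in sorted(genome.chroms):
        seq = genome.chroms[name]
        stream.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            stream.write(seq[i : i + 70] + "\n")


def write_fastq(reads: list[SimulatedRead], stream: IO[str]) -> None:
    for r in reads:
        stream.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_chrom_sizes(genome: Genome, stream: IO[str]) -> None:
    for name in sorted(genome.chroms):
        stream.write(f"{name}\t{len(genome.chroms[name])}\n")
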