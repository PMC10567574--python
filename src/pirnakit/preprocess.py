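"""Adapter trimming and size selection for NEXTflex-style small-RNA reads.

Library layout: 4 random bases + insert + 4 random bases + 3' adapter.
Reads are trimmed at the earliest adapter occurrence, size-selected to
26-43 nt (i.e. 18-35 nt inserts plus the 8 random bases), then the random
4-mers are stripped from both ends.  Qualities are carried through but
never used for filtering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "RawRead",
    "TrimConfig",
    "TrimmedRead",
    "Rejection",
    "TrimStats",
    "DEFAULT_ADAPTER",
    "trim_read",
    "preprocess_fastq",
]

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality string length "
                f"{len(self.qualities)} != sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class TrimConfig:
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 26
    max_len: int = 43
    random_bases_each_side: int = 4
    min_adapter_overlap: int = 3
    max_error_rate: float = 0.0  # fraction of mismatches tolerated in the match

    def __post_init__(self) -> None:
        if self.min_len < 2 * self.random_bases_each_side + 1:
            raise ValueError("min_len must exceed twice the random-base padding")
        if self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")
        if not (0.0 <= self.max_error_rate < 1.0):
            raise ValueError("max_error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrimmedRead:
    read_id: str
    insert: str
    left_random: str
    right_random: str
    qualities: str | None = None


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # "empty" | "too_short" | "too_long"


@dataclass
class TrimStats:
    kept: int = 0
    rejected: Counter = field(default_factory=Counter)
    insert_lengths: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return self.kept + sum(self.rejected.values())

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write(f"kept\t{self.kept}\n")
        for reason in sorted(self.rejected):
            stream.write(f"rejected.{reason}\t{self.rejected[reason]}\n")
        for length in sorted(self.insert_lengths):
            stream.write(f"insert_len.{length}\t{self.insert_lengths[length]}\n")


def _find_adapter(seq: str, cfg: TrimConfig) -> int | None:
    """Return the earliest start of the 3' adapter in *seq*, or None.

    A full adapter match may sit anywhere; a partial match (a prefix of the
    adapter, >= min_adapter_overlap bases) is only accepted when it runs to
    the end of the read.
    """
    adapter = cfg.adapter
    alen = len(adapter)
    if cfg.max_error_rate == 0.0:
        full = seq.find(adapter)
        limit = full if full != -1 else len(seq)
        # look for an earlier terminal partial match
        lo = max(0, len(seq) - alen + 1)
        for i in range(lo, limit):
            n = len(seq) - i
            if n < cfg.min_adapter_overlap:
                break
            if seq[i:] == adapter[:n]:
                return i
        return full if full != -1 else None
    for i in range(len(seq) - cfg.min_adapter_overlap + 1):
        n = min(alen, len(seq) - i)
        if n < alen and i + n != len(seq):
            continue
        allowed = int(cfg.max_error_rate * n)
        mm = 0
        for a, b in zip(seq[i : i + n], adapter[:n]):
            if a != b:
                mm += 1
                if mm > allowed:
                    break
        else:
            return i
    return None


def trim_read(read: RawRead, cfg: TrimConfig | None = None) -> Union[TrimmedRead, Rejection]:
    """Trim the 3' adapter, size-select, and strip the random 4-mers.

    A read without a detectable adapter is kept whole when its length falls
    inside ``[min_len, max_len]`` (inserts near the maximum may not reach
    the adapter).
    """
    cfg = cfg or TrimConfig()
    seq = read.sequence
    if not seq:
        return Rejection(read.read_id, "empty")
    cut = _find_adapter(seq, cfg)
    trimmed = seq if cut is None else seq[:cut]
    if len(trimmed) < cfg.min_len:
        return Rejection(read.read_id, "too_short")
    if len(trimmed) > cfg.max_len:
        return Rejection(read.read_id, "too_long")
    k = cfg.random_bases_each_side
    quals = None
    if read.qualities is not None:
        quals = read.qualities[k : len(trimmed) - k]
    return TrimmedRead(
        read_id=read.read_id,
        insert=trimmed[k : len(trimmed) - k],
        left_random=trimmed[:k],
        right_random=trimmed[len(trimmed) - k :],
        qualities=quals,
    )


def _iter_fastq(stream: IO[str]) -> Iterator[RawRead]:
    index = 0
    try:
        for title, seq, qual in FastqGeneralIterator(stream):
            index += 1
            yield RawRead(title.split()[0], seq.upper(), qual)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ near record {index + 1}: {exc}") from exc


def preprocess_fastq(
    in_stream: IO[str] | Iterable[RawRead],
    cfg: TrimConfig | None = None,
    out_stream: IO[str] | None = None,
) -> TrimStats:
    """Trim a FASTQ stream (or iterable of :class:`RawRead`), writing kept
    inserts as FASTQ to *out_stream* and returning tally statistics."""
    cfg = cfg or TrimConfig()
    reads = _iter_fastq(in_stream) if hasattr(in_stream, "read") else in_stream
    stats = TrimStats()
    for read in reads:
        result = trim_read(read, cfg)
        if isinstance(result, Rejection):
            stats.rejected[result.reason] += 1
            continue
        stats.kept += 1
        stats.insert_lengths[len(result.insert)] += 1
        if out_stream is not None:
            qual = result.qualities or "I" * len(result.insert)
            out_stream.write(f"@{result.read_id}\n{result.insert}\n+\n{qual}\n")
    return stats
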