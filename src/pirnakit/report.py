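"""Sample-level outputs: category totals, per-locus two-sample comparisons
on a log scale, and normalized per-base coverage tracks (bedGraph)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .align import AlignedRead
from .annotation import GenomeAnnotation
from .classify import (
    MAX_READ_LEN,
    MIN_READ_LEN,
    CountTable,
    NormalizationError,
)

__all__ = [
    "SampleComparison",
    "total_by_category",
    "compare_samples",
    "coverage_track",
    "write_bedgraph",
]

DEFAULT_PSEUDOCOUNT = 0.1


@dataclass(frozen=True)
class SampleComparison:
    locus_id: str
    rpm_a: float
    rpm_b: float
    pseudocount: float

    @property
    def log10_a(self) -> float:
        return math.log10(self.rpm_a + self.pseudocount)

    @property
    def log10_b(self) -> float:
        return math.log10(self.rpm_b + self.pseudocount)


def total_by_category(
    tables: Iterable[CountTable],
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-sample RPM and raw totals for each category table, plus optional
    group means over replicate samples.

    All tables sharing a category must share a locus universe.
    """
    tables = list(tables)
    universe: dict[str, set[str]] = {}
    rows = []
    for t in tables:
        key = t.category.value
        loci = set(t.counts)
        if key in universe and universe[key] != loci:
            raise ValueError(f"mismatched locus sets across {key} tables")
        universe.setdefault(key, loci)
        rows.append(
            {
                "sample_id": t.sample_id,
                "category": key,
                "mode": t.mode,
                "total_raw": t.total_raw,
                "total_rpm": t.total_rpm if t.rpm else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    if groups:
        sample_to_group = {s: g for g, samples in groups.items() for s in samples}
        df["group"] = df["sample_id"].map(sample_to_group)
        means = (
            df.groupby(["group", "category"], dropna=True)["total_rpm"]
            .mean()
            .rename("group_mean_rpm")
            .reset_index()
        )
        df = df.merge(means, on=["group", "category"], how="left")
    return df


def compare_samples(
    table_a: CountTable,
    table_b: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[SampleComparison]:
    """Paired per-locus RPM values for scatter plotting on log10 axes."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if set(table_a.counts) != set(table_b.counts):
        raise ValueError("tables cover different locus sets")
    if not table_a.rpm or not table_b.rpm:
        raise ValueError("both tables must be RPM-normalized first")
    return [
        SampleComparison(
            locus_id=locus_id,
            rpm_a=table_a.rpm[locus_id],
            rpm_b=table_b.rpm[locus_id],
            pseudocount=pseudocount,
        )
        for locus_id in sorted(table_a.counts)
    ]


def comparison_frame(comparisons: Iterable[SampleComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": c.locus_id,
            "rpm_a": c.rpm_a,
            "rpm_b": c.rpm_b,
            "log10_a": c.log10_a,
            "log10_b": c.log10_b,
        }
        for c in comparisons
    )


def coverage_track(
    reads: Iterable[AlignedRead],
    annotation: GenomeAnnotation,
    denominator: int,
) -> list[tuple[str, int, int, float]]:
    """Per-base coverage of 18-35-nt reads sense-overlapping piRNA loci,
    scaled by 1e6 / denominator, as merged bedGraph runs."""
    if denominator <= 0:
        raise NormalizationError("coverage normalization requires denominator > 0")
    if not annotation.chrom_sizes:
        raise ValueError("annotation must carry chromosome sizes")
    loci_by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for locus in annotation.pirna_loci:
        iv = locus.interval
        loci_by_key.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
    depth = {
        chrom: np.zeros(size, dtype=np.int64)
        for chrom, size in annotation.chrom_sizes.items()
    }
    for read in reads:
        if not read.mapped or not (MIN_READ_LEN <= read.length <= MAX_READ_LEN):
            continue
        iv = read.interval
        hits = loci_by_key.get((iv.chrom, iv.strand), ())
        if any(s < iv.end and iv.start < e for s, e in hits):
            depth[iv.chrom][iv.start : iv.end] += 1
    scale = 1e6 / denominator
    track: list[tuple[str, int, int, float]] = []
    for chrom in sorted(depth):
        arr = depth[chrom]
        if not arr.any():
            continue
        boundaries = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(arr)]))
        for s, e in zip(starts, ends):
            value = int(arr[s])
            if value:
                track.append((chrom, int(s), int(e), value * scale))
    return track


def write_bedgraph(track: Iterable[tuple[str, int, int, float]], stream: IO[str]) -> None:
    for chrom, start, end, value in track:
        stream.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")
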