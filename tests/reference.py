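"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain quadratic scans over unindexed data,
deliberately sharing no code with the package's classifier or aligner.
"""

from __future__ import annotations


def ref_revcomp(seq: str) -> str:
    table = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(table[b] for b in reversed(seq))


def ref_read_five_prime(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def ref_sequenced_first_base(seq_forward: str, strand: str) -> str:
    if strand == "+":
        return seq_forward[0]
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[seq_forward[-1]]


def ref_classify(read, annotation, windows, mode):
    """Brute-force assignment of one AlignedRead.

    read: object with .interval (chrom,start,end,strand), .strand,
    .sequence (forward projection), .mapped.
    Returns a set of (category_value, locus_id|None) using the same string
    labels as the package's ReadCategory values.
    """
    length = read.interval.end - read.interval.start
    if not read.mapped or length < 18 or length > 35:
        return set()
    # structural: sense overlap with any structural locus
    for s in annotation.structural_loci:
        siv = s.interval
        if (
            siv.chrom == read.interval.chrom
            and siv.strand == read.strand
            and read.interval.start < siv.end
            and siv.start < read.interval.end
        ):
            return {("structural", None)}
    out = set()
    mature_label = {"type1": "mature_type1", "type2": "mature_type2"}
    precursor_label = {"type1": "precursor_type1", "type2": "precursor_type2"}
    for locus in annotation.pirna_loci:
        liv = locus.interval
        if liv.chrom != read.interval.chrom or liv.strand != read.strand:
            continue
        if mode == "stringent":
            contained = liv.start <= read.interval.start and read.interval.end <= liv.end
            first = ref_sequenced_first_base(read.sequence, read.strand)
            if length == 21 and contained and first == "T":
                out.add((mature_label[locus.pirna_type], locus.locus_id))
        else:
            if read.interval.start < liv.end and liv.start < read.interval.end:
                out.add((mature_label[locus.pirna_type], locus.locus_id))
    for w in windows:
        p = w.position
        if p.chrom != read.interval.chrom or p.strand != read.strand:
            continue
        if mode == "stringent":
            fp = ref_read_five_prime(read.interval.start, read.interval.end, read.strand)
            if 23 <= length <= 35 and fp == p.start:
                out.add((precursor_label[w.pirna_type], w.locus_id))
        else:
            if read.interval.start <= p.start < read.interval.end:
                out.add((precursor_label[w.pirna_type], w.locus_id))
    if not out:
        out.add(("other_nonstructural", None))
    return out


def ref_denominator(reads, annotation) -> int:
    n = 0
    for read in reads:
        length = read.interval.end - read.interval.start
        if not read.mapped or length < 18 or length > 35:
            continue
        structural = any(
            s.interval.chrom == read.interval.chrom
            and s.interval.strand == read.strand
            and read.interval.start < s.interval.end
            and s.interval.start < read.interval.end
            for s in annotation.structural_loci
        )
        if not structural:
            n += 1
    return n


def ref_align(insert: str, chroms: dict[str, str]):
    """Scan every position on both strands; return the best hit as
    (mismatches, chrom, start, strand) or None, using the documented
    tie-break order (stratum, chrom, start, + before -)."""
    hits = []
    for strand in ("+", "-"):
        query = insert if strand == "+" else ref_revcomp(insert)
        for chrom in chroms:
            seq = chroms[chrom]
            for start in range(len(seq) - len(query) + 1):
                mm = sum(
                    1 for a, b in zip(query, seq[start : start + len(query)]) if a != b
                )
                if mm <= 1:
                    hits.append((mm, chrom, start, 0 if strand == "+" else 1))
    if not hits:
        return None
    mm, chrom, start, srank = min(hits)
    return mm, chrom, start, "+" if srank == 0 else "-"
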