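import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pirnakit.annotation import (
    GenomeAnnotation,
    GenomicInterval,
    PiRNALocus,
    PrecursorWindow,
    StructuralLocus,
    derive_precursor_windows,
)
from pirnakit.classify import (
    Classifier,
    CountTable,
    NormalizationError,
    ReadCategory,
    classify_read,
    compute_denominator,
    count_by_locus,
    is_mature,
    is_precursor,
    is_structural,
    normalize_rpm,
)
from conftest import make_read
from reference import ref_classify, ref_denominator


def random_instance(rng, n_loci=30, n_structural=5, chrom_len=20_000):
    """Random annotation + windows for oracle comparisons."""
    loci = []
    starts = rng.choice(chrom_len - 100, size=n_loci, replace=False)
    for i, s in enumerate(sorted(int(x) for x in starts)):
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(PiRNALocus(f"L{i}", GenomicInterval("chr1", s + 50, s + 71, strand)))
    structural = []
    for _ in range(n_structural):
        s = int(rng.integers(0, chrom_len - 200))
        strand = "+" if rng.random() < 0.5 else "-"
        structural.append(
            StructuralLocus(
                GenomicInterval("chr1", s, s + int(rng.integers(60, 150)), strand),
                ["rRNA", "tRNA", "snRNA", "snoRNA"][int(rng.integers(4))],
            )
        )
    ann = GenomeAnnotation(
        pirna_loci=loci, structural_loci=structural, chrom_sizes={"chr1": chrom_len + 200}
    )
    return ann, derive_precursor_windows(ann)


def random_reads(rng, ann, n=300, chrom_len=20_000):
    reads = []
    loci = ann.pirna_loci
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(18, 36))
        if loci and rng.random() < 0.6:
            # drop reads near loci so interesting cases happen often
            locus = loci[int(rng.integers(len(loci)))]
            anchor = locus.interval.start + int(rng.integers(-40, 40))
            start = max(0, min(chrom_len - length, anchor))
            strand = locus.interval.strand if rng.random() < 0.8 else strand
        else:
            start = int(rng.integers(0, chrom_len - length))
        first = "T" if rng.random() < 0.6 else "ACG"[int(rng.integers(3))]
        reads.append(
            make_read(
                chrom="chr1", start=start, length=length, strand=strand,
                first_base=first, read_id=f"r{i}",
            )
        )
    return reads


class TestIsStructural:
    def test_sense_overlap_true(self, small_annotation, read_factory):
        read = read_factory(start=5010, length=22, strand="+")
        assert is_structural(read, small_annotation)

    def test_antisense_false(self, small_annotation, read_factory):
        read = read_factory(start=5010, length=22, strand="-")
        assert not is_structural(read, small_annotation)

    def test_against_brute_force(self, rng):
        ann, _ = random_instance(rng)
        for read in random_reads(rng, ann, 200):
            expected = ("structural", None) in ref_classify(read, ann, [], "stringent")
            assert is_structural(read, ann) == expected


class TestIsMature:
    LOCUS = PiRNALocus("a", GenomicInterval("chr1", 999, 1020, "+"))

    def test_exact_21nt_t_start(self, read_factory):
        assert is_mature(read_factory(start=999, length=21, first_base="T"), self.LOCUS)

    def test_wrong_first_base(self, read_factory):
        assert not is_mature(read_factory(start=999, length=21, first_base="A"), self.LOCUS)

    def test_minus_strand_first_base_uses_sequenced_orientation(self):
        locus = PiRNALocus("b", GenomicInterval("chr1", 999, 1020, "-"))
        # forward projection ends with A <=> sequenced read starts with T
        read = make_read(start=999, length=21, strand="-", first_base="T")
        assert read.sequence.endswith("A")
        assert is_mature(read, locus)

    def test_exhaustive_variants_single_locus(self):
        # all lengths x offsets x first bases against the plus-strand locus
        for length in (20, 21, 22):
            for offset in (-1, 0, 1):
                for base in "ACGT":
                    for strand in "+-":
                        read = make_read(
                            start=999 + offset, length=length, strand=strand,
                            first_base=base,
                        )
                        expected = (
                            length == 21 and offset == 0 and base == "T" and strand == "+"
                        )
                        assert is_mature(read, self.LOCUS) == expected


class TestIsPrecursor:
    WINDOW = PrecursorWindow("a", GenomicInterval("chr1", 997, 998, "+"))

    def test_28nt_at_minus2(self, read_factory):
        assert is_precursor(read_factory(start=997, length=28), self.WINDOW)

    def test_21nt_at_minus2_too_short(self, read_factory):
        assert not is_precursor(read_factory(start=997, length=21), self.WINDOW)

    def test_offset_scan_only_minus2_passes(self, read_factory):
        # locus 5' end at 999; candidate 5' ends from -5 to +5 around it
        for shift in range(-5, 6):
            read = read_factory(start=999 + shift, length=28)
            assert is_precursor(read, self.WINDOW) == (shift == -2)

    def test_minus_strand_five_prime(self):
        window = PrecursorWindow("b", GenomicInterval("chr1", 1021, 1022, "-"))
        read = make_read(start=1021 - 27, length=28, strand="-")
        assert read.interval.end - 1 == 1021
        assert is_precursor(read, window)


class TestClassifyRead:
    def test_structural_short_circuits(self):
        ann = GenomeAnnotation(
            pirna_loci=[PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+"))],
            structural_loci=[StructuralLocus(GenomicInterval("chr1", 90, 130, "+"), "rRNA")],
        )
        windows = derive_precursor_windows(ann)
        read = make_read(start=100, length=21, first_base="T")
        assert classify_read(read, ann, windows) == {(ReadCategory.STRUCTURAL, None)}

    def test_multi_assignment_over_identical_loci(self):
        loci = [
            PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+")),
            PiRNALocus("b", GenomicInterval("chr1", 100, 121, "+")),
        ]
        ann = GenomeAnnotation(pirna_loci=loci)
        read = make_read(start=100, length=21, first_base="T")
        got = classify_read(read, ann, [])
        assert got == {
            (ReadCategory.MATURE_TYPE1, "a"),
            (ReadCategory.MATURE_TYPE1, "b"),
        }

    def test_unmatched_read_is_other(self):
        ann = GenomeAnnotation(
            pirna_loci=[PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+"))]
        )
        read = make_read(start=5000, length=25)
        assert classify_read(read, ann, []) == {(ReadCategory.OTHER, None)}

    def test_relaxed_any_sense_overlap(self):
        ann = GenomeAnnotation(
            pirna_loci=[PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+"))]
        )
        windows = derive_precursor_windows(ann)
        # 19-nt read overlapping the locus tail: relaxed mature, not stringent
        read = make_read(start=115, length=19, first_base="G")
        assert classify_read(read, ann, windows, "relaxed") == {
            (ReadCategory.MATURE_TYPE1, "a")
        }
        assert classify_read(read, ann, windows, "stringent") == {
            (ReadCategory.OTHER, None)
        }

    @pytest.mark.parametrize("mode", ["stringent", "relaxed"])
    def test_oracle_equivalence(self, rng, mode):
        ann, windows = random_instance(rng)
        classifier = Classifier(ann, windows, mode)
        for read in random_reads(rng, ann, 400):
            got = {(c.value, lid) for c, lid in classifier.classify(read)}
            assert got == ref_classify(read, ann, windows, mode)

    def test_stringent_subset_of_relaxed(self, rng):
        ann, windows = random_instance(rng)
        stringent = Classifier(ann, windows, "stringent")
        relaxed = Classifier(ann, windows, "relaxed")
        for read in random_reads(rng, ann, 300):
            s = {a for a in stringent.classify(read) if a[0] is not ReadCategory.OTHER}
            r = {a for a in relaxed.classify(read) if a[0] is not ReadCategory.OTHER}
            assert s <= r

    def test_mature_precursor_disjoint_by_length(self, rng):
        ann, windows = random_instance(rng)
        classifier = Classifier(ann, windows, "stringent")
        for read in random_reads(rng, ann, 300):
            cats = {c for c, _ in classifier.classify(read)}
            assert not (
                ReadCategory.MATURE_TYPE1 in cats
                and ReadCategory.PRECURSOR_TYPE1 in cats
            )


class TestCounting:
    def test_counts_on_one_locus(self):
        ann = GenomeAnnotation(
            pirna_loci=[
                PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+")),
                PiRNALocus("b", GenomicInterval("chr1", 500, 521, "+")),
            ]
        )
        reads = [
            make_read(start=100, length=21, first_base="T", read_id=f"m{i}")
            for i in range(5)
        ]
        table = count_by_locus(reads, ann, [], "stringent", ReadCategory.MATURE_TYPE1)
        assert table.counts == {"a": 5, "b": 0}

    def test_empty_stream_all_zero(self):
        ann = GenomeAnnotation(
            pirna_loci=[PiRNALocus("a", GenomicInterval("chr1", 100, 121, "+"))]
        )
        table = count_by_locus([], ann, [], "stringent", ReadCategory.MATURE_TYPE1)
        assert table.counts == {"a": 0}

    def test_denominator_excludes_structural(self):
        ann = GenomeAnnotation(
            structural_loci=[StructuralLocus(GenomicInterval("chr1", 0, 1000, "+"), "rRNA")]
        )
        reads = [
            make_read(start=10, length=21, strand="+", read_id=f"s{i}") for i in range(30)
        ] + [
            make_read(start=2000 + 40 * i, length=21, strand="+", read_id=f"n{i}")
            for i in range(70)
        ]
        assert compute_denominator(reads, ann) == 70

    def test_denominator_against_brute_force(self, rng):
        ann, _ = random_instance(rng)
        reads = random_reads(rng, ann, 400)
        assert compute_denominator(reads, ann) == ref_denominator(reads, ann)

    def test_denominator_size_gate(self):
        ann = GenomeAnnotation()
        short = make_read(start=10, length=17)
        long = make_read(start=10, length=36)
        ok = make_read(start=10, length=18)
        assert compute_denominator([short, long, ok], ann) == 1


class TestNormalize:
    def table(self, counts):
        return CountTable("s", ReadCategory.MATURE_TYPE1, "stringent", counts)

    def test_rpm_formula(self):
        t = normalize_rpm(self.table({"a": 70}), 1_000_000)
        assert t.rpm["a"] == pytest.approx(70.0)

    def test_zero_raw_zero_rpm(self):
        t = normalize_rpm(self.table({"a": 0}), 100)
        assert t.rpm["a"] == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(NormalizationError):
            normalize_rpm(self.table({"a": 1}), 0)

    @given(
        raw=st.integers(min_value=0, max_value=10_000),
        denom=st.integers(min_value=1, max_value=10_000),
        k=st.integers(min_value=2, max_value=50),
    )
    def test_denominator_scaling(self, raw, denom, k):
        t1 = normalize_rpm(self.table({"a": raw}), denom)
        tk = normalize_rpm(self.table({"a": raw}), denom * k)
        assert tk.rpm["a"] * k == pytest.approx(t1.rpm["a"])
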