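# pirnakit

Small-RNA read classification and quantification for *C. elegans* piRNAs
(21U RNAs), together with an executable rule model of the PUCH nuclease's
substrate specificity and a ground-truth read simulator so the whole
pipeline is testable offline.

## What it does

* **annotation** — loads GTF annotations (piRNA genes via
  `gene_biotype "piRNA"`; rRNA/tRNA/snRNA/snoRNA as the structural class),
  removes type-1 piRNA loci that overlap miRNAs/snoRNAs/exons on the same
  strand, and derives the single-base precursor-counting window 2 nt
  upstream of each locus 5′ end. Internal coordinates are 0-based
  half-open; GTF I/O converts at the boundary.
* **preprocess** — NEXTflex-style trimming: finds the 3′ adapter
  (`TGGAATTCTCGGGTGCCAAGG`), size-selects trimmed reads to 26–43 nt and
  strips the 2× 4 random bases, yielding 18–35-nt inserts.
* **align** — exact/1-mismatch best-hit placement of inserts on small
  genomes (pigeonhole 9-mer seeds, deterministic tie-breaking), emitting
  coordinate-sorted SAM with `<len>M` CIGARs and `NM` tags.
* **classify** — the core computation. Reads are partitioned with
  structural precedence:
  * *structural*: ≥1 bp sense overlap with a structural RNA locus —
    excluded from all counting and from the normalization denominator;
  * *mature* (stringent): 21 nt, sequenced 5′ base T, fully contained in a
    piRNA locus, sense;
  * *precursor* (stringent): 23–35 nt with the 5′ end exactly at the −2
    window, sense;
  * *relaxed* mode instead counts any 18–35-nt sense overlap.
  Per-locus counts are normalized to reads per million non-structural
  18–35-nt reads (RPM).
* **report** — per-sample category totals with replicate group means,
  per-locus log10 scatter comparisons between samples (pseudocount 0.1
  RPM), and normalized per-base coverage tracks (bedGraph).
* **cleavage_model** — PUCH specificity as a decision engine: cleavage
  between nucleotides 2 and 3 leaving a 5′-monophosphate, requiring the
  wild-type trimer (TOFU-1 + TOFU-2 + SLFL-3 or SLFL-4), an m7G cap, U at
  position 3, no EDTA, and Mg/Mn (or high Ca, never Zn); a position-1 C
  slows cleavage; the 3′ tail is irrelevant.
* **simulate** — deterministic synthetic genomes/annotations/read sets
  with planted ground truth and genotype presets (`wild_type`,
  `tofu2_E216A`, `slfl34_null`, `slfl3_dTM_slfl4`, `tofu2_pid1`).

## CLI

```bash
pirnakit run-all --seed 1 --genotype wild_type --n-reads 50000 --out out/wt
pirnakit simulate --seed 1 --genotype tofu2_E216A --out out/simdir
pirnakit trim -i reads.fastq -o trimmed.fastq --stats stats.tsv
pirnakit align -i trimmed.fastq -g genome.fa -o aligned.sam
pirnakit classify -i aligned.sam -a annotation.gtf --chrom-sizes genome.chrom.sizes \
    --mode stringent --out-prefix counts
pirnakit report --table-a counts_wt.tsv --table-b counts_mut.tsv --out scatter.tsv
pirnakit cleave --out panel.tsv
```

`run-all` wires simulate → trim → align → classify → report into one
output directory with a `manifest.json` recording configuration, seeds and
per-stage record counts. Exit codes: 0 success, 1 usage error, 2 data
error.

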