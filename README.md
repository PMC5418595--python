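# combilib

Verification of combinatorial Golden Gate promoter libraries from long
sequencing reads, plus the accompanying assay arithmetic. The package covers:

- **`combilib.library_model`** — promoter parts (strong / medium / weak /
  inducible), gene units, the slot-based combinatorial design, its design-space
  size and chance category distribution, and the alignment reference database
  (parts + combined CDS/terminator units + backbone/lambda decoys).
- **`combilib.synthetic_data`** — ground-truthed simulation: random assemblies
  (multigene, digested single-gene, undigested single-gene), restriction-digest
  size selection against inclusive bp windows, contaminant reads, and a
  configurable substitution/insertion/deletion error model. Fully seeded.
- **`combilib.alignment_io`** — parser/serializer for the LAST `-fTAB` tabular
  alignment dialect (0-based coordinates, minus-strand starts converted to
  forward-strand), and a numba-accelerated O(n·m) local aligner
  (`naive_align`, match +1 / mismatch −1 / gap open 2 / extend 1) used as a
  test-scale oracle in place of an external aligner.
- **`combilib.read_classifier`** — the read-identification algorithm: order
  alignments by read then read coordinate, collapse/merge per-region segments,
  drop reads whose best alignment is a decoy, match chains against construct
  templates, enforce the 15 % length rule (inclusive) and the 50 bp
  end-anchoring rule for digested single-gene calls, and record the promoter
  at each gene slot (`tabulate` → per-stage count tables).
- **`combilib.bias_stats`** — per-gene χ² goodness-of-fit against the chance
  category distribution with an exact multinomial fallback when expected
  counts drop below 5; two-sided Fisher's exact test (exact integer
  hypergeometric enumeration) for producer-strain category enrichment;
  Benjamini–Hochberg adjustment.
- **`combilib.assay_quant`** — growth-inhibition percentage from OD600
  fold-changes, LCMS calibration-line fitting over an automatically detected
  linear range, quantification with LOD (3:1) / LOQ (10:1) signal-to-noise
  flags, and yield fold-changes with pg/ng/µg·ml⁻¹ unit normalisation.

## CLI

```sh
combilib simulate --n-reads 200 --seed 1 --scale 0.15 --outdir demo/
combilib align --db demo/reference.fasta --reads demo/reads.fasta \
    --min-score 25 --out demo/aln.tab
combilib parse-tab demo/aln.tab
combilib classify --tab demo/aln.tab --design demo/design.tsv \
    --design-fasta demo/design.fasta \
    --out-verdicts demo/verdicts.tsv --out-counts demo/counts.tsv
combilib test-bias --tables demo/counts.tsv --design demo/design.tsv \
    --design-fasta demo/design.fasta
combilib assay --plate plate.csv
combilib quantify --standards standards.csv --samples samples.csv
```

`--scale` shrinks the demo design's region lengths (the classification rules
are scale-free); use scale 1.0 with an external aligner's TAB output for
full-size data. `combilib align` is dynamic programming over every region and
is intended for test-scale inputs only.

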