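# gapweaver

Close, validate and annotate assembly gaps. gapweaver re-implements a
long-read genome-improvement pipeline as a reusable toolkit:

- **gap closing** — detect N-run gaps in chromosome scaffolds and fill them
  with donor contigs anchored on both flanks, with a configurable
  fill-length deviation tolerance and a shrinkage guard that rejects
  mis-ligating donors (small non-linear homologies);
- **validation** — check closed gaps for collinearity against an independent
  assembly, and for coverage by barcoded linked-read molecules;
- **scaffold support** — optical-map coverage filtering of scaffolded
  contigs and adjudication of candidate inversions;
- **unplaced contigs** — decide which previously unplaced contigs are now
  represented in the patched assembly, and concatenate the remainder with
  N spacers;
- **repeats** — telomere motif scanning of raw long reads with end
  extension of the assembly, and centromere monomer-array detection with
  higher-order-repeat periodicity;
- **enrichment** — permutation tests (length-preserving random shuffles)
  for repeat-count and gene-base overlap enrichment of newly added
  sequence;
- **simulation** — truth-known synthetic genomes exercising every stage,
  including planted anomalies that each validator must catch.

All coordinates are 0-based half-open internally; 1-based conventions only
appear at serialization boundaries (XMAP). Every edit transforming one
assembly version into the next is recorded in a patch ledger (AGP-like
TSV) that also provides coordinate liftover in both directions.

## Test

```sh
python -m pytest -q tests/
```

The suite is self-contained: all fixtures are generated programmatically
from seeded simulations (no data downloads).

## CLI

```sh
gapweaver gaps --assembly ref.fa --min-run 1          # BED of N-run gaps
gapweaver metrics --assembly ref.fa                   # N50/L50/N90/L90 ...
gapweaver close --assembly ref.fa --donors contigs.fa --paf donors.paf \
    -a 1.0 --flank 1000                               # patched FASTA + ledger + report
gapweaver apply --assembly ref.fa --ledger ledger.tsv --out new.fa
gapweaver lift --ledger ledger.tsv --chrom chrI --pos 12345
gapweaver align-filter --paf in.paf --out kept.paf    # identity > 0.98, span > 4 kb
gapweaver validate --assembly ref.fa --ledger ledger.tsv --bam linked.bam
gapweaver optical-prune --assembly asm.fa --contigs-bed tiles.bed --optical aln.xmap
gapweaver inversions --inversions-bed inv.bed --optical aln.xmap
gapweaver chrun --contigs chrUn.fa --paf chrun.paf --ledger ledger.tsv
gapweaver telomeres --reads reads.fa --assembly asm.fa --paf reads.paf
gapweaver centromeres --contigs contigs.fa --consensus monomer.fa
gapweaver enrich --segments-bed fills.bed --features-bed repeats.bed \
    --genome-tsv genome.tsv --stat count --n-perm 10000 --seed 17
gapweaver simulate --seed 17 --out fixtures/         # truth-known dataset
```

Linked reads may be supplied as a BAM/SAM with `BX` barcode tags or as a
TSV (`read  barcode  chrom  start  end`). Optical alignments as XMAP or a
simplified TSV (`optical_contig  chrom  start  end  collinear`).

## Layout

```
src/gapweaver/
  genome_model.py      assemblies, gaps, patch ledger, liftover, contiguity metrics
  alignments.py        PAF parsing, collinearity filter, unique anchor spans, placement
  gap_filler.py        anchoring, closing, partial extension, shrinkage guard
  scaffold_support.py  optical-map contig support, pruning, inversion adjudication
  gap_validator.py     collinearity + linked-read molecule validation
  unplaced.py          unplaced-contig disposition and concatenation
  repeats.py           telomere motifs and merging; monomer arrays and HOR period
  enrichment.py        segment shuffling and permutation tests
  simulate.py          truth-known synthetic fixtures with planted anomalies
  cli.py               click-based command line
```
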