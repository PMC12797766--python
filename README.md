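# pb10x

Computational toolkit for a plate-based, 10X-compatible 5′ scRNA-seq
workflow in which the template-switching oligo (TSO) carries a well-specific
barcode. It covers the full desk-side loop around such a protocol:

- **design** — select well barcodes from a vendor whitelist under a minimum
  pairwise Levenshtein-distance constraint (default 24 barcodes at distance
  ≥ 5) and assemble the 60-nt barcoded TSOs
  (`handle + barcode16 + UMI9 + TTTCTTATAT + GGG`, 5′-biotin-blocked).
- **simulate** — a ground-truthed read simulator for the protocol's
  geometry (R1 = 26 nt: barcode + UMI + first spacer base; R2 = 90 nt), with
  a toy transcriptome (including a short mitochondrial class),
  negative-binomial expression, and two injectable artifact classes: TSO
  concatemers (junction motif `ATATGGGCTAC`) and strand-invasion reads whose
  upstream reference context carries the read's own UMI–spacer–GGG pattern.
- **demux** — positional R1 parsing, Hamming-1 whitelist correction
  (unique-match-or-drop), well→pool assignment (pools of 24), per-cell read
  counts.
- **qc** — concatemer detection by exact junction literals (k = 11) and
  strand-invasion profiling: fuzzy matching of the UMI–spacer–GGG pattern
  against the 23-bp window upstream of each deduplicated 5′ UMI-read's
  alignment start, 0–3 mismatches, with per-protocol presets
  (`ss3x` UMI 10 incl. variable WW spacer, `pb10x` UMI 9, `tenx` UMI 10).
- **metrics** — seeded subsampling, sequencing saturation
  (`1 − unique/total` over (cell, gene, UMI) triples), saturation curves over
  a depth grid, per-gene dropout ratios, per-cell QC (genes, UMIs, % mito),
  and paired-TCR recovery from AIRR contig tables (complete + productive +
  CDR3 filter).

## CLI

All subcommands run through a single entry point, `pb10x`:

```bash
# select 24 barcodes at Levenshtein >= 5 and write the TSO order sheet
pb10x design --whitelist whitelist.txt --n 24 --dmin 5 --out order

# simulate a 24-cell pool with artifacts, writing FASTQ + truth + reference
pb10x simulate --cells 24 --depth 1000 --concatemer-rate 0.1 \
    --invasion-rate 0.05 --seed 100 --out sim/

# demultiplex one pool's R1 against the whitelist
pb10x demux --r1 sim/R1.fastq.gz --whitelist whitelist.txt \
    --layout sim/layout.tsv --out demux/

# artifact QC
pb10x qc concatemer --r2 sim/R2.fastq.gz
pb10x qc invasion --tags sim/tags.tsv --ref sim/reference.fasta --method pb10x
pb10x qc matrix --dense counts.tsv --out qc/

# metrics
pb10x saturate --tags sim/truth.tsv --grid 100,250,500 --seed 100
pb10x tcr --airr airr.tsv --cells cells.txt
```

`--seed` is mandatory for every stochastic subcommand; identical seeds give
byte-identical outputs.

## Layout

```
src/pb10x/
  design.py     barcode selection + TSO assembly (Levenshtein core)
  plate.py      wells, layouts, pooling
  simulate.py   ground-truthed read/expression/AIRR simulators
  demux.py      R1 parsing, barcode correction, read counting
  artifacts.py  concatemer + strand-invasion QC
  metrics.py    saturation, dropout, per-cell QC, TCR recovery
  io.py         gzip-transparent FASTA/FASTQ/GTF/TSV helpers
  cli.py        click entry point
tests/          pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
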