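# icrdesign

Design and analysis toolkit for CpG-island-like regulatory elements
(imprinting-control-region style), built around five ideas:

- **Sequence profiling and twin search** (`icrdesign.seqfeatures`): CpG/GC
  statistics for sequences and fixed genome windows, plus a ranked search
  for genome windows matching a query's length, GC%, CpG count and CpG
  spacing distribution (weighted |ΔGC| + relative |ΔCpG| + spacing-KS
  pseudo-metric).
- **Constrained inter-CpG shuffling** (`icrdesign.shuffle`): permute only
  the bases between CpG dinucleotides while preserving the exact number and
  position of every CpG and per-tile GC content, forbidding novel CpGs and
  chosen motifs (ZFP57's TGCCGC on both strands by default), and driving
  sequence mismatch to a target or maximum via hill-climbing. Includes
  motif reconstitution (byte-copy of motif spans back into a shuffled
  sequence, with junction repair).
- **Motif scanning and walking-swap scans** (`icrdesign.motifscan`):
  exact/IUPAC or PWM log-odds scanning on both strands, disruption reports,
  and a sliding donor-window replacement scan with pluggable scorers.
- **Single-molecule bisulfite analysis** (`icrdesign.bisulfite`): in-silico
  bisulfite conversion, global alignment of amplicon reads in
  bisulfite-collapsed space (directional or non-directional, all four
  strand forms), per-CpG/per-molecule methylation calls with QC, and
  coverage-filtered summaries.
- **Synthetic data** (`icrdesign.synthetic`): generators for
  CpG-island-like sequences with exact CpG counts, toy genomes with planted
  (optionally disguised) twins, and bisulfite read sets under bimodal /
  disordered / per-site epiallele scenarios — every pipeline stage is
  testable without downloads.

Coordinates are 0-based half-open everywhere, including BED output.

## CLI

One umbrella command, `icrdesign`, with per-task subcommands. Data goes to
files, logs to stderr; commands that consume randomness require `--seed`
and are then bitwise reproducible.

```bash
# composition profile of each FASTA record
icrdesign profile input.fa --out profiles.tsv

# 1-kb window scan of a genome
icrdesign scan-windows genome.fa --window 1000 --out windows.tsv

# rank genome windows by similarity to a query element
icrdesign twins genome.fa --query icr.fa --top-k 5 \
    --out-tsv twins.tsv --out-bed twins.bed

# constrained shuffle to maximum mismatch, with audit report
icrdesign shuffle --fasta icr.fa --maximize --seed 7 \
    --out shuffled.fa --report audit.json

# motif scan (default motif TGCCGC, both strands)
icrdesign scan-motifs icr.fa --out hits.bed

# walking 10-bp donor-window swap scan under the motif-count scorer
icrdesign walk-swap --base shuffled.fa --donor icr.fa \
    --window 10 --step 1 --scorer motif-count --out walk.tsv

# single-molecule methylation calling
icrdesign bs-call --reference amplicon.fa --reads reads.fq \
    --mode non-directional --min-coverage 500 \
    --out-matrix lollipop.tsv --out-summary summary.tsv

# synthetic inputs
icrdesign simulate sequence --length 3000 --gc 0.6 --n-cpg 120 --seed 7 --out icr.fa
icrdesign simulate genome --contig-length 200000 --plant-query icr.fa \
    --disguise keep_grid_reshuffle --seed 4 --out genome.fa --out-coords coords.tsv
icrdesign simulate reads --reference amplicon.fa --mode disordered --p 0.403 \
    --n-molecules 2000 --conversion-rate 0.99 --error-rate 0.001 \
    --seed 1 --out reads.fq --out-truth truth.tsv
```

A YAML config (`icrdesign --config run.yaml <subcommand> ...`) can override
any default; unknown keys are rejected. CLI flags take precedence over the
config file.

## Package layout

```
src/icrdesign/
  core.py         shared sequence types (GenomicSequence, CpGGrid)
  seqfeatures.py  profiles, window scans, twin search
  shuffle.py      constrained shuffling, mismatch, reconstitution
  motifscan.py    motif definitions/scanning, walking-swap scans, scorers
  bisulfite.py    conversion simulation, alignment, calling, summaries
  synthetic.py    sequence/genome/read generators with ground truth
  io.py           FASTA/FASTQ/BED/TSV/manifest I/O
  config.py       validated YAML configuration
  cli.py          click-based CLI
tests/            unit, property (hypothesis) and acceptance suites
scripts/acceptance.py
```
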