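# circtrans

Tools for studying cap-independent translation of circular RNAs:

- **screen** — recover random 10-nt inserts from sorted-fraction reporter
  screen reads (exact vector-flank matching), extend each insert into a
  14-mer with two vector nucleotides per side, count the 9 overlapping
  hexamers per fraction, and score per-hexamer enrichment between the
  green (translating) and dark fractions with a pooled two-proportion
  z statistic (enriched: z > 7, depleted: z < −7 by default). Includes
  base/dinucleotide composition statistics and deterministic
  average-linkage motif clustering with consensus position-frequency
  matrices.
- **hexstats** — per-transcript hexamer-set frequencies, two-sample
  Kolmogorov–Smirnov comparisons between transcript classes, positional
  sliding-window profiles over anchored regions, and a heptamer→hexamer
  split lookup against the enrichment score table.
- **circorf** — ORF prediction on circular sequences via the 4×
  concatemer: NTG starts, ≥20 aa cORFs, and rolling-circle ORFs (rcORFs,
  stop-free frame paths), plus a survey classifying circles by host-gene
  overlap (≥7 aa shared run), homology to known proteins (≤2
  substitutions, ungapped), with reversed/shuffled control sets and
  first-exon statistics.
- **junction** — translation through the back-splice junction in all
  three frames, in-silico tryptic digestion (cleave after K/R, not
  before P, ≤3 missed cleavages), the junction-spanning peptide database
  (length ≥8, ≥2 novel aa per side), and the sequential PSM filter
  cascade: thresholds (q < 0.01, length, flanks, missed cleavages,
  modification whitelist) → exact reference match → ≤2-mismatch homology
  → b/y fragment ions on both sides of the junction. Linear
  splice-junction control peptides and per-junction spectra/sample
  summaries included.
- **simulate** — ground-truthed generators for screen reads (planted
  active hexamers), circles (planted cORFs/rcORFs/ORF-free), and PSM
  tables (true junction PSMs plus one planted violator per filter rule),
  so every stage is testable offline.
- **pipeline** — YAML-config orchestration with deterministic per-stage
  seeding and a machine-readable run report.

## CLI

One entry point with subcommands:

```sh
circtrans simulate screen --seed 1 --out sim/
circtrans screen score --green sim/medium.fastq --green sim/high.fastq \
    --dark sim/negative.fastq --out scored/
circtrans screen cluster --scores scored/hexamer_scores.tsv --n-clusters 11 --out scored/

circtrans simulate circs --seed 1 --out circs/
circtrans orfs call --fasta circs/circs.fa --min-aa 20 --out orfs.tsv
circtrans orfs survey --fasta circs/circs.fa --host-prot circs/host_proteins.fa \
    --known circs/host_proteins.fa --controls reversed,shuffled --seed 17 --out survey.tsv

circtrans pepdb build --circs circs/circs.fa --out db.fa
circtrans pepdb filter --psms psms.tsv --ref uniprot.fa --db db.fa \
    --report report.tsv --out filtered.tsv

circtrans hexstats compare --fasta-a circs.fa --fasta-b mrna.fa --set ires_like.txt --out ks.tsv
circtrans run --config pipeline.yaml --out out/
```

The vector context for `screen score` is configurable via
`--vector vector.yaml` (`upstream_flank`/`downstream_flank`); defaults
carry the reporter's `…AA` / `AT…` extension dinucleotides.

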