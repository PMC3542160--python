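# smallrna

A plant small-RNA analysis toolkit: hairpin-based miRNA discovery,
degradome-supported target validation, 21-nt tasiRNA phasing-register
analysis, and precursor-processing statistics — plus a synthetic-data
generator with planted ground truth so the whole pipeline is testable
without any downloads.

## What it does

* **read_processing** — 3' adapter trimming, 15–31 nt length filtering,
  read collapsing, exact (perfect-match, both strands) genome mapping,
  reads-per-million normalisation against the per-library genome-matched
  total, and redundant/unique length-distribution profiling.
* **known_annotation** — removal of ncRNA look-alikes and assignment of
  tags to known miRNA families by ungapped alignment with at most two
  mismatches (±2 nt offsets allowed); per-family expression tables.
* **hairpin_discovery** — novel/candidate miRNA calling from unassigned
  20–22 nt tags: genomic windows are folded with an exact
  maximum-base-pair folder (A-U/G-C/G-U, minimum loop 3), the
  mature/star duplex must show ≤4 mismatches and ≤1 asymmetric bulge,
  mature+star reads must exceed 75% of the reads at the locus, and >75%
  of locus reads must come from tags unique to the locus family. A
  detected star read (5' end within 1 nt, length within 2 nt of the
  prediction) upgrades a candidate to novel.
* **degradome** — plant-style target scoring (mismatch 1, G:U wobble
  0.5, bulge 2, penalties doubled at miRNA positions 2–13; thresholds
  4.5 for known and 5 for novel/candidate miRNAs), per-transcript
  t-plots in tags-per-billion, and category 0–4 cleavage classification
  at the site opposite miRNA position 10.
* **phasing** — 21 phasing registers anchored at a cleavage site,
  radial-plot-ready profiles, per-tissue accumulation tables, signed
  `locus-siRNA(±offset)` naming, and an optional binomial enrichment
  statistic.
* **processing_stats** — APE = SFI·100/(LFI+SFI) and RTA =
  (LFI+SFI)/CFI from band-intensity TSVs, with a rank-correlation
  uncoupling summary.
* **synthetic_data** — toy genomes with planted miRNA hairpins
  (validated in genomic context so they pass the discovery criteria by
  construction; negative-control mode plants failing ones), TAS-like
  transcripts with phased siRNAs downstream of a trigger-miRNA cleavage
  site, target transcripts with controlled alignment scores, Poisson (or
  negative-binomial) read counts, 24-nt-dominant background, and
  degradome tag pile-ups — all byte-reproducible per seed.

Two bundled TSV catalogs (47 peach-specific miRNAs and their
degradome-validated targets) document the output table schemas and feed
the summary operations.

## Command line

```bash
# simulate a full synthetic dataset + ready-to-run config
smallrna simulate --seed 1 --outdir synthetic

# run everything the config allows
smallrna run-all --config synthetic/config.yaml

# individual stages (same config; unrelated inputs are ignored)
smallrna preprocess    --config synthetic/config.yaml
smallrna discover      --config synthetic/config.yaml
smallrna degradome     --config synthetic/config.yaml
smallrna phasing       --config synthetic/config.yaml

# summaries and blot statistics
smallrna summarize --mirna-table results/mirna_calls.tsv
smallrna ape --intensities bands.tsv --out ape.tsv
```

Outputs are plain text: TSV tables (miRNA catalog, target calls,
register profiles, tissue accumulation, APE/RTA), GFF3 loci, BED hits,
JSON stats/manifest. Reruns with the same seed produce byte-identical
tables.

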