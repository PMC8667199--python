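# trajectome

Analysis toolkit for a two-condition (injury vs sham), two-timepoint
(day 1 / day 14) bulk RNA-seq + promoter H3K4me3 ChIP-seq design:

- **dge** — per-timepoint moderated differential expression on log2 CPM
  (TMM-normalized) with voom-style precision weights, empirical-Bayes
  variance shrinkage and Benjamini–Hochberg correction;
- **trajectory** — eight-way expression-trajectory module assignment
  (persistent / partial-recovery / delayed / full-recovery patterns in
  both directions) with baseline-anchored log2 RPKM profiles and a
  Sankey flow export;
- **go_enrichment** — per-module hypergeometric over-representation
  against any GMT library, with BH-adjusted p and Storey q cutoffs;
- **promoter_chip** — promoter-window coverage from bedGraph pileups,
  signal-per-million depth normalization, within-sample rank comparison,
  signed Poisson log10 likelihood-ratio differential scores, a
  strong-enrichment flag and top-k gene selection;
- **module_integration** — one-way ANOVA of promoter scores across
  trajectory modules vs the non-DE reference, with Tukey–Kramer
  adjusted module-vs-reference contrasts;
- **simulate** — negative-binomial count and Poisson pileup simulators
  with known ground-truth module labels and epigenetic shifts, used as
  the acceptance surface for everything above.

All coordinates are 0-based half-open internally; GTF input is converted
at the reader boundary. All analysis stages are deterministic; all
simulator randomness flows through explicit seeds.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (partition
identity, classifier recovery, DE type-I calibration, exact
hypergeometric/log-LR/ANOVA oracles, rank-invariance under per-sample
scaling, and integration sign recovery). One test is skipped unless the
deposited full DE table is supplied via `TRAJECTOME_SD1=<tsv>`.

## CLI

```sh
trajectome simulate --n-genes 2000 --seed 1 --out-dir sim/
trajectome run-all \
  --counts sim/counts.tsv --samples sim/samples.tsv --genes sim/genes.tsv \
  --gmt library.gmt \
  --bedgraph chip_tbi_day1 sim/chip_tbi_day1.bedgraph \
  --bedgraph chip_sham_day1 sim/chip_sham_day1.bedgraph \
  --chip-samples sim/chip_samples.tsv \
  --out-dir out/
```

Individual stages are also exposed: `trajectome dge | trajectory |
enrich | chip | integrate`. Every output TSV starts with a commented
header recording the package version and stage parameters; reruns on the
same inputs are byte-identical.

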