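# mthet

Mitochondrial heteroplasmy analysis from Sanger-trace peak heights.

`mthet` turns paired-read electropherogram peak heights (or transcribed
percentage tables) into per-site nucleotide proportions and heteroplasmy
calls, summarises haplotypes and variable sites from pre-aligned amplicons,
screens the candidate explanations for double peaks (nuclear pseudogenes,
mitochondrial gene duplication, doubly uniparental inheritance, de novo
mutation, paternal leakage) by explicit elimination rules, and models
mother-to-egg transmission through a germline bottleneck. A full synthetic
simulator generates labelled traces, families, tissue panels and clone sets
under each scenario so the whole pipeline is testable end to end.

## Modules

| module | what it does |
|---|---|
| `mthet.trace_sim` | synthetic traces, families, tissue panels, clone pools per scenario |
| `mthet.peak_calls` | peak-height → proportion conversion, heteroplasmy calling, replicate confirmation, per-family/per-tissue counts |
| `mthet.haplotyping` | variable sites, singleton vs parsimony-informative classes, haplotype enumeration, clone combinations, reading frame and syn/non-syn counts (translation table 5) |
| `mthet.inheritance` | per-hypothesis verdicts (rejected / not_rejected / insufficient_data) with evidence records |
| `mthet.bottleneck` | binomial bottleneck model and moment estimator of the effective size N |
| `mthet.datasets` | packaged fixture tables and ready-made labelled scenario datasets |
| `mthet.cli` | `mthet` command-line interface |

The packaged fixtures under `mthet/fixtures/` transcribe the published
percentage tables (16S family table; COI adult table; COI brood/tissue
table) in a tidy CSV dialect:
`specimen, role, sex, tissue, mother_id, population, position, base1, base2, pct1, pct2`.

## CLI

```sh
mthet reproduce-paper                      # fixture tables end to end, checked counts
mthet simulate --scenario paternal_leakage --seed 1 --out out/sim
mthet call --input src/mthet/fixtures/table4_coi_adults.csv --out out/calls
mthet classify --input 16S=src/mthet/fixtures/table2_16s.csv \
               --input COI=src/mthet/fixtures/table5_coi_families_tissues.csv \
               --out out/verdicts
mthet haplotypes --fasta aln.fasta --coding --out out/haps
mthet bottleneck --input transmission.csv --out out/bn
```

Every subcommand writes a `manifest.json` with the thresholds in force.
Key defaults: minor-fraction call threshold 0.05, baseline criterion
3× baseline level, detection floor 0.05 with dropout margin 0.02, NUMT
signal ratio 1/3.

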