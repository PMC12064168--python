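# trhkit

Tandem-repeat comparative toolkit: catalog ingestion and filtering, native
UCSC chain-file liftover, reciprocal cross-species TR homology with motif
alignment gating, and population-genetic summaries of TR genotype VCFs —
plus a fully deterministic synthetic-fixture generator so the whole pipeline
is testable without any external data.

## Modules

| Module | What it does |
| --- | --- |
| `trhkit.tr_catalog` | Parse TRF `-d`/`-ngs` tables (1-based → 0-based half-open at ingest), merge overlapping records, filter (length ≤ 10 kbp, copy number ≥ 2.5), catalog BED round-trip I/O. |
| `trhkit.chain_lift` | Parse/validate/write UCSC chain files; lift intervals bidirectionally through the best-scoring chain with a `min_match` mapped-fraction policy and per-reason unmapped reporting. |
| `trhkit.homology` | Needleman–Wunsch global motif alignment, percent-identity similarity (plain or rotation/revcomp-insensitive), lifted-vs-catalog overlap intersection, reciprocal reconciliation into a homologous-pair (phTR) table. |
| `trhkit.popgen` | TR genotype VCF parsing (pysam), observed heterozygosity, Nei's unbiased gene diversity, unique-allele counts and allele-length ranges, per-population summaries, genotype matrix, violin plots. |
| `trhkit.synthetic_fixtures` | Seeded paired toy genomes with planted homologous TRs, exact chains in both directions, catalogs, multi-sample genotype VCFs and ground-truth tables. |

## CLI

All functionality is exposed through the `trh` command:

```sh
# generate a self-consistent fixture bundle
trh simulate --seed 7 --preset small -o fixtures/

# build a filtered catalog from TRF output
trh catalog --trf genome.dat --max-len 10000 --min-copies 2.5 -o catalog.bed

# lift a catalog through a chain file
trh lift --catalog A.bed --chain AtoB.chain --min-match 0.95 -o A_on_B.bed

# reciprocal homology at 10% overlap / 95% motif similarity
trh homologs --catalog-a A.bed --catalog-b B.bed \
    --chain-ab AtoB.chain --chain-ba BtoA.chain \
    --min-overlap 0.10 --min-similarity 95 -o phTR.tsv --plot scatter.png

# genotype tables + population statistics from a TR VCF
trh popgen --vcf cohort.vcf --pop-map pops.tsv -o stats/ --plot violin.png
```

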