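# stepcore

Stepwise construction of a representative core collection for a plant
breeding program, fusing incomplete pedigree records with partial SNP
genotyping.

The pipeline:

1. **Curate** SNP dosage data: optional cross-platform merge by
   per-marker concordance (r² ≥ 0.7 by default), missingness (≤ 10%)
   and MAF (≥ 0.05) filters, mean imputation, greedy LD pruning.
2. **Relate**: pedigree additive relationship matrix **A** (tabular
   method) and VanRaden genomic relationship matrix **G**.
3. **Fuse**: rescale G to the pedigree base (Ga = βG + α so diagonal
   and overall means match A22), assemble the hybrid **H** matrix by
   the single-step block formula, convert H to a correlation matrix and
   a scaled distance matrix **D** (zero diagonal, off-diagonal in
   [0, 1]).
4. **Select**: mandatory entries (recent crossing parents used ≥ 4
   times in the last 3 years, trait "must-haves", previously sequenced
   genotypes) plus free slots minimizing the accession-to-nearest-entry
   (A-NE) criterion by seeded swap descent; a multi-run consensus
   (default 3000 iterations) with breeder-preference tie-breaking
   finalizes the core; A-NE-vs-size curves with a random baseline
   support size choice.
5. **Diagnose**: pedigree completeness, overall and per-genotype
   A-vs-G correlations, pair/genotype outlier flags (sample-swap and
   bad-record detection), marker-subsampling reliability analysis, PCA
   of relationship matrices.

A seeded simulator (`stepcore.simulate`) generates breeding-program-like
fixtures — multi-generation pedigrees over weakly connected
sub-populations, gene-dropped genotypes with exact realized IBD,
missing links, sample swaps — so everything is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (analytic kinship
values, H-collapse, optimizer-vs-exhaustive-oracle equivalence, IBD
oracle recovery, scaling/distance properties, subsampling reliability,
link-recovery and swap-recovery scenarios).

## CLI

```sh
# simulate a fixture bundle
stepcore simulate --seed 1 --outdir bundle/ --generations 4 --markers 1000

# individual stages
stepcore curate --dosages bundle/dosages.tsv --out curated.tsv
stepcore amat   --pedigree bundle/pedigree.csv --out A.tsv
stepcore fuse   --pedigree bundle/pedigree.csv --dosages curated.tsv \
                --out H.tsv --dist-out D.tsv
stepcore select --dist D.tsv --size 192 --iterations 3000 --seed 1 \
                --report core.json
stepcore subsample --dosages curated.tsv --out subsample.json

# or everything from one YAML config
stepcore run --config config.yaml --outdir run1/
```

Config keys mirror `stepcore.cli.RunConfig` (paths for pedigree,
dosages, crossings and id lists; all thresholds and seeds; unknown keys
are rejected).

## File formats

- Pedigree: header CSV `id,mother,father[,group]`; unknown parent =
  empty or `0`.
- Dosages: TSV, genotypes as rows, markers as columns, missing = `NA`;
  or biallelic VCF (dosage from GT).
- Relationship matrices: square TSV with ids as first row/column and a
  `# kind:` metadata line.
- Crossings: CSV `mother,father,year`; id lists: one id per line.

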