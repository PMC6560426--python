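# rumenamp

Analysis pipeline for rumen 16S rRNA V1–V3 amplicon studies comparing two
treatment groups. It covers the full chain from raw reads to group
statistics:

* **Read QC** — intact 27F/519R primer check (exact, IUPAC-aware), 400–580 nt
  length window, and a quality rule (≤ 1% of bases below Phred 15); primers
  are trimmed from retained reads.
* **OTU inference** — greedy abundance-sorted centroid clustering at a 5%
  dissimilarity cutoff, using Needleman–Wunsch alignment with free end gaps
  (distance excludes end-gap columns).
* **Artifact screens** — a reference-based split-alignment chimera test,
  a 5′/3′ end-integrity screen (> 5 nt unaligned overhang vs the best
  equal-or-longer hit fails), and a single-read OTU screen (full-span best
  hit with ≤ 1% dissimilarity required).
* **Taxonomy** — naive-Bayes 8-mer classifier with 100-fold bootstrap
  confidence (ranks below 0.8 reported as `unclassified <parent>`), plus a
  separate best-hit identity percentage against the reference set.
* **Diversity & ordination** — rarefaction (default 1800 reads), Chao1
  (bias-corrected), Shannon, Simpson dominance, Good's coverage,
  Bray–Curtis PCoA and CCA against metadata covariates.
* **Statistics** — main-OTU selection (≥ 1% mean relative abundance in
  either group), pooled-variance unpaired t-tests (raw-data and
  mean/SEM/n summary forms), Pearson correlations, fold changes, and
  report tables grouped by phylum/family.
* **Synthetic data** — a ground-truthed study generator (reference DB with
  controlled divergence, log-normal communities, planted enriched taxa,
  quality-linked substitution errors, chimera/end-damage/off-target
  artifact reads) so the whole chain runs offline and is testable.

## CLI

Each stage is a subcommand of `rumenamp`; stages chain through plain-text
files (FASTQ/FASTA/TSV):

```bash
rumenamp simulate --n-taxa 6 --n-per-group 10 --reads-per-sample 2000 --seed 1 --out study
rumenamp qc       --fastq-dir study --out qc
rumenamp cluster  --fastq-dir qc --cutoff 0.05 --out otus
rumenamp screen   --counts otus/otu_counts.tsv --centroids otus/otu_centroids.fasta \
                  --refs study/refs.fasta --tax study/refs.tax --out screened
rumenamp classify --centroids otus/otu_centroids.fasta --refs study/refs.fasta \
                  --tax study/refs.tax --seed 1 --out taxonomy.tsv
rumenamp diversity --counts screened/otu_counts_screened.tsv --depth 1800 --seed 1 --out div
rumenamp ordinate  --counts div/otu_counts_rarefied.tsv --method pcoa --out pcoa
rumenamp ordinate  --counts div/otu_counts_rarefied.tsv --method cca \
                   --env study/metadata.tsv --covariates propionate_mM,butyrate_mM --out cca
rumenamp report    --counts screened/otu_counts_screened.tsv --taxonomy taxonomy.tsv \
                   --metadata study/metadata.tsv --out report
rumenamp ttest-summary --mean-a 43.68 --sem-a 6.92 --n-a 10 \
                       --mean-b 73.22 --sem-b 6.79 --n-b 10
```

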