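# File formats

All formats are plain text, tab-separated unless noted, with 0-based
half-open genomic coordinates. They are designed for small demonstrative
runs; the `replicate` subcommand performs genome-scale analysis in memory.

## Simulation outputs (`domsweep simulate --out DIR`)

- `positions.tsv` — one column `pos`: bp coordinate of each segregating site.
- `haplotypes.tsv` — first line `#L=<int> chrom=<name>`; header of haplotype
  columns `<id>_h0`, `<id>_h1` per individual; one row per segregating site
  with 0/1 alleles (allele 0 is ancestral).
- `labels.tsv` — `id`, `subpop` (OrI/OrII/OrIII/aus/indica/japonica),
  `status` (wild/domesticated).
- `truth_pi_<subpop>.tsv` — true per-site pairwise diversity of each
  20 kbp window, one value per row.
- `readpile.tsv` — first line `#error_rate=<e>`; header `pos` then two
  columns per individual `<id>_ref`, `<id>_alt` (read counts supporting
  allele 0 / allele 1); one row per site, covering every position in [0, L).

## Genotype likelihoods (`domsweep gl`)

`#error_rate=<e>` line, then a header `pos`, `pass`, and three columns per
individual (`<id>_AA`, `<id>_Aa`, `<id>_aa`) holding unnormalized log
genotype likelihoods for 0, 1, 2 copies of allele 1. `pass` is the 0/1
site-filter flag (minInd / setMinDepth / setMaxDepth).

## SAF and SFS (`domsweep sfs`)

- SAF: header `pos`, `L0` … `L2n`; per-site log-likelihoods over derived
  allele counts, normalized to max 0 per row. Only filter-passing sites.
- SFS: a single line of 2n+1 probabilities summing to 1.

## Window tables (`domsweep theta`)

Columns: `chrom`, `start`, `end`, `sum_tP` (summed per-site theta_pi over
sites with data), `n_sites` (sites with data), `tP_per_site`
(`sum_tP / n_sites`), `pass` (True iff `n_sites / span >= 0.25`). The first
three columns are BED-compatible. The last window may be partial and is
judged against its own span.

## Scan outputs (`domsweep scan --out DIR`)

- `ratio_<subpop>.tsv` — `chrom`, `start`, `end`, `pi_w`, `pi_d`, `ratio`,
  `finite`. Only windows passing the data filter in both the wild reference
  (OrII) and the domesticated subpopulation appear. `ratio` is `inf` when
  `pi_d` is 0.
- `threshold.txt` — the common significance threshold: the minimum over the
  three domesticated subpopulations of the 97.5th percentile
  (linear-interpolation) of finite ratios.
- `cldgr.tsv` — windows exceeding the threshold in all three subpopulations,
  with per-subpopulation ratios and (if `--genes` was given) a
  comma-separated `genes` overlap column.
- `cldgr_merged.bed` — book-ended CLDGR windows merged into maximal runs:
  `chrom`, `start`, `end`, `n_windows`.

## Gene annotations

BED3+name: `chrom`, `start`, `end`, `name`; half-open intervals. A gene
overlaps a window iff they share at least one base.

## Trees (`domsweep tree`, `domsweep classify`)

Newick with branch lengths. Leaf names are `<subpop>_<k>`; the
classification commands recover the subpopulation from the name prefix.
Classifications: `domesticate_monophyletic`, `subpop_concordant`, `other`.

## Replication experiment (`domsweep replicate --out DIR`)

- `config.yaml` — the fully resolved run configuration.
- `rep<NNN>/windows_<subpop>_<size>.tsv` — window tables per subpopulation
  and window size.
- `rep<NNN>/cldgr.tsv` — CLDGR calls for the replicate.
- `report.json` — aggregate metrics: `cldgr_sweep_recall`, `cldgr_fraction`,
  `genomewide_class_freq`, `sweep_class_freq`, `flank_class_freq`,
  `concat_flip_fraction`, `concat_flip_k`.

## Run configuration (YAML)

Top-level keys mirror `pipeline.RunConfig`; the `demography` mapping mirrors
`simpop.DemographyConfig` (fields: `n_per_subpop`, `L`, `mu`,
`theta_neutral`, `split_depths`, `bottleneck_factor`, `sweep_interval`,
`post_sweep_time`, `block_length`, `chrom`, `seed`, `progenitors`).
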