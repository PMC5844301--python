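# domsweep

Genotype-likelihood population genomics for testing rice-style domestication
histories on synthetic low-coverage data.

The package re-implements, as a tested pipeline, a probabilistic workflow
for inferring domestication history from low-coverage resequencing-like
evidence:

1. **simpop** — a coalescent simulator for a six-subpopulation history:
   three wild groups (OrI, OrII, OrIII) and three domesticated groups (aus,
   indica, japonica), each domesticate descending from a distinct wild
   progenitor through a bottleneck, plus a single hard-sweep domestication
   haplotype originating on the japonica lineage and introgressed into all
   domesticates. Low-coverage (1–2×) reads with base-call errors are then
   drawn per site and individual.
2. **genolik** — diploid genotype likelihoods from read counts, ANGSD-style
   site filters (minInd / setMinDepth / setMaxDepth with the one-third /
   five-times defaults), a likelihood-ratio SNP test, and genotype
   posteriors.
3. **safsfs** — per-site sample allele frequency likelihoods (dynamic
   program over individuals), EM estimation of the site frequency spectrum,
   and SFS-as-prior allele-frequency posteriors.
4. **thetawin** — per-site Tajima/Watterson theta from the posteriors and
   nonoverlapping window aggregation with the 25% data-fraction filter.
5. **sweepscan** — the pi_w/pi_d scan against the OrII wild reference, the
   common empirical threshold (minimum of the per-subpopulation 97.5th
   percentiles), colocated low-diversity genomic region (CLDGR) calling
   across all three domesticated subpopulations, and BED gene-overlap
   annotation.
6. **treetopo** — pairwise genetic distances from genotype posteriors,
   neighbor-joining trees, rooting on the OrII outgroup, and classification
   of each tree as `domesticate_monophyletic` (single de novo domestication
   with introgression), `subpop_concordant` (each domesticate with its own
   progenitor — the genome-wide pattern), or `other`; plus gene-flank and
   concatenation dilution experiments.
7. **pipeline** — end-to-end replication experiments with seeded,
   bit-reproducible outputs.

## Command line

```sh
domsweep simulate --config cfg.yaml --out simdir      # haplotypes, truth, reads
domsweep gl    --pile simdir/readpile.tsv --out gl.tsv
domsweep sfs   --gl gl.tsv --saf-out x.saf --sfs-out x.sfs
domsweep theta --saf x.saf --sfs x.sfs --length 60000 --out windows.tsv
domsweep scan  --wild w_OrII.tsv --aus w_aus.tsv --indica w_indica.tsv \
               --japonica w_japonica.tsv --genes genes.bed --out scandir
domsweep tree  --pile simdir/readpile.tsv --region 20000:40000 --out t.nwk
domsweep classify --tree t.nwk
domsweep replicate --out rundir --replicates 20 --seed 1
```

File formats are documented in `docs/formats.md`. A YAML configuration can
override any demography or run parameter; see `pipeline.RunConfig` and
`simpop.DemographyConfig`.

## Notes on modeling simplifications

- Recombination is modeled as independent non-recombining blocks (default
  5 kbp), not a full ancestral recombination graph.
- The sweep is a haplotype transplant (one japonica haplotype copied onto
  all domesticated haplotypes over the sweep interval, plus short
  post-sweep mutation), not forward-time selection.
- A single symmetric base-miscall rate stands in for per-read qualities.
- Plain Saitou–Nei neighbor joining is used rather than balanced
  minimum-evolution refinements.
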