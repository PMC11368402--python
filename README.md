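# shelterload

Analysis toolkit for the genetic load sheltered by dominant vs. recessive
alleles at a sporophytic self-incompatibility (SSI) locus. The package
bundles:

- **`ssi_sim`** — forward-time Wright–Fisher simulator of a panmictic
  diploid population under SSI with a pollen dominance hierarchy
  (classes I < II < III < IV, codominance within classes) and a fully
  linked locus accumulating fully recessive deleterious mutations
  (zygote survival `(1 − s)^n`); includes the deterministic S-allele
  frequency equilibrium used for initialisation and per-lineage
  fixed/segregating load summaries.
- **`topo_scan`** — sliding-window comparison of the maximised log
  likelihood of two constrained topologies (haplotypes clustered by
  linked S-allele vs. by population), Felsenstein pruning under JC69/K80
  with per-branch optimisation, and an empirical null band from control
  regions.
- **`trio_phasing`** — resolution of parental S-linked haplotypes from
  parent–offspring trios (no-recombination assumption), with Mendelian-
  error masking and per-trio QC.
- **`load_stats`** — 0-fold/4-fold site degeneracy from FASTA + GFF3,
  variant-site filters (quality ≥ 60, biallelic SNPs, depth bounds from
  control regions, removal of population-fixed sites), per-lineage
  fixed/segregating mutation counts within 25 kb of the S-locus, and
  Poisson-GLM dominance trends.
- **`popgen_fst`** — Hudson-type FST profiles in non-overlapping 5-kb
  windows for both grouping keys, with a genomic-control band.
- **`mendel_pheno`** — Monte-Carlo tests for distorted Mendelian
  segregation of S-locus homozygotes, homozygote-vs-heterozygote
  phenotype contrasts, and covariate screening by permutation.
- **`synthetic_data`** — seed-deterministic generators for every input
  the pipeline consumes (reference + annotation with degeneracy truth,
  labeled haplotypes with lineage structure within `d0` of the S-locus,
  trios with truth phase, family phenotype tables), with machine-readable
  truth tables.
- **`io_cli`** / **`cli`** — VCF/FASTA/GFF3/TSV/newick readers and
  writers (cyvcf2, Biopython, gffutils) and the `shelterload` command
  line interface.

## CLI

```bash
shelterload synth --preset fig45 --seed 3 --out data/        # synthetic inputs
shelterload simulate --config sim.json --seed 1 --out sim/   # SSI simulator
shelterload phase --vcf data/trios.vcf --trios data/trio_manifest.tsv \
    --s-genotypes data/s_genotypes.tsv --out phased/
shelterload scan --haplotypes data/haplotypes.fasta --positions data/positions.tsv \
    --s-locus 50001 55000 --window 50 --step 10 --model jc69 --out scan/
shelterload load-stats --haplotypes data/haplotypes_long.tsv \
    --s-locus 50001 55000 --window 25000 --out load/
shelterload fst --haplotypes data/haplotypes.fasta --positions data/positions.tsv \
    --s-locus 50001 55000 --region 1 105000 --out fst/
shelterload mendel --families data/families.tsv --n-perm 10000 --seed 1 --out mendel/
```

Every run writes a `manifest.json` (command, seed, parameter echo, input
checksums) next to its outputs. Exit codes: 0 ok, 2 input error, 3
precondition violation.

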