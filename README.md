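# qtlatlas

A multi-tissue molecular-QTL toolkit: from count-scale molecular phenotypes
and genotypes to cis/trans/interaction QTL calls, tissue-sharing statistics,
and GWAS integration (enrichment, colocalization, SMR + HEIDI, TWAS, and
cross-species meta-TWAS) — exercised end to end on seeded synthetic data with
planted ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `qtlatlas.simdata` | Seeded generators: AR(1)-LD genotypes with breed structure, log-normal-Poisson expression counts with planted cis effects and hidden confounders, multinomial intron clusters with planted splicing shifts, RSS-model GWAS cohorts, interval annotations/TADs, ortholog TWAS pairs — plus a `SimTruth` ledger of every planted effect. |
| `qtlatlas.phenoprep` | TPM, expression filters, TMM normalization, rank-based inverse normal transform, PSI computation with the three splicing filters, SVD hidden-factor estimation, genotype PCs, TAU tissue specificity. |
| `qtlatlas.cis_qtl` | Nominal cis scan (±1 Mb, MAF ≥ 5%, MAC ≥ 6), adaptive permutation pass with Beta-approximated empirical p, two-layer FDR with per-feature nominal thresholds, grouped (splicing) mode, forward-backward conditional signals, log2 aFC, trans scan, single-causal ABF fine-mapping. |
| `qtlatlas.interaction_qtl` | Genotype × continuous-context interaction scan and stratified effect summaries. |
| `qtlatlas.multi_tissue` | Fixed-effect meta-analysis, m-values (exact enumeration / importance sampling), pairwise effect correlations, Storey's π1, k-means clustering similarity (Rand index). |
| `qtlatlas.gwas_integration` | Sample-size-weighted meta-GWAS, locus clumping, λ-scaled overlap enrichment, MAF-matched backgrounds, five-hypothesis ABF colocalization (RCP), SMR + HEIDI, nested-CV elastic-net TWAS models, summary and multi-tissue TWAS, annotation/TAD enrichment, tissue-relevance scores. |
| `qtlatlas.cross_species` | Ortholog |effect| correlation with a permutation null, case-control effective n, cross-species meta-TWAS, gain/loss analysis. |
| `qtlatlas.pipeline` | `run_end_to_end(seed)`: the whole chain on a 200-sample toy genome. |

## CLI

Console scripts mirror the pipeline stages (all inputs/outputs are plain
text: VCF, BED-like TSV matrices, TSV tables):

```bash
simdata genotypes --config cfg.json --seed 1 --out sim/
simdata phenotypes --config cfg.json --seed 1 --out sim/
phenoprep expression --counts sim/counts.bed --out prep/
phenoprep covariates --expression prep/expression.bed --genotypes sim/genotypes.vcf --out prep/
cisqtl nominal --vcf sim/genotypes.vcf --bed prep/expression.bed --out nominal.tsv
cisqtl permute --vcf sim/genotypes.vcf --bed prep/expression.bed --seed 1 --out perm.tsv
cisqtl call --records perm.tsv --nominal nominal.tsv --out calls.tsv
ieqtl scan --vcf ... --bed ... --context context.tsv --out out/
multitissue mvalue --input meta_input.tsv --out mvalues.tsv
integrate loci --gwas gwas.tsv --out loci.tsv
xspecies correlate --twas-a a.tsv --twas-b b.tsv --orthologs map.tsv
```

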