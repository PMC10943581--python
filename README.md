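# ratioqtl

Ratio-QTL analysis for affinity proteomics GWAS: select protein pairs by
shrinkage partial correlation (Gaussian graphical model edges), test
genetic association of log-ratio phenotypes, and quantify the improvement
over the single-protein tests with the p-gain statistic — plus a
synthetic-cohort generator so the whole pipeline runs and is validated
without any cohort download.

## What is in here

| module | purpose |
| --- | --- |
| `ratioqtl.simulate` | synthetic cohorts from the additive log-linear model `log(P_i) = alpha_i + beta_i*SNP + gamma_i*W + eps_i`, with scenario presets (`opposite_beta`, `single_beta_shared_W`, `shared_beta_shared_W`, `null`) |
| `ratioqtl.preprocess` | missingness filters (samples first, then proteins), minimum imputation, Blom inverse-normal transform, log-ratio phenotypes |
| `ratioqtl.ggm` | Schafer-Strimmer shrinkage partial correlations, Fisher-z p-values, Bonferroni-significant edge calling |
| `ratioqtl.assoc` | variant QC (mind/geno/maf/mac/HWE), exact Hardy-Weinberg test, covariate-adjusted OLS association, and a log-space t-tail accurate for `-log10 p` in the thousands |
| `ratioqtl.pgain` | `log10_pgain`, Bonferroni critical values (p-gain 10 per test), Monte-Carlo null calibration |
| `ratioqtl.pipeline` | candidate selection (edges x known pQTLs), targeted discovery/replication scan, ratio GWAS with 1 Mb signal pruning, cis/trans and novelty annotation, all-ratios-at-one-variant mode |
| `ratioqtl.enrichment` | resampling fold-enrichment against an interaction reference, Fisher's exact test |
| `ratioqtl.io` / `ratioqtl.cli` | TSV / PLINK-`.raw` readers and writers, YAML config, `ratioqtl` command line |

All p-values and p-gains live on the `-log10` scale end to end; raw
p-values are never materialized, so associations with `-log10 p > 3000`
round-trip exactly.

## Command line

```sh
ratioqtl simulate --scenario opposite_beta --n-samples 6000 \
    --n-discovery 5000 --seed 1 --out sim/

ratioqtl ggm --npx sim/proteins.tsv --alpha 0.05 --out edges.tsv

ratioqtl scan --proteins sim/proteins.tsv --genotypes sim/genotypes.raw \
    --covariates sim/covariates.tsv --cohorts sim/cohorts.tsv \
    --edges edges.tsv --pqtls pqtls.tsv --variants sim/variants.tsv \
    --out rqtls.tsv

ratioqtl gwas --proteins sim/proteins.tsv --genotypes sim/genotypes.raw \
    --covariates sim/covariates.tsv --cohorts sim/cohorts.tsv \
    --ratios ratios.tsv --variants sim/variants.tsv --out gwas.tsv

ratioqtl calibrate-pgain --rho 0.3 --n 1000 --reps 10000 --seed 1
ratioqtl enrich --pairs pairs.tsv --reference string.tsv --score-min 0.7 \
    --n 100 --seed 1 --out enrich.json
```

Every subcommand writes a JSON run log (`<out>.log.json`) with the
thresholds, per-stage counts and the seed.

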