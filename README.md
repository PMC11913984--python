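# rapidgs

A desk-scale, fully synthetic re-implementation of a rapid-cycling genomic
selection experiment in a heterozygous, panmictic (landrace-type)
population: simulate founders, train a multi-trait GBLUP model, run three
cycles of selection and recombination in two replications, extract
doubled-haploid (DH) populations per cycle, and reproduce the analysis
layer (adjusted entry means, heterogeneous variance components, selection
response regressions, prediction accuracies, bootstrap comparisons).

## Layout

| module | what it does |
| --- | --- |
| `rapidgs.genmap` | genetic maps (cM positions on chromosomes) |
| `rapidgs.landrace` | founder simulation under linkage equilibrium, polygenic correlated trait architectures, plot-level multi-environment phenotypes |
| `rapidgs.breeding` | meiosis (Haldane), crossing, selfing, diallel mating, DH induction, pedigrees |
| `rapidgs.relatedness` | VanRaden method-1 GRM with explicit reference frequencies, modified Rogers' distance, PCoA, marker-based pedigree validation |
| `rapidgs.gblup` | single-trait REML GBLUP (spectral profile likelihood) and multi-trait EM-REML; prediction of unphenotyped candidates via cross-GRM, with an independent joint-MME route |
| `rapidgs.selection` | the multi-trait selection criterion (directional early-height + stabilizing final-height), truncation selection with founder contribution caps, MRD-maximizing mate pairing, and the full scheme orchestrator |
| `rapidgs.mixedmodel` | average-information REML engine with per-term variances (heterogeneous variance groups) |
| `rapidgs.trial` | plant-stand filter, iterative Grubbs outlier test, adjusted entry means / variance components, entry-mean heritability with CI, population comparisons, variance-heterogeneity LRT |
| `rapidgs.response` | selection-response regressions (per-replication slopes + common-slope LRT), C0-anchored standardization, prediction ability/accuracy, check-adjusted retraining, bootstrap ability comparisons, trait correlations, report tables |
| `rapidgs.io`, `rapidgs.config`, `rapidgs.cli` | VCF/TSV/CSV formats, YAML configs, run logging, command line |

## CLI

```bash
rapidgs simulate --n 200 --outdir out/sim              # founders + trial phenotypes
rapidgs run-scheme --seed 1 --outdir out/run           # full-size scheme
rapidgs run-scheme --scaled --seed 1 --outdir out/run  # desk-scale scheme
rapidgs select --gebvs gebvs.csv --n-select 20 --out ranked.csv
rapidgs response --gebvs out/run/gebvs.csv --trait PH_V4
rapidgs accuracy --gebvs g.csv --means m.csv --trait PH_V4 --h2 0.64
```

`run-scheme` writes GEBV/TBV tables, population means, per-cycle slopes,
the pedigree, the config, and a JSON run log (config hash + per-stage
sub-seeds); reruns with the same config and seed are bit-identical.

## Notes

- Genotypes are 0/1/2 alternate-allele counts; DH lines take only 0/2.
- Reference allele frequencies are an explicit argument to every GRM
  operation because they set the GEBV location (the base population is
  anchored at mean GEBV 0).
- Founders are simulated under linkage equilibrium; LD emerges downstream
  from selection and mating, which drives the accuracy-decline mechanism
  the test suite checks.
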