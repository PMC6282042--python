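# lvscan

Latent-variable construction for correlated phenotypes, single-step GBLUP
whole-genome window scans, and causal classification of genomic regions.

The pipeline mirrors a two-stage analysis used in beef-cattle genetics:

1. **Structural equation model (SEM).** Six fixed-effect-adjusted indicator
   traits (quality grade, fat over ribeye, marbling; juiciness, tenderness,
   connective tissue) measure two latent variables — *carcass quality* and
   *meat quality* — linked by a causal path (carcass → meat). The model is
   fitted by maximum likelihood with robust (sandwich) standard errors,
   assessed with GFI / AGFI / RMR / CFI / RMSEA and a Bollen–Stine
   bootstrap, and per-animal factor scores are extracted.
2. **Whole-genome scan.** Factor scores are analysed with a single-step
   GBLUP animal model (pedigree **A**, genomic **G**, combined **H**
   relationship matrices; EM-REML variance components; back-solved SNP
   effects). Additive variance is partitioned into non-overlapping 20-SNP
   windows for three scans — carcass, meat, and meat conditioned on the
   carcass score — and every window is classified as `direct_A_only`,
   `direct_B_only`, `direct_both` (pleiotropic), `indirect_via_A`, or
   `not_associated`.

A first-class synthetic-data module (`lvscan.synthetic`) generates
pedigrees, gene-dropped genotypes, planted QTL of each effect class, and
factor-structured phenotypes with configurable heritabilities, genetic
correlation and causal-path strength, so the whole pipeline is testable
without external data.

## Command line

```bash
# full pipeline from a YAML config (simulation block or input paths)
lvscan all --config config.yaml

# write a synthetic dataset (pedigree, genotypes, phenotypes, truth tables)
lvscan simulate --seed 1 --out data/sim --animals 800 --snps 1000

# fit the structural model to a phenotype table
lvscan sem --phenotypes data/sim/phenotypes.tsv
```

Minimal config:

```yaml
outdir: runs/demo
seed: 1
simulate:
  n_founders: 200
  n_generations: 3
  n_sires: 40
  n_animals_target: 1000
  n_snps: 2000
  qtl_plan: [[3, direct_A, 0.3], [13, direct_B, 0.35],
             [23, pleiotropic, 0.35], [33, indirect, 0.7]]
  rg_target: null
classifier: {assoc_threshold: 1.5, strong_threshold: 3.0}
```

The run directory receives adjusted phenotypes, SEM estimates and report,
factor scores, QC report, per-window variance table, per-window effect
classes, per-class BED files and a `summary.json` with the config digest
and seed needed to reproduce the run.

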