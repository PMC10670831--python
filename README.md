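# gutstress

Compositional microbiome analysis of a porcine social-stress cohort, packaged
as a tested, reusable pipeline. It covers:

- **Synthetic cohort generation** (`gutstress.synthetic_cohort`) — 38 animals
  from 9 litters in balanced stress/control groups, three gut sites
  (caecum/colon/feces), log-normal + multinomial genus counts with a dominant
  Prevotella-like genus, ~57% zeros, planted stress-enriched/depleted genera
  and a small "susceptible" subpopulation for four pathogen genera. Ground
  truth is written beside the data so every downstream stage has a
  parameter-recovery test.
- **Table I/O** (`gutstress.tables_io`) — TSV/CSV genus count tables (plus a
  BIOM-TSV dialect), sample metadata validation and joins.
- **Preprocessing** (`gutstress.preprocess`) — per-group prevalence-threshold
  search scored by random-forest out-of-bag error, mean-relative-abundance
  filter (strictly < 0.001 removed), Monte-Carlo Dirichlet zero replacement
  and centred-log-ratio (clr) transformation (K instances + mean instance).
- **Diversity** (`gutstress.diversity`) — richness and adjusted Shannon
  (evenness) with a REML mixed-model treatment contrast (litter random
  intercept), Bray-Curtis dissimilarity, within-group dissimilarity, and a
  sequential (litter-first) PERMANOVA with free label permutation.
- **Biomarker discovery** (`gutstress.plsda_biomarkers`) — NIPALS PLS1
  discriminant analysis, leave-one-out component selection, VIP scores,
  recursive VIP < 0.8 elimination with a discrimination-loss stopping rule,
  and Welch t-tests averaged over the clr instances with BH adjustment and
  pooled-SD effect sizes.
- **Pathogen resistance** (`gutstress.pathogen_resistance`) — the 2.5x
  within-group-median susceptibility classifier and a conjugate Gibbs sampler
  for a Bayesian linear mixed model reporting Pr0 (posterior probability an
  effect is positive).
- **Phenotypes** (`gutstress.phenotypes`) — trapezoidal cortisol AUC over the
  07:00-16:00 profile, ADG/DFI/FCR (pen feed totals apportioned by metabolic
  weight + gain), lesion totals, and a Table-1-style control-minus-stress
  contrast report.

## CLI

```bash
gutstress simulate --seed 1 --out scratch/demo            # synthetic cohort (+ truth.json)
gutstress preprocess --data scratch/demo --site all       # filters + clr ensemble
gutstress diversity  --data scratch/demo --perms 999      # alpha/beta report
gutstress biomarkers --data scratch/demo --site feces     # PLSDA-VIP + Welch report
gutstress resistance --data scratch/demo --factor 2.5     # susceptibility + Pr0
gutstress phenotypes --data scratch/demo                  # Table-1-style contrasts
gutstress all --seed 1 --out scratch/demo                 # everything end to end
```

Every subcommand takes `--seed`; `--config YAML` at the root supplies option
defaults, and `--log-level` controls logging.

## Layout

```
src/gutstress/        package modules (one per pipeline stage)
tests/                pytest suite incl. acceptance criteria
scripts/acceptance.py acceptance report generator
```
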