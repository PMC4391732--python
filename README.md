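# coalbench

**Does modeling incomplete lineage sorting actually buy you a better species
tree?** `coalbench` is a self-contained simulation benchmark that pits the
traditional supermatrix approach — Bayesian inference on concatenated
alignments — against two coalescent-aware species-tree estimators, a
GLASS/STEM-style clustering estimator and minimize-deep-coalescences (MDC),
under conditions where the only source of gene-tree/species-tree discord is
the multispecies coalescent.

It is written for molecular phylogeneticists who want a transparent,
reproducible testbed: every stage — species-tree simulation, coalescent
gene trees, sequence evolution, tree estimation, scoring — is implemented
as a tested library function, and the whole factorial experiment runs from
one config.

## The models

**Simulation.** Species trees arise under a uniform-speciation (Yule)
process conditioned on *n* = 8 tips and rescaled to total depths of 1N and
10N generations (1 coalescent unit = N). Within each species tree, gene
trees follow the neutral multispecies coalescent: *k* lineages in a branch
coalesce at rate C(*k*, 2) per unit, survivors passing to the parent
branch; a single allele per species. Sequences (1000 bp per locus) evolve
along each gene tree under HKY with ts/tv ratio 3.0 (κ derived from the
stationary frequencies), continuous Γ(α = 0.8) rate heterogeneity, base
frequencies π = (A 0.3, C 0.2, G 0.2, T 0.3), and a strict clock.

**Estimation.** The 540 loci per species tree are partitioned into
consecutive matrices of 3, 9 and 27 loci (180 / 60 / 20 matrices). Each
matrix is analyzed three ways:

- *concatenation* — Metropolis–Hastings MCMC over clock trees under
  HKY+Γ₄ (two independent runs, stopped when the average standard
  deviation of split frequencies drops below 0.01; 25% burn-in; thinned
  sample), summarized as the majority-rule-plus-all-compatible-splits
  consensus;
- *stem* — single-linkage clustering on D(i,j) = minimum over loci of the
  estimated coalescence time of species *i* and *j* (the GLASS tree, which
  is also the STEM ML topology for one allele per species and equal
  population sizes), from clock ML gene trees;
- *mdc* — the rooted topology minimizing the total number of extra
  lineages implied by the estimated gene trees, found *exactly* by a
  dynamic program over taxon subsets (135,135 topologies at 8 taxa).

**Scoring.** Accuracy is the Robinson–Foulds distance between the unrooted
estimate and the true species tree: |B₁ \ B₂| + |B₂ \ B₁| over non-trivial
bipartitions (max 10 at 8 taxa). Discord is averaged per species tree,
then across species trees, and one-way ANOVAs on the per-species-tree
means compare methods at fixed design cells and locus counts within
methods (α = 0.05).

## Worked example

Nine loci from one deep (10N) species tree, species trees estimated from
clock ML gene trees:

```python
import numpy as np
from coalbench import (simulate_species_tree, MSCSimulator, simulate_alignment,
                       estimate_gene_tree_ml, glass_species_tree, mdc_species_tree,
                       robinson_foulds, STUDY_MODEL)

rng = np.random.default_rng(42)
species = simulate_species_tree(n_taxa=8, depth=10.0, rng=rng)
sim = MSCSimulator(species)
gene_trees = [sim.simulate(rng) for _ in range(9)]
alignments = [simulate_alignment(gt, 1000, STUDY_MODEL, rng) for gt in gene_trees]
estimated = [estimate_gene_tree_ml(a, STUDY_MODEL) for a in alignments]
```

Rescaling the estimated branch lengths to coalescent units (divide by the
0.05 substitutions/site/unit simulation scale) and estimating:

```
GLASS/STEM  RF to truth: 0
MDC         RF to truth: 0 (deep-coalescence score 5)
```

Both coalescent methods recover the true topology exactly (RF = 0) — at
10N the minimum coalescence times hug the speciation times and deep
coalescences are rare; MDC's score of 5 says the nine genealogies imply
only five extra lineages in total.

## The experiment

```bash
python analysis/01_design_counts.py      # 180/60/20 matrices, 9000/3000/1000 analyses
python analysis/02_simulator_checks.py   # simulator vs closed-form coalescent theory
python analysis/03_run_benchmark.py      # desk-scale factorial benchmark (~10 min)
python analysis/04_plot_discord.py       # mean +/- SD discord figure
```

`03_run_benchmark.py` runs the design at desk scale (6 species trees, 27
loci per tree-depth, full 1000-bp loci, capped MCMC) and prints the
two-stage mean discord table and ANOVA report. Typical findings, matching
the full-scale study: mean RF falls from 3 → 27 loci and from 1N → 10N for
*every* method (e.g. concatenation 5.7 → 4.3 at 1N), and at 10N the three
methods are statistically indistinguishable (across-method ANOVA p ≈
0.84–0.97), while at 1N/3-loci the methods differ significantly.

A `coalbench` CLI exposes each stage individually (`coalbench
simulate-species-trees`, `simulate-gene-trees`, `simulate-seqs`,
`infer-genetrees`, `infer-concat`, `infer-stem`, `infer-mdc`, `run-all
--config experiment.yaml`); see `coalbench --help`.

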