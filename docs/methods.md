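# Methods

This note documents the models, the estimation machinery, the defaults and
the numerical choices behind `coalbench`, and what the desk-scale runs do
and do not demonstrate.

## Simulation model

**Species trees.** Uniform speciation is implemented as a forward Yule
process: every extant lineage splits at rate 1, the splitting lineage
chosen uniformly; the process stops at the target tip count, runs one
further exponential waiting time to place the present, and node times are
rescaled linearly so the root-to-tip height equals the requested depth
exactly. The topology distribution is the Yule/ERM distribution (verified
against brute-force enumeration of growth histories); the rescaling makes
the depth a design parameter rather than a random outcome, which is what
the 1N-vs-10N contrast needs. One base topology per replicate is rescaled
to *both* depths, so the depth contrast is paired.

**Coalescent.** Gene trees follow the neutral multispecies coalescent with
one allele per species, constant population size on every branch including
the root stem, and no migration. Time is in coalescent units with 1 unit =
N generations and pairwise coalescence rate 1 per unit. The benchmark's
depth labels "1N" and "10N" map to 1.0 and 10.0 units
(`coalescent_unit_in_N` rescales this if a different convention is
wanted); what drives all qualitative results is the 1:10 ratio, not the
absolute constant. The simulator is validated against two closed forms:
the 3-taxon concordance probability 1 − (2/3)e^(−t) on a grid of internal
branch lengths, and the mean pairwise coalescence time τ + 1 for two
species diverged τ units ago.

**Sequences.** HKY with the rate matrix normalized to one expected
substitution per site per unit branch length. The transition/transversion
*ratio* R = 3.0 is converted to the rate-matrix κ via
κ = R (π_A+π_G)(π_C+π_T) / (π_Aπ_G + π_Cπ_T) (κ = 6.25 at the study
frequencies); the conversion is unit-tested by summing stationary fluxes
over the 12 substitution types. Transition probabilities come from the
closed-form HKY spectral decomposition (checked against a numerical matrix
exponential to 1e-13). Site rates are continuous Gamma(α = 0.8, mean 1)
draws, i.i.d. across sites and shared across branches (strict clock).

**Substitution scale.** The mapping from coalescent branch lengths to
substitutions per site is not part of the coalescent model and must be
chosen; the default `subst_scale = 0.05` substitutions/site per coalescent
unit makes 1N trees low-signal (total height 0.05 subs/site) and 10N trees
informative (0.5 subs/site). Absolute discord levels depend on this knob;
the locus-number and depth *trends* and the method *comparisons* do not,
which is why the benchmark's claims are stated as trends.

## Inference machinery

**Likelihood.** Felsenstein pruning over unique site patterns under HKY
with k = 4 discrete gamma categories (mean-per-category discretization).
Using discrete gamma for inference against continuous-gamma simulation is
deliberate and mirrors standard practice. The implementation is tested
against exhaustive summation over ancestral states (1e-10) and the pulley
principle (re-rooting invariance, 1e-9).

**Clock ML gene trees.** UPGMA on Jukes–Cantor-corrected distances gives a
rooted, ultrametric start (saturated distances capped at 3 subs/site);
node heights are then optimized by L-BFGS-B on a log-root-height plus
per-node logit-fraction parameterization, which enforces validity by
construction; rooted NNI hill climbing with re-optimization follows,
scanning candidates in fixed order and accepting only strict improvements
(deterministic). Constant alignments return the distance tie-break
resolution flagged `low_signal`. The search is verified against exhaustive
optimization of all 105 rooted 5-taxon topologies; the 8-taxon space
(135,135 topologies) is checked by strong-signal recovery instead, since
exhaustively optimizing it is not informative enough to justify its cost.

**Bayesian concatenation.** A from-scratch Metropolis–Hastings sampler
over (clock topology, node heights, κ, π, α): proposal mix NNI (weight 3),
node-height slide (3), root-height multiplier (1), Dirichlet proposal on π
(1), multipliers on κ and α (1 each). Metropolis-coupled heating is
omitted — eight-taxon clock space is small enough that plain MH mixes —
and that is the one deliberate simplification relative to full production
samplers.
Priors: uniform on labeled topologies; exponential on the root height with
mean set from the starting tree; node heights uniform given the root;
Dirichlet(1,1,1,1) on π; broad lognormals (σ = 2) on κ and α. The second
run starts from a randomly NNI-shuffled tree so the split-frequency
diagnostic compares genuinely independent runs. Convergence: every 1,000
generations (500 in scaled runs) the average standard deviation of split
frequencies (ASDSF) across runs is computed over splits reaching frequency
0.1 in at least one run; sampling stops below 0.01 (after a minimum), and
hitting the generation cap returns the sample flagged `converged=False`,
never silently. Draws are thinned, the first 25% of each run discarded,
and the pooled sample summarized as the majority-rule consensus with all
compatible splits greedily added in decreasing frequency order (ties
broken lexicographically on the smaller split side).

**GLASS/STEM.** D(i,j) = minimum over loci of the coalescence time of i
and j; single-linkage clustering of D is the species-tree estimate, with
join heights equal to the minima (taxa sorted before clustering for
deterministic ties). For one allele per species and equal population
sizes the GLASS topology coincides with STEM's ML topology, so this
estimator stands in for both; STEM's branch-length ML and population-size
machinery are out of scope. Estimated gene trees are rescaled from
substitutions/site to coalescent units by dividing by `subst_scale` — a
necessary assumption, since rates are not re-estimated per locus.

**MDC.** A gene tree leaves, in the species-tree branch above cluster A,
one lineage per *maximal* gene-tree clade contained in A; the
deep-coalescence score sums (lineages − 1) over internal non-root
branches and gene trees. Because the per-branch cost depends only on the
cluster, the minimum over all rooted binary topologies is found exactly by
dynamic programming over taxon subsets — equivalent to exhaustive
enumeration but O(3^n) instead of O((2n−3)!!·n) — with the optimum count
tracked and ties broken by lexicographic Newick order. Verified against
full enumeration at 5 taxa and an independent lineage-climbing embedding
oracle. Exhaustive scoring is limited to ≤ 10 species by design.

## Scoring and statistics

Robinson–Foulds distances are computed on unrooted trees (consensus root
placement is irrelevant), raw and unnormalized; polytomies contribute
fewer bipartitions. Mean discord is two-stage — average RF within each
species tree, then across species trees — and the ANOVAs treat the
species tree as the experimental unit (n = number of species trees per
group). The per-matrix alternative would pseudo-replicate: matrices from
one species tree share its topology. Raw p-values are reported with
significance at 0.05 and no multiple-testing correction, matching the
benchmark's reporting convention; a Bonferroni flag is available.
Zero within-group variance is reported with a degeneracy flag (p = 1 for
equal means, p = 0 otherwise) rather than an error.

## Design, seeding, scale

The full design is 50 species trees × 2 depths × 540 loci, partitioned
into consecutive blocks of 3/9/27 (block membership is
simulation-order-consecutive; loci are exchangeable, so any deterministic
assignment is equivalent). A single iteration of the simulation is run by
default (`n_iterations` exposes replication). All randomness derives from
one root seed through per-(iteration, species tree, depth, locus, stage)
spawn keys, so stages can be re-run independently and identical configs
give byte-identical tables; per-cell results are cached under the output
directory keyed by a config hash, making runs resumable.

The shipped analysis scripts and the acceptance run use a desk-scale
design chosen to finish in minutes on one CPU while keeping the per-locus
data exactly at study scale: 5–6 species trees, 27 loci of the full
1000 bp per tree-depth (blocks of 3/9/27 → 9/3/1 matrices), and MCMC
bounds of 1,000–4,000 generations with diagnostics every 500 and thinning
10. At these sizes many low-signal (1N) cells hit the generation cap
before ASDSF < 0.01; they are flagged, retained, and contribute honestly
to the discord means, as their full-scale counterparts would after longer
runs. The desk-scale runs reproduce the qualitative results — accuracy
rises with locus number and depth for every method; the three methods are
statistically indistinguishable at 10N; methods separate at 1N with few
loci — but not absolute full-scale quantities: with 5–6 species trees the
ANOVA has low power, so "p > 0.05 at 10N" is reproduced under conditions
friendlier to it than the 50-tree original.

## Numerical notes

- Height parameterizations clamp exponent arguments (|x| ≤ 50) against
  optimizer line-search overshoot; non-finite likelihoods are mapped to a
  large penalty inside the optimizer and to rejection inside the MCMC.
- UPGMA/linkage heights are nudged strictly increasing along root paths so
  tied or zero merges still yield valid clock trees.
- Distance saturation (p ≥ 0.75) is capped at 3 subs/site before
  clustering.
- A note on rate heterogeneity and distance variance: integrating out an
  i.i.d. per-site rate leaves each site marginally Bernoulli, so the
  replicate variance of an observed pairwise distance is p̄(1−p̄)/L at any
  gamma shape; heterogeneity shows up as a *depression of the mean*
  distance (Jensen), not as inflated variance. The test suite asserts this
  correct signature.

## What the synthetic data does not capture

Real multilocus data add alignment error, indels, model misspecification,
among-branch rate variation, recombination within loci, linkage between
loci, gene flow and paralogy. None are simulated here — the generator
isolates coalescent and mutational variance by design — so passing tests
say nothing about method ranking under those violations. Multiple alleles
per species are accepted by the simulator but unused in the benchmark
design; clade-support comparisons are out of scope.
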