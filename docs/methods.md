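# Methods

This note records the models the package implements, the assumptions
behind them, and the numerical and design choices made where several
reasonable options existed.

## Genomes, maps, and map functions

Genomes are dense three-dimensional arrays (individual × marker ×
chromosome phase) with biallelic coding {0, 1}; dosage is the phase sum.
Markers are stored sorted by (chromosome, physical position), with
chromosome order fixed by first appearance. Physical positions are
1-based (VCF convention); genetic positions are always Morgans
internally, with unit conversion confined to the I/O boundary.

Genetic maps are per-chromosome linear splines from base pairs to
Morgans. Queries beyond the terminal knots are **clamped** to the
terminal genetic position: extrapolation cannot produce negative or
runaway distances, and marker order is preserved.

Two map functions convert genetic distance d (Morgans) to recombination
fraction r:

- Haldane (no interference): r = (1 − e^(−2d)) / 2
- Kosambi (interference-corrected): r = tanh(2d) / 2

Both are strictly increasing with range [0, 0.5); Kosambi ≥ Haldane
pointwise. The inverses are closed-form and round-trip to < 1e−10.

### Identity-by-state kinship

No single IBS convention is universal; the package uses

K_ij = 1 − (1 / (ploidy · p)) Σ_k |g_ik − g_jk|

on dosage coding. This yields a symmetric matrix in [0, 1] with unit
diagonal that is monotone in allele sharing, and it is simple to verify
against a hand computation. Note the alternative allele-matching
convention (het–het pairs scoring 0.5) gives different absolute values;
only relative comparisons within one convention are meaningful. For
diploids the O(n²p) pairwise sum is reduced to three matrix products via
|Δ| = Δ² − 2·[|Δ| = 2].

## Recombination and mating

Crossover probabilities between successive markers are pre-computed into
a per-marker vector `pxo` with the chosen map function. The first marker
of each chromosome receives probability 0.5: a single uniform draw per
marker then both randomizes each chromosome's starting phase and
enforces independent assortment between chromosomes — no separate
phase-initialization step is needed. A gamete is sampled by flipping the
copied phase wherever u_i < pxo_i; crossovers are marker-interval
events, so events distal to the terminal markers are irrelevant.

Mating protocols: self, two-way, three-way (gamete of the A×B F1 ×
gamete of C), four-way (gametes of two F1s), and doubled-haploid
variants that duplicate one gamete of the terminal hybrid into both
phases. Random intermating samples distinct unordered parent pairs
uniformly (a parent may appear in several pairs) and tags progeny with
their cross index as a family label. All stochastic operations consume a
single caller-supplied `numpy.random.Generator`, so any run is
reproducible bit-for-bit from its seed.

Not modelled: crossover interference beyond the map function, obligate
chiasma, mutation, genotyping error.

## Genomic models

The linear genomic model is Y = XB + ZU with X fixed to a column of
ones (one intercept per trait). The additive design is the 0/1/2 dosage
of allele code 1 (the counted allele is a convention and is used
consistently everywhere). With dominance, a binary heterozygote
indicator (1 iff dosage = 1) multiplies per-marker dominance effects.
Breeding values are the additive-only evaluation; dominance contributes
to genotypic value but not to breeding value. Model fitting is out of
scope — trained effects are inputs, serialized as CSV pairs
(effects + intercepts) or HDF5.

Simulated traits draw each marker's effect row i.i.d. from MVN(0, Σ).
The default two-trait configuration uses Σ = [[1, −0.4], [−0.4, 1]]
(competing traits) with intercepts 10 and 25.

## Phenotypes and heritability

Phenotypes follow y_ijk = g_ik + l_jk + ε_ijk with ε_ijk ~ N(0, σ²_ε,k)
i.i.d. and location means zero by default (no genotype-by-environment
interaction). The error variance is backsolved once from the base
population's genetic variance to hit a target single-location
narrow-sense heritability:

σ²_ε = σ²_g (1 − h²) / h².

Two choices matter here: the genetic variance estimator is the sample
variance (denominator n − 1) of true breeding values in the base
population, and h² is defined at the plot level (single location), not
on entry means. The error variance is then held constant for the rest
of the simulation, so realized heritability erodes as selection removes
genetic variance — a deliberate property, not drift. Estimated breeding
values are entry means across locations, which converge to the
genotypic value as locations increase (MSE ∝ 1/L).

## Selection problems and protocols

A selection problem couples a subset decision space (J distinct indices
out of n; the cardinality constraint holds by construction of the
encoding), a latent function L, and transforms T_obj / T_ineq / T_eq
that re-partition L(x) into minimized objectives and constraints.

Subset OCS uses latent [mean BV per trait, mean kinship
(1/J²)·x'Kx]; the default objective transform negates the BV components.
The kinship scale is read as 1/J² (mean pairwise kinship including
self-pairs); a 1/(2J²) reading differs only by a constant factor and
cannot change the Pareto set.

Other protocols: truncation on trait-sum scores (stable ties by
ascending index); within-family selection keeping round-half-up
(proportion × family size) members per family — so 5% of a family of 80
keeps exactly 4; weighted genomic selection dividing each effect by
√(favorable-allele frequency) with the frequency clamped below at
1/(2n) (the favorable allele is allele 1 when the effect is ≥ 0, else
allele 0); optimal haploid value (2 × sum over blocks of the better
phase's block value, blocks cut contiguously per chromosome); and
uniform random selection.

### Pseudoweight frontier pick

Given a nondominated front, each objective column is oriented so larger
is better, min-max scaled to [0, 1] (a constant column scales to 0 —
it then contributes equally to every distance), and the point with the
smallest Euclidean distance to the preference vector is chosen, ties to
the lowest index. Orienting *before* scaling (so 1 = most preferred) is
a choice; the alternative orientation would invert the meaning of the
preference weights. The rule is invariant to positive affine rescaling
of any objective.

## Optimizers

All optimizers work on the subset encoding with feasibility-preserving
variation: exchange crossover (non-shared members of the two parents
are shuffled and swapped with probability ½ each) and replacement
mutation (each member replaced with probability 1/J by a uniformly
random non-member). These rates are package choices; all correctness
tests are oracle-containment checks rather than trajectory matches, so
they are robust to the operator settings.

- `subset_ga`: elitist single-objective GA, binary tournament on
  (constraint violation, objective).
- `hill_climber_swap`: steepest descent over the 1-swap neighborhood;
  every accepted step strictly improves, so it terminates.
- `nsga2`: fast nondominated sorting + crowding-distance survival;
  binary tournament on (rank, crowding), ties to the lower index.
- `nsga3`: survival by reference-point niching on a Das–Dennis simplex
  lattice (12 divisions → 91 directions for three objectives).
  Normalization uses the ideal point and extreme-point intercepts found
  by an achievement scalarizing function; when the extreme-point system
  is singular or yields non-positive intercepts, it falls back to
  max-range normalization. Parents are drawn uniformly, per the
  reference algorithm.

Duplicates may exist inside a population but the reported front is
deduplicated on decision vectors. Returned fronts are the final
population's rank-0 set: with a population comfortably larger than the
true Pareto set, every Pareto point once found is retained, so on small
instances the front converges to a subset of the exact Pareto set
(verified against exhaustive enumeration of all C(12,4) = 495 subsets).
Convergence budgets for that check (population 150, 500 generations)
were sized so the search reliably discovers ≥ 90% of the exact set.

## Synthetic data

The founder generator emulates a diversity panel of common biallelic
SNPs: per marker an allele frequency is drawn uniform on
[min_maf, 1 − min_maf] and haplotype alleles are i.i.d. Bernoulli at
that frequency; markers whose realized minor allele frequency is not
strictly above the threshold are resampled. Genetic positions are
evenly spaced along chromosomes of fixed Morgan length; physical
positions are fixed-spacing integers (only genetic positions matter to
the simulation). Defaults: 942 individuals, 2,000 markers, 10
chromosomes, MAF > 0.2, 2 Morgans per chromosome.

Founders are generated at **linkage equilibrium**. Real panels carry
linkage disequilibrium; in the simulated program LD is built by the
burn-in generations of mating, which is also why the recurrent-program
scenario runs a burn-in before its main loop. Passing tests therefore
demonstrate correctness of the machinery and the qualitative
selection-response behaviour, not calibration to any real panel's LD
structure or allele-frequency spectrum.

## Scenario drivers

- **Frontier mapping (scenario 1 style)**: synthetic panel → two-trait
  model → true breeding values and IBS kinship → subset OCS (J = 20) →
  NSGA-III (population 100, 91 reference points). The full-scale budget
  is 1,500 generations; library defaults and the worked examples use
  reduced generations, which lowers frontier resolution but changes
  nothing structural.
- **Frontier + decision (scenario 2 style)**: identical optimization
  driven by a marker-effect model's GEBVs (loadable from CSV/HDF5, or
  synthetic stand-ins), then a pseudoweight pick. The preference vector
  is ordered like the objectives (trait 1, trait 2, kinship), so the
  "0.2 on inbreeding, 0.4 on each trait" preference is (0.4, 0.4, 0.2).
- **Recurrent program (scenario 3 style)**: stage A, random parents
  from the panel randomly intermated (20 biparental crosses × 80
  progeny per generation, parents re-drawn at random each generation);
  error variances for heritabilities (0.4, 0.6) backsolved from the
  stage-A end population. Stage B, phenotypic burn-in: 4-location
  phenotypes, entry-mean EBVs, within-family top 5% into a candidate
  pool spanning the previous three generations, top 40 by EBV trait-sum
  as parents. Stage C, main loop: identical structure, but evaluation
  switches to true-model GEBVs — both the within-family narrowing and
  the parental choice use them, and since phenotypes would go unused
  they are not simulated in this stage — and the 40 parents are a
  subset chosen by bi-objective NSGA-II (maximize both trait means of
  the subset) reduced by an equal-preference (0.5, 0.5) pseudoweight
  pick. The burn-in uses the same 20 × 80 crossing shape as the main
  loop; the program is treated as one pipeline shape throughout.

The desk-scale configuration (`Scenario3Config.reduced()`) keeps the
structure but shrinks the arithmetic: 200-individual panel, 300
markers, 20 parents, 10 crosses × 20 progeny, 5 generations per stage,
and a 20% within-family proportion so each family of 20 still
contributes 4 candidates and the pool always covers the parental subset
size. Tests and the acceptance checks run at these sizes.

## Degenerate inputs and tie-breaking

- Strict inequality in the MAF filter; threshold ties are excluded.
- Round half up in within-family counts (2.5 → 3).
- All argmin/argsort tie-breaks are stable (lowest index wins).
- A constant objective column scales to 0 in the pseudoweight pick
  rather than raising.
- Multi-allelic VCF records error by default (`on_multiallelic="skip"`
  drops them); unphased genotypes always error, naming the record.
- The dominance design multiplies the heterozygote indicator by the
  dosage in some formulations; at dosage 1 the two readings coincide,
  and the binary indicator is implemented.

## Known limitations

- Diploid only for meiosis; no polyploid recombination model.
- No epistasis, GxE, or model fitting (effects are inputs).
- Founders lack LD and population structure; no coalescent realism.
- Optimizers are exact only in the oracle-checkable regime (small n);
  at scale they are heuristics and frontier quality depends on the
  evaluation budget.
- Real-valued (contribution-proportion) OCS and mate allocation are not
  implemented; decisions are fixed-size subsets.
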