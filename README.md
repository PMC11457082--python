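# breedopt

Stochastic simulation of breeding programs and multi-objective
optimization of selection decisions.

Plant and animal breeding is almost always multi-objective: genetic gain
for several (often competing) traits has to be balanced against the loss
of genetic diversity that selection causes. `breedopt` lets a breeder or
quantitative geneticist simulate a whole recurrent-selection program —
genomes, meiosis, mating, multi-location phenotyping, breeding-value
estimation — and treat each selection decision as an explicit
optimization problem whose Pareto frontier can be mapped and reduced to
a single, defensible choice.

## The core formalism

A selection decision is a subset $x$ of $J$ candidates from $n$. Every
selection problem is written as

$$\min_x\; T_{obj}(L(x)) \quad\text{s.t.}\quad T_{ineq}(L(x)) \le 0,\; T_{eq}(L(x)) = 0,\; x \in \Omega,$$

where the latent function $L$ maps a decision to the raw quantities the
protocol cares about and the user-supplied transforms re-partition that
vector into minimized objectives and constraints. The flagship instance
is subset **optimal contribution selection** (OCS) with breeding values
$bv_1, bv_2$ and an identity-by-state kinship matrix $K$:

$$\max_x \tfrac1J bv_1'x,\qquad \max_x \tfrac1J bv_2'x,\qquad \min_x \tfrac1{J^2} x'Kx,\qquad \mathbf 1'x = J,$$

i.e. maximize the selected subset's mean merit for each trait while
minimizing its mean kinship. Frontiers are approximated with built-in
NSGA-II (crowding-distance survival) or NSGA-III (reference-point
niching on a Das–Dennis simplex lattice) over a feasibility-preserving
subset encoding, and a single decision is extracted by the
*pseudoweight* rule: scale each objective to $[0,1]$ (oriented so larger
is better) and take the point nearest a preference vector.

Around that core the package provides phased genome matrices with
VCF/HDF5 I/O, genetic maps with Haldane and Kosambi map functions,
two-step recombination simulation ($u_i < (p_{xo})_i$ flips the copied
phase), self/two-/three-/four-way and doubled-haploid mating protocols,
additive(+dominance) linear genomic models $Y = XB + ZU$, phenotype
simulation $y_{ijk} = g_{ik} + l_{jk} + \varepsilon_{ijk}$ with an
error-variance backsolve that realizes a target single-location
heritability, and classical protocols (truncation, within-family,
weighted genomic selection, optimal haploid value, random selection).

## Worked example

Map an OCS frontier on a synthetic diversity panel and pick one
selection decision:

```python
import numpy as np
import breedopt as bo

rng = np.random.default_rng(42)

# 1. synthetic diversity panel: 200 individuals, 500 common markers
panel, gmap = bo.generate_founders(
    bo.FounderSpec(n_individuals=200, n_markers=500, n_chromosomes=10, min_maf=0.2),
    rng,
)

# 2. two competing traits (effect correlation -0.4, intercepts 10 and 25)
model = bo.scenario_trait_model(panel.n_markers, rng)
bv = model.breeding_values(panel.dosage)
K = bo.ibs_kinship(panel)

# 3. subset optimal contribution selection: pick 20 parents
problem = bo.ocs_subset_problem(bv, K, J=20)
front = bo.nsga3(problem, pop_size=100, generations=80,
                 refs=bo.das_dennis_reference_points(3, 12), rng=rng)
print(f"nondominated solutions found: {front.n_solutions}")

# 4. reduce the frontier to one decision (traits weighted 0.4, kinship 0.2)
pick = bo.pseudoweight_pick(front.objectives, [0.4, 0.4, 0.2])
```

Output:

```
nondominated solutions found: 95
picked subset mean BV trait 1: 19.953 (population 11.581)
picked subset mean BV trait 2: 36.406 (population 22.155)
picked subset mean kinship:    0.670 (population 0.658)
```

The 95 nondominated subsets trace the trade-off surface between the two
trait means and mean kinship. The picked subset beats the population
mean by ~8 and ~14 units for the two traits while keeping its mean
kinship near the population average — the compromise encoded by the
(0.4, 0.4, 0.2) preference.

A full recurrent program (random intermating, phenotypic burn-in with
within-family selection, then NSGA-II parental selection at equal
preference) runs from the command line:

```sh
breedopt simulate --seed 7 --out run7       # desk-scale defaults
breedopt simulate --paper-scale --seed 7    # full program shape
breedopt frontier --n 200 --markers 500 --j 20 --seed 1 --out front1
breedopt gamete-stats --distance 0.2 --gametes 50000
```

Each run writes `means.csv` / `fronts.csv` plus a `manifest.json` that
echoes the seed and configuration needed to reproduce it exactly.

## Layout

- `src/breedopt/genome.py` — phased genomes, genetic maps, map functions, kinship, VCF/HDF5 I/O
- `src/breedopt/meiosis.py` — crossover simulation and mating protocols
- `src/breedopt/model.py` — linear genomic models and effect sampling
- `src/breedopt/phenotype.py` — phenotype simulation, heritability backsolve, entry-mean EBVs
- `src/breedopt/selection.py` — selection-problem formalism and protocols
- `src/breedopt/optimize.py` — nondominated sorting, subset GA, hill climber, NSGA-II/III
- `src/breedopt/pipeline.py` — breeding operators, the universal loop, scenario drivers
- `src/breedopt/synthetic.py` — synthetic panels, maps, and trait models
- `src/breedopt/cli.py` — command-line entry points

See `docs/methods.md` for the modelling assumptions and numerical
choices.
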