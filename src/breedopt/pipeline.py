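"""Breeding-program state, the universal breeding loop, and scenario drivers.

A breeding program is a sequence of five Operators — initialization,
evaluation, parental selection, mating, survivor selection — each a pure
transform of a :class:`BreedingProgramState`.  Assembled into the
universal breeding loop they simulate recurrent selection; the scenario
drivers wire concrete protocols into that loop:

* scenario 1 — map the three-objective Pareto frontier of subset optimal
  contribution selection (two trait means vs mean kinship) with NSGA-III
  on a synthetic diversity panel;
* scenario 2 — the same optimization from a marker-effect model's GEBVs,
  reduced to one decision by a pseudoweight preference pick;
* scenario 3 — a full recurrent program: random intermating, a
  phenotypic burn-in with within-family selection, then a main loop of
  bi-objective NSGA-II parental selection at equal preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import optimize
from .genome import (
    GeneticMap,
    PhasedGenomeMatrix,
    concat_individuals,
    ibs_kinship,
    read_hdf5,
    write_hdf5,
)
from .meiosis import CrossoverProbabilities, crossover_probs_for, random_intermate
from .model import LinearGenomicModel
from .phenotype import (
    backsolve_error_variance,
    estimate_breeding_values,
    simulate_phenotypes,
)
from .selection import (
    ocs_subset_problem,
    pseudoweight_pick,
    truncation_select,
    within_family_select,
)
from .synthetic import FounderSpec, generate_founders, scenario_trait_model

__all__ = [
    "BreedingProgramState",
    "OperatorSet",
    "universal_breeding_algorithm",
    "Scenario1Config",
    "Scenario2Config",
    "Scenario3Config",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3",
]


# ---------------------------------------------------------------------------
# state and the universal loop
# ---------------------------------------------------------------------------

@dataclass
class BreedingProgramState:
    """Everything an Operator may read or transform.

    ``candidate_genomes`` and ``candidate_values`` hold the rolling pool
    of parental candidates with their generation-of-origin tags;
    ``selected_parents`` carries the parental decision between the
    parental-selection and mating operators.
    """

    genomes: PhasedGenomeMatrix
    genomic_model: LinearGenomicModel
    generation: int = 0
    family: np.ndarray | None = None
    phenotypes: object | None = None
    breeding_values: np.ndarray | None = None
    candidate_genomes: PhasedGenomeMatrix | None = None
    candidate_values: np.ndarray | None = None
    candidate_origin: np.ndarray | None = None
    selected_parents: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.breeding_values is not None:
            if self.breeding_values.shape[0] != self.genomes.n_individuals:
                raise ValueError("breeding_values row count mismatch")
        if self.candidate_genomes is not None:
            m = self.candidate_genomes.n_individuals
            if self.candidate_values is not None and self.candidate_values.shape[0] != m:
                raise ValueError("candidate_values row count mismatch")
            if self.candidate_origin is not None and self.candidate_origin.size != m:
                raise ValueError("candidate_origin length mismatch")


Operator = Callable[[BreedingProgramState, np.random.Generator], BreedingProgramState]


@dataclass
class OperatorSet:
    """The five breeding operators, each a pure (state, rng) -> state map."""

    initialize: Operator
    evaluate: Operator
    parent_select: Operator
    mate: Operator
    survivor_select: Operator


def universal_breeding_algorithm(
    ops: OperatorSet,
    state0: BreedingProgramState,
    n_generations: int,
    rng: np.random.Generator,
    hooks: list[Callable[[BreedingProgramState], dict]] | None = None,
) -> tuple[BreedingProgramState, list[dict]]:
    """Run the generational loop and collect per-generation metrics.

    Applies ``initialize`` once, then per generation
    evaluate -> parent_select -> mate -> survivor_select, incrementing
    the generation counter.  Every hook is called on the end-of-
    generation state; its dict is merged into that generation's log row.
    An operator that breaks a state invariant raises an error naming it.
    """
    hooks = hooks or []
    state = _checked(ops.initialize, "initialize", state0, rng)
    log: list[dict] = []
    for _ in range(n_generations):
        state = _checked(ops.evaluate, "evaluate", state, rng)
        state = _checked(ops.parent_select, "parent_select", state, rng)
        state = _checked(ops.mate, "mate", state, rng)
        state = _checked(ops.survivor_select, "survivor_select", state, rng)
        state = replace(state, generation=state.generation + 1)
        row = {"generation": state.generation}
        for hook in hooks:
            row.update(hook(state))
        log.append(row)
    return state, log


def _checked(
    op: Operator, name: str, state: BreedingProgramState, rng: np.random.Generator
) -> BreedingProgramState:
    out = op(state, rng)
    if not isinstance(out, BreedingProgramState):
        raise TypeError(f"operator {name!r} did not return a state")
    try:
        out.validate()
    except ValueError as exc:
        raise ValueError(f"operator {name!r} produced an invalid state: {exc}")
    return out


def checkpoint_state(state: BreedingProgramState, path) -> None:
    """Persist genomes + counters to HDF5 (model kept alongside by caller)."""
    write_hdf5(state.genomes, path)
    import h5py

    with h5py.File(path, "a") as f:
        f.attrs["generation"] = state.generation
        if state.family is not None:
            f.create_dataset("family", data=state.family)


def restore_state(path, model: LinearGenomicModel) -> BreedingProgramState:
    genomes = read_hdf5(path)
    import h5py

    with h5py.File(path, "r") as f:
        gen = int(f.attrs["generation"])
        family = f["family"][()] if "family" in f else None
    return BreedingProgramState(
        genomes=genomes, genomic_model=model, generation=gen, family=family
    )


# ---------------------------------------------------------------------------
# scenario 1: tri-objective subset OCS frontier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario1Config:
    """Panel shape and optimizer settings for the OCS frontier run."""

    n_individuals: int = 942
    n_markers: int = 2000
    n_chromosomes: int = 10
    min_maf: float = 0.2
    subset_size: int = 20
    pop_size: int = 100
    ref_divisions: int = 12  # 91 reference points for 3 objectives
    generations: int = 1500


@dataclass
class FrontierResult:
    """Mapped frontier plus the inputs that produced it."""

    solution: object
    problem: object
    breeding_values: np.ndarray
    kinship: np.ndarray
    picked: int | None = None

    def front_frame(self) -> pd.DataFrame:
        df = self.solution.to_frame()
        df.columns = ["solution", "neg_mean_bv1", "neg_mean_bv2", "mean_kinship", "decision"]
        return df


def run_scenario1(
    config: Scenario1Config, rng: np.random.Generator, out_dir=None
) -> FrontierResult:
    """Map the Pareto frontier for tri-objective subset OCS.

    Generates a synthetic common-marker panel, samples the two-trait
    model, builds the subset OCS problem (two mean-breeding-value
    objectives, one mean-kinship objective) and approximates the
    frontier with NSGA-III.
    """
    spec = FounderSpec(
        n_individuals=config.n_individuals,
        n_markers=config.n_markers,
        n_chromosomes=config.n_chromosomes,
        min_maf=config.min_maf,
    )
    genomes, _ = generate_founders(spec, rng)
    model = scenario_trait_model(genomes.n_markers, rng)
    bv = model.breeding_values(genomes.dosage)
    K = ibs_kinship(genomes)
    problem = ocs_subset_problem(bv, K, config.subset_size)
    refs = optimize.das_dennis_reference_points(3, config.ref_divisions)
    solution = optimize.nsga3(
        problem,
        pop_size=config.pop_size,
        generations=config.generations,
        refs=refs,
        rng=rng,
    )
    result = FrontierResult(solution, problem, bv, K)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.front_frame().to_csv(out_dir / "fronts.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# scenario 2: frontier + pseudoweight decision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario2Config:
    """GEBV-based OCS with a preference-vector decision.

    The preference is ordered like the objectives (trait 1, trait 2,
    kinship); the default weights the two traits 0.4 each and
    inbreeding 0.2.
    """

    n_individuals: int = 599
    n_markers: int = 1280
    n_chromosomes: int = 10
    min_maf: float = 0.1
    subset_size: int = 20
    pop_size: int = 100
    ref_divisions: int = 12
    generations: int = 1500
    preference: tuple = (0.4, 0.4, 0.2)


def run_scenario2(
    config: Scenario2Config,
    rng: np.random.Generator,
    genomes: PhasedGenomeMatrix | None = None,
    model: LinearGenomicModel | None = None,
    out_dir=None,
) -> FrontierResult:
    """Map the OCS frontier from a marker-effect model and pick one point.

    Genotypes and the effect model may be supplied (e.g. loaded from
    files exported by an external model fit); otherwise synthetic
    stand-ins are generated.  GEBVs are computed from the model, the
    frontier is mapped exactly as in scenario 1, and a single solution
    is chosen by pseudoweight distance to the preference vector.
    """
    if genomes is None:
        spec = FounderSpec(
            n_individuals=config.n_individuals,
            n_markers=config.n_markers,
            n_chromosomes=config.n_chromosomes,
            min_maf=config.min_maf,
        )
        genomes, _ = generate_founders(spec, rng)
    if model is None:
        model = scenario_trait_model(genomes.n_markers, rng)
    gebv = model.breeding_values(genomes.dosage)
    K = ibs_kinship(genomes)
    problem = ocs_subset_problem(gebv, K, config.subset_size)
    refs = optimize.das_dennis_reference_points(3, config.ref_divisions)
    solution = optimize.nsga3(
        problem,
        pop_size=config.pop_size,
        generations=config.generations,
        refs=refs,
        rng=rng,
    )
    picked = pseudoweight_pick(
        solution.objectives, np.asarray(config.preference, dtype=np.float64)
    )
    result = FrontierResult(solution, problem, gebv, K, picked=picked)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df = result.front_frame()
        df["picked"] = df["solution"] == picked
        df.to_csv(out_dir / "fronts.csv", index=False)
    return result


# ---------------------------------------------------------------------------
# scenario 3: full recurrent breeding program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario3Config:
    """Recurrent-selection program settings.

    Defaults follow the full-scale program: 40 parents intermated in 20
    biparental crosses of 80 progeny, heritabilities 0.4 and 0.6
    assigned once in the base population, four phenotyping locations,
    top 5% within-family survivor selection, candidates pooled over the
    previous three generations, and a bi-objective NSGA-II parental
    selection at equal preference in the main loop.
    """

    n_panel: int = 942
    n_markers: int = 1000
    n_chromosomes: int = 10
    min_maf: float = 0.2
    n_parents: int = 40
    n_crosses: int = 20
    progeny_per_cross: int = 80
    stage_a_generations: int = 10
    burnin_generations: int = 10
    main_generations: int = 10
    n_locations: int = 4
    heritabilities: tuple = (0.4, 0.6)
    family_proportion: float = 0.05
    pool_window: int = 3
    nsga2_pop_size: int = 100
    nsga2_generations: int = 200

    @staticmethod
    def reduced() -> "Scenario3Config":
        """Desk-scale program: same structure, smaller populations.

        10 crosses of 20 progeny, 20 parents, 20% within-family keep (so
        the candidate pool still feeds the parental subset), 5
        generations per stage, and a lighter NSGA-II budget.
        """
        return Scenario3Config(
            n_panel=200,
            n_markers=300,
            n_parents=20,
            n_crosses=10,
            progeny_per_cross=20,
            stage_a_generations=5,
            burnin_generations=5,
            main_generations=5,
            family_proportion=0.2,
            nsga2_pop_size=60,
            nsga2_generations=60,
        )


@dataclass
class Scenario3Result:
    """Trajectory log of a recurrent-selection simulation."""

    means: pd.DataFrame  # columns: stage, generation, trait, mean_bv, var_bv
    fronts: list[np.ndarray]  # main-loop NSGA-II fronts (latent scale)
    error_variances: np.ndarray
    final_state: BreedingProgramState

    def main_loop_means(self) -> np.ndarray:
        """(n_generations + 1, t) mean true BV over the main loop."""
        df = self.means[self.means["stage"] == "main"]
        return (
            df.pivot_table(index="generation", columns="trait", values="mean_bv")
            .sort_index()
            .to_numpy()
        )


def _pool_prune(
    pool: list[tuple[int, PhasedGenomeMatrix, np.ndarray]], current_gen: int, window: int
) -> list[tuple[int, PhasedGenomeMatrix, np.ndarray]]:
    return [e for e in pool if current_gen - e[0] <= window - 1]


def run_scenario3(
    config: Scenario3Config, rng: np.random.Generator, out_dir=None
) -> Scenario3Result:
    """Simulate the full recurrent breeding program.

    Stage A: random parents from a synthetic panel are randomly
    intermated for several generations to build a base population.
    Error variances for the target single-location heritabilities are
    backsolved from that population's genetic variances and then held
    fixed.  Stage B (burn-in): multi-location phenotypes, entry-mean
    EBVs, within-family survivor selection into a rolling candidate
    pool, and truncation of the pool to the parent set.  Stage C (main
    loop): identical, except parents are a subset chosen by bi-objective
    NSGA-II on true-model GEBVs, reduced to one decision by an
    equal-preference pseudoweight pick.
    """
    spec = FounderSpec(
        n_individuals=config.n_panel,
        n_markers=config.n_markers,
        n_chromosomes=config.n_chromosomes,
        min_maf=config.min_maf,
    )
    panel, gmap = generate_founders(spec, rng)
    model = scenario_trait_model(panel.n_markers, rng)
    pxo = crossover_probs_for(panel, gmap, "haldane")
    t = model.n_traits

    # stage A: random intermating from randomly chosen panel genotypes
    start = rng.choice(panel.n_individuals, size=config.n_parents, replace=False)
    parents = panel.take_individuals(start)
    rows: list[dict] = []
    population = parents
    family = np.zeros(parents.n_individuals, dtype=np.intp)
    for g in range(config.stage_a_generations):
        population, family = random_intermate(
            parents, config.n_crosses, config.progeny_per_cross, pxo, rng,
            name_prefix=f"a{g}_",
        )
        nxt = rng.choice(
            population.n_individuals, size=config.n_parents, replace=False
        )
        parents = population.take_individuals(nxt)
        _log_means(rows, "stage_a", g + 1, model, population)

    # base-population genetic variances -> fixed error variances
    base_bv = model.breeding_values(population.dosage)
    sigma2_g = base_bv.var(axis=0, ddof=1)
    sigma2_e = backsolve_error_variance(
        sigma2_g, np.asarray(config.heritabilities, dtype=np.float64)
    )

    pool: list[tuple[int, PhasedGenomeMatrix, np.ndarray]] = []
    fronts: list[np.ndarray] = []
    gen = 0

    def phenotype_ebv(pop: PhasedGenomeMatrix) -> np.ndarray:
        g_vals = model.predict(pop.dosage)
        table = simulate_phenotypes(
            g_vals, config.n_locations, sigma2_e, rng,
            individual_names=pop.individual_names,
            trait_names=model.trait_names,
        )
        return estimate_breeding_values(table)

    # stage B: phenotypic burn-in
    _log_means(rows, "burnin", 0, model, population)
    for g in range(config.burnin_generations):
        ebv = phenotype_ebv(population)
        fam_keep = within_family_select(ebv, family, config.family_proportion)
        pool.append((gen, population.take_individuals(fam_keep), ebv[fam_keep]))
        pool = _pool_prune(pool, gen, config.pool_window)
        cand_genomes = concat_individuals([e[1] for e in pool])
        cand_values = np.vstack([e[2] for e in pool])
        top = truncation_select(cand_values, config.n_parents)
        parents = cand_genomes.take_individuals(top)
        population, family = random_intermate(
            parents, config.n_crosses, config.progeny_per_cross, pxo, rng,
            name_prefix=f"b{g}_",
        )
        gen += 1
        _log_means(rows, "burnin", g + 1, model, population)

    # stage C: main loop with bi-objective parental selection
    _log_means(rows, "main", 0, model, population)
    for g in range(config.main_generations):
        gebv = model.breeding_values(population.dosage)
        fam_keep = within_family_select(gebv, family, config.family_proportion)
        pool.append((gen, population.take_individuals(fam_keep), gebv[fam_keep]))
        pool = _pool_prune(pool, gen, config.pool_window)
        cand_genomes = concat_individuals([e[1] for e in pool])
        cand_values = np.vstack([e[2] for e in pool])

        # bi-objective subset problem: maximize each trait's subset mean
        J = config.n_parents
        from .selection import SelectionProblem

        def latent(x, _vals=cand_values):
            return _vals[x].mean(axis=0)

        problem = SelectionProblem(
            n_candidates=cand_values.shape[0],
            subset_size=J,
            latent=latent,
            n_obj=t,
            t_obj=lambda lat: -lat,
            obj_names=[f"-mean_bv_{j + 1}" for j in range(t)],
        )
        solution = optimize.nsga2(
            problem,
            pop_size=config.nsga2_pop_size,
            generations=config.nsga2_generations,
            rng=rng,
        )
        fronts.append(-solution.objectives)  # back to mean-BV scale
        pick = pseudoweight_pick(
            solution.objectives, np.full(t, 0.5), senses=["min"] * t
        )
        parents = cand_genomes.take_individuals(solution.decisions[pick])
        population, family = random_intermate(
            parents, config.n_crosses, config.progeny_per_cross, pxo, rng,
            name_prefix=f"c{g}_",
        )
        gen += 1
        _log_means(rows, "main", g + 1, model, population)

    means = pd.DataFrame(rows)
    final_state = BreedingProgramState(
        genomes=population,
        genomic_model=model,
        generation=gen,
        family=family,
    )
    result = Scenario3Result(means, fronts, sigma2_e, final_state)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        means.to_csv(out_dir / "means.csv", index=False)
        front_rows = []
        for i, F in enumerate(fronts):
            for s, row in enumerate(F):
                front_rows.append(
                    {"generation": i, "solution": s,
                     **{f"mean_bv{j + 1}": row[j] for j in range(F.shape[1])}}
                )
        pd.DataFrame(front_rows).to_csv(out_dir / "fronts.csv", index=False)
    return result


def _log_means(
    rows: list[dict], stage: str, generation: int,
    model: LinearGenomicModel, population: PhasedGenomeMatrix,
) -> None:
    bv = model.breeding_values(population.dosage)
    for j, trait in enumerate(model.trait_names):
        rows.append(
            {
                "stage": stage,
                "generation": generation,
                "trait": trait,
                "mean_bv": float(bv[:, j].mean()),
                "var_bv": float(bv[:, j].var(ddof=1)),
            }
        )
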