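"""Selection problems, protocols, and frontier decision rules.

A selection problem is described by a decision space, a latent function
``L`` mapping a decision to a real vector, and user transforms that
re-partition the latent vector into minimized objectives, inequality
constraints (feasible when <= 0) and equality constraints.  Concrete
protocols build these problems (subset optimal contribution selection)
or make selections directly (truncation, within-family, weighted genomic
selection, optimal haploid value, random).  ``pseudoweight_pick``
extracts one decision from a nondominated front by normalized distance
to a preference vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genome import PhasedGenomeMatrix

__all__ = [
    "SelectionProblem",
    "SelectionSolution",
    "SelectionConfiguration",
    "ocs_subset_problem",
    "truncation_select",
    "within_family_select",
    "weighted_gs_scores",
    "ohv_values",
    "ohv_select",
    "random_select",
    "pseudoweight_pick",
    "select",
]


def _identity(v: np.ndarray) -> np.ndarray:
    return v


def _empty(v: np.ndarray) -> np.ndarray:
    return np.empty(0)


@dataclass
class SelectionProblem:
    """Optimization problem min_x t_obj(L(x)) over a subset decision space.

    ``x`` is a set of ``subset_size`` distinct candidate indices; the
    encoding makes the cardinality constraint hold by construction.
    Objectives are minimized; maximization is encoded by negation inside
    ``t_obj``.
    """

    n_candidates: int
    subset_size: int
    latent: Callable[[np.ndarray], np.ndarray]
    n_obj: int
    t_obj: Callable[[np.ndarray], np.ndarray] = _identity
    t_ineq: Callable[[np.ndarray], np.ndarray] = _empty
    t_eq: Callable[[np.ndarray], np.ndarray] = _empty
    n_ineq: int = 0
    n_eq: int = 0
    obj_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.subset_size <= self.n_candidates:
            raise ValueError(
                f"subset size {self.subset_size} infeasible for "
                f"{self.n_candidates} candidates"
            )
        if self.n_obj < 1:
            raise ValueError("need at least one objective")
        if not self.obj_names:
            self.obj_names = [f"obj{i + 1}" for i in range(self.n_obj)]

    def check_decision(self, x: Sequence[int]) -> np.ndarray:
        x = np.asarray(x, dtype=np.intp)
        if x.ndim != 1 or x.size != self.subset_size:
            raise ValueError(
                f"decision must select exactly {self.subset_size} candidates"
            )
        if np.unique(x).size != x.size:
            raise ValueError("decision contains repeated candidates")
        if x.min() < 0 or x.max() >= self.n_candidates:
            raise ValueError("candidate index out of range")
        return np.sort(x)

    def evaluate(
        self, x: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(objectives, inequality values, equality values) at decision x."""
        x = self.check_decision(x)
        lat = np.asarray(self.latent(x), dtype=np.float64)
        obj = np.atleast_1d(np.asarray(self.t_obj(lat), dtype=np.float64))
        ineq = np.atleast_1d(np.asarray(self.t_ineq(lat), dtype=np.float64))
        eq = np.atleast_1d(np.asarray(self.t_eq(lat), dtype=np.float64))
        if obj.size != self.n_obj:
            raise ValueError("t_obj output length does not match n_obj")
        return obj, ineq, eq

    def objectives(self, x: Sequence[int]) -> np.ndarray:
        return self.evaluate(x)[0]

    def violation(self, x: Sequence[int]) -> float:
        _, ineq, eq = self.evaluate(x)
        return float(np.clip(ineq, 0, None).sum() + np.abs(eq).sum())


@dataclass
class SelectionSolution:
    """Optimizer output: decision vectors with their objective values."""

    decisions: np.ndarray  # (m, J) index sets, rows sorted
    objectives: np.ndarray  # (m, n_obj)
    violations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.decisions = np.atleast_2d(np.asarray(self.decisions, dtype=np.intp))
        self.objectives = np.atleast_2d(np.asarray(self.objectives, dtype=np.float64))
        if self.decisions.shape[0] != self.objectives.shape[0]:
            raise ValueError("decision/objective row mismatch")
        if self.violations is None:
            self.violations = np.zeros(self.decisions.shape[0])

    @property
    def n_solutions(self) -> int:
        return self.decisions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.objectives, columns=[f"obj{i+1}" for i in range(self.objectives.shape[1])]
        )
        df.insert(0, "solution", np.arange(self.n_solutions))
        df["decision"] = [" ".join(map(str, row)) for row in self.decisions]
        return df


@dataclass
class SelectionConfiguration:
    """A concrete selection decision ready for mating."""

    selected: np.ndarray
    objectives: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=np.intp)


# ---------------------------------------------------------------------------
# optimal contribution selection (subset variant)
# ---------------------------------------------------------------------------

def ocs_subset_problem(
    bv: np.ndarray, K: np.ndarray, J: int, obj_names: list[str] | None = None
) -> SelectionProblem:
    """Subset optimal contribution selection.

    Latent vector: per-trait mean breeding value of the selected subset,
    (1/J) * bv_t' x, followed by the mean pairwise kinship
    (1/J^2) * x' K x.  The default objective transform negates the
    breeding-value components (maximized) and keeps kinship positive
    (minimized).
    """
    bv = np.atleast_2d(np.asarray(bv, dtype=np.float64))
    if bv.ndim != 2:
        raise ValueError("breeding values must be (n, t)")
    n, t = bv.shape
    K = np.asarray(K, dtype=np.float64)
    if K.shape != (n, n):
        raise ValueError("kinship matrix shape mismatch")
    if J > n:
        raise ValueError(f"subset size {J} exceeds {n} candidates")

    def latent(x: np.ndarray) -> np.ndarray:
        mean_bv = bv[x].mean(axis=0)
        mean_kin = K[np.ix_(x, x)].sum() / (J * J)
        return np.concatenate([mean_bv, [mean_kin]])

    def t_obj(lat: np.ndarray) -> np.ndarray:
        out = lat.copy()
        out[:t] = -out[:t]
        return out

    names = obj_names or [f"-mean_bv_{j + 1}" for j in range(t)] + ["mean_kinship"]
    return SelectionProblem(
        n_candidates=n,
        subset_size=J,
        latent=latent,
        n_obj=t + 1,
        t_obj=t_obj,
        obj_names=names,
    )


# ---------------------------------------------------------------------------
# direct selection protocols
# ---------------------------------------------------------------------------

def truncation_select(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest trait-sum scores; ties by ascending index."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} from {n} candidates")
    totals = scores.sum(axis=1)
    order = np.argsort(-totals, kind="stable")
    return order[:k]


def within_family_select(
    scores: np.ndarray, family: Sequence, proportion: float
) -> np.ndarray:
    """Top fraction of each family by trait-sum score.

    Keeps round-half-up(proportion * family_size) members per family
    (so 5% of a family of 80 keeps exactly 4); returns the union of the
    per-family picks in ascending index order.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must lie in (0, 1]")
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    family = np.asarray(family)
    if family.size != scores.shape[0]:
        raise ValueError("family labels length mismatch")
    if family.size == 0:
        raise ValueError("no individuals to select from")
    totals = scores.sum(axis=1)
    keep: list[int] = []
    for fam in pd.unique(family):
        members = np.flatnonzero(family == fam)
        m = members.size
        n_keep = int(np.floor(proportion * m + 0.5))  # round half up
        order = members[np.argsort(-totals[members], kind="stable")]
        keep.extend(order[:n_keep].tolist())
    return np.sort(np.asarray(keep, dtype=np.intp))


def weighted_gs_scores(
    dosages: np.ndarray,
    additive_effects: np.ndarray,
    frequencies: np.ndarray,
) -> np.ndarray:
    """Weighted genomic selection scores.

    Each marker effect is divided by the square root of its favorable
    allele frequency (the allele whose dosage increase raises the score;
    allele 1 when the effect is >= 0, else allele 0), clamped below at
    1/(2n) to keep rare-allele weights finite.
    """
    Z = np.atleast_2d(np.asarray(dosages, dtype=np.float64))
    U = np.atleast_2d(np.asarray(additive_effects, dtype=np.float64))
    f = np.asarray(frequencies, dtype=np.float64)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    if Z.shape[1] != U.shape[0] or f.size != U.shape[0]:
        raise ValueError("marker dimension mismatch")
    n = Z.shape[0]
    f_fav = np.where(U >= 0, f[:, None], 1.0 - f[:, None])
    f_fav = np.maximum(f_fav, 1.0 / (2.0 * max(n, 1)))
    return Z @ (U / np.sqrt(f_fav))


def ohv_values(
    phased: PhasedGenomeMatrix,
    additive_effects: np.ndarray,
    blocks_per_chromosome: int = 1,
) -> np.ndarray:
    """Optimal haploid values per individual and trait.

    Chromosomes are cut into contiguous marker blocks; for each block the
    better of the individual's two phases (by summed allele x effect) is
    kept, and OHV = 2 * sum of the best-block values — the genotypic
    value of the best doubled haploid derivable without recombination
    inside blocks.
    """
    if blocks_per_chromosome < 1:
        raise ValueError("blocks_per_chromosome must be >= 1")
    U = np.atleast_2d(np.asarray(additive_effects, dtype=np.float64))
    if U.shape[0] != phased.n_markers:
        raise ValueError("marker dimension mismatch")
    n, t = phased.n_individuals, U.shape[1]
    ohv = np.zeros((n, t))
    for lo, hi in phased.chromosome_spans():
        for block in np.array_split(np.arange(lo, hi), blocks_per_chromosome):
            if block.size == 0:
                continue
            # (n, phases, t) haploid block values
            hap = np.einsum(
                "imh,mt->iht", phased.alleles[:, block, :].astype(np.float64), U[block]
            )
            ohv += 2.0 * hap.max(axis=1)
    return ohv


def ohv_select(
    phased: PhasedGenomeMatrix,
    additive_effects: np.ndarray,
    blocks_per_chromosome: int,
    k: int,
) -> np.ndarray:
    """Top-k individuals by optimal haploid value (trait-sum, stable ties)."""
    return truncation_select(
        ohv_values(phased, additive_effects, blocks_per_chromosome), k
    )


def random_select(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct indices drawn uniformly without replacement."""
    if k > n:
        raise ValueError(f"cannot select {k} from {n} candidates")
    return rng.choice(n, size=k, replace=False)


# ---------------------------------------------------------------------------
# frontier decision rule
# ---------------------------------------------------------------------------

def pseudoweight_pick(
    front: np.ndarray,
    preference: np.ndarray,
    senses: Sequence[str] | None = None,
) -> int:
    """Pick one frontier point by distance to a preference vector.

    Each objective column is oriented so that larger is better, then
    min-max scaled to [0, 1] (a constant column scales to 0).  The point
    whose scaled coordinates lie closest (Euclidean) to the preference
    vector is returned; ties break to the lowest index.

    ``senses`` gives per-objective orientation, "max" or "min"
    (default: all "min", matching minimized optimizer output).
    """
    F = np.atleast_2d(np.asarray(front, dtype=np.float64))
    m, d = F.shape
    if m == 0:
        raise ValueError("empty front")
    w = np.asarray(preference, dtype=np.float64)
    if w.size != d:
        raise ValueError("preference length does not match objective count")
    if senses is None:
        senses = ["min"] * d
    if len(senses) != d:
        raise ValueError("senses length does not match objective count")
    oriented = F.copy()
    for j, s in enumerate(senses):
        if s == "min":
            oriented[:, j] = -oriented[:, j]
        elif s != "max":
            raise ValueError(f"sense must be 'max' or 'min', got {s!r}")
    lo = oriented.min(axis=0)
    rng_ = oriented.max(axis=0) - lo
    scaled = np.zeros_like(oriented)
    nonconst = rng_ > 0
    scaled[:, nonconst] = (oriented[:, nonconst] - lo[nonconst]) / rng_[nonconst]
    dist = np.linalg.norm(scaled - w[None, :], axis=1)
    return int(np.argmin(dist))


def select(
    problem: SelectionProblem,
    rng: np.random.Generator,
    preference: np.ndarray | None = None,
    pop_size: int = 100,
    generations: int = 200,
    nd_transform: Callable[[np.ndarray], int] | None = None,
    optimizer: str | None = None,
    **optimizer_kwargs,
) -> SelectionConfiguration:
    """Solve a selection problem and reduce it to one concrete decision.

    Single-objective problems run the subset genetic algorithm and return
    its best decision.  Multi-objective problems map the front with
    NSGA-II (or NSGA-III when ``optimizer="nsga3"``) and reduce the
    nondominated set with ``nd_transform`` — by default a pseudoweight
    pick with the given (or uniform) preference vector.
    """
    from . import optimize

    if problem.n_obj == 1:
        sol = optimize.subset_ga(
            problem, pop_size=pop_size, generations=generations, rng=rng,
            **optimizer_kwargs,
        )
        return SelectionConfiguration(sol.decisions[0], sol.objectives[0])

    if optimizer in (None, "nsga2"):
        sol = optimize.nsga2(
            problem, pop_size=pop_size, generations=generations, rng=rng,
            **optimizer_kwargs,
        )
    elif optimizer == "nsga3":
        sol = optimize.nsga3(
            problem, pop_size=pop_size, generations=generations, rng=rng,
            **optimizer_kwargs,
        )
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    if sol.n_solutions == 0:
        raise ValueError("optimizer returned an empty front")
    if nd_transform is not None:
        pick = nd_transform(sol.objectives)
    else:
        if preference is None:
            preference = np.full(problem.n_obj, 1.0 / problem.n_obj)
        pick = pseudoweight_pick(sol.objectives, preference)
    return SelectionConfiguration(sol.decisions[pick], sol.objectives[pick])
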