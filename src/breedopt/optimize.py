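"""Evolutionary optimizers over fixed-size subset decision spaces.

All objectives are minimized.  Decision vectors are sorted arrays of
``J`` distinct candidate indices; the variation operators (exchange
crossover between non-shared members, single-member replacement
mutation) preserve feasibility by construction, so the subset-size
constraint never needs a penalty.  NSGA-II survival uses nondominated
sorting plus crowding distance; NSGA-III replaces crowding with
reference-point niching on a Das-Dennis simplex lattice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .selection import SelectionProblem, SelectionSolution

__all__ = [
    "nondominated_sort",
    "crowding_distance",
    "das_dennis_reference_points",
    "subset_ga",
    "hill_climber_swap",
    "nsga2",
    "nsga3",
    "exhaustive_pareto",
]


# ---------------------------------------------------------------------------
# nondominated sorting machinery
# ---------------------------------------------------------------------------

def nondominated_sort(objectives: np.ndarray) -> np.ndarray:
    """Front index per point (0 = nondominated), minimizing all objectives.

    Point p dominates q iff p <= q in every objective with at least one
    strict inequality; fronts are peeled successively and duplicates
    share a front.
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=np.float64))
    if np.isnan(F).any():
        raise ValueError("NaN objective value")
    m = F.shape[0]
    # domination counts and dominated lists (fast nondominated sort)
    le = np.ones((m, m), dtype=bool)
    lt = np.zeros((m, m), dtype=bool)
    for j in range(F.shape[1]):
        col = F[:, j]
        le &= col[:, None] <= col[None, :]
        lt |= col[:, None] < col[None, :]
    dominates = le & lt  # [i, j] True if i dominates j
    n_dom = dominates.sum(axis=0)
    rank = np.full(m, -1, dtype=np.intp)
    current = np.flatnonzero(n_dom == 0)
    level = 0
    remaining = m
    while current.size:
        rank[current] = level
        remaining -= current.size
        n_dom = n_dom - dominates[current].sum(axis=0)
        n_dom[rank >= 0] = -1
        current = np.flatnonzero(n_dom == 0)
        level += 1
    return rank


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance for one front.

    Boundary points of every objective get infinity; interior points sum
    normalized neighbor gaps per objective.
    """
    F = np.atleast_2d(np.asarray(objectives, dtype=np.float64))
    m, d = F.shape
    dist = np.zeros(m)
    if m <= 2:
        return np.full(m, np.inf)
    for j in range(d):
        order = np.argsort(F[:, j], kind="stable")
        col = F[order, j]
        span = col[-1] - col[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if span > 0:
            gaps = (col[2:] - col[:-2]) / span
            for k, idx in enumerate(order[1:-1]):
                if not np.isinf(dist[idx]):
                    dist[idx] += gaps[k]
    return dist


def das_dennis_reference_points(n_obj: int, divisions: int) -> np.ndarray:
    """Das-Dennis simplex-lattice reference directions.

    All vectors (i1, ..., im) / divisions with non-negative integers
    summing to ``divisions``; count = C(divisions + m - 1, m - 1).
    """
    if n_obj < 2:
        raise ValueError("reference points require >= 2 objectives")
    if divisions < 1:
        raise ValueError("divisions must be >= 1")
    points = []

    def recurse(prefix: list[int], remaining: int, depth: int) -> None:
        if depth == n_obj - 1:
            points.append(prefix + [remaining])
            return
        for i in range(remaining + 1):
            recurse(prefix + [i], remaining - i, depth + 1)

    recurse([], divisions, 0)
    refs = np.asarray(points, dtype=np.float64) / divisions
    assert refs.shape[0] == comb(divisions + n_obj - 1, n_obj - 1)
    return refs


# ---------------------------------------------------------------------------
# subset encoding and variation operators
# ---------------------------------------------------------------------------

def _random_subset(n: int, J: int, rng: np.random.Generator) -> np.ndarray:
    return np.sort(rng.choice(n, size=J, replace=False))


def _exchange_crossover(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Swap each pair of non-shared members between two parents w.p. 1/2."""
    sa, sb = set(a.tolist()), set(b.tolist())
    only_a = np.array(sorted(sa - sb), dtype=np.intp)
    only_b = np.array(sorted(sb - sa), dtype=np.intp)
    shared = np.array(sorted(sa & sb), dtype=np.intp)
    k = only_a.size
    if k == 0:
        return a.copy(), b.copy()
    rng.shuffle(only_a)
    rng.shuffle(only_b)
    swap = rng.random(k) < 0.5
    child_a = np.where(swap, only_b, only_a)
    child_b = np.where(swap, only_a, only_b)
    return (
        np.sort(np.concatenate([shared, child_a])),
        np.sort(np.concatenate([shared, child_b])),
    )


def _replacement_mutation(
    x: np.ndarray, n: int, rng: np.random.Generator, rate: float | None = None
) -> np.ndarray:
    """Replace each member w.p. ``rate`` (default 1/J) by a random non-member."""
    J = x.size
    if J == n:
        return x.copy()
    if rate is None:
        rate = 1.0 / J
    out = x.copy()
    member = np.zeros(n, dtype=bool)
    member[out] = True
    for i in range(J):
        if rng.random() < rate:
            while True:
                cand = int(rng.integers(n))
                if not member[cand]:
                    break
            member[out[i]] = False
            member[cand] = True
            out[i] = cand
    return np.sort(out)


def _evaluate_batch(
    problem: SelectionProblem, decisions: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    objs = np.empty((len(decisions), problem.n_obj))
    viol = np.empty(len(decisions))
    for i, x in enumerate(decisions):
        obj, ineq, eq = problem.evaluate(x)
        objs[i] = obj
        viol[i] = np.clip(ineq, 0, None).sum() + np.abs(eq).sum()
    return objs, viol


# ---------------------------------------------------------------------------
# single-objective search
# ---------------------------------------------------------------------------

def subset_ga(
    problem: SelectionProblem,
    pop_size: int = 50,
    generations: int = 200,
    rng: np.random.Generator | None = None,
    crossover_prob: float = 0.9,
) -> SelectionSolution:
    """Elitist genetic algorithm for single-objective subset problems.

    Binary tournament on (violation, objective), exchange crossover,
    single-member replacement mutation; the best-ever feasible-first
    solution is tracked and returned.
    """
    if problem.n_obj != 1:
        raise ValueError("subset_ga handles single-objective problems")
    rng = rng if rng is not None else np.random.default_rng()
    n, J = problem.n_candidates, problem.subset_size
    if J == n:
        x = np.arange(n, dtype=np.intp)
        obj, _, _ = problem.evaluate(x)
        return SelectionSolution(x[None, :], obj[None, :])
    pop = [_random_subset(n, J, rng) for _ in range(pop_size)]
    objs, viol = _evaluate_batch(problem, pop)
    key = lambda i: (viol[i], objs[i, 0])
    best_i = min(range(pop_size), key=key)
    best_x, best_obj, best_viol = pop[best_i].copy(), objs[best_i].copy(), viol[best_i]

    for _ in range(generations):
        children: list[np.ndarray] = []
        while len(children) < pop_size:
            i1, i2 = rng.integers(pop_size, size=2)
            p1 = i1 if key(i1) <= key(i2) else i2
            i3, i4 = rng.integers(pop_size, size=2)
            p2 = i3 if key(i3) <= key(i4) else i4
            if rng.random() < crossover_prob:
                c1, c2 = _exchange_crossover(pop[p1], pop[p2], rng)
            else:
                c1, c2 = pop[p1].copy(), pop[p2].copy()
            children.append(_replacement_mutation(c1, n, rng))
            if len(children) < pop_size:
                children.append(_replacement_mutation(c2, n, rng))
        c_objs, c_viol = _evaluate_batch(problem, children)
        # elitism: carry the best-ever into the next population
        pop, objs, viol = children, c_objs, c_viol
        worst_i = max(range(pop_size), key=key)
        pop[worst_i], objs[worst_i], viol[worst_i] = (
            best_x.copy(),
            best_obj.copy(),
            best_viol,
        )
        cand = min(range(pop_size), key=key)
        if (viol[cand], objs[cand, 0]) < (best_viol, best_obj[0]):
            best_x, best_obj, best_viol = (
                pop[cand].copy(),
                objs[cand].copy(),
                viol[cand],
            )
    return SelectionSolution(best_x[None, :], best_obj[None, :], np.array([best_viol]))


def hill_climber_swap(
    problem: SelectionProblem, x0: np.ndarray
) -> tuple[np.ndarray, float]:
    """Steepest-descent over the 1-swap neighborhood of a subset.

    Repeatedly applies the single best member-for-non-member exchange
    until no swap improves the objective; each accepted step strictly
    improves.
    """
    if problem.n_obj != 1:
        raise ValueError("hill climber handles single-objective problems")
    x = problem.check_decision(x0)
    n = problem.n_candidates
    best = float(problem.objectives(x)[0])
    improved = True
    while improved:
        improved = False
        members = set(x.tolist())
        best_swap = None
        for pos in range(x.size):
            for cand in range(n):
                if cand in members:
                    continue
                trial = x.copy()
                trial[pos] = cand
                val = float(problem.objectives(np.sort(trial))[0])
                if val < best - 1e-12 and (best_swap is None or val < best_swap[2]):
                    best_swap = (pos, cand, val)
        if best_swap is not None:
            pos, cand, val = best_swap
            x[pos] = cand
            x = np.sort(x)
            best = val
            improved = True
    return x, best


# ---------------------------------------------------------------------------
# multi-objective search
# ---------------------------------------------------------------------------

def _tournament_rank_crowd(
    rank: np.ndarray, crowd: np.ndarray, rng: np.random.Generator
) -> int:
    i, j = rng.integers(rank.size, size=2)
    if rank[i] < rank[j]:
        return int(i)
    if rank[j] < rank[i]:
        return int(j)
    if crowd[i] > crowd[j]:
        return int(i)
    if crowd[j] > crowd[i]:
        return int(j)
    return int(min(i, j))


def _dedup_front(
    decisions: list[np.ndarray], objs: np.ndarray
) -> SelectionSolution:
    seen = {}
    for i, x in enumerate(decisions):
        seen.setdefault(tuple(x.tolist()), i)
    idx = sorted(seen.values())
    return SelectionSolution(
        np.stack([decisions[i] for i in idx]), objs[idx]
    )


def _moea_offspring(
    pop: list[np.ndarray],
    parent_picker,
    n: int,
    rng: np.random.Generator,
    crossover_prob: float,
) -> list[np.ndarray]:
    children: list[np.ndarray] = []
    while len(children) < len(pop):
        p1 = parent_picker()
        p2 = parent_picker()
        if rng.random() < crossover_prob:
            c1, c2 = _exchange_crossover(pop[p1], pop[p2], rng)
        else:
            c1, c2 = pop[p1].copy(), pop[p2].copy()
        children.append(_replacement_mutation(c1, n, rng))
        if len(children) < len(pop):
            children.append(_replacement_mutation(c2, n, rng))
    return children


def nsga2(
    problem: SelectionProblem,
    pop_size: int = 100,
    generations: int = 200,
    rng: np.random.Generator | None = None,
    crossover_prob: float = 0.9,
) -> SelectionSolution:
    """NSGA-II over the subset encoding; returns the final front 0.

    Standard generational loop: binary tournament on (rank, crowding),
    exchange crossover, replacement mutation, then (rank, crowding)
    survival over the merged parent+offspring population.
    """
    if problem.n_obj < 2:
        raise ValueError("nsga2 requires >= 2 objectives")
    rng = rng if rng is not None else np.random.default_rng()
    n, J = problem.n_candidates, problem.subset_size
    pop = [_random_subset(n, J, rng) for _ in range(pop_size)]
    objs, _ = _evaluate_batch(problem, pop)
    rank = nondominated_sort(objs)
    crowd = np.zeros(pop_size)
    for r in np.unique(rank):
        sel = np.flatnonzero(rank == r)
        crowd[sel] = crowding_distance(objs[sel])

    for _ in range(generations):
        picker = lambda: _tournament_rank_crowd(rank, crowd, rng)
        children = _moea_offspring(pop, picker, n, rng, crossover_prob)
        c_objs, _ = _evaluate_batch(problem, children)
        all_pop = pop + children
        all_objs = np.vstack([objs, c_objs])
        all_rank = nondominated_sort(all_objs)
        # survival: fill by fronts, truncate last by crowding
        survivors: list[int] = []
        for r in range(all_rank.max() + 1):
            front = np.flatnonzero(all_rank == r)
            if len(survivors) + front.size <= pop_size:
                survivors.extend(front.tolist())
            else:
                cd = crowding_distance(all_objs[front])
                order = np.argsort(-cd, kind="stable")
                need = pop_size - len(survivors)
                survivors.extend(front[order[:need]].tolist())
                break
        pop = [all_pop[i] for i in survivors]
        objs = all_objs[survivors]
        rank = nondominated_sort(objs)
        crowd = np.zeros(pop_size)
        for r in np.unique(rank):
            sel = np.flatnonzero(rank == r)
            crowd[sel] = crowding_distance(objs[sel])

    front = np.flatnonzero(rank == 0)
    return _dedup_front([pop[i] for i in front], objs[front])


# -- NSGA-III survival ------------------------------------------------------

def _asf(F: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Achievement scalarizing function of translated objectives."""
    w = np.where(weights == 0, 1e-6, weights)
    return (F / w).max(axis=1)


def _normalize(F: np.ndarray) -> np.ndarray:
    """NSGA-III adaptive normalization: ideal point + extreme-point intercepts."""
    ideal = F.min(axis=0)
    T = F - ideal
    d = F.shape[1]
    extremes = np.empty(d, dtype=np.intp)
    for j in range(d):
        w = np.full(d, 1e-6)
        w[j] = 1.0
        extremes[j] = int(np.argmin(_asf(T, w)))
    intercepts = None
    E = T[extremes]
    try:
        if np.linalg.matrix_rank(E) == d:
            plane = np.linalg.solve(E, np.ones(d))
            with np.errstate(divide="ignore"):
                a = 1.0 / plane
            if np.all(np.isfinite(a)) and np.all(a > 1e-12):
                intercepts = a
    except np.linalg.LinAlgError:
        intercepts = None
    if intercepts is None:
        intercepts = T.max(axis=0)
    intercepts = np.where(intercepts <= 1e-12, 1.0, intercepts)
    return T / intercepts


def _associate(N: np.ndarray, refs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reference direction per point by perpendicular distance."""
    norms = np.linalg.norm(refs, axis=1)
    unit = refs / norms[:, None]
    proj = N @ unit.T  # (m, nref) scalar projections
    # squared perpendicular distance
    d2 = (N * N).sum(axis=1)[:, None] - proj**2
    niche = np.argmin(d2, axis=1)
    dist = np.sqrt(np.clip(d2[np.arange(N.shape[0]), niche], 0, None))
    return niche, dist


def _niching_survival(
    all_objs: np.ndarray,
    all_rank: np.ndarray,
    refs: np.ndarray,
    pop_size: int,
    rng: np.random.Generator,
) -> list[int]:
    """NSGA-III environmental selection: fill by fronts, niche the last."""
    survivors: list[int] = []
    last_front: np.ndarray | None = None
    for r in range(all_rank.max() + 1):
        front = np.flatnonzero(all_rank == r)
        if len(survivors) + front.size <= pop_size:
            survivors.extend(front.tolist())
            if len(survivors) == pop_size:
                return survivors
        else:
            last_front = front
            break
    assert last_front is not None
    considered = np.array(survivors + last_front.tolist(), dtype=np.intp)
    N = _normalize(all_objs[considered])
    niche_of, dist = _associate(N, refs)
    n_surv = len(survivors)
    counts = np.zeros(refs.shape[0], dtype=np.intp)
    for k in niche_of[:n_surv]:
        counts[k] += 1
    # candidates from the last front, positions n_surv.. in `considered`
    pending = {
        i: (niche_of[n_surv + i], dist[n_surv + i])
        for i in range(last_front.size)
    }
    need = pop_size - n_surv
    active = set(range(refs.shape[0]))
    chosen: list[int] = []
    while len(chosen) < need:
        active_list = sorted(active)
        min_count = min(counts[j] for j in active_list)
        min_niches = [j for j in active_list if counts[j] == min_count]
        jbar = int(min_niches[rng.integers(len(min_niches))])
        members = [i for i, (nj, _) in pending.items() if nj == jbar]
        if not members:
            active.discard(jbar)
            continue
        if counts[jbar] == 0:
            pick = min(members, key=lambda i: (pending[i][1], i))
        else:
            pick = members[int(rng.integers(len(members)))]
        chosen.append(pick)
        counts[jbar] += 1
        del pending[pick]
    return survivors + [int(last_front[i]) for i in chosen]


def nsga3(
    problem: SelectionProblem,
    pop_size: int = 100,
    generations: int = 200,
    refs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    crossover_prob: float = 0.9,
) -> SelectionSolution:
    """NSGA-III over the subset encoding; returns the final front 0.

    Survival replaces crowding distance with reference-point niching:
    normalize by the ideal point and extreme-point intercepts, associate
    each member to its nearest reference direction by perpendicular
    distance, and fill under-represented niches from the split front.
    """
    if problem.n_obj < 2:
        raise ValueError("nsga3 requires >= 2 objectives")
    rng = rng if rng is not None else np.random.default_rng()
    if refs is None:
        divisions = 12 if problem.n_obj == 3 else max(pop_size // problem.n_obj, 4)
        refs = das_dennis_reference_points(problem.n_obj, divisions)
    refs = np.atleast_2d(np.asarray(refs, dtype=np.float64))
    if refs.size == 0:
        raise ValueError("empty reference point set")
    n, J = problem.n_candidates, problem.subset_size
    pop = [_random_subset(n, J, rng) for _ in range(pop_size)]
    objs, _ = _evaluate_batch(problem, pop)

    for _ in range(generations):
        picker = lambda: int(rng.integers(pop_size))  # NSGA-III random parents
        children = _moea_offspring(pop, picker, n, rng, crossover_prob)
        c_objs, _ = _evaluate_batch(problem, children)
        all_pop = pop + children
        all_objs = np.vstack([objs, c_objs])
        all_rank = nondominated_sort(all_objs)
        survivors = _niching_survival(all_objs, all_rank, refs, pop_size, rng)
        pop = [all_pop[i] for i in survivors]
        objs = all_objs[survivors]

    rank = nondominated_sort(objs)
    front = np.flatnonzero(rank == 0)
    return _dedup_front([pop[i] for i in front], objs[front])


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def exhaustive_pareto(problem: SelectionProblem) -> SelectionSolution:
    """Exact Pareto set by enumerating every feasible subset (tiny n only)."""
    n, J = problem.n_candidates, problem.subset_size
    decisions = [np.array(c, dtype=np.intp) for c in combinations(range(n), J)]
    objs, _ = _evaluate_batch(problem, decisions)
    rank = nondominated_sort(objs)
    front = np.flatnonzero(rank == 0)
    return _dedup_front([decisions[i] for i in front], objs[front])
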