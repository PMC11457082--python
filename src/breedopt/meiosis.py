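"""Recombination simulation and mating protocols.

Recombination is simulated in two steps.  Recombination probabilities
between successive markers are pre-computed from genetic map distances
with a map function and stored in a per-marker vector ``pxo``; the first
marker of every chromosome gets probability 0.5, which randomizes the
starting phase and enforces independent assortment between chromosomes.
A gamete is then sampled by drawing one uniform number per marker and
flipping the copied phase wherever the draw falls below ``pxo``.

Mating protocols cover self-crosses, two-/three-/four-way crosses and
doubled-haploid generation from each hybrid type.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import PhasedGenomeMatrix, map_function

__all__ = [
    "CrossoverProbabilities",
    "CrossPlan",
    "CROSS_KINDS",
    "compute_crossover_probs",
    "sample_gamete",
    "mate",
    "random_intermate",
]

CROSS_KINDS = {
    "self": 1,
    "two_way": 2,
    "three_way": 3,
    "four_way": 4,
    "dh_two_way": 2,
    "dh_three_way": 3,
    "dh_four_way": 4,
}


@dataclass(frozen=True)
class CrossoverProbabilities:
    """Per-marker crossover probabilities aligned to marker order."""

    pxo: np.ndarray
    chromosome_start_mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pxo", np.asarray(self.pxo, dtype=np.float64))
        object.__setattr__(
            self,
            "chromosome_start_mask",
            np.asarray(self.chromosome_start_mask, dtype=bool),
        )
        if self.pxo.shape != self.chromosome_start_mask.shape:
            raise ValueError("pxo and chromosome_start_mask length mismatch")
        if self.pxo.size:
            if np.any(self.pxo < 0) or np.any(self.pxo > 0.5):
                raise ValueError("crossover probabilities must lie in [0, 0.5]")
            if not np.all(self.pxo[self.chromosome_start_mask] == 0.5):
                raise ValueError("chromosome-start markers must have pxo = 0.5")


@dataclass(frozen=True)
class Cross:
    """One planned cross: parent indices, kind, and progeny count."""

    parents: tuple
    kind: str
    n_progeny: int

    def __post_init__(self) -> None:
        if self.kind not in CROSS_KINDS:
            raise ValueError(f"unknown cross kind {self.kind!r}")
        if len(self.parents) != CROSS_KINDS[self.kind]:
            raise ValueError(
                f"{self.kind} cross needs {CROSS_KINDS[self.kind]} parents, "
                f"got {len(self.parents)}"
            )
        if self.n_progeny < 1:
            raise ValueError("n_progeny must be >= 1")


CrossPlan = list  # list[Cross]


def compute_crossover_probs(
    genetic_pos: Sequence[float],
    chromosome: Sequence,
    kind: str = "haldane",
) -> CrossoverProbabilities:
    """Pre-compute per-marker crossover probabilities from map positions.

    For a marker that is not first on its chromosome,
    ``pxo[i] = map_function(kind, d[i] - d[i-1])``; chromosome-start
    markers get 0.5.
    """
    d = np.asarray(genetic_pos, dtype=np.float64)
    chromosome = np.asarray(chromosome, dtype=object)
    if d.shape != chromosome.shape:
        raise ValueError("genetic_pos and chromosome length mismatch")
    p = d.size
    start = np.ones(p, dtype=bool)
    if p:
        start[1:] = chromosome[1:] != chromosome[:-1]
    gaps = np.zeros(p)
    if p:
        gaps[1:] = d[1:] - d[:-1]
    if np.any(gaps[~start] < 0):
        raise ValueError("genetic positions decrease within a chromosome")
    pxo = np.where(start, 0.5, 0.0)
    interior = ~start
    pxo[interior] = map_function(kind, gaps[interior])
    return CrossoverProbabilities(pxo, start)


def crossover_probs_for(
    genomes: PhasedGenomeMatrix,
    gmap,
    kind: str = "haldane",
) -> CrossoverProbabilities:
    """Convenience: interpolate marker Morgans from a map, then pre-compute."""
    morgans = np.empty(genomes.n_markers)
    for lo, hi in genomes.chromosome_spans():
        morgans[lo:hi] = gmap.interpolate(
            genomes.chromosome[lo], genomes.physical_pos[lo:hi]
        )
    return compute_crossover_probs(morgans, genomes.chromosome, kind)


def _gametes(
    phased: np.ndarray, pxo: np.ndarray, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Sample ``n`` gametes from one diploid genome ``(p, 2)``; vectorized."""
    p = phased.shape[0]
    u = rng.random((n, p))
    # current phase flips where u < pxo; cumulative xor gives the phase track
    flips = u < pxo[None, :]
    phase = np.bitwise_xor.accumulate(flips, axis=1).astype(np.intp)
    return phased[np.arange(p)[None, :], phase]


def sample_gamete(
    parent: PhasedGenomeMatrix,
    individual: int,
    pxo: CrossoverProbabilities,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one haploid allele vector from a diploid parent.

    One uniform draw per marker; the copied phase flips exactly where the
    draw is below the marker's crossover probability.
    """
    if parent.ploidy != 2:
        raise ValueError("gamete sampling requires diploid parents")
    if pxo.pxo.size != parent.n_markers:
        raise ValueError("pxo length does not match marker count")
    return _gametes(parent.alleles[individual], pxo.pxo, rng, 1)[0]


def _hybrid_gamete(
    alleles: np.ndarray,
    parents: tuple,
    pxo: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from the terminal hybrid of a 1-4 parent cross tree.

    self: gamete(A); two_way: gamete(A) x gamete(B) -> gamete(F1);
    three_way: gamete(F1(A,B)) x gamete(C) -> gamete; four_way uses two F1s.
    The caller pairs the returned gametes into progeny.
    """
    k = len(parents)
    if k == 1:
        return _gametes(alleles[parents[0]], pxo, rng, 1)[0]
    if k == 2:
        f1 = np.stack(
            [
                _gametes(alleles[parents[0]], pxo, rng, 1)[0],
                _gametes(alleles[parents[1]], pxo, rng, 1)[0],
            ],
            axis=1,
        )
        return _gametes(f1, pxo, rng, 1)[0]
    if k == 3:
        f1 = np.stack(
            [
                _gametes(alleles[parents[0]], pxo, rng, 1)[0],
                _gametes(alleles[parents[1]], pxo, rng, 1)[0],
            ],
            axis=1,
        )
        hybrid = np.stack(
            [
                _gametes(f1, pxo, rng, 1)[0],
                _gametes(alleles[parents[2]], pxo, rng, 1)[0],
            ],
            axis=1,
        )
        return _gametes(hybrid, pxo, rng, 1)[0]
    f1a = np.stack(
        [
            _gametes(alleles[parents[0]], pxo, rng, 1)[0],
            _gametes(alleles[parents[1]], pxo, rng, 1)[0],
        ],
        axis=1,
    )
    f1b = np.stack(
        [
            _gametes(alleles[parents[2]], pxo, rng, 1)[0],
            _gametes(alleles[parents[3]], pxo, rng, 1)[0],
        ],
        axis=1,
    )
    hybrid = np.stack(
        [_gametes(f1a, pxo, rng, 1)[0], _gametes(f1b, pxo, rng, 1)[0]], axis=1
    )
    return _gametes(hybrid, pxo, rng, 1)[0]


def mate(
    parents: PhasedGenomeMatrix,
    plan: CrossPlan,
    pxo: CrossoverProbabilities,
    rng: np.random.Generator,
    name_prefix: str = "prog",
) -> PhasedGenomeMatrix:
    """Execute a cross plan and return the progeny genome matrix.

    Two-way progeny receive one gamete from each parent; selfs two gametes
    from the same parent; three-/four-way crosses route through simulated
    F1 hybrids; ``dh_*`` kinds double a single gamete from the terminal
    hybrid into both phases.
    """
    if parents.ploidy != 2:
        raise ValueError("mating protocols require diploid parents")
    alleles = parents.alleles
    n_par = parents.n_individuals
    out = []
    names = []
    counter = 0
    for cross in plan:
        for i in cross.parents:
            if not 0 <= i < n_par:
                raise IndexError(f"parent index {i} out of range")
        for _ in range(cross.n_progeny):
            if cross.kind == "self":
                a = _gametes(alleles[cross.parents[0]], pxo.pxo, rng, 2)
                child = a.T
            elif cross.kind == "two_way":
                g0 = _gametes(alleles[cross.parents[0]], pxo.pxo, rng, 1)[0]
                g1 = _gametes(alleles[cross.parents[1]], pxo.pxo, rng, 1)[0]
                child = np.stack([g0, g1], axis=1)
            elif cross.kind in ("three_way", "four_way"):
                if cross.kind == "three_way":
                    f1 = np.stack(
                        [
                            _gametes(alleles[cross.parents[0]], pxo.pxo, rng, 1)[0],
                            _gametes(alleles[cross.parents[1]], pxo.pxo, rng, 1)[0],
                        ],
                        axis=1,
                    )
                    g0 = _gametes(f1, pxo.pxo, rng, 1)[0]
                    g1 = _gametes(alleles[cross.parents[2]], pxo.pxo, rng, 1)[0]
                else:
                    f1a = np.stack(
                        [
                            _gametes(alleles[cross.parents[0]], pxo.pxo, rng, 1)[0],
                            _gametes(alleles[cross.parents[1]], pxo.pxo, rng, 1)[0],
                        ],
                        axis=1,
                    )
                    f1b = np.stack(
                        [
                            _gametes(alleles[cross.parents[2]], pxo.pxo, rng, 1)[0],
                            _gametes(alleles[cross.parents[3]], pxo.pxo, rng, 1)[0],
                        ],
                        axis=1,
                    )
                    g0 = _gametes(f1a, pxo.pxo, rng, 1)[0]
                    g1 = _gametes(f1b, pxo.pxo, rng, 1)[0]
                child = np.stack([g0, g1], axis=1)
            else:  # dh_*
                g = _hybrid_gamete(alleles, cross.parents, pxo.pxo, rng)
                child = np.stack([g, g], axis=1)
            out.append(child)
            names.append(f"{name_prefix}{counter}")
            counter += 1
    if not out:
        empty = np.zeros((0, parents.n_markers, 2), dtype=np.int8)
        return PhasedGenomeMatrix(
            empty, [], parents.marker_ids, parents.chromosome, parents.physical_pos
        )
    return PhasedGenomeMatrix(
        np.stack(out, axis=0),
        names,
        parents.marker_ids,
        parents.chromosome,
        parents.physical_pos,
    )


def random_intermate(
    parents: PhasedGenomeMatrix,
    n_crosses: int,
    progeny_per_cross: int,
    pxo: CrossoverProbabilities,
    rng: np.random.Generator,
    name_prefix: str = "prog",
) -> tuple[PhasedGenomeMatrix, np.ndarray]:
    """Random biparental intermating with family labels.

    Samples ``n_crosses`` distinct unordered parent pairs uniformly (a
    parent may recur across pairs); each pair yields ``progeny_per_cross``
    two-way progeny labelled with their cross index.
    """
    n = parents.n_individuals
    if n < 2 and n_crosses > 0:
        raise ValueError("random intermating needs >= 2 parents")
    max_pairs = n * (n - 1) // 2
    if n_crosses > max_pairs:
        raise ValueError(
            f"n_crosses={n_crosses} exceeds {max_pairs} distinct pairs"
        )
    pairs: list[tuple[int, int]] = []
    seen = set()
    while len(pairs) < n_crosses:
        i, j = rng.choice(n, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    plan = [Cross((i, j), "two_way", progeny_per_cross) for i, j in pairs]
    progeny = mate(parents, plan, pxo, rng, name_prefix=name_prefix)
    family = np.repeat(np.arange(n_crosses), progeny_per_cross)
    return progeny, family
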