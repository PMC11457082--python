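"""Synthetic founder panels, genetic maps, and trait models.

Emulates the empirical inputs the simulations need — a diversity panel
of biallelic SNPs with common minor alleles and interpolated genetic
positions — so every pipeline runs end-to-end without external data.
Founders are drawn at linkage equilibrium: marker allele frequencies are
uniform on [min_maf, 1 - min_maf] and haplotype alleles are Bernoulli
draws at that frequency; burn-in generations of mating build linkage
disequilibrium downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GeneticMap, PhasedGenomeMatrix
from .model import LinearGenomicModel, sample_trait_effects

__all__ = [
    "FounderSpec",
    "generate_founders",
    "scenario_trait_model",
    "write_fixture_files",
]

# two competing quantitative traits: unit effect variances, negative
# cross-trait covariance, intercepts 10 and 25
TRAIT_COVARIANCE = np.array([[1.0, -0.4], [-0.4, 1.0]])
TRAIT_INTERCEPTS = np.array([10.0, 25.0])


@dataclass(frozen=True)
class FounderSpec:
    """Shape of a synthetic founder panel.

    Defaults emulate a diversity panel of 942 individuals scored at
    2,000 common markers (minor allele frequency > 0.2) spread over 10
    chromosomes of 2 Morgans each.
    """

    n_individuals: int = 942
    n_markers: int = 2000
    n_chromosomes: int = 10
    min_maf: float = 0.2
    chromosome_length_morgan: float = 2.0

    def __post_init__(self) -> None:
        if self.n_markers % self.n_chromosomes:
            raise ValueError("n_markers must divide evenly across chromosomes")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must lie in [0, 0.5)")
        if self.n_individuals < 1 or self.n_chromosomes < 1:
            raise ValueError("need >= 1 individual and chromosome")


def generate_founders(
    spec: FounderSpec, rng: np.random.Generator, max_retries: int = 1000
) -> tuple[PhasedGenomeMatrix, GeneticMap]:
    """Sample a founder panel and matching genetic map.

    Per marker, an allele frequency is drawn uniform on
    [min_maf, 1 - min_maf] and haplotypes are Bernoulli at that
    frequency; markers whose realized minor allele frequency fails the
    strict ``min_maf`` threshold are resampled (bounded retries).
    Genetic positions are evenly spaced on [0, chromosome_length]; the
    map stores terminal knots plus a mid knot per chromosome, and
    physical positions are fixed-spacing integers.
    """
    n, p = spec.n_individuals, spec.n_markers
    per_chrom = p // spec.n_chromosomes
    freqs = rng.uniform(spec.min_maf, 1.0 - spec.min_maf, size=p)
    alleles = (rng.random((n, p, 2)) < freqs[None, :, None]).astype(np.int8)

    if spec.min_maf > 0:
        for _ in range(max_retries):
            maf = np.minimum(
                alleles.sum(axis=(0, 2)) / (2 * n),
                1 - alleles.sum(axis=(0, 2)) / (2 * n),
            )
            bad = np.flatnonzero(maf <= spec.min_maf)
            if bad.size == 0:
                break
            f_new = rng.uniform(spec.min_maf, 1.0 - spec.min_maf, size=bad.size)
            alleles[:, bad, :] = (
                rng.random((n, bad.size, 2)) < f_new[None, :, None]
            ).astype(np.int8)
        else:
            raise RuntimeError(
                "could not realize the requested minor allele frequencies; "
                "increase n_individuals or lower min_maf"
            )

    spacing = 100_000  # bp between adjacent markers
    chroms = np.repeat(
        [f"chr{c + 1}" for c in range(spec.n_chromosomes)], per_chrom
    ).astype(object)
    physical = np.tile(spacing * (1 + np.arange(per_chrom)), spec.n_chromosomes)
    marker_ids = [f"m{i}" for i in range(p)]
    names = [f"ind{i}" for i in range(n)]
    genomes = PhasedGenomeMatrix(alleles, names, marker_ids, chroms, physical)

    knots = {}
    length = spec.chromosome_length_morgan
    first_bp, last_bp = spacing, spacing * per_chrom
    mid_bp = (first_bp + last_bp) / 2
    for c in range(spec.n_chromosomes):
        knots[f"chr{c + 1}"] = (
            np.array([first_bp, mid_bp, last_bp], dtype=np.float64),
            np.array([0.0, length / 2, length]),
        )
    return genomes, GeneticMap(knots)


def scenario_trait_model(
    n_markers: int, rng: np.random.Generator
) -> LinearGenomicModel:
    """Two negatively correlated additive traits.

    Marker effects are i.i.d. MVN(0, [[1, -0.4], [-0.4, 1]]) rows; the
    intercepts are 10 and 25.
    """
    if n_markers < 2:
        raise ValueError("need >= 2 markers")
    return sample_trait_effects(
        n_markers, TRAIT_COVARIANCE, TRAIT_INTERCEPTS, rng
    )


def write_fixture_files(directory, rng: np.random.Generator | None = None):
    """Write a small VCF + genetic-map CSV + model CSVs for I/O tests.

    Returns the in-memory objects the files encode, so callers can check
    round trips: (genomes, genetic_map, model, paths-dict).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = FounderSpec(
        n_individuals=4, n_markers=6, n_chromosomes=2, min_maf=0.0,
        chromosome_length_morgan=1.0,
    )
    genomes, gmap = generate_founders(spec, rng)
    model = scenario_trait_model(spec.n_markers, rng)

    vcf_path = directory / "fixture.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in genomes.chromosomes:
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genomes.individual_names)
    )
    for k in range(genomes.n_markers):
        gts = "\t".join(
            f"{genomes.alleles[i, k, 0]}|{genomes.alleles[i, k, 1]}"
            for i in range(genomes.n_individuals)
        )
        lines.append(
            f"{genomes.chromosome[k]}\t{genomes.physical_pos[k]}\t"
            f"{genomes.marker_ids[k]}\tA\tT\t.\tPASS\t.\tGT\t{gts}"
        )
    vcf_path.write_text("\n".join(lines) + "\n")

    map_path = directory / "fixture_map.csv"
    gmap.to_csv(map_path)
    eff_path = directory / "fixture_effects.csv"
    int_path = directory / "fixture_intercepts.csv"
    model.to_csv(eff_path, int_path)
    paths = {
        "vcf": vcf_path,
        "map": map_path,
        "effects": eff_path,
        "intercepts": int_path,
    }
    return genomes, gmap, model, paths
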