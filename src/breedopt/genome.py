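"""Phased genome storage, genetic maps and map functions, kinship, and I/O.

Genomes are held as dense three-dimensional integer arrays indexed by
(individual, marker, chromosome phase) with biallelic coding {0, 1}.
Genetic maps pair physical base-pair positions with genetic positions in
Morgans and interpolate between knots with a linear spline.  The Haldane
and Kosambi map functions convert genetic distance to recombination
fraction and back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PhasedGenomeMatrix",
    "GeneticMap",
    "MAP_FUNCTIONS",
    "map_function",
    "inverse_map_function",
    "haldane",
    "haldane_inverse",
    "kosambi",
    "kosambi_inverse",
    "read_vcf",
    "write_hdf5",
    "read_hdf5",
    "concat_individuals",
    "allele_frequency",
    "minor_allele_frequency",
    "filter_maf",
    "ibs_kinship",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhasedGenomeMatrix:
    """Phased biallelic genotypes for a set of individuals.

    Parameters
    ----------
    alleles
        ``(n_individuals, n_markers, ploidy)`` small-integer array with
        allele codes in ``{0, 1}``.
    individual_names
        One identifier per individual.
    marker_ids
        One identifier per marker.
    chromosome
        Per-marker chromosome label.  Markers must be grouped by
        chromosome with non-decreasing physical position inside a group.
    physical_pos
        Per-marker physical position in base pairs (1-based, VCF style).
    """

    alleles: np.ndarray
    individual_names: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray
    physical_pos: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3:
            raise ValueError("alleles must be (individual, marker, phase)")
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.physical_pos = np.asarray(self.physical_pos, dtype=np.int64)
        self.individual_names = list(self.individual_names)
        self.marker_ids = list(self.marker_ids)
        n, p, _ = self.alleles.shape
        if len(self.individual_names) != n:
            raise ValueError("individual_names length mismatch")
        if len(self.marker_ids) != p or len(self.chromosome) != p or len(self.physical_pos) != p:
            raise ValueError("marker metadata length mismatch")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must be 0 or 1 (biallelic)")
        self._check_sorted()

    def _check_sorted(self) -> None:
        # chromosomes must form contiguous blocks with non-decreasing bp
        seen: set = set()
        prev = None
        prev_pos = -1
        for c, bp in zip(self.chromosome, self.physical_pos):
            if c != prev:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} is not contiguous")
                seen.add(c)
                prev, prev_pos = c, bp
            elif bp < prev_pos:
                raise ValueError(
                    f"markers not sorted by position on chromosome {c!r}"
                )
            else:
                prev_pos = bp

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    @property
    def ploidy(self) -> int:
        return self.alleles.shape[2]

    @property
    def dosage(self) -> np.ndarray:
        """``(n, p)`` count of allele 1 per individual and marker."""
        return self.alleles.sum(axis=2, dtype=np.int64)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in storage order (unique, order-preserving)."""
        out, seen = [], set()
        for c in self.chromosome:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def chromosome_spans(self) -> list[tuple[int, int]]:
        """Half-open marker index ranges ``[start, stop)`` per chromosome."""
        spans = []
        start = 0
        for i in range(1, self.n_markers + 1):
            if i == self.n_markers or self.chromosome[i] != self.chromosome[start]:
                spans.append((start, i))
                start = i
        return spans

    def take_individuals(self, idx: Sequence[int]) -> "PhasedGenomeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return PhasedGenomeMatrix(
            self.alleles[idx],
            [self.individual_names[i] for i in idx],
            self.marker_ids,
            self.chromosome,
            self.physical_pos,
        )

    def take_markers(self, idx: Sequence[int]) -> "PhasedGenomeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return PhasedGenomeMatrix(
            self.alleles[:, idx],
            self.individual_names,
            [self.marker_ids[i] for i in idx],
            self.chromosome[idx],
            self.physical_pos[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhasedGenomeMatrix):
            return NotImplemented
        return (
            self.alleles.shape == other.alleles.shape
            and np.array_equal(self.alleles, other.alleles)
            and self.individual_names == other.individual_names
            and self.marker_ids == other.marker_ids
            and all(a == b for a, b in zip(self.chromosome, other.chromosome))
            and np.array_equal(self.physical_pos, other.physical_pos)
        )


@dataclass
class GeneticMap:
    """Per-chromosome linear-spline map from base pairs to Morgans.

    ``knots`` maps a chromosome label to a pair of arrays
    ``(physical_pos_bp, genetic_pos_morgan)`` sorted by physical position
    with non-decreasing genetic position.
    """

    knots: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (bp, m) in self.knots.items():
            bp = np.asarray(bp, dtype=np.float64)
            m = np.asarray(m, dtype=np.float64)
            if bp.shape != m.shape or bp.ndim != 1:
                raise ValueError(f"malformed knots for chromosome {chrom!r}")
            order = np.argsort(bp, kind="stable")
            bp, m = bp[order], m[order]
            if np.any(np.diff(m) < 0):
                raise ValueError(
                    f"genetic positions decrease with physical position on {chrom!r}"
                )
            if np.any(m < 0):
                raise ValueError("genetic positions must be >= 0 Morgan")
            clean[chrom] = (bp, m)
        self.knots = clean

    def interpolate(self, chrom, physical) -> np.ndarray:
        """Genetic positions (Morgan) for query base-pair positions.

        Piecewise linear between knots; queries beyond the terminal knots
        are clamped to the terminal genetic position.
        """
        if chrom not in self.knots:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        bp, m = self.knots[chrom]
        if bp.size < 2:
            raise ValueError(f"chromosome {chrom!r} needs >= 2 map knots")
        return np.interp(np.asarray(physical, dtype=np.float64), bp, m)

    @classmethod
    def from_csv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path)
        required = {"chrom", "pos_bp", "pos_morgan"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"genetic map CSV missing columns: {sorted(missing)}")
        knots = {
            str(chrom): (g["pos_bp"].to_numpy(), g["pos_morgan"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=False)
        }
        return cls(knots)

    def to_csv(self, path) -> None:
        rows = [
            {"chrom": chrom, "pos_bp": int(b), "pos_morgan": g}
            for chrom, (bp, m) in self.knots.items()
            for b, g in zip(bp, m)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def haldane(d):
    """Haldane map function: r = (1 - exp(-2d)) / 2, d in Morgans."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("genetic distance must be >= 0")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def haldane_inverse(r):
    """Inverse Haldane: d = -ln(1 - 2r) / 2 for r in [0, 0.5)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return -0.5 * np.log(1.0 - 2.0 * r)


def kosambi(d):
    """Kosambi map function: r = tanh(2d) / 2, d in Morgans."""
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("genetic distance must be >= 0")
    return 0.5 * np.tanh(2.0 * d)


def kosambi_inverse(r):
    """Inverse Kosambi: d = arctanh(2r) / 2 for r in [0, 0.5)."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    return 0.5 * np.arctanh(2.0 * r)


MAP_FUNCTIONS = {
    "haldane": (haldane, haldane_inverse),
    "kosambi": (kosambi, kosambi_inverse),
}


def _lookup(kind: str):
    try:
        return MAP_FUNCTIONS[kind]
    except KeyError:
        raise ValueError(
            f"unknown map function {kind!r}; choose from {sorted(MAP_FUNCTIONS)}"
        ) from None


def map_function(kind: str, d):
    """Recombination fraction for genetic distance ``d`` (Morgans)."""
    return _lookup(kind)[0](d)


def inverse_map_function(kind: str, r):
    """Genetic distance (Morgans) for recombination fraction ``r``."""
    return _lookup(kind)[1](r)


# ---------------------------------------------------------------------------
# VCF and HDF5 I/O
# ---------------------------------------------------------------------------

def read_vcf(path, on_multiallelic: str = "error") -> PhasedGenomeMatrix:
    """Load phased biallelic genotypes from a VCF file.

    All genotypes must be phased (``|`` separated).  Multi-allelic records
    raise by default; pass ``on_multiallelic="skip"`` to drop them.
    Markers are re-sorted by (chromosome, position); chromosome order is
    order of first appearance in the file.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids, chroms, pos = [], [], [], []
    ploidy = None
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}"
            )
        geno = var.genotypes  # list of [a0, ..., phased]
        site = np.empty((len(samples), len(geno[0]) - 1), dtype=np.int8)
        for i, g in enumerate(geno):
            if not g[-1]:
                raise ValueError(
                    f"unphased genotype for sample {samples[i]} at {var.CHROM}:{var.POS}"
                )
            site[i] = g[:-1]
        if ploidy is None:
            ploidy = site.shape[1]
        elif site.shape[1] != ploidy:
            raise ValueError(f"mixed ploidy at {var.CHROM}:{var.POS}")
        cols.append(site)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
    vcf.close()
    if not cols:
        alleles = np.zeros((len(samples), 0, 2), dtype=np.int8)
        return PhasedGenomeMatrix(alleles, samples, [], np.array([], dtype=object), [])
    alleles = np.stack(cols, axis=1)
    chrom_rank = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    order = sorted(range(len(ids)), key=lambda i: (chrom_rank[chroms[i]], pos[i]))
    return PhasedGenomeMatrix(
        alleles[:, order],
        samples,
        [ids[i] for i in order],
        np.array([chroms[i] for i in order], dtype=object),
        [pos[i] for i in order],
    )


def write_hdf5(m: PhasedGenomeMatrix, path) -> None:
    """Serialize a phased genome matrix to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("alleles", data=m.alleles)
        str_dt = h5py.string_dtype(encoding="utf-8")
        f.create_dataset("individual_names", data=m.individual_names, dtype=str_dt)
        f.create_dataset("marker_ids", data=m.marker_ids, dtype=str_dt)
        f.create_dataset(
            "chromosome", data=[str(c) for c in m.chromosome], dtype=str_dt
        )
        f.create_dataset("physical_pos", data=m.physical_pos)


def read_hdf5(path) -> PhasedGenomeMatrix:
    """Load a phased genome matrix written by :func:`write_hdf5`."""
    with h5py.File(path, "r") as f:
        try:
            return PhasedGenomeMatrix(
                f["alleles"][()],
                [s.decode() for s in f["individual_names"][()]],
                [s.decode() for s in f["marker_ids"][()]],
                np.array([s.decode() for s in f["chromosome"][()]], dtype=object),
                f["physical_pos"][()],
            )
        except KeyError as exc:
            raise ValueError(f"malformed genome HDF5 file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# allele frequencies and kinship
# ---------------------------------------------------------------------------

def concat_individuals(parts: Sequence[PhasedGenomeMatrix]) -> PhasedGenomeMatrix:
    """Stack genome matrices over the individual axis (same marker set)."""
    if not parts:
        raise ValueError("nothing to concatenate")
    first = parts[0]
    for other in parts[1:]:
        if other.marker_ids != first.marker_ids:
            raise ValueError("marker sets differ between parts")
    names = [n for p in parts for n in p.individual_names]
    return PhasedGenomeMatrix(
        np.concatenate([p.alleles for p in parts], axis=0),
        names,
        first.marker_ids,
        first.chromosome,
        first.physical_pos,
    )


def allele_frequency(m: PhasedGenomeMatrix) -> np.ndarray:
    """Per-marker frequency of allele code 1."""
    if m.n_individuals == 0:
        raise ValueError("allele frequency undefined with zero individuals")
    return m.dosage.mean(axis=0) / m.ploidy


def minor_allele_frequency(m: PhasedGenomeMatrix) -> np.ndarray:
    """Per-marker minor allele frequency, min(f, 1 - f) in [0, 0.5]."""
    f = allele_frequency(m)
    return np.minimum(f, 1.0 - f)


def filter_maf(m: PhasedGenomeMatrix, threshold: float) -> PhasedGenomeMatrix:
    """Markers with minor allele frequency strictly above ``threshold``."""
    keep = np.flatnonzero(minor_allele_frequency(m) > threshold)
    return m.take_markers(keep)


def ibs_kinship(m: PhasedGenomeMatrix) -> np.ndarray:
    """Identity-by-state kinship: 1 - mean absolute dosage difference / ploidy.

    K[i, j] = 1 - (1 / (ploidy * p)) * sum_k |g_ik - g_jk| on dosage
    coding, giving a symmetric matrix in [0, 1] with unit diagonal.
    """
    if m.n_markers == 0:
        raise ValueError("kinship undefined with zero markers")
    D = m.dosage.astype(np.float64)
    # |a-b| = (a-b)^2 - 2*[|a-b| == 2] for dosages in {0,1,2}; the correction
    # counts opposite-homozygote marker pairs via indicator matrix products.
    sq = (D * D).sum(axis=1)
    cross = D @ D.T
    sum_sq_diff = sq[:, None] + sq[None, :] - 2.0 * cross
    if m.ploidy == 2:
        A0 = (D == 0).astype(np.float64)
        A2 = (D == 2).astype(np.float64)
        opp = A0 @ A2.T
        sum_abs = sum_sq_diff - 2.0 * (opp + opp.T)
    else:
        # general ploidy: direct pairwise loop (dosage range > {0,1,2})
        n = D.shape[0]
        sum_abs = np.empty((n, n))
        for i in range(n):
            sum_abs[i] = np.abs(D - D[i]).sum(axis=1)
    K = 1.0 - sum_abs / (m.ploidy * m.n_markers)
    # enforce exact symmetry against float round-off
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K
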