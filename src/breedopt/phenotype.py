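"""Multi-location phenotype simulation and entry-mean breeding values.

Phenotypes follow y_ijk = g_ik + l_jk + e_ijk: genotypic value plus a
location mean plus i.i.d. normal error with per-trait variance.  The
error variance is backsolved once from the founder-population genetic
variance so that a single location realizes a target narrow-sense
heritability, and is then held constant — heritability erodes as
selection removes genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeTable",
    "backsolve_error_variance",
    "simulate_phenotypes",
    "estimate_breeding_values",
    "realized_heritability",
]


@dataclass
class PhenotypeTable:
    """Balanced phenotype records: one value per (individual, location, trait).

    ``values`` is an ``(n, n_locations, t)`` array; metadata records the
    location means and per-trait error variances used in simulation.
    """

    values: np.ndarray
    individual_names: list[str]
    trait_names: list[str]
    location_means: np.ndarray
    error_variances: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (individual, location, trait)")
        n, L, t = self.values.shape
        if len(self.individual_names) != n:
            raise ValueError("individual_names length mismatch")
        if len(self.trait_names) != t:
            raise ValueError("trait_names length mismatch")
        self.location_means = np.asarray(self.location_means, dtype=np.float64)
        if self.location_means.shape != (L, t):
            raise ValueError("location_means must be (n_locations, n_traits)")
        if self.error_variances is not None:
            self.error_variances = np.asarray(self.error_variances, dtype=np.float64)
            if np.any(self.error_variances < 0):
                raise ValueError("error variances must be >= 0")

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n, L, t = self.values.shape
        rows = [
            {
                "individual": self.individual_names[i],
                "location": j,
                "trait": self.trait_names[k],
                "value": self.values[i, j, k],
            }
            for i in range(n)
            for j in range(L)
            for k in range(t)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def backsolve_error_variance(genetic_variance, h2):
    """Error variance giving a target single-location heritability.

    sigma2_e = sigma2_g * (1 - h2) / h2, so that
    sigma2_g / (sigma2_g + sigma2_e) = h2 at one location.
    """
    sigma2_g = np.asarray(genetic_variance, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    if np.any(h2 <= 0) or np.any(h2 > 1):
        raise ValueError("heritability must lie in (0, 1]")
    if np.any(sigma2_g < 0):
        raise ValueError("genetic variance must be >= 0")
    return sigma2_g * (1.0 - h2) / h2


def simulate_phenotypes(
    genotypic_values: np.ndarray,
    n_locations: int,
    error_variances,
    rng: np.random.Generator,
    location_means=None,
    individual_names: list[str] | None = None,
    trait_names: list[str] | None = None,
) -> PhenotypeTable:
    """Simulate y_ijk = g_ik + l_jk + e_ijk with e ~ N(0, sigma2_e,k)."""
    g = np.asarray(genotypic_values, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("genotypic_values must be (individuals, traits)")
    if n_locations < 1:
        raise ValueError("n_locations must be >= 1")
    n, t = g.shape
    sig2 = np.broadcast_to(
        np.asarray(error_variances, dtype=np.float64), (t,)
    ).copy()
    if np.any(sig2 < 0):
        raise ValueError("error variances must be >= 0")
    if location_means is None:
        lmeans = np.zeros((n_locations, t))
    else:
        lmeans = np.broadcast_to(
            np.asarray(location_means, dtype=np.float64), (n_locations, t)
        ).copy()
    noise = rng.standard_normal((n, n_locations, t)) * np.sqrt(sig2)[None, None, :]
    values = g[:, None, :] + lmeans[None, :, :] + noise
    return PhenotypeTable(
        values=values,
        individual_names=(
            individual_names if individual_names is not None else [f"i{i}" for i in range(n)]
        ),
        trait_names=(
            trait_names if trait_names is not None else [f"trait{j + 1}" for j in range(t)]
        ),
        location_means=lmeans,
        error_variances=sig2,
    )


def estimate_breeding_values(table: PhenotypeTable) -> np.ndarray:
    """Entry-mean estimated breeding values: mean across locations, per trait."""
    return table.values.mean(axis=1)


def realized_heritability(
    genotypic_values: np.ndarray, phenotypes: np.ndarray
) -> np.ndarray:
    """Per-trait Var(g) / Var(y) for phenotypes from a single location."""
    g = np.asarray(genotypic_values, dtype=np.float64)
    y = np.asarray(phenotypes, dtype=np.float64)
    if g.shape != y.shape or g.ndim != 2:
        raise ValueError("genotypic values and phenotypes must be matching (n, t)")
    if g.shape[0] < 2:
        raise ValueError("need >= 2 individuals to estimate variances")
    var_y = y.var(axis=0, ddof=1)
    if np.any(var_y == 0):
        raise ValueError("zero phenotypic variance")
    return g.var(axis=0, ddof=1) / var_y
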