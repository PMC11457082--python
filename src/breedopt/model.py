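"""Linear genomic models: trait intercepts plus marker effects.

The model is Y = XB + ZU with X fixed to an all-ones column, so each
trait has a single intercept.  Z carries allele-1 dosages (0/1/2) for
additive effects and, when dominance effects are present, a binary
heterozygote indicator (1 iff dosage == 1).  Breeding values use the
additive part only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "LinearGenomicModel",
    "sample_trait_effects",
]


@dataclass
class LinearGenomicModel:
    """Multi-trait linear genomic model.

    Parameters
    ----------
    intercepts
        Length-``t`` vector of trait intercepts.
    additive_effects
        ``(p, t)`` additive marker-effect matrix on dosage coding.
    dominance_effects
        Optional ``(p, t)`` dominance effects applied through the
        heterozygote indicator, or None for a strictly additive model.
    trait_names
        Length-``t`` trait labels.
    """

    intercepts: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray | None = None
    trait_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=np.float64))
        self.additive_effects = np.asarray(self.additive_effects, dtype=np.float64)
        if self.additive_effects.ndim != 2:
            raise ValueError("additive_effects must be (markers, traits)")
        t = self.intercepts.size
        if self.additive_effects.shape[1] != t:
            raise ValueError("trait count mismatch between intercepts and effects")
        if self.dominance_effects is not None:
            self.dominance_effects = np.asarray(
                self.dominance_effects, dtype=np.float64
            )
            if self.dominance_effects.shape != self.additive_effects.shape:
                raise ValueError("dominance_effects shape mismatch")
        if self.trait_names is None:
            self.trait_names = [f"trait{i + 1}" for i in range(t)]
        elif len(self.trait_names) != t:
            raise ValueError("trait_names length mismatch")

    @property
    def n_markers(self) -> int:
        return self.additive_effects.shape[0]

    @property
    def n_traits(self) -> int:
        return self.intercepts.size

    @property
    def has_dominance(self) -> bool:
        return self.dominance_effects is not None

    # -- prediction -------------------------------------------------------

    def _check_dosages(self, dosages: np.ndarray) -> np.ndarray:
        Z = np.asarray(dosages)
        if Z.ndim != 2 or Z.shape[1] != self.n_markers:
            raise ValueError(
                f"dosage matrix has {Z.shape[-1] if Z.ndim == 2 else '?'} markers, "
                f"model has {self.n_markers}"
            )
        return Z.astype(np.float64)

    def predict(self, dosages: np.ndarray) -> np.ndarray:
        """Genotypic values: intercept + additive + dominance (if present).

        The dominance design column is the heterozygote indicator
        I(dosage == 1).
        """
        Z = self._check_dosages(dosages)
        vals = self.intercepts[None, :] + Z @ self.additive_effects
        if self.dominance_effects is not None:
            Zd = (np.asarray(dosages) == 1).astype(np.float64)
            vals = vals + Zd @ self.dominance_effects
        return vals

    def breeding_values(self, dosages: np.ndarray) -> np.ndarray:
        """True breeding values: additive-only evaluation, dominance excluded."""
        Z = self._check_dosages(dosages)
        return self.intercepts[None, :] + Z @ self.additive_effects

    # -- serialization ----------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(effects, intercepts) long-format DataFrames."""
        rows = []
        for k in range(self.n_markers):
            for j, trait in enumerate(self.trait_names):
                row = {
                    "marker_id": f"m{k}",
                    "trait": trait,
                    "additive_effect": self.additive_effects[k, j],
                }
                if self.dominance_effects is not None:
                    row["dominance_effect"] = self.dominance_effects[k, j]
                rows.append(row)
        eff = pd.DataFrame(rows)
        inter = pd.DataFrame(
            {"trait": self.trait_names, "intercept": self.intercepts}
        )
        return eff, inter

    def to_csv(self, effects_path, intercepts_path) -> None:
        eff, inter = self.to_frames()
        eff.to_csv(effects_path, index=False)
        inter.to_csv(intercepts_path, index=False)

    @classmethod
    def from_frames(
        cls, effects: pd.DataFrame, intercepts: pd.DataFrame
    ) -> "LinearGenomicModel":
        for col in ("marker_id", "trait", "additive_effect"):
            if col not in effects.columns:
                raise ValueError(f"effects table missing column {col!r}")
        for col in ("trait", "intercept"):
            if col not in intercepts.columns:
                raise ValueError(f"intercept table missing column {col!r}")
        traits = list(intercepts["trait"])
        markers = list(dict.fromkeys(effects["marker_id"]))
        t_idx = {t: j for j, t in enumerate(traits)}
        m_idx = {m: k for k, m in enumerate(markers)}
        Ua = np.zeros((len(markers), len(traits)))
        has_dom = "dominance_effect" in effects.columns
        Ud = np.zeros_like(Ua) if has_dom else None
        seen_traits = set()
        for row in effects.itertuples(index=False):
            if row.trait not in t_idx:
                raise ValueError(
                    f"effect row for trait {row.trait!r} has no intercept row"
                )
            seen_traits.add(row.trait)
            Ua[m_idx[row.marker_id], t_idx[row.trait]] = row.additive_effect
            if has_dom:
                Ud[m_idx[row.marker_id], t_idx[row.trait]] = row.dominance_effect
        missing = set(traits) - seen_traits
        if missing and len(effects):
            raise ValueError(f"no effects given for traits {sorted(missing)}")
        return cls(
            intercepts=intercepts["intercept"].to_numpy(dtype=np.float64),
            additive_effects=Ua,
            dominance_effects=Ud,
            trait_names=[str(t) for t in traits],
        )

    @classmethod
    def from_csv(cls, effects_path, intercepts_path) -> "LinearGenomicModel":
        if not Path(intercepts_path).exists():
            raise ValueError(f"missing intercept table {intercepts_path}")
        return cls.from_frames(
            pd.read_csv(effects_path), pd.read_csv(intercepts_path)
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("intercepts", data=self.intercepts)
            f.create_dataset("additive_effects", data=self.additive_effects)
            if self.dominance_effects is not None:
                f.create_dataset("dominance_effects", data=self.dominance_effects)
            f.create_dataset(
                "trait_names",
                data=self.trait_names,
                dtype=h5py.string_dtype(encoding="utf-8"),
            )

    @classmethod
    def from_hdf5(cls, path) -> "LinearGenomicModel":
        with h5py.File(path, "r") as f:
            return cls(
                intercepts=f["intercepts"][()],
                additive_effects=f["additive_effects"][()],
                dominance_effects=(
                    f["dominance_effects"][()] if "dominance_effects" in f else None
                ),
                trait_names=[s.decode() for s in f["trait_names"][()]],
            )


def sample_trait_effects(
    n_markers: int,
    covariance: np.ndarray,
    intercepts: np.ndarray,
    rng: np.random.Generator,
    trait_names: list[str] | None = None,
) -> LinearGenomicModel:
    """Draw i.i.d. multivariate-normal marker effects for ``t`` traits.

    Each marker's effect row is drawn from MVN(0, covariance); the
    covariance must be symmetric positive semi-definite.
    """
    cov = np.asarray(covariance, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-10 * max(1.0, abs(eig.max())):
        raise ValueError("covariance must be positive semi-definite")
    effects = rng.multivariate_normal(
        mean=np.zeros(cov.shape[0]), cov=cov, size=n_markers, method="svd"
    )
    return LinearGenomicModel(
        intercepts=np.asarray(intercepts, dtype=np.float64),
        additive_effects=effects,
        trait_names=trait_names,
    )
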