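"""Domain containers shared across the pipeline.

Conventions: isotope values are per-mil (‰) δ13C / δ15N relative to the
usual standards; diet proportions live on the probability simplex; the
predation matrix is prey (rows) × predator (columns).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Controlled vocabulary of gut-content diet categories (the deposited
#: diet-composition table's 12 columns).
DIET_CATEGORIES = (
    "substrate",
    "unidentified.animal.matter",
    "plant",
    "periphyton",
    "phytoplankton",
    "zooplankton",
    "insect",
    "decapod",
    "mollusc",
    "fish",
    "detritus",
    "hirudinea",
)

ISOTOPES = ("d13C", "d15N")


class EmptyDietError(ValueError):
    """All FO×VO products are zero — feeding index undefined."""


@dataclass
class IsotopeSample:
    """One bulk tissue measurement for a taxon."""

    taxon: str
    d13C: float
    d15N: float
    c_to_n: float | None = None
    whole_body: bool = False
    lipid_corrected: bool = False

    def __post_init__(self) -> None:
        if self.c_to_n is not None and self.c_to_n <= 0:
            raise ValueError(f"C:N ratio must be positive, got {self.c_to_n}")
        if not (-45.0 <= self.d13C <= -5.0):
            warnings.warn(
                f"{self.taxon}: d13C={self.d13C}‰ outside the typical "
                "[-45, -5]‰ range",
                stacklevel=2,
            )
        if not (-10.0 <= self.d15N <= 25.0):
            warnings.warn(
                f"{self.taxon}: d15N={self.d15N}‰ outside the typical "
                "[-10, 25]‰ range",
                stacklevel=2,
            )


@dataclass
class SourceSpec:
    """A candidate prey/resource for a mixing model.

    Carries the source's isotopic summary (mean/SD per isotope), the
    trophic enrichment factor (TEF) mean/SD applied for the consumer the
    model belongs to, and elemental concentrations for the
    concentration-dependent mixture (1.0 = concentration-independent).
    """

    name: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    tef_d13C: float = 0.4
    tef_sd_d13C: float = 1.3
    tef_d15N: float = 0.0
    tef_sd_d15N: float = 0.0
    conc_C: float = 1.0
    conc_N: float = 1.0
    synthetic: bool = False  # e.g. the imputed "unknown producer" node

    def __post_init__(self) -> None:
        for attr in ("sd_d13C", "sd_d15N", "tef_sd_d13C", "tef_sd_d15N"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        for attr in ("conc_C", "conc_N"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_d13C, self.mean_d15N])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_d13C, self.sd_d15N])

    @property
    def tef_means(self) -> np.ndarray:
        return np.array([self.tef_d13C, self.tef_d15N])

    @property
    def tef_sds(self) -> np.ndarray:
        return np.array([self.tef_sd_d13C, self.tef_sd_d15N])

    @property
    def concs(self) -> np.ndarray:
        return np.array([self.conc_C, self.conc_N])


@dataclass
class GutRecord:
    """Volumetric composition of one gut over diet categories."""

    species: str
    gut_id: str
    composition: dict[str, float]

    def __post_init__(self) -> None:
        for cat, v in self.composition.items():
            if v < 0:
                raise ValueError(f"gut {self.gut_id}: negative proportion for {cat}")
        total = sum(self.composition.values())
        if total > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"gut {self.gut_id}: nonzero composition sums to {total}, not 1"
            )


@dataclass
class FeedingIndexTable:
    """Per-species FO / VO / FI summary over diet categories."""

    species: str
    n_guts: int
    fo: dict[str, float]
    vo: dict[str, float]
    fi: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        cats = sorted(self.fo)
        return pd.DataFrame(
            {
                "category": cats,
                "FO": [self.fo[c] for c in cats],
                "VO": [self.vo[c] for c in cats],
                "FI": [self.fi.get(c, 0.0) for c in cats],
            }
        )


@dataclass
class MixingProblem:
    """Consumer isotope observations plus its candidate sources."""

    consumer: str
    observations: np.ndarray  # (n_samples, 2) columns d13C, d15N
    sources: list[SourceSpec]

    def __post_init__(self) -> None:
        self.observations = np.atleast_2d(np.asarray(self.observations, float))
        if self.observations.shape[1] != 2:
            raise ValueError("observations must have two columns (d13C, d15N)")
        if self.observations.shape[0] < 1:
            raise ValueError("at least one consumer observation required")
        if self.observations.shape[0] < 3:
            warnings.warn(
                f"{self.consumer}: fewer than 3 isotope samples", stacklevel=2
            )
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names in mixing problem")

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


@dataclass
class McmcSettings:
    iterations: int = 30_000
    burn_in: int = 10_000
    chains: int = 4
    thin: int = 10
    seed: int = 0
    proposal_scale: float = 0.5
    sigma_prior_scale: float = 10.0  # half-Normal scale for residual SDs (‰)

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains required (Gelman-Rubin)")
        if self.thin < 1 or self.proposal_scale <= 0:
            raise ValueError("thin >= 1 and proposal_scale > 0 required")
        if (self.iterations - self.burn_in) // self.thin < 1:
            raise ValueError("settings leave zero post-thinning draws")

    @property
    def n_kept(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, by chain.

    p has shape (chains, draws, n_sources); sigma (chains, draws, 2).
    """

    source_names: list[str]
    p: np.ndarray
    sigma: np.ndarray
    acceptance_rate: np.ndarray  # per chain

    def __post_init__(self) -> None:
        if self.p.ndim != 3 or self.sigma.ndim != 3:
            raise ValueError("p and sigma must be 3-d (chains, draws, dim)")
        sums = self.p.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("stored diet proportions are off the simplex")
        if np.any(self.sigma <= 0):
            raise ValueError("stored residual SDs must be positive")

    @property
    def n_chains(self) -> int:
        return self.p.shape[0]

    def pooled_p(self) -> np.ndarray:
        return self.p.reshape(-1, self.p.shape[2])

    def pooled_sigma(self) -> np.ndarray:
        return self.sigma.reshape(-1, 2)


@dataclass
class PredationMatrix:
    """Prey (rows) × predator (columns) proportional-contribution matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate taxon labels in predation matrix")
        arr = self.values.to_numpy(float)
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("matrix entries must lie in [0, 1]")
        colsums = arr.sum(axis=0)
        bad = [
            c
            for c, s in zip(self.values.columns, colsums)
            if s > 0 and abs(s - 1.0) > 1e-6
        ]
        if bad:
            raise ValueError(f"positive consumer columns must sum to 1: {bad}")

    @property
    def prey(self) -> list[str]:
        return list(self.values.index)

    @property
    def predators(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class WebIndices:
    """Topology and overlap summary of one food web."""

    S: int
    L: int
    link_density: float
    connectance: float
    frac_basal: float
    frac_intermediate: float
    frac_top: float
    mean_pianka: float
    niche_breadth: dict[str, float]
    mean_niche_breadth: float
    isolated_nodes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "S": self.S,
                    "L": self.L,
                    "link_density": self.link_density,
                    "connectance": self.connectance,
                    "frac_basal": self.frac_basal,
                    "frac_intermediate": self.frac_intermediate,
                    "frac_top": self.frac_top,
                    "mean_pianka": self.mean_pianka,
                    "mean_niche_breadth": self.mean_niche_breadth,
                }
            ]
        )


__all__ = [
    "DIET_CATEGORIES",
    "ISOTOPES",
    "EmptyDietError",
    "IsotopeSample",
    "SourceSpec",
    "GutRecord",
    "FeedingIndexTable",
    "MixingProblem",
    "McmcSettings",
    "PosteriorDraws",
    "PredationMatrix",
    "WebIndices",
    "replace",
]
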