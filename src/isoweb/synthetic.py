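"""Synthetic reservoir communities with known ground truth.

The generator emulates the field data the pipeline was designed for:
isotopically distinct basal/prey sources with per-isotope mean and SD,
consumers whose δ13C/δ15N values are draws from the concentration-
dependent mixture forward model under known diet proportions and TEFs,
and per-gut volumetric compositions that are noisy around the true diet
(with random item drop-out, so frequency of occurrence is genuinely
below one).  Fixtures are written in the deposited CSV dialects.

Randomness: each stage consumes its own ``numpy`` generator seeded as
``default_rng([seed, stage])`` with stage 0 = community, 1 = isotopes,
2 = guts, and draws are taken in the documented order, so outputs are
byte-reproducible from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mixing import mixture_moments
from .types import DIET_CATEGORIES, GutRecord, IsotopeSample, MixingProblem, SourceSpec

#: Canonical source names, reused as the gut diet categories so the
#: category → source mapping is the identity on synthetic communities.
SOURCE_NAME_ROSTER = (
    "periphyton",
    "phytoplankton",
    "plant",
    "zooplankton",
    "insect",
    "decapod",
    "mollusc",
    "detritus",
    "fish",
    "substrate",
    "hirudinea",
    "unidentified.animal.matter",
)

SOURCE_FILE_COLUMNS = [
    "Sources",
    "Meand13C",
    "SDd13C",
    "Meand15N",
    "SDd15N",
    "tefd13C",
    "tefSDd13C",
    "tefd15N",
    "tefSDd15N",
    "conc13C",
    "conc15N",
]

DIET_TABLE_META_COLUMNS = [
    "Reservoir",
    "Latitude",
    "Longitude",
    "Sampling period",
    "Fish species",
    "Replicates",
]


@dataclass
class SimConfig:
    """Study conditions for one synthetic community."""

    n_sources: int = 3
    n_consumers: int = 5
    samples_per_taxon: int = 20
    gut_samples_per_consumer: int = 20
    #: (low, high) of the uniform ranges the source means are drawn from, ‰
    d13C_range: tuple[float, float] = (-32.0, -18.0)
    d15N_range: tuple[float, float] = (0.0, 12.0)
    #: within-taxon isotopic SD per isotope (d13C, d15N), ‰
    source_sd: tuple[float, float] = (0.7, 0.7)
    tef_d13C: tuple[float, float] = (0.4, 1.3)  # the generic δ13C TEF
    tef_d15N: tuple[float, float] = (3.4, 1.0)  # fish-consumer δ15N TEF
    residual_sd: tuple[float, float] = (0.5, 0.5)
    diet_concentration: float = 1.0
    gut_dropout: float = 0.3
    use_concentration_dependence: bool = False
    conc_C_range: tuple[float, float] = (0.2, 0.6)
    conc_N_range: tuple[float, float] = (0.02, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sources", "n_consumers", "samples_per_taxon",
                     "gut_samples_per_consumer"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("source_sd", "residual_sd"):
            if any(v < 0 for v in getattr(self, name)):
                raise ValueError(f"{name} entries must be >= 0")
        if self.tef_d13C[1] < 0 or self.tef_d15N[1] < 0:
            raise ValueError("TEF SDs must be >= 0")
        if self.n_sources > 1:
            for rng_ in (self.d13C_range, self.d15N_range):
                if not rng_[1] > rng_[0]:
                    raise ValueError(
                        "source mean ranges must be non-degenerate when "
                        "n_sources > 1"
                    )
        if not 0 <= self.gut_dropout < 1:
            raise ValueError("gut_dropout must be in [0, 1)")
        if self.diet_concentration <= 0:
            raise ValueError("diet_concentration must be positive")


@dataclass
class CommunityTruth:
    """Ground truth of one synthetic community."""

    source_specs: list[SourceSpec]
    consumer_names: list[str]
    true_diets: dict[str, np.ndarray]  # consumer -> simplex over its sources
    consumer_sources: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = {s.name for s in self.source_specs}
        for c, p in self.true_diets.items():
            if np.any(np.asarray(p) < 0) or abs(np.sum(p) - 1.0) > 1e-12:
                raise ValueError(f"true diet of {c} is not a simplex vector")
            extra = set(self.consumer_sources.get(c, [])) - names
            if extra:
                raise ValueError(f"{c}: unknown sources {extra}")

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.source_specs]


def _source_names(k: int) -> list[str]:
    names = list(SOURCE_NAME_ROSTER[: min(k, len(SOURCE_NAME_ROSTER))])
    names += [f"source{i + 1}" for i in range(len(SOURCE_NAME_ROSTER), k)]
    return names


def generate_community(config: SimConfig) -> CommunityTruth:
    """Draw source signatures and true consumer diets.

    δ13C means are drawn stratified — one source per equal-width bin of
    the configured range — so sources are isotopically distinct by
    construction (mirroring the pooling of indistinct taxa that precedes
    modelling); δ15N means are independent uniform.  Diets are
    Dirichlet(diet_concentration) over all sources.
    """
    rng = np.random.default_rng([config.seed, 0])
    k = config.n_sources
    lo, hi = config.d13C_range
    width = (hi - lo) / k
    specs = []
    for i, name in enumerate(_source_names(k)):
        mean_c = rng.uniform(lo + i * width, lo + (i + 1) * width)
        mean_n = rng.uniform(*config.d15N_range)
        conc = (1.0, 1.0)
        if config.use_concentration_dependence:
            conc = (rng.uniform(*config.conc_C_range), rng.uniform(*config.conc_N_range))
        specs.append(
            SourceSpec(
                name=name,
                mean_d13C=mean_c,
                sd_d13C=config.source_sd[0],
                mean_d15N=mean_n,
                sd_d15N=config.source_sd[1],
                tef_d13C=config.tef_d13C[0],
                tef_sd_d13C=config.tef_d13C[1],
                tef_d15N=config.tef_d15N[0],
                tef_sd_d15N=config.tef_d15N[1],
                conc_C=conc[0],
                conc_N=conc[1],
            )
        )
    consumers = [f"consumer{i + 1:02d}" for i in range(config.n_consumers)]
    alpha = np.full(k, config.diet_concentration)
    diets = {c: rng.dirichlet(alpha) if k > 1 else np.ones(1) for c in consumers}
    return CommunityTruth(
        source_specs=specs,
        consumer_names=consumers,
        true_diets=diets,
        consumer_sources={c: [s.name for s in specs] for c in consumers},
    )


def sample_isotopes(
    truth: CommunityTruth, config: SimConfig
) -> dict[str, list[IsotopeSample]]:
    """Draw per-taxon isotope samples from the forward model.

    Source taxa: Normal(mean, within-taxon SD) per isotope.  Consumers:
    Normal(mu_mix, sigma_mix) with the concentration-dependent mixture
    moments under the consumer's true diet, the sources' SD/TEF spread
    and the configured residual SD.
    """
    rng = np.random.default_rng([config.seed, 1])
    out: dict[str, list[IsotopeSample]] = {}
    m = config.samples_per_taxon
    for spec in truth.source_specs:
        c = rng.normal(spec.mean_d13C, spec.sd_d13C, m)
        n = rng.normal(spec.mean_d15N, spec.sd_d15N, m)
        out[spec.name] = [
            IsotopeSample(spec.name, float(ci), float(ni)) for ci, ni in zip(c, n)
        ]
    by_name = {s.name: s for s in truth.source_specs}
    for consumer in truth.consumer_names:
        sources = [by_name[n] for n in truth.consumer_sources[consumer]]
        mean, var = mixture_moments(
            truth.true_diets[consumer], sources, np.asarray(config.residual_sd)
        )
        sd = np.sqrt(var)
        c = rng.normal(mean[0], sd[0], m)
        n = rng.normal(mean[1], sd[1], m)
        out[consumer] = [
            IsotopeSample(consumer, float(ci), float(ni)) for ci, ni in zip(c, n)
        ]
    return out


def sample_guts(truth: CommunityTruth, config: SimConfig) -> list[GutRecord]:
    """Draw per-gut volumetric compositions around each true diet.

    Items are independently dropped from a gut with probability
    ``gut_dropout`` (at least one item always survives); the surviving
    diet is renormalised and the composition drawn from a Dirichlet with
    mean equal to it and total concentration ``diet_concentration`` per
    retained item, so larger concentrations shrink gut-to-gut noise.
    """
    rng = np.random.default_rng([config.seed, 2])
    records = []
    for consumer in truth.consumer_names:
        p = np.asarray(truth.true_diets[consumer], float)
        names = truth.consumer_sources[consumer]
        for g in range(config.gut_samples_per_consumer):
            keep = (rng.random(len(p)) >= config.gut_dropout) & (p > 0)
            if not keep.any():
                keep[int(np.argmax(p))] = True
            pk = p[keep] / p[keep].sum()
            alpha = config.diet_concentration * keep.sum() * pk
            gamma = rng.gamma(np.maximum(alpha, 1e-12))
            comp_kept = (
                gamma / gamma.sum()
                if gamma.sum() > 0
                else np.eye(len(pk))[int(np.argmax(pk))]
            )
            comp = dict.fromkeys(names, 0.0)
            for name, v in zip(np.asarray(names, object)[keep], comp_kept):
                comp[str(name)] = float(v)
            records.append(
                GutRecord(species=consumer, gut_id=f"{consumer}-g{g + 1:03d}",
                          composition=comp)
            )
    return records


def _empirical_source_table(
    truth: CommunityTruth, isotopes: dict[str, list[IsotopeSample]]
) -> pd.DataFrame:
    rows = []
    for spec in truth.source_specs:
        samples = isotopes[spec.name]
        c = np.array([s.d13C for s in samples])
        n = np.array([s.d15N for s in samples])
        rows.append(
            {
                "Sources": spec.name,
                "Meand13C": c.mean(),
                "SDd13C": c.std(ddof=1) if len(c) > 1 else 0.5,
                "Meand15N": n.mean(),
                "SDd15N": n.std(ddof=1) if len(n) > 1 else 0.5,
                "tefd13C": spec.tef_d13C,
                "tefSDd13C": spec.tef_sd_d13C,
                "tefd15N": spec.tef_d15N,
                "tefSDd15N": spec.tef_sd_d15N,
                "conc13C": spec.conc_C,
                "conc15N": spec.conc_N,
            }
        )
    return pd.DataFrame(rows, columns=SOURCE_FILE_COLUMNS)


def write_fixture(
    truth: CommunityTruth,
    isotopes: dict[str, list[IsotopeSample]],
    guts: list[GutRecord],
    outdir: str | Path,
    reservoir: str = "SYN",
) -> list[Path]:
    """Write the community in the deposited CSV dialects.

    Per consumer: ``<name>.csv`` (columns D13C, D15N) and
    ``<name>.Sources.csv`` (the 11 source columns, source mean/SD taken
    from the sampled source data).  Plus ``diet_composition.csv``
    (species-level mean volumetric proportions in the diet-table
    dialect), ``gut_records.csv`` (per-gut long format, which the GCA
    stage consumes since mean proportions alone cannot yield FO) and
    ``truth.json`` (ground truth for recovery tests).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    source_table = _empirical_source_table(truth, isotopes)
    by_source = source_table.set_index("Sources")
    for consumer in truth.consumer_names:
        samples = isotopes[consumer]
        df = pd.DataFrame(
            {"D13C": [s.d13C for s in samples], "D15N": [s.d15N for s in samples]}
        )
        p = outdir / f"{consumer}.csv"
        df.to_csv(p, index=False)
        written.append(p)
        src = by_source.loc[truth.consumer_sources[consumer]].reset_index()
        p = outdir / f"{consumer}.Sources.csv"
        src[SOURCE_FILE_COLUMNS].to_csv(p, index=False)
        written.append(p)

    # diet table: species-level mean VO in the 12-category dialect, with
    # extra columns appended for any non-roster source names
    diet_cols = list(DIET_CATEGORIES) + sorted(
        set(truth.source_names) - set(DIET_CATEGORIES)
    )
    rows = []
    for consumer in truth.consumer_names:
        mine = [g for g in guts if g.species == consumer]
        row = {
            "Reservoir": reservoir,
            "Latitude": "1°21.0'N",
            "Longitude": "103°49.11'E",
            "Sampling period": "synthetic",
            "Fish species": consumer,
            "Replicates": len(mine),
        }
        for cat in diet_cols:
            row[cat] = (
                sum(g.composition.get(cat, 0.0) for g in mine) / len(mine)
                if mine
                else 0.0
            )
        rows.append(row)
    diet = pd.DataFrame(rows, columns=DIET_TABLE_META_COLUMNS + diet_cols)
    p = outdir / "diet_composition.csv"
    diet.to_csv(p, index=False)
    written.append(p)

    gut_rows = [
        {"species": g.species, "gut_id": g.gut_id, "category": cat, "proportion": v}
        for g in guts
        for cat, v in sorted(g.composition.items())
    ]
    p = outdir / "gut_records.csv"
    pd.DataFrame(gut_rows, columns=["species", "gut_id", "category", "proportion"]).to_csv(
        p, index=False
    )
    written.append(p)

    payload = {
        "consumers": truth.consumer_names,
        "sources": truth.source_names,
        "true_diets": {
            c: dict(zip(truth.consumer_sources[c], map(float, truth.true_diets[c])))
            for c in truth.consumer_names
        },
    }
    p = outdir / "truth.json"
    p.write_text(json.dumps(payload, indent=1, sort_keys=True))
    written.append(p)
    return written


def reference_problem(seed: int = 7) -> tuple[MixingProblem, np.ndarray]:
    """The reference 3-source recovery problem: truth p = (0.7, 0.2, 0.1).

    Three well-separated sources with tight spreads and 30 consumer
    observations drawn from the forward model; used to verify that the
    sampler recovers known diet proportions.
    """
    sources = [
        SourceSpec("pelagic", -30.0, 0.5, 3.0, 0.5, 0.4, 0.3, 3.4, 0.3),
        SourceSpec("littoral", -20.0, 0.5, 5.0, 0.5, 0.4, 0.3, 3.4, 0.3),
        SourceSpec("terrestrial", -26.0, 0.5, 11.0, 0.5, 0.4, 0.3, 3.4, 0.3),
    ]
    truth_p = np.array([0.7, 0.2, 0.1])
    mean, var = mixture_moments(truth_p, sources, np.array([0.3, 0.3]))
    rng = np.random.default_rng([seed, 3])
    obs = rng.normal(mean, np.sqrt(var), size=(30, 2))
    return MixingProblem("reference", obs, sources), truth_p


__all__ = [
    "SimConfig",
    "CommunityTruth",
    "SOURCE_NAME_ROSTER",
    "SOURCE_FILE_COLUMNS",
    "DIET_TABLE_META_COLUMNS",
    "generate_community",
    "sample_isotopes",
    "sample_guts",
    "write_fixture",
    "reference_problem",
]
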