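"""Isotope-data preparation: lipid normalisation, trophic-discrimination
factors, pooling of isotopically indistinct taxa, source summaries and
the imputed unknown-producer node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .types import IsotopeSample, SourceSpec

#: Default taxon-group trophic enrichment factors for δ15N (mean, SD in ‰).
#: The δ13C TEF is generic: 0.4 ± 1.3‰.
DEFAULT_TEF_TABLE: dict[str, tuple[float, float]] = {
    "fish": (3.4, 1.0),
    "invertebrate": (2.5, 1.0),
    "primary_consumer": (2.2, 1.0),
}
GENERIC_TEF_D13C: tuple[float, float] = (0.4, 1.3)

#: C:N gate above which whole-body samples are lipid-normalised.
LIPID_CN_THRESHOLD = 3.5


def lipid_correct(sample: IsotopeSample) -> IsotopeSample:
    """Arithmetic lipid normalisation of δ13C for whole-body samples.

    For aquatic animals with C:N > 3.5 the lipid-rich tissue depletes
    δ13C; the standard normalisation is

        δ13C' = δ13C − 3.32 + 0.99 · C:N

    δ15N is never altered, and a sample is corrected at most once.
    """
    if not sample.whole_body or sample.lipid_corrected:
        return sample
    if sample.c_to_n is None:
        raise ValueError(
            f"{sample.taxon}: whole-body sample lacks the C:N ratio needed "
            "for lipid correction"
        )
    if sample.c_to_n <= LIPID_CN_THRESHOLD:
        return sample
    return replace(
        sample,
        d13C=sample.d13C - 3.32 + 0.99 * sample.c_to_n,
        lipid_corrected=True,
    )


@dataclass
class SourceSummary:
    """Per-taxon isotopic summary (before TEF attachment)."""

    name: str
    mean_d13C: float
    sd_d13C: float
    mean_d15N: float
    sd_d15N: float
    n: int


def summarize_sources(
    samples_by_taxon: dict[str, list[IsotopeSample]],
    warn_below: int = 3,
    single_sample_whitelist: set[str] | frozenset[str] = frozenset(),
    sd_floor: float = 0.5,
) -> dict[str, SourceSummary]:
    """Arithmetic mean and sample SD (n−1) per source taxon.

    Taxa below ``warn_below`` samples warn; single-sample taxa are an
    error unless whitelisted (abundant taxa that are hard to isolate,
    e.g. Copepoda), in which case the SD is set to ``sd_floor``.
    """
    out: dict[str, SourceSummary] = {}
    for taxon in sorted(samples_by_taxon):
        samples = samples_by_taxon[taxon]
        c = np.array([s.d13C for s in samples])
        n = np.array([s.d15N for s in samples])
        if len(samples) < 2:
            if taxon not in single_sample_whitelist:
                raise ValueError(
                    f"source taxon {taxon!r} has {len(samples)} sample(s); "
                    "at least 2 required unless whitelisted"
                )
            out[taxon] = SourceSummary(
                taxon, float(c[0]), sd_floor, float(n[0]), sd_floor, 1
            )
            continue
        if len(samples) < warn_below:
            warnings.warn(
                f"source taxon {taxon!r} has only {len(samples)} samples "
                f"(minimum of {warn_below} recommended)",
                stacklevel=2,
            )
        out[taxon] = SourceSummary(
            taxon,
            float(c.mean()),
            float(c.std(ddof=1)),
            float(n.mean()),
            float(n.std(ddof=1)),
            len(samples),
        )
    return out


def attach_tefs(
    summaries: dict[str, SourceSummary],
    tef_table: dict[str, tuple[float, float]] | None = None,
    group_map: dict[str, str] | None = None,
    generic_d13c: tuple[float, float] = GENERIC_TEF_D13C,
    fallback_group: str | None = None,
    concentrations: dict[str, tuple[float, float]] | None = None,
) -> list[SourceSpec]:
    """Build SourceSpecs by joining summaries with a δ15N TEF lookup.

    ``group_map`` sends each source taxon to a TEF table group; an
    unresolvable taxon with no ``fallback_group`` is an error.  The δ13C
    TEF is the generic 0.4 ± 1.3‰ unless overridden.
    """
    table = DEFAULT_TEF_TABLE if tef_table is None else tef_table
    group_map = group_map or {}
    concentrations = concentrations or {}
    specs = []
    for name in sorted(summaries):
        s = summaries[name]
        group = group_map.get(name, name)
        if group not in table:
            if fallback_group is None or fallback_group not in table:
                raise KeyError(
                    f"no δ15N TEF entry for source {name!r} (group {group!r}) "
                    "and no fallback group configured"
                )
            group = fallback_group
        tef_n, tef_n_sd = table[group]
        conc_c, conc_n = concentrations.get(name, (1.0, 1.0))
        specs.append(
            SourceSpec(
                name=name,
                mean_d13C=s.mean_d13C,
                sd_d13C=s.sd_d13C,
                mean_d15N=s.mean_d15N,
                sd_d15N=s.sd_d15N,
                tef_d13C=generic_d13c[0],
                tef_sd_d13C=generic_d13c[1],
                tef_d15N=tef_n,
                tef_sd_d15N=tef_n_sd,
                conc_C=conc_c,
                conc_N=conc_n,
            )
        )
    return specs


@dataclass
class PoolingDecision:
    members: tuple[str, ...]
    pooled_label: str
    pooled: bool
    p_d13C: float
    p_d15N: float
    excluded: tuple[str, ...] = ()


@dataclass
class PoolingReport:
    decisions: list[PoolingDecision] = field(default_factory=list)


def _isotope_test(groups: list[np.ndarray]) -> float:
    if len(groups) == 2:
        return float(stats.ttest_ind(groups[0], groups[1], equal_var=False).pvalue)
    return float(stats.f_oneway(*groups).pvalue)


def pool_taxa(
    samples_by_taxon: dict[str, list[IsotopeSample]],
    candidate_sets: list[tuple[tuple[str, ...], str]],
    alpha: float = 0.05,
    rule: str = "not_distinct",
) -> tuple[dict[str, list[IsotopeSample]], PoolingReport]:
    """Pool phenotypically similar taxa that cannot be separated isotopically.

    Each candidate set is tested per isotope with a Welch t-test (pairs)
    or one-way ANOVA (larger sets).  Rules:

    - ``"not_distinct"`` (default): pool when NEITHER isotope differs
      significantly (p ≥ alpha on both) — the taxa are statistically
      inseparable, so they form one node at the target label.
    - ``"either"``: pool when at least one isotope fails to separate.

    Sample counts are conserved; taxa outside every candidate set pass
    through untouched, and pooling never crosses candidate sets.
    """
    if rule not in {"not_distinct", "either"}:
        raise ValueError(f"unknown pooling rule {rule!r}")
    out = {k: list(v) for k, v in samples_by_taxon.items()}
    report = PoolingReport()
    for members, label in candidate_sets:
        usable, excluded = [], []
        for m in members:
            if m in out and len(out[m]) >= 2:
                usable.append(m)
            else:
                excluded.append(m)
                warnings.warn(
                    f"taxon {m!r} excluded from pooling candidate {label!r} "
                    "(absent or < 2 samples)",
                    stacklevel=2,
                )
        if len(usable) < 2:
            continue
        c_groups = [np.array([s.d13C for s in out[m]]) for m in usable]
        n_groups = [np.array([s.d15N for s in out[m]]) for m in usable]
        p_c = _isotope_test(c_groups)
        p_n = _isotope_test(n_groups)
        if rule == "not_distinct":
            pooled = p_c >= alpha and p_n >= alpha
        else:
            pooled = p_c >= alpha or p_n >= alpha
        report.decisions.append(
            PoolingDecision(
                members=tuple(usable),
                pooled_label=label,
                pooled=pooled,
                p_d13C=p_c,
                p_d15N=p_n,
                excluded=tuple(excluded),
            )
        )
        if pooled:
            merged = []
            for m in usable:
                merged.extend(replace(s, taxon=label) for s in out.pop(m))
            out[label] = merged
    return out, report


def make_unknown_producer(
    zooplankton_samples: list[IsotopeSample],
    zooplankton_tef: tuple[float, float] = (GENERIC_TEF_D13C[0], 2.2),
    name: str = "unknown producer",
) -> SourceSpec:
    """Impute a missing basal producer from zooplankton signatures.

    Zooplankton are one trophic step above the missing producer, so the
    node's mean is the zooplankton mean minus the zooplankton TEF
    (δ13C, δ15N order in ``zooplankton_tef``); SDs are the zooplankton
    sample SDs.  The node is flagged synthetic in provenance.
    """
    if not zooplankton_samples:
        raise ValueError("cannot build unknown producer: no zooplankton samples")
    c = np.array([s.d13C for s in zooplankton_samples])
    n = np.array([s.d15N for s in zooplankton_samples])
    sd_c = float(c.std(ddof=1)) if len(c) > 1 else 0.5
    sd_n = float(n.std(ddof=1)) if len(n) > 1 else 0.5
    return SourceSpec(
        name=name,
        mean_d13C=float(c.mean()) - zooplankton_tef[0],
        sd_d13C=sd_c,
        mean_d15N=float(n.mean()) - zooplankton_tef[1],
        sd_d15N=sd_n,
        synthetic=True,
    )


__all__ = [
    "DEFAULT_TEF_TABLE",
    "GENERIC_TEF_D13C",
    "LIPID_CN_THRESHOLD",
    "lipid_correct",
    "SourceSummary",
    "summarize_sources",
    "attach_tefs",
    "pool_taxa",
    "PoolingDecision",
    "PoolingReport",
    "make_unknown_producer",
]
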