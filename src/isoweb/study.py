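"""Structure of the 12-reservoir study the pipeline was built around.

Two small packaged tables: the taxon-presence matrix (which basal
sources, invertebrate groups and fish occur in which reservoir) and the
tissue-sample counts by broad category.  They document the sampling
design the synthetic generator emulates and give the pipeline a
realistic taxon registry to validate against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

GROUPS = ("basal", "invertebrate", "fish")


def _data_path(name: str):
    return resources.files("isoweb").joinpath("data", name)


def taxon_presence() -> pd.DataFrame:
    """Presence (0/1) of every taxon across the 12 reservoirs."""
    with resources.as_file(_data_path("study_taxa.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown taxon groups in study table: {bad}")
    return df


def group_counts() -> dict[str, int]:
    """Number of distinct taxa per group (basal / invertebrate / fish)."""
    df = taxon_presence()
    return df["group"].value_counts().to_dict()


def reservoir_node_counts() -> pd.Series:
    """Number of taxa recorded per reservoir."""
    df = taxon_presence()
    res_cols = [c for c in df.columns if c.startswith("res")]
    return df[res_cols].sum(axis=0)


def tissue_sample_counts() -> pd.Series:
    """Tissue samples analysed for isotopes, by broad category."""
    with resources.as_file(_data_path("tissue_samples.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("category")["count"]


def total_tissue_samples() -> int:
    return int(tissue_sample_counts().sum())


__all__ = [
    "taxon_presence",
    "group_counts",
    "reservoir_node_counts",
    "tissue_sample_counts",
    "total_tissue_samples",
]
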