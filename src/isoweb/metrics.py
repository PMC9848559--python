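"""Food-web network indices from a predation matrix.

S is the number of distinct taxa (union of rows and columns), L the
number of realised links above a threshold, link density L/S and
directed connectance L/S² (L/[S(S−1)] available).  Nodes split into
basal (no prey), top (prey but no predators) and intermediate (both);
isolated nodes count as basal.  Diet-overlap summaries: Pianka's
pairwise niche overlap and Levins' niche breadth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import PredationMatrix, WebIndices


def _node_roles(
    matrix: PredationMatrix, link_threshold: float
) -> tuple[list[str], dict[str, str], list[str]]:
    vals = matrix.values
    nodes = list(dict.fromkeys(list(vals.index) + list(vals.columns)))
    eats: dict[str, set[str]] = {n: set() for n in nodes}
    eaten_by: dict[str, set[str]] = {n: set() for n in nodes}
    for prey in vals.index:
        for pred in vals.columns:
            if vals.loc[prey, pred] > link_threshold:
                eats[pred].add(prey)
                eaten_by[prey].add(pred)
    roles, isolated = {}, []
    for n in nodes:
        has_prey, has_pred = bool(eats[n]), bool(eaten_by[n])
        if has_prey and has_pred:
            roles[n] = "intermediate"
        elif has_prey:
            roles[n] = "top"
        else:
            roles[n] = "basal"  # includes isolated nodes
            if not has_pred:
                isolated.append(n)
    return nodes, roles, isolated


def web_indices(
    matrix: PredationMatrix,
    link_threshold: float = 0.0,
    connectance_kind: str = "directed",
) -> WebIndices:
    """Topology summary of one web; any entry > ``link_threshold`` is a link."""
    if link_threshold < 0:
        raise ValueError("link_threshold must be >= 0")
    vals = matrix.values
    if vals.size == 0:
        raise ValueError("empty predation matrix")
    nodes, roles, isolated = _node_roles(matrix, link_threshold)
    s = len(nodes)
    l = int((vals.to_numpy() > link_threshold).sum())
    if connectance_kind == "directed":
        conn = l / s**2
    elif connectance_kind == "no_self":
        conn = l / (s * (s - 1))
    else:
        raise ValueError(f"unknown connectance kind {connectance_kind!r}")
    counts = pd.Series(list(roles.values())).value_counts()
    breadth = niche_breadth(matrix)
    b = breadth["B"]
    try:
        mean_pianka = float(pianka_overlap(matrix)[1])
    except ValueError:
        mean_pianka = float("nan")  # fewer than two consumers
    return WebIndices(
        S=s,
        L=l,
        link_density=l / s,
        connectance=conn,
        frac_basal=counts.get("basal", 0) / s,
        frac_intermediate=counts.get("intermediate", 0) / s,
        frac_top=counts.get("top", 0) / s,
        mean_pianka=mean_pianka,
        niche_breadth=b.to_dict(),
        mean_niche_breadth=float(b.mean()),
        isolated_nodes=isolated,
    )


def pianka_overlap(matrix: PredationMatrix) -> tuple[pd.DataFrame, float]:
    """Pairwise Pianka overlap of consumer diet columns, and its mean.

    O_jk = Σ_i p_ij p_ik / sqrt(Σ_i p_ij² · Σ_i p_ik²) over the shared
    prey index set; mean over unordered consumer pairs.  All-zero
    consumer columns are excluded with a warning.
    """
    vals = matrix.values
    cols = []
    for c in vals.columns:
        if vals[c].sum() > 0:
            cols.append(c)
        else:
            warnings.warn(f"consumer {c!r} has an all-zero diet column", stacklevel=2)
    if len(cols) < 2:
        raise ValueError("Pianka overlap needs at least 2 consumers with diets")
    p = vals[cols].to_numpy(float)  # (prey, consumers)
    norm = np.sqrt((p**2).sum(axis=0))
    overlap = (p.T @ p) / np.outer(norm, norm)
    out = pd.DataFrame(overlap, index=cols, columns=cols)
    iu = np.triu_indices(len(cols), k=1)
    return out, float(overlap[iu].mean())


def niche_breadth(matrix: PredationMatrix) -> pd.DataFrame:
    """Levins' B = 1/Σp² per consumer, with the standardised form.

    B_A = (B − 1)/(N_j − 1) where N_j is the consumer's number of
    positive prey entries; undefined (NaN) for single-prey specialists.
    """
    vals = matrix.values
    rows = []
    for c in vals.columns:
        p = vals[c].to_numpy(float)
        tot = p.sum()
        if tot <= 0:
            rows.append({"consumer": c, "B": np.nan, "B_A": np.nan, "n_prey": 0})
            continue
        p = p / tot
        b = 1.0 / np.sum(p**2)
        n_prey = int((p > 0).sum())
        ba = (b - 1.0) / (n_prey - 1.0) if n_prey > 1 else np.nan
        rows.append({"consumer": c, "B": b, "B_A": ba, "n_prey": n_prey})
    return pd.DataFrame(rows).set_index("consumer")


__all__ = ["web_indices", "pianka_overlap", "niche_breadth"]
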