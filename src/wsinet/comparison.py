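"""Cross-dataset comparison: shared-gene restriction through an ortholog
map, Pearson correlation matrices, and Ward hierarchical clustering.

Model-group profiles (log2 FC or wSI per gene) are compared with human
tissue/condition profiles on the complete-case intersection of gene ids —
mouse ids are mapped to their human orthologs before intersecting, and no
imputation is ever performed.  Group similarity is summarized as a
symmetric Pearson correlation matrix; group structure as agglomerative
Ward clustering on Euclidean distances between profile vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import GeneSetCollection, OrthologMap


@dataclass
class GroupProfile:
    """Per-group vector of one value per gene (log2 FC or wSI)."""

    label: str
    values: dict[str, float]
    value_kind: str = "fc"  # "fc" | "wsi"

    def __post_init__(self) -> None:
        if self.value_kind not in ("fc", "wsi"):
            raise ValueError(f"value_kind must be 'fc' or 'wsi', got {self.value_kind!r}")

    @property
    def genes(self) -> set[str]:
        return set(self.values)

    def vector(self, genes: list[str]) -> np.ndarray:
        return np.array([self.values[g] for g in genes], dtype=float)


def shared_genes(
    profiles: list[GroupProfile],
    ortholog_map: OrthologMap | None = None,
    uppercase: bool = False,
) -> tuple[list[str], list[GroupProfile]]:
    """Intersect gene ids across all profiles after ortholog translation.

    Ids found among the map's mouse keys are translated to their human
    ortholog; other ids pass through (optionally uppercased for symbol
    comparison).  Raises on an empty intersection with a per-profile
    coverage report.
    """

    def _translate(p: GroupProfile) -> GroupProfile:
        values: dict[str, float] = {}
        for g, v in p.values.items():
            h = ortholog_map.get(g) if ortholog_map else None
            key = h if h is not None else (g.upper() if uppercase else g)
            values[key] = v
        return GroupProfile(p.label, values, p.value_kind)

    translated = [_translate(p) for p in profiles]
    common: set[str] = set.intersection(*(p.genes for p in translated))
    if not common:
        report = "; ".join(f"{p.label}: {len(p.genes)} genes" for p in translated)
        raise ValueError(f"no genes shared across profiles ({report})")
    genes = sorted(common)
    restricted = [
        GroupProfile(p.label, {g: p.values[g] for g in genes}, p.value_kind)
        for p in translated
    ]
    return genes, restricted


def correlation_matrix(profiles: list[GroupProfile]) -> pd.DataFrame:
    """Pairwise Pearson r over the profiles' shared-gene vectors.

    Profiles must already be restricted to a common gene set.  Constant
    profiles get NaN rows/columns (their correlation is undefined); the
    diagonal is exactly 1 for non-constant profiles.
    """
    genes_sets = {frozenset(p.genes) for p in profiles}
    if len(genes_sets) != 1:
        raise ValueError("profiles must be restricted to the same gene set first")
    genes = sorted(profiles[0].genes)
    if len(genes) < 2:
        raise ValueError("need >= 2 shared genes")
    x = np.vstack([p.vector(genes) for p in profiles])
    labels = [p.label for p in profiles]
    constant = x.std(axis=1) == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    r = np.clip(r, -1.0, 1.0, out=r) if not np.isnan(r).all() else r
    # enforce exact symmetry
    iu = np.triu_indices_from(r, k=1)
    r[(iu[1], iu[0])] = r[iu]
    return pd.DataFrame(r, index=labels, columns=labels)


@dataclass
class WardResult:
    labels: list[str]
    linkage: np.ndarray          # scipy linkage matrix (merges + heights)
    heights: np.ndarray          # merge heights in agglomeration order
    flat_clusters: dict[str, int] | None = None


def ward_cluster(
    profiles: list[GroupProfile], n_clusters: int | None = None
) -> WardResult:
    """Agglomerative Ward clustering on Euclidean distances between profile
    vectors; deterministic given input order.  ``n_clusters`` additionally
    cuts the tree into that many flat clusters."""
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    genes_sets = {frozenset(p.genes) for p in profiles}
    if len(genes_sets) != 1:
        raise ValueError("profiles must be restricted to the same gene set first")
    genes = sorted(profiles[0].genes)
    x = np.vstack([p.vector(genes) for p in profiles])
    z = linkage(x, method="ward", metric="euclidean")
    labels = [p.label for p in profiles]
    flat = None
    if n_clusters is not None:
        assignment = fcluster(z, t=n_clusters, criterion="maxclust")
        flat = dict(zip(labels, (int(a) for a in assignment)))
    return WardResult(labels=labels, linkage=z, heights=z[:, 2].copy(),
                      flat_clusters=flat)


def subset_by_terms(
    profiles: list[GroupProfile],
    gene_sets: GeneSetCollection,
    term_ids: list[str],
) -> list[GroupProfile]:
    """Restrict profiles to the union of the requested terms' members
    (intersected with the profiles' shared genes)."""
    unknown = [t for t in term_ids if t not in gene_sets]
    if unknown:
        raise KeyError(f"unknown term id(s): {unknown}")
    members: set[str] = set()
    for t in term_ids:
        members |= gene_sets[t].members
    out = []
    for p in profiles:
        keep = {g: v for g, v in p.values.items() if g in members}
        if not keep:
            raise ValueError(
                f"profile {p.label!r} shares no genes with the requested terms"
            )
        out.append(GroupProfile(p.label, keep, p.value_kind))
    return out
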