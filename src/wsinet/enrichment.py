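"""Over-representation analysis with per-term average fold change.

A query gene list is tested against each namespaced gene set with the
one-sided hypergeometric upper-tail test; pathway-namespace terms are kept
at FDR < 0.05 (Benjamini-Hochberg, computed within namespace) while GO
biological-process and cellular-component terms are kept at raw p < 0.05,
both strict.  Each reported term also carries the arithmetic mean log2 fold
change of the query genes that enrich it, the summary used to read
direction into an enrichment table.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io_formats import FoldChangeTable, GeneSetCollection, NAMESPACES


def ora_test(query: set[str], term: set[str], universe: set[str]) -> float:
    """One-sided hypergeometric upper-tail p of observing >= the observed
    overlap between ``query`` and ``term`` within ``universe``."""
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be contained in the universe")
    m = len(universe)
    n_term = len(term & universe)
    n_query = len(query)
    k = len(query & term & universe)
    # P(X >= k), X ~ Hypergeom(M=m, K=n_term, N=n_query)
    return float(hypergeom.sf(k - 1, m, n_term, n_query))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def average_fc(overlap: Iterable[str], fc: FoldChangeTable) -> float:
    """Arithmetic mean log2 FC of the genes enriching a term."""
    genes = list(overlap)
    if not genes:
        raise ValueError("empty overlap")
    missing = [g for g in genes if g not in fc]
    if missing:
        raise ValueError(f"overlap genes missing from FC table: {missing[:5]}")
    return float(np.mean([fc.entries[g] for g in genes]))


def enrich(
    query: set[str],
    collection: GeneSetCollection,
    fc: FoldChangeTable,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """ORA of ``query`` against every term; FDR within namespace.

    The universe defaults to the genes detected in the contrast under
    analysis (i.e. the FC table's gene set), overridable.  Returns a
    DataFrame with columns term, namespace, n_overlap, p, fdr, average_fc,
    members (comma-joined), in collection order.
    """
    if universe is None:
        universe = fc.genes
    rows = []
    for term_id, gs in collection.terms.items():
        overlap = query & gs.members & universe
        p = ora_test(query, gs.members, universe)
        afc = average_fc(overlap, fc) if overlap else np.nan
        rows.append(
            (term_id, gs.namespace, len(overlap), p, afc, ",".join(sorted(overlap)))
        )
    df = pd.DataFrame(
        rows, columns=["term", "namespace", "n_overlap", "p", "average_fc", "members"]
    )
    df["fdr"] = np.nan
    for ns in NAMESPACES:
        mask = df["namespace"] == ns
        if mask.any():
            df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p"])
    return df[["term", "namespace", "n_overlap", "p", "fdr", "average_fc", "members"]]


def significant_terms(results: pd.DataFrame, namespace: str) -> pd.DataFrame:
    """Significance filter: pathway terms at FDR < 0.05; BP and CC terms at
    raw p < 0.05 (both strict)."""
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    sub = results[results["namespace"] == namespace]
    if namespace == "pathway":
        return sub[sub["fdr"] < 0.05]
    return sub[sub["p"] < 0.05]
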