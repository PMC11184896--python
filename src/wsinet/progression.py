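"""Putative fold-change construction and the progression screen.

Contrasts measured against the untreated APP/PS1 group are re-referenced to
wild type by summing log2 fold changes: FC(treat vs WT) = FC(APP vs WT) +
FC(treat vs APP).  Each gene's three WT-referenced values, taken in the
hypothesized order of increasing immune impairment (HOE_WT, APP_WT, BK_WT),
are then correlated against the ordinal position (1, 2, 3); genes with
|r| strictly above the r threshold and p strictly below the p threshold
pass, partitioned by the sign of r.

Note on the p-value: with three points the two-sided t-test has a single
degree of freedom, so p < 0.05 requires |r| >~ 0.997 — far stricter than
the |r| > 0.9 rule it accompanies.  Both thresholds are therefore plain
parameters; relaxing ``p_threshold`` to 1.0 reduces the screen to the
correlation rule alone.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FoldChangeTable

logger = logging.getLogger("wsinet")

ORDER = ("HOE_WT", "APP_WT", "BK_WT")  # hypothesized progression order


def putative_fc(
    fc_app_vs_wt: FoldChangeTable, fc_treat_vs_app: FoldChangeTable
) -> FoldChangeTable:
    """Re-reference a treated-vs-APP contrast to WT by entrywise sum of
    log2 FCs over the gene intersection; genes absent from either table are
    dropped (count logged)."""
    common = fc_app_vs_wt.genes & fc_treat_vs_app.genes
    if not common:
        raise ValueError("no genes shared between the two fold-change tables")
    dropped = len(fc_app_vs_wt.genes | fc_treat_vs_app.genes) - len(common)
    if dropped:
        logger.info("putative_fc: %d genes absent from one table dropped", dropped)
    label = f"{fc_treat_vs_app.contrast}+{fc_app_vs_wt.contrast}"
    entries = {
        g: fc_app_vs_wt.entries[g] + fc_treat_vs_app.entries[g]
        for g in fc_app_vs_wt.entries
        if g in common
    }
    return FoldChangeTable(label, entries)


def progression_correlation(triplet: tuple[float, float, float]) -> tuple[float, float]:
    """Pearson r of (hoe_wt, app_wt, bk_wt) against position (1, 2, 3), with
    the two-sided t-test p at n-2 = 1 degrees of freedom.

    A constant triplet has undefined correlation: returns (nan, nan).
    """
    y = np.asarray(triplet, dtype=float)
    if y.shape != (3,) or not np.isfinite(y).all():
        raise ValueError("need three finite values")
    x = np.array([1.0, 2.0, 3.0])
    sy = y - y.mean()
    denom = np.sqrt((sy**2).sum() * 2.0)  # sum((x - 2)^2) = 2
    if denom == 0.0:
        return (float("nan"), float("nan"))
    r = float((sy * (x - 2.0)).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt(1.0 / (1.0 - r * r))
    return (r, float(2.0 * stats.t.sf(abs(t), df=1)))


def build_records(
    fc_hoe_wt: FoldChangeTable,
    fc_app_wt: FoldChangeTable,
    fc_bk_wt: FoldChangeTable,
) -> pd.DataFrame:
    """One row per gene in the three-way intersection: the WT-referenced
    triplet plus its progression r and p."""
    common = fc_hoe_wt.genes & fc_app_wt.genes & fc_bk_wt.genes
    if not common:
        raise ValueError("no genes shared across the three tables")
    rows = []
    for g in sorted(common):
        trip = (fc_hoe_wt.entries[g], fc_app_wt.entries[g], fc_bk_wt.entries[g])
        r, p = progression_correlation(trip)
        rows.append((g, *trip, r, p))
    return pd.DataFrame(
        rows, columns=["gene", "fc_hoe_wt", "fc_app_wt", "fc_bk_wt", "r", "p"]
    )


def screen(
    records: pd.DataFrame, r_threshold: float = 0.9, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply the progression screen: passes iff |r| > r_threshold (strict)
    AND p < p_threshold (strict); undefined r never passes.

    Adds ``passes`` and ``sign`` ('+', '-', or '') columns.
    """
    out = records.copy()
    r = out["r"].to_numpy(float)
    p = out["p"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        passes = (np.abs(r) > r_threshold) & (p < p_threshold)
    passes &= np.isfinite(r)
    out["passes"] = passes
    out["sign"] = np.where(~passes, "", np.where(r > 0, "+", "-"))
    return out


def passing_partition(screened: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(positive-correlation genes, negative-correlation genes) that pass."""
    pos = set(screened.loc[screened["passes"] & (screened["r"] > 0), "gene"])
    neg = set(screened.loc[screened["passes"] & (screened["r"] < 0), "gene"])
    return pos, neg
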