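"""Differential expression: expressed-probe filter, rank products, a
SAM-style moderated statistic, the dual-method significance call, and the
delta-Ct helper for qPCR validation.

The design is a two-color contrast per array, so both statistics run in
one-class form on dye-swap-corrected log2 ratios: a gene is differential
when its replicate ratios are consistently displaced from zero.  A gene is
*called* differential only when rank products and the SAM statistic agree
at the chosen level (p <= alpha by both methods, inclusive).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

logger = logging.getLogger("wsinet")

__all__ = [
    "filter_expressed",
    "rank_product",
    "sam_statistic",
    "call_de",
    "de_pipeline",
    "delta_ct_relative_expression",
]


def filter_expressed(matrix: ExpressionMatrix, min_support: int = 3) -> set[str]:
    """Probes whose foreground exceeds background in >= ``min_support``
    replicates (the expressed-probe rule; 3 of 4 by default)."""
    if matrix.foreground is None or matrix.background is None:
        raise ValueError("expression matrix lacks foreground/background intensities")
    if min_support > matrix.n_replicates:
        raise ValueError(
            f"min_support={min_support} exceeds replicate count {matrix.n_replicates}"
        )
    support = (matrix.foreground > matrix.background).sum(axis=1)
    return {p for p, s in zip(matrix.probes, support) if s >= min_support}


def _within_replicate_ranks(values: np.ndarray, direction: str) -> np.ndarray:
    """Rank each column; rank 1 = most extreme in ``direction`` (average
    ranks on ties)."""
    if direction == "up":
        return rankdata(-values, method="average", axis=0)
    if direction == "down":
        return rankdata(values, method="average", axis=0)
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def rank_product(
    matrix: ExpressionMatrix | np.ndarray,
    n_perm: int | str = 200,
    direction: str = "up",
    seed: int | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Rank-product statistic with a within-replicate permutation null.

    RP_g is the geometric mean over replicates of gene g's within-replicate
    rank (rank 1 = most up- or down-regulated).  The null permutes the rank
    vector independently within each replicate; p_g is the fraction of
    permutations whose RP at g's position is <= the observed RP_g, with the
    +1/(n_perm+1) correction.  ``n_perm="exhaustive"`` enumerates all
    (n!)^k per-replicate permutations exactly (no correction); only
    sensible for tiny matrices.

    Returns a DataFrame indexed by gene with columns ``rp`` and ``p``.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.corrected_ratios()
        genes = genes or list(matrix.probes)
    else:
        values = np.asarray(matrix, dtype=float)
        genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    n, k = values.shape
    for j in range(k):
        if np.unique(values[:, j]).size == 1:
            warnings.warn(f"replicate column {j} is constant (all ranks tied)")
    ranks = _within_replicate_ranks(values, direction)
    log_rp_obs = np.log(ranks).mean(axis=1)
    rp_obs = np.exp(log_rp_obs)

    if n_perm == "exhaustive":
        count = np.zeros(n)
        total = 0
        perms = list(itertools.permutations(range(n)))
        for combo in itertools.product(perms, repeat=k):
            perm_log = np.zeros(n)
            for j, pi in enumerate(combo):
                perm_log += np.log(ranks[list(pi), j])
            count += perm_log / k <= log_rp_obs + 1e-12
            total += 1
        p = count / total
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = np.zeros(n)
        log_ranks = np.log(ranks)
        for _ in range(int(n_perm)):
            perm_log = np.zeros(n)
            for j in range(k):
                perm_log += log_ranks[rng.permutation(n), j]
            count += perm_log / k <= log_rp_obs + 1e-12
        p = (count + 1.0) / (n_perm + 1.0)
    return pd.DataFrame({"rp": rp_obs, "p": p}, index=pd.Index(genes, name="gene"))


def sam_statistic(
    matrix: ExpressionMatrix | np.ndarray,
    s0_rule: str = "median",
    s0_value: float | None = None,
    n_perm: int = 1024,
    seed: int | None = None,
    genes: list[str] | None = None,
    pool_null: bool = True,
) -> pd.DataFrame:
    """One-class SAM: d_g = mean(r_g) / (s_g + s0) with a sign-flip null.

    s_g is the standard error of gene g's replicate log ratios; s0 is the
    median of all s_g (``s0_rule="median"``) or a fixed value.  The null
    flips replicate signs (exhaustive over all 2^k patterns when
    2^k <= n_perm, otherwise sampled); the two-sided p compares |d| against
    the permuted statistics pooled across all genes (``pool_null=True``,
    the cited method's scheme) or against the gene's own flips, with the +1
    correction either way.
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.corrected_ratios()
        genes = genes or list(matrix.probes)
    else:
        values = np.asarray(matrix, dtype=float)
        genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    n, k = values.shape
    if k < 2:
        raise ValueError("need >= 2 replicates per gene")

    def _d(x: np.ndarray, s0: float) -> np.ndarray:
        m = x.mean(axis=1)
        se = x.std(axis=1, ddof=1) / np.sqrt(k)
        return m / (se + s0)

    se_obs = values.std(axis=1, ddof=1) / np.sqrt(k)
    if s0_rule == "median":
        s0 = float(np.median(se_obs))
    elif s0_rule == "fixed":
        if s0_value is None:
            raise ValueError("s0_rule='fixed' requires s0_value")
        s0 = float(s0_value)
    else:
        raise ValueError(f"unknown s0_rule {s0_rule!r}")

    d_obs = _d(values, s0)

    if 2**k <= n_perm:
        patterns = np.array(list(itertools.product((1.0, -1.0), repeat=k)))
    else:
        rng = np.random.default_rng(seed)
        patterns = rng.choice((1.0, -1.0), size=(n_perm, k))
    perm_abs = np.empty((len(patterns), n))
    for i, signs in enumerate(patterns):
        perm_abs[i] = np.abs(_d(values * signs[None, :], s0))

    abs_obs = np.abs(d_obs)
    if pool_null:
        pool = np.sort(perm_abs.ravel())
        total = pool.size
        # count of pooled |d*| >= |d_g| via right-tail search
        idx = np.searchsorted(pool, abs_obs - 1e-12, side="left")
        count = total - idx
    else:
        count = (perm_abs >= abs_obs[None, :] - 1e-12).sum(axis=0)
        total = len(patterns)
    p = (count + 1.0) / (total + 1.0)
    return pd.DataFrame({"d": d_obs, "p": np.minimum(p, 1.0)},
                        index=pd.Index(genes, name="gene"))


def call_de(
    rp_p: Mapping[str, float],
    sam_p: Mapping[str, float],
    alpha: float = 0.05,
    mean_fc: Mapping[str, float] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Dual-method call: significant iff rp_p <= alpha AND sam_p <= alpha.

    Both p-value maps must cover the same gene universe; direction is
    recorded from the sign of the mean FC when supplied.
    """
    rp_genes, sam_genes = set(rp_p), set(sam_p)
    if rp_genes != sam_genes:
        missing = sorted((rp_genes ^ sam_genes))
        raise ValueError(f"mismatched gene universes; differing ids: {missing[:10]}")
    rows = []
    for g in rp_p:
        sig = rp_p[g] <= alpha and sam_p[g] <= alpha
        fc = mean_fc.get(g, np.nan) if mean_fc else np.nan
        direction = "up" if fc > 0 else ("down" if fc < 0 else "none")
        rows.append((g, fc, rp_p[g], sam_p[g], sig, direction))
    table = pd.DataFrame(
        rows, columns=["gene", "mean_fc", "rp_p", "sam_p", "significant", "direction"]
    )
    return set(table.loc[table["significant"], "gene"]), table


def de_pipeline(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    min_support: int = 3,
    n_perm_rp: int = 200,
    n_perm_sam: int = 1024,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full DE stage for one contrast.

    Filters expressed probes, runs rank products in both directions
    (combined two-sided as min(1, 2*min(p_up, p_down))), the one-class SAM
    statistic, and the dual-method call.  Returns a DataFrame with columns
    gene, mean_fc, rp_up_p, rp_down_p, sam_d, sam_p, significant.
    """
    expressed = filter_expressed(matrix, min_support=min_support)
    keep = [i for i, p in enumerate(matrix.probes) if p in expressed]
    if not keep:
        raise ValueError("no expressed probes after filtering")
    genes = [matrix.probes[i] for i in keep]
    values = matrix.corrected_ratios()[keep]
    logger.info("%s: %d of %d probes expressed", matrix.contrast, len(keep),
                len(matrix.probes))

    rp_up = rank_product(values, n_perm=n_perm_rp, direction="up",
                         seed=seed, genes=genes)
    rp_down = rank_product(values, n_perm=n_perm_rp, direction="down",
                           seed=None if seed is None else seed + 1, genes=genes)
    sam = sam_statistic(values, n_perm=n_perm_sam, seed=seed, genes=genes)
    rp_two_sided = np.minimum(1.0, 2.0 * np.minimum(rp_up["p"], rp_down["p"]))
    mean_fc = dict(zip(genes, values.mean(axis=1)))
    _, call = call_de(dict(rp_two_sided), dict(sam["p"]), alpha=alpha, mean_fc=mean_fc)
    call = call.set_index("gene")
    out = pd.DataFrame(
        {
            "gene": genes,
            "mean_fc": [mean_fc[g] for g in genes],
            "rp_up_p": rp_up["p"].to_numpy(),
            "rp_down_p": rp_down["p"].to_numpy(),
            "sam_d": sam["d"].to_numpy(),
            "sam_p": sam["p"].to_numpy(),
            "significant": [bool(call.loc[g, "significant"]) for g in genes],
        }
    )
    return out


def delta_ct_relative_expression(ct_target: float, ct_reference: float) -> float:
    """Relative expression by the delta-Ct rule: 2^-(Ct_target - Ct_reference)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(2.0 ** -(ct_target - ct_reference))
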