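"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design end-to-end: four dye-swapped
two-color replicates per contrast across four neurosphere groups (WT,
untreated APP/PS1, bradykinin-treated, HOE-140-treated), a planted
immune-gene module whose fold change increases monotonically along the
HOE -> APP -> BK axis, a sparse hub-skewed interaction network, namespaced
gene-set collections containing the planted module, a partial one-to-one
mouse-to-human ortholog map, and "human" tissue x condition fold-change
tables with a tunable Pearson correlation to a designated model group.

All randomness flows from ``SimulationConfig.seed`` through named
substreams, so one integer reproduces every artifact byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    ExpressionMatrix,
    FoldChangeTable,
    GeneSet,
    GeneSetCollection,
    InteractionSet,
    OrthologMap,
)

CONTRAST_APP = "APP_WT_vs_WT"
CONTRAST_HOE = "HOE_APP_vs_APP_WT"
CONTRAST_BK = "BK_APP_vs_APP_WT"
CONTRASTS = (CONTRAST_APP, CONTRAST_HOE, CONTRAST_BK)

TISSUES = ("EC", "TC", "FC", "CB")
CONDITIONS = ("AD", "AsymAD")

# substream ids keep the per-stage RNGs independent of one another
_STREAM = {"expression": 1, "interactions": 2, "orthologs": 3, "gene_sets": 4, "human": 5}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Defaults are the conditions the analysis is exercised under: 1000 genes,
    a 5% immune module planted at +2.0 log2 units in APP/PS1 vs WT, an extra
    +1.0 under bradykinin and -1.0 under HOE-140 (monotone progression),
    per-replicate log-ratio noise sd 0.3, and 4 dye-swapped replicates.
    """

    n_genes: int = 1000
    n_replicates_per_contrast: int = 4
    frac_immune_module: float = 0.05
    base_fc_appwt: float = 2.0
    delta_bk: float = 1.0      # extra planted log2 FC under bradykinin (>= 0)
    delta_hoe: float = -1.0    # planted log2 FC reduction under HOE-140 (<= 0)
    noise_sd: float = 0.3
    n_interactions: int = 3000
    hub_exponent: float = 1.5
    n_tissues: int = 4
    n_conditions: int = 2
    human_correlation: float = 0.5
    seed: int = 0
    # fraction of non-module probes simulated below background (fails the
    # expressed-probe filter most of the time); module probes stay expressed
    frac_unexpressed: float = 0.02

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates_per_contrast < 1:
            raise ValueError("n_genes and n_replicates_per_contrast must be positive")
        if not 0.0 <= self.frac_immune_module <= 1.0:
            raise ValueError("frac_immune_module must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.delta_bk < 0:
            raise ValueError("delta_bk must be >= 0")
        if self.delta_hoe > 0:
            raise ValueError("delta_hoe must be <= 0")
        if self.hub_exponent <= 0:
            raise ValueError("hub_exponent must be positive")
        if not -1.0 <= self.human_correlation <= 1.0:
            raise ValueError("human_correlation must be in [-1, 1]")
        if self.n_tissues < 1 or self.n_conditions < 1:
            raise ValueError("n_tissues and n_conditions must be positive")
        if self.n_tissues > len(TISSUES) or self.n_conditions > len(CONDITIONS):
            raise ValueError(
                f"at most {len(TISSUES)} tissues and {len(CONDITIONS)} conditions supported"
            )

    def rng(self, stage: str) -> np.random.Generator:
        """Named substream: deterministic per (seed, stage)."""
        return np.random.default_rng([int(self.seed) % (2**31), _STREAM[stage]])

    @property
    def n_module(self) -> int:
        if self.frac_immune_module == 0:
            return 0
        return max(1, round(self.frac_immune_module * self.n_genes))

    def to_dict(self) -> dict:
        return asdict(self)


def gene_ids(config: SimulationConfig) -> list[str]:
    width = max(4, len(str(config.n_genes)))
    return [f"Mg{i:0{width}d}" for i in range(1, config.n_genes + 1)]


@dataclass
class SimulatedExpression:
    """Per-contrast measured matrices plus the planted ground truth."""

    matrices: dict[str, ExpressionMatrix]
    truth: dict[str, FoldChangeTable]
    module_genes: list[str]
    config: SimulationConfig = field(repr=False, default=None)


def simulate_expression(config: SimulationConfig) -> SimulatedExpression:
    """Simulate probe x replicate log-ratio matrices for all three contrasts.

    Module genes carry planted mean log2 FCs (``base_fc_appwt`` in
    APP/PS1 vs WT, ``delta_hoe`` in HOE vs APP, ``delta_bk`` in BK vs APP);
    all other genes have mean 0.  Noise is i.i.d. Gaussian per replicate;
    replicates hybridized in the swapped dye orientation store the negated
    log ratio (balanced half/half).  Foreground/background intensities are
    emitted per probe and replicate so the expressed-probe filter has
    something to chew on.
    """
    genes = gene_ids(config)
    rng = config.rng("expression")
    n, k = config.n_genes, config.n_replicates_per_contrast

    module_idx = np.sort(rng.choice(n, size=config.n_module, replace=False))
    module = [genes[i] for i in module_idx]
    planted = {
        CONTRAST_APP: config.base_fc_appwt,
        CONTRAST_HOE: config.delta_hoe,
        CONTRAST_BK: config.delta_bk,
    }
    is_module = np.zeros(n, dtype=bool)
    is_module[module_idx] = True

    # non-module probes flagged unexpressed sit at/below background
    unexpressed = np.zeros(n, dtype=bool)
    candidates = np.flatnonzero(~is_module)
    n_unexpr = int(round(config.frac_unexpressed * candidates.size))
    if n_unexpr:
        unexpressed[rng.choice(candidates, size=n_unexpr, replace=False)] = True

    dye_swap = np.array([j % 2 == 1 for j in range(k)])
    sign = np.where(dye_swap, -1.0, 1.0)

    matrices, truth = {}, {}
    for contrast in CONTRASTS:
        mu = np.where(is_module, planted[contrast], 0.0)
        ratios = mu[:, None] + rng.normal(0.0, config.noise_sd, size=(n, k))
        stored = ratios * sign  # dye-swap sign convention
        background = rng.lognormal(mean=np.log(100.0), sigma=0.2, size=(n, k))
        lift = np.where(unexpressed[:, None], rng.normal(-0.5, 0.5, (n, k)),
                        rng.normal(1.0, 0.5, (n, k)))
        foreground = background * np.exp(lift)
        matrices[contrast] = ExpressionMatrix(
            contrast=contrast,
            probes=list(genes),
            replicates=[f"R{j + 1}" for j in range(k)],
            dye_swap=dye_swap.copy(),
            ratios=stored,
            foreground=foreground,
            background=background,
        )
        truth[contrast] = FoldChangeTable(contrast, dict(zip(genes, mu)))
    return SimulatedExpression(matrices=matrices, truth=truth,
                               module_genes=module, config=config)


def simulate_interactions(genes: list[str], config: SimulationConfig) -> InteractionSet:
    """Sample an undirected simple graph with hub-skewed degrees.

    Configuration-model-style: each gene gets a heavy-tailed propensity
    ``u^(-hub_exponent)`` (u uniform) and edge endpoints are drawn with
    probability proportional to it; self-loops and duplicate unordered pairs
    are rejected.  The graph may be disconnected.
    """
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes")
    max_edges = n * (n - 1) // 2
    if config.n_interactions > max_edges:
        raise ValueError(
            f"n_interactions={config.n_interactions} exceeds simple-graph bound {max_edges}"
        )
    rng = config.rng("interactions")
    w = rng.uniform(size=n) ** (-config.hub_exponent)
    p = w / w.sum()
    iset = InteractionSet()
    stall = 0
    while len(iset) < config.n_interactions:
        batch = max(64, config.n_interactions - len(iset))
        pairs = rng.choice(n, size=(batch, 2), p=p)
        before = len(iset)
        for u, v in pairs:
            if u == v:
                continue
            iset.add(genes[u], genes[v])
            if len(iset) == config.n_interactions:
                break
        stall = stall + 1 if len(iset) == before else 0
        if stall > 50:
            # dense regime: fill deterministically from the remaining pairs
            for i in range(n):
                for j in range(i + 1, n):
                    if len(iset) == config.n_interactions:
                        return iset
                    if (genes[i], genes[j]) not in iset:
                        iset.add(genes[i], genes[j])
    return iset


def simulate_ortholog_map(
    mouse_ids: list[str], config: SimulationConfig, frac_mapped: float = 0.8
) -> OrthologMap:
    """Partial one-to-one map: a random ``frac_mapped`` subset of mouse ids
    maps to its uppercased human symbol."""
    if not mouse_ids:
        raise ValueError("empty mouse id list")
    rng = config.rng("orthologs")
    n_map = int(round(frac_mapped * len(mouse_ids)))
    chosen = rng.choice(len(mouse_ids), size=n_map, replace=False)
    pairs = {mouse_ids[i]: mouse_ids[i].upper() for i in np.sort(chosen)}
    return OrthologMap(pairs)


def simulate_gene_sets(
    genes: list[str],
    config: SimulationConfig,
    module_genes: list[str] | None = None,
    n_terms_per_namespace: int = 10,
) -> GeneSetCollection:
    """Random namespaced gene sets over ``genes``, plus one planted
    immune-response term per namespace containing the module genes (so
    enrichment has a true positive to find)."""
    if not genes:
        raise ValueError("empty gene id list")
    rng = config.rng("gene_sets")
    terms: dict[str, GeneSet] = {}
    if module_genes:
        pool = [g for g in genes if g not in set(module_genes)]
        for ns, label in (("BP", "innate_immune_response_activation"),
                          ("CC", "inflammasome_complex"),
                          ("pathway", "cytokine_signaling")):
            extra = list(rng.choice(len(pool), size=min(10, len(pool)), replace=False))
            members = set(module_genes) | {pool[i] for i in extra}
            terms[f"{ns}:immune"] = GeneSet(name=label, namespace=ns, members=members)
    for ns in ("BP", "CC", "pathway"):
        for t in range(n_terms_per_namespace):
            size = int(rng.integers(10, 51))
            size = min(size, len(genes))
            idx = rng.choice(len(genes), size=size, replace=False)
            terms[f"{ns}:{t + 1:03d}"] = GeneSet(
                name=f"{ns.lower()}_term_{t + 1}",
                namespace=ns,
                members={genes[i] for i in idx},
            )
    return GeneSetCollection(terms)


def simulate_human_dataset(
    human_ids: list[str],
    config: SimulationConfig,
    model_fc: FoldChangeTable | None = None,
) -> dict[str, FoldChangeTable]:
    """Human tissue x condition FC tables correlated with a model profile.

    Each table is ``c*x + sqrt(1-c^2)*sd(x)*eps`` with x the designated model
    vector over ``human_ids`` and c = ``human_correlation``, which hits
    Pearson level c in expectation and degenerates to an exact copy at c=1.
    When no model profile is supplied a standard-normal profile is drawn.
    """
    if not human_ids:
        raise ValueError("empty human id list")
    rng = config.rng("human")
    if model_fc is None:
        x = rng.normal(size=len(human_ids))
    else:
        x = np.array([model_fc.entries.get(g, np.nan) for g in human_ids])
        if np.isnan(x).any():
            missing = [g for g, v in zip(human_ids, x) if np.isnan(v)]
            raise ValueError(f"model profile missing genes: {missing[:5]}")
    c = config.human_correlation
    sd_x = float(np.std(x)) or 1.0
    tables: dict[str, FoldChangeTable] = {}
    for cond in CONDITIONS[: config.n_conditions]:
        for tissue in TISSUES[: config.n_tissues]:
            label = f"{cond}_{tissue}"
            eps = rng.normal(size=len(human_ids))
            y = c * x + np.sqrt(max(0.0, 1.0 - c * c)) * sd_x * eps
            tables[label] = FoldChangeTable(label, dict(zip(human_ids, y)))
    return tables
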