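# Methods

This note records the statistical model behind each stage, the parameter
choices that matter, and the places where the published description of the
analysis left the design genuinely open — together with the reading this
package commits to.

## Study design being modeled

Three two-color microarray contrasts over differentiated neurospheres:
untreated APP/PS1 vs wild type (`APP_WT_vs_WT`), HOE-140-treated vs
untreated APP/PS1 (`HOE_APP_vs_APP_WT`), and bradykinin-treated vs
untreated APP/PS1 (`BK_APP_vs_APP_WT`), each with four biological
replicates hybridized with dye swapping.  Every downstream quantity is a
function of per-gene log2 ratios per replicate; normalization upstream of
the log ratios is assumed done (the generator emits already-normalized
ratios, since the upstream normalization applied to the original arrays is
not specified anywhere we could follow).

## Synthetic data generator

The generator's defaults *are* the conditions the test-suite statements are
made under, and they are not tuned per test:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 1000 | probes per array |
| `n_replicates_per_contrast` | 4 | dye-swapped biological replicates |
| `frac_immune_module` | 0.05 | planted immune-module fraction |
| `base_fc_appwt` | +2.0 | planted log2 FC of module genes, APP vs WT |
| `delta_bk` | +1.0 | extra planted log2 FC under bradykinin |
| `delta_hoe` | −1.0 | planted log2 FC reduction under HOE-140 |
| `noise_sd` | 0.3 | per-replicate Gaussian sd of log2 ratios |
| `n_interactions` | 3000 | PPI edges |
| `hub_exponent` | 1.5 | degree-propensity tail heaviness |
| `human_correlation` | 0.5 | target Pearson r of human tables to the model |
| `frac_unexpressed` | 0.02 | non-module probes planted below background |

Genes, module size, noise level and replicate count follow the design
described above; the treatment deltas (±1.0) are chosen once so the
planted module is strictly monotone along HOE → APP → BK with
condition-scale effects (log2 units of 1–3), the kind of separation the
immune panels in this system display.  Noise is i.i.d. Gaussian on log2
ratios; the dye swap is a sign flip on half the replicates, undone by
`ExpressionMatrix.corrected_ratios()`.  Foreground/background intensities
are lognormal with expressed probes lifted ~e above background and a 2%
sliver of non-module probes planted below it, exercising the
expressed-probe filter.  Interactions are drawn configuration-model style:
per-gene propensity u^(−hub_exponent) with u ~ U(0,1) (a Pareto tail), edge
endpoints sampled proportionally, self-loops and duplicates rejected —
producing the hubs that make wSI discriminative.  Human tables are
y = c·x + √(1−c²)·sd(x)·ε against the designated model vector x, which has
Pearson correlation exactly c in expectation and degenerates to a copy at
c = 1.

What the generator does **not** emulate: probe-level image artifacts,
intensity-dependent (loess-type) bias, correlated noise between replicates,
batch structure, or realistic gene-gene correlation outside the planted
module.  Passing tests therefore demonstrate correctness of the statistical
machinery under the declared model, not robustness to the full messiness of
real arrays.

All randomness descends from the single `seed` through fixed named
substreams (expression/interactions/orthologs/gene_sets/human), so one
integer reproduces every artifact byte-identically.

## Differential expression

*Expressed-probe filter.* A probe is expressed when foreground exceeds
background in ≥ `min_support` replicates (default 3 of 4).

*Rank products.* Within each replicate, genes are ranked (rank 1 = most
up-regulated for direction "up", most down-regulated for "down"; average
ranks on ties); RP_g is the geometric mean of the ranks.  The null
permutes the rank vector independently within each replicate;
p_g = (#{RP*_g ≤ RP_g} + 1)/(n_perm + 1).  An `n_perm="exhaustive"` mode
enumerates all (n!)^k per-replicate permutations exactly (no +1
correction), which is what the enumeration oracle in the test suite is
checked against.

*SAM (one-class).* Each contrast is already a two-sample comparison
realized as a ratio, so the statistic is one-class on dye-swap-corrected
ratios: d_g = mean(r_g)/(s_g + s0), with s_g the standard error and s0 the
median of all s_g (the original exchangeability-percentile tuning of s0 is
deliberately not reproduced; at this scale the median fudge factor serves
the same variance-stabilizing purpose).  The null flips replicate signs —
exhaustively over all 2^k patterns when 2^k ≤ n_perm, sampled otherwise.
**Pooling decision:** with k = 4 replicates a per-gene sign-flip null has
only 16 outcomes and its smallest achievable two-sided p is 2/16 > 0.05,
which would make the dual p ≤ 0.05 call structurally impossible.  The SAM
family resolves this by pooling permuted statistics across genes, and that
is the default here (`pool_null=True`): p_g compares |d_g| against all
|d*| over genes × patterns, with the +1 correction.  A per-gene mode is
retained for study.  s0 is held at its observed value across permutations.

*Dual call.* Significant ⇔ rank-product p ≤ α **and** SAM p ≤ α (inclusive,
α = 0.05).  In the pipeline the two rank-product directions are combined
two-sided as p_rp = min(1, 2·min(p_up, p_down)) before the call; the
Bonferroni-style doubling keeps the null call rate at (below) the nominal
level, which the calibration test verifies (≤ 1.5× nominal over 20 seeds).

*Delta-Ct.* Relative expression 2^−(Ct_target − Ct_reference); included
because the qPCR validation arm of the design uses it.

## Progression screen

Putative WT-referenced fold changes are sums of log2 contrasts over the
gene intersection (only genes identified in all three groups are
comparable).  Each gene's triplet (HOE_WT, APP_WT, BK_WT) is correlated
against the ordinal index (1, 2, 3) — the only defensible regressor for a
hypothesized order — giving r, and a two-sided t-test p with n−2 = 1
degree of freedom.  A constant triplet has undefined r and never passes.

The printed screen is |r| > 0.9 **and** p < 0.05, both strict, and both are
exposed as parameters with exactly those defaults.  Note the tension: with
one degree of freedom, p < 0.05 requires |r| ≳ 0.997, so the p rule
dominates the r rule; how the original p-values were computed is not
documented, and this package does not guess — it documents the t-test it
uses and lets the caller relax `p_threshold` (at 1.0 the screen reduces to
the correlation rule, under which ≥ 90% of planted monotone genes pass at
the default noise level).

## Enrichment

The test is the standard one-sided hypergeometric upper tail of the
query/term overlap within the universe; the universe defaults to the genes
detected in the contrast under analysis (detection-aware background),
overridable.  FDR is Benjamini–Hochberg, computed within namespace.
Significance follows the published rules: pathway terms at FDR < 0.05, GO
BP and CC terms at raw p < 0.05, all strict.  Each term carries the
arithmetic mean log2 FC of its overlapping query genes (`average_fc`).  No
GO-graph ancestor propagation is performed; the local GMT is authoritative.

## Weighted network and wSI

Edge weight: w(u,v) = 1 / max(median(|fc_u|, |fc_v|), ε), ε = 10⁻⁶; the
median of two values is their mean.  Two deliberate readings:

- **Magnitudes, not signed FCs.** The inverse-median formula applied to
  signed values yields negative "distances" for downregulated pairs, which
  have no shortest-path semantics.  Absolute values with an ε floor are the
  only reading that keeps the metric well-defined; the sign is kept as node
  metadata.  Consequence: a strongly *down*-regulated pair is just as
  close as a strongly up-regulated one.
- **Normalization before summation.** Raw betweenness grows ~n² while
  closeness is O(1)-ish, so an unnormalized sum would be all betweenness.
  Closeness is (n−1)/Σd and betweenness uses the 2/((n−1)(n−2)) pair
  normalization, putting both summands on [0, 1] before
  wSI = closeness + betweenness.  A `normalized=False` flag exposes the raw
  quantities (closeness then 1/Σd, betweenness unscaled).

Centralities are computed on the main connected component (largest; ties
broken by smallest member id) with Dijkstra shortest paths and Brandes
pair-dependency betweenness counting *all* co-minimal paths — the standard,
deterministic semantics.  The test suite holds these equal to a brute-force
all-simple-paths enumeration on 100+ random graphs of ≤ 7 nodes.

## Cross-dataset comparison

Profiles (FC or wSI per gene) are restricted to the complete-case
intersection after mapping mouse ids through the ortholog table (no
imputation; an explicit uppercase-normalization option exists for symbol
matching, since silent case folding hides mapping bugs).  Correlation
matrices are plain Pearson with exact symmetry and unit diagonal; constant
profiles yield NaN rows/columns rather than a fabricated value.  Clustering
is agglomerative Ward on Euclidean distances (scipy linkage), checked
against a brute-force agglomeration that recomputes the variance-increase
distance √(2|A||B|/(|A|+|B|)) · ‖c_A − c_B‖ at every step.  Heatmaps are
emitted as data (matrix + linkage); plotting is presentation, not
computation.

## Numerical choices and degenerate inputs

- Permutation p-values use the +1/(n_perm+1) correction (valid,
  super-uniform under the null); exhaustive enumerations use exact counts.
- Tie comparisons in permutation counting use a 10⁻¹² slack so that exact
  ties are counted as ties in floating point.
- Rank ties take average ranks (deterministic); a constant replicate
  proceeds with a warning.
- Duplicate gene ids, non-numeric values, mismatched gene universes, empty
  intersections, and disconnected networks fed to the centrality step are
  hard errors with the offender named; self-loop interaction lines are
  skipped with a warning.
- Problem sizes in the shipped checks (1000-gene simulations over 20
  seeds, ≤ 7-node oracle graphs, ≤ 6-profile Ward oracles, 200-gene
  correlation recovery) are chosen so the whole suite runs in seconds on a
  single CPU while keeping every statistical statement testable.

## Known limitations

- The published transcript counts (3,639 / 978 / 835 differential
  transcripts, term counts, the 8-mouse/5-human progression genes, the 11
  genes shared with the patient dataset) depend on the deposited raw
  arrays and on specific UniProt/Ensembl/GO/Reactome versions; they are
  out of scope here and not reproduced.
- The enrichment stage implements membership ORA; whether the original
  web-tool runs were FC-weighted is unknowable from the description, and
  `average_fc` is reported as a summary, matching the stated definition.
- Interaction lists are taken as given binary pairs; multi-protein complex
  records must be expanded upstream.
- The wSI sign and normalization readings above are this package's own
  resolutions of genuinely under-specified points; both are surfaced as
  flags/metadata rather than buried.
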