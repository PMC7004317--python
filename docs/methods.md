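# Methods

## Statistical model and procedure

The pipeline operates on a normalized log2 gene-expression matrix with two
sample groups, control and case. It makes the standard working assumptions
of two-group microarray analysis: expression values are approximately
Gaussian per gene on the log2 scale, samples are independent, and genes are
tested marginally.

**Differential expression.** Per gene, an unpaired two-sample *t*-test
(Student's pooled-variance form by default; Welch's form behind a flag)
compares case against control, the statistic signed as
mean(case) − mean(control). Raw *p* values are adjusted by the
Benjamini–Hochberg step-up rule, q₍ᵢ₎ = min over j ≥ i of min(1, p₍ⱼ₎·m/j)
over the ascending order statistics. A gene passes when its adjusted *p*
(raw *p* behind a flag) is at most α.

**Centrality.** The interaction edge list is cleaned to a simple undirected
graph — self-loops dropped, (a, b)/(b, a) merged, symbols upper-cased — and
induced on the DEGs. Degree DC(v) is the partner count. Betweenness BC(v)
sums σ_st(v)/σ_st over unordered pairs s ≠ v ≠ t, computed by Brandes'
single-source accumulation (via networkx) and normalized by
(n − 1)(n − 2)/2 so that BC ∈ [0, 1]. Pairs in different components
contribute zero; disconnected graphs keep the global normalization.

**Hub and bottleneck calls.** The hub cutoff is mean(DC) + k·SD(DC) with
k = 2 and sample SD (ddof = 1) by default; a hub must *strictly* exceed the
cutoff, so a constant-degree network has no hubs rather than all of them.
Bottlenecks are the top quantile (default 0.25) of the betweenness
distribution: rank descending, take ceil(q·n), extend to all nodes tied
with the boundary value. Zero-betweenness nodes are never called
bottlenecks — a node that no shortest path passes through is not a
bottleneck in any meaningful sense — so when the boundary falls at zero
only the positive-BC nodes are kept, and an all-zero distribution yields an
empty call with a warning.

**SS-PIN.** Hubs, bottlenecks and the salt-sensitivity label set are
unioned into HBS (overlaps reported by inclusion–exclusion); the SS-PIN is
the induced subgraph of the PIN on HBS. SSG labels absent from the network
are kept in the label set but reported as unmapped and excluded from the
subnetwork, since nothing can be said about their interactions.

**Differential co-expression.** Sample Pearson correlations are computed
for all unordered gene pairs of the SS-PIN, separately over the case and
the control samples. Zero-variance genes yield missing (NaN) correlations,
never 0. Disease edges are pairs with r ≥ threshold (default 0.8,
positive-only: the screen targets strong positive co-expression; an
absolute-value mode exists for exploration). Each disease edge is annotated
with its control-condition r; a missing control value is carried as NaN
with a warning, not dropped.

**Prioritization.** Co-expressed SSGs are classified *reported* if they
belong to the disease annotation set, else *unreported*. A candidate's
connectivity is the number of contrast rows incident to it. Unreported
candidates with connectivity ≥ min_connectivity (default 3) are selected,
ranked by connectivity descending with alphabetical tie-break. The
published analysis did not state its shortlist rule explicitly;
min_connectivity = 3 reproduces the published five-gene shortlist on the
bundled reference tables and is exposed in the configuration rather than
hard-coded.

**Enrichment.** Over-representation of a query set in each GMT library set
is scored by the upper-tail hypergeometric probability P(X ≥ overlap) with
population |universe|, successes |set ∩ universe| and draws |query|,
BH-adjusted across the library. The universe defaults to the analyzed
network's nodes and is overridable. This is a deliberately generic,
corpus-free replacement for web-service annotation systems, so the stage
runs offline and its numbers depend only on the supplied GMT files.

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| deg.alpha | 0.05 | probability | conventional FDR level |
| deg.use_adjusted | true | — | "FDR at 0.05" reads as a threshold on adjusted p; raw-p mode selectable |
| hub.multiplier | 2 | SDs | the mean + 2 SD hub rule |
| hub.sd_mode | sample | — | ddof = 1; population mode selectable |
| bottleneck.quantile | 0.25 | fraction | top-quartile betweenness rule |
| coexpr.threshold | 0.8 | r | strong positive co-expression screen |
| prioritize.min_connectivity | 3 | partners | reproduces the published shortlist; a modeling choice, configurable |

## Synthetic data

The generator emulates the targeted study design: 14 control and 16 case
samples by default, gene baselines drawn once from N(8, 2) log2 units
(typical microarray scale; the baseline magnitude is irrelevant to both the
t-test and correlation), i.i.d. Gaussian noise with sd 0.5, 50 planted DE
genes shifted by 2 log2 units in the case group.

Co-expression blocks use a shared latent factor: for block gene g and
sample s in the block's active condition(s), the noise term is
√ρ·f_s + √(1 − ρ)·ε_gs with f and ε standard normal, giving expected
pairwise Pearson correlation exactly ρ at O(block size) cost (a Cholesky
construction would be equivalent but quadratic). A `case_only` block
correlates only in the case samples — the differential co-expression
signal; `both` correlates everywhere. One default block of 10 genes at
ρ = 0.9 ties to the pipeline's r ≥ 0.8 screen. Planted blocks are nested
inside the planted DE set (both are sliced from the front of one shuffled
gene order), mirroring the studied setting in which the interesting SSGs
are themselves differentially expressed and therefore present in the
DEG-induced network; the case-group mean shift is constant within a sample
group and does not perturb within-condition correlations.

The synthetic interaction network shares the expression symbol universe
(500 nodes by default). Non-hub, non-bridge nodes are split into 4
communities, each internally Erdős–Rényi at p = 0.03 (background degree
≈ 3.7); communities are connected *only* through 3 designated bridge nodes,
each attached to at least a quarter of every community — guaranteeing the
bridges high betweenness without disconnecting the graph. Five hub nodes
then wire to 40 partners each (≈ 10× background degree) by preferential
attachment. All randomness flows from one integer seed through
deterministically spawned sub-streams, so equal seeds give bit-identical
matrices and edge sets.

What the generator does **not** emulate: probe-level effects, batch
effects, heavy-tailed or count-based (RNA-seq) noise, correlated background
structure beyond the planted blocks, and the degree mixing of real
interactomes. Passing recovery tests therefore demonstrates that the
pipeline's operations are correct and well-calibrated under their own
assumptions, not that the biological conclusions of any particular dataset
are reproduced.

## Numerical choices

- Correlation matrices are rounded at 1e-12 before thresholding, so
  identical expression profiles sit exactly at r = 1 and boundary
  thresholds (e.g. r ≥ 1.0) behave deterministically despite BLAS
  summation-order noise; values are clipped to [−1, 1].
- Degenerate t-tests: zero variance in both groups with equal means gives
  t = 0, p = 1; with unequal means the difference is infinitely
  significant under the model, recorded as p = 0 with a signed infinite t
  and a logged warning.
- Correlation r values are serialized to 4 decimal places, matching the
  precision of the reference tables; the round-trip tests assert equality
  at that precision.
- Hub calls on a single-node network treat the undefined sample SD as 0
  with a warning. Betweenness on fewer than 3 nodes is 0 by convention.
- Ties: bottleneck boundary ties are included (order-independence);
  prioritization ties rank alphabetically.

## Scale of the shipped analyses

The default test and acceptance runs use desk-scale problem sizes chosen to
exercise every code path with comfortable statistical margins: 500-gene
matrices (200 for null-rate checks, 60-gene matrices with 100 + 100 samples
for block-recovery checks), 500-node networks over 10 seeds, 20-seed
Monte-Carlo replicates, and 200 random ≤ 12-node graphs for the
betweenness oracle. The study-scale set arithmetic (40/502/47 genes,
2691 nodes, 15474 edges) is exact and runs at full size.

## Known limitations

- The t-test assumes approximate normality per gene; no moderated-variance
  (empirical Bayes) variant is provided.
- Thresholded co-expression is a point decision: no confidence statement
  accompanies an edge, and differential co-expression is not tested
  formally (no Fisher z), matching the analysis being reproduced.
- The bottleneck quantile is taken over all analyzed nodes; on very sparse
  graphs where most betweenness is zero the call reduces to the positive-BC
  nodes.
- Enrichment treats gene sets as flat lists; no ontology-graph propagation.
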