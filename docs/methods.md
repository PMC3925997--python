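# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `crossnet`, and what the synthetic benchmark does and
does not establish.

## Mutual information estimation

Pairwise dependence is measured with a B-spline binning estimator. Each
sample vector is rank-transformed (average ranks for ties) and mapped
linearly onto the knot domain `[0, M − k + 1]`, where `M` is the number of
bins and `k` the spline order. The knot vector is uniform with the first
and last knot repeated `k` times, giving `M` basis functions that sum to 1
everywhere; each sample therefore contributes soft membership weights over
at most `k` adjacent bins. Order 1 degenerates to indicator functions —
i.e. an ordinary hard histogram — which is the anchor used by the test
suite's independent oracle. Plugin entropies H(X), H(Y) are computed from
the column sums of the weight matrices and H(X,Y) from the weighted joint
`p(a,b) = (1/n) Σ_s w_a(x_s) w_b(y_s)`.

Rank transformation makes the estimate invariant to monotone
transformations of the data and robust to outliers, which is the main
reason to prefer MI over Pearson correlation on heterogeneous compendia.

**Normalization.** MI is divided by `min(H(X), H(Y))`. Because the joint's
marginals equal the per-gene marginals by construction, `MI ≤ min(H)`
analytically, so scores lie in [0, 1]. Floating-point round-off can exceed
the bound by ~1e-16; values are clipped to [0, 1]. Two caveats worth
knowing:

* a *constant* vector has zero marginal entropy; any pair involving it
  scores 0 (genes with zero variance are kept in the universe rather than
  dropped, so gene sets stay aligned across thresholds);
* for `k > 1` the soft joint of two *identical* vectors is not diagonal —
  the spline spread inflates H(X,Y) — so the self-score at `M = 10, k = 3`
  is ≈ 0.53, not 1. Only the hard-histogram limit (`k = 1`) attains exactly
  1 for duplicated profiles. The [0, 1] bound itself holds at every order.

**Defaults.** `M = clamp(round(sqrt(n_samples)), 4, 16)` (the square-root
rule keeps counts per 2-D bin ≈ constant as n grows), `k = 3`. At least 8
samples are required; fewer make the plugin entropies meaningless.

## CLR background correction

For gene *i*, the mean μ_i and standard deviation σ_i of its off-diagonal
MI row define a local background; `z_i(j) = max(0, (MI_ij − μ_i)/σ_i)` and
`CLR_ij = sqrt(z_i(j)² + z_j(i)²)`. σ_i = 0 is handled as z_i ≡ 0. CLR
removes per-gene biases (e.g. genes that are promiscuously correlated with
everything) and puts all species on a comparable Z-score scale, which is
what makes a *shared* threshold across species meaningful. One structural
consequence used below: when a large fraction of a gene's partners are
truly correlated, the background becomes bimodal and within-module Z-scores
shrink — very large modules partially self-mask.

Networks are built with an inclusive edge rule (`CLR ≥ t`, ties kept);
higher-threshold networks are exact subgraphs of lower-threshold ones.
Isolated genes remain as nodes. The regulation view directs every
TF-incident link TF→gene and keeps TF–TF links as reciprocal directed
pairs; no one-way TF→TF direction is claimed anywhere downstream.

## Degree-distribution classification

The connected-node degree sample is fitted to

* a discrete power law `P(x) ∝ x^−α` for `x ≥ x_min`, normalized by the
  Hurwitz zeta function, α by bounded MLE, x_min by scanning observed
  degrees and minimizing the KS distance of the tail fit. Candidate x_min
  values must retain at least max(10, n/5) tail points — without that
  constraint the scan can select a tiny tail on which the subsequent model
  comparison has no power;
* a Poisson with λ = sample mean (the MLE), truncated to the common support
  `x ≥ x_min` for the comparison.

Classification is by total log-likelihood gap on the common support with a
margin of 2: `scale_free` if the power law leads by ≥ 2, `random` if
Poisson leads by ≥ 2, `indeterminate` otherwise (including the
all-degrees-equal case). At least 50 connected nodes are required.

## Conservation procedures

**Rankings.** Top/bottom-fraction membership (default 10%, motifs 20%) is
exactly ⌈f·n⌉ items, ranked by value with ties broken by identifier, so
results are deterministic. Unconnected genes are excluded from centrality
rankings; GO subnetworks require 10–1000 connected annotated genes.
Empirical p-values from randomized gene/term lists use the (r+1)/(n_rand+1)
correction and never report 0.

**Neighbourhood tests.** For gene A (species S1) and ortholog A′ (S2): N =
genes in the S1 universe (all matrix genes, configurable), n = |neighbours
of A|, k = |distinct S1 genes orthologous to neighbours of A′|, x = overlap.
`p_conserved = P(X ≥ x)`, `p_diverged = P(X ≤ x)` under
Hypergeometric(N, k, n). BH-FDR is applied separately to the conserved and
diverged one-sided families of each directional comparison — pooling the
two families would let the (many, tiny) conserved p-values distort the
diverged ranks. Categories: Conserved / Conserved-and-Diverged / Diverged /
None; the "most significant" ortholog is chosen by (p, overlap, bit-score,
identifier) so reciprocal-best comparisons are fully deterministic. Missing
bit-scores rank as −∞ (never "most similar").

The randomized-network alternative to FDR thresholds (name-shuffled
networks) is available for link conservation as an explicit null sample;
for neighbourhood significance the FDR route is the default on cost
grounds.

**Link conservation** counts S1 links whose endpoints are both eligible
(connected, with a connected ortholog) and asks whether *any* ortholog pair
of the endpoints is linked in S2; the denominator is links, not gene pairs.

## The synthetic-data generator

Each module m has a per-sample latent factor `z_m ~ N(0,1)`; a gene in m is
`loading · z_m + N(0, noise_sd)` with `loading ~ U(0.8, 1.5)`; off-module
genes follow private factors of the same form. Default scenario: 2 species,
300 genes × 100 samples each, 4 modules of 70–75 genes, ortholog classes
90% conserved (same module across species) / 5% diverged (different
modules) / 5% unrelated (no ortholog), 10% of conserved partners duplicated
into a conserved `_a` copy (matching module) and a diverged `_b` copy
(another module), one designated TF per module plus extras to 8%, one GO
term per module plus a background term, additive noise sd 0.5. Bit-scores
are ~200 ± 10, and for duplicated genes a fair coin decides whether the
*diverged* copy receives the higher score, so sequence similarity is
deliberately uninformative about regulatory conservation.

Three design choices deserve their rationale:

* **Loading floor 0.8.** At noise sd 0.5 a loading of 0.5 gives SNR 1; such
  genes have no recoverable neighbourhood at CLR 2 and their planted labels
  are undecidable in principle. The floor keeps the weakest module gene at
  SNR ≈ 2.6 so the planted truth is recoverable — which is the point of a
  planted benchmark.
* **Module size vs count.** Divergence detection needs the null overlap
  expectation `n·k/N` to dominate the residual overlap between a gene's
  module and the mapped neighbourhood of its diverged partner. Four modules
  of ~72 genes give `n·k/N ≈ 16` against a contamination of ≈ 3–4 genes,
  putting the lower hypergeometric tail near 1e-4 — comfortably below the
  BH cutoff — whereas many small modules (low `n·k/N`) or three very large
  ones (CLR self-masking, see above) both lose power.
* **Round-robin placement of diverged partners.** Each source module cycles
  its diverged/duplicated-copy partners through the other modules in turn.
  Availability-driven placement tended to dump all of one module's diverged
  copies into whichever module still had free slots, making the planted
  divergences contaminate each other's mapped neighbourhoods.

All randomness flows from `numpy.random.default_rng([seed, stream])` with
separate streams for layout and per-species expression, so
`simulate_expression` is reproducible independently of call order and a
regenerated study is byte-identical.

**What passing the benchmark shows — and what it does not.** The generator
reproduces the statistical skeleton the analysis relies on (modular
co-expression, ortholog classes with matched/mismatched neighbourhoods,
paralog subfunctionalization, uninformative bit-scores). It does not
emulate microarray probe effects, cross-hybridization between paralogs,
heterogeneous experiment batches, overlapping modules, or realistic
scale-free topology at low thresholds; recovery rates on it are therefore
an upper bound on what identical settings would achieve on real compendia.

## Motif analysis

Motif classes are typed directed graphs (TF/gene) with reciprocal TF–TF and
TF→gene links only, identified by the minimal bit-string of the typed
adjacency matrix over type-preserving permutations. Exhaustive enumeration
gives 6 connected classes at size 3 (2 all-TF, 3 with two TFs, 1 star) and
24 at size 4 (6 all-TF, 11 with one gene, 6 with two genes including the
bi-fan, 1 star). The class named `ffl` — two connected TFs regulating the
same gene — is the feed-forward-loop *pattern* of this link semantics, not
a one-way-directed FFL. Counting is an induced-subgraph census (ESU
enumeration), so class counts sum to the number of connected induced
subgraphs, a property the tests verify against brute-force subset
enumeration. Null counts come from degree-preserving rewiring: bipartite
double edge swaps for TF→gene (preserving each TF's out-degree and each
gene's in-degree) and undirected swaps for TF–TF, 10 swap attempts per
edge, strata kept separate so rewired networks remain valid regulation
networks.

## Numerical conventions and degenerate inputs

Ratios with zero denominators (connectivity with no internal links, Z with
zero randomized spread, tau of an all-zero gene, conservation fractions
with no eligible items) are NaN, reported, and excluded from rankings.
Readers reject malformed files with the offending line number instead of
repairing them. Warnings (unknown TF IDs, under-sized rewiring strata,
n_rand < 100) never abort an analysis.

## Problem sizes

The default benchmark scenario (2 × 300 genes × 100 samples, CLR grid 2–5,
100 randomizations where nulls are sampled) runs the full pipeline in well
under a minute on one CPU; motif Z-scores on the module subnetworks with
100 rewired networks add a few seconds per species. These sizes were chosen
so the planted effects are detected with wide margins while the whole suite
stays interactive.

## Known limitations

* The min-entropy MI normalization is one of several reasonable choices;
  scores are comparable within a run but not across different bin counts.
* The power-law/Poisson comparison is a two-model likelihood contest, not a
  goodness-of-fit test; `scale_free` means "power law beats Poisson", not
  "power law is true".
* N in the hypergeometric test counts all genes in the species' matrix;
  restricting to connected genes would shift all tails conservatively and
  is available via the `N` parameter.
* Reciprocal classification resolves ties deterministically by identifier;
  biological ties are invisible to it.
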