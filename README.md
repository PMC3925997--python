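# crossnet

Comparative analysis of gene co-expression networks across species
("comparative regulomics"): infer a network per species from expression
compendia, characterize its organization, and quantify — gene by gene —
where regulation has been conserved and where it has diverged.

The package is aimed at computational biologists who have per-species
expression matrices, an ortholog map (OrthoMCL-style groups) and a list of
annotated transcription factors, and who want to answer questions such as:
*which genes keep the same co-expression neighbourhood in another species?*
*After a gene duplication, which paralog retained the ancestral regulation?*
*Is the most sequence-similar ortholog also the most functionally
equivalent one?* A synthetic-data generator with planted, labelled
conservation structure makes every stage of the pipeline testable without
any external data.

## The method

**Network inference.** For every gene pair the package computes mutual
information with a B-spline estimator: sample values are rank-transformed,
given soft membership weights over *M* bins by B-spline basis functions of
order *k* (order 1 reduces to a hard histogram), and plugin entropies are
taken from the weighted counts,

    MI(X,Y) = [H(X) + H(Y) − H(X,Y)] / min(H(X), H(Y))  ∈ [0, 1].

The context likelihood of relatedness (CLR) then background-corrects each
pair against the two genes' own MI distributions:

    z_i(j) = max(0, (MI_ij − μ_i) / σ_i),   CLR_ij = sqrt(z_i(j)² + z_j(i)²).

Thresholding the CLR matrix yields the undirected co-expression network;
links incident to annotated TFs form the directed regulation network
(TF→gene; TF–TF links are kept reciprocal — no one-way TF direction is ever
inferred).

**Network properties and motifs.** Degree distributions are fitted by
maximum likelihood to a discrete power law (Hurwitz-zeta normalization,
KS-minimizing x_min) and a Poisson, and classified scale-free / random /
indeterminate by the log-likelihood gap. Centralities (degree, average
nearest-neighbour degree, betweenness), GO-subnetwork statistics (density,
connectivity, in/outgoing regulation connectivity), the tau
tissue-specificity index, and typed 3/4-node motif censuses with Z-scores
against degree-preserving rewired networks are all provided, together with
the top-decile + randomized-list procedure for scoring their cross-species
conservation.

**Cross-species comparison.** A link A–B is conserved if any ortholog of A
links to any ortholog of B in the other species. A gene's neighbourhood is
compared with an ortholog's by mapping the ortholog's neighbours back
through the ortholog groups and testing the overlap *x* against
Hypergeometric(N, k, n) — N genes in the focal species, n neighbours of A,
k mapped neighbours of the ortholog. The upper tail scores conservation,
the lower tail divergence; Benjamini–Hochberg FDR (default 0.05) is applied
per one-sided family, and genes are categorized Conserved /
Conserved-and-Diverged / Diverged / None, with reciprocal-best,
multi-ortholog and sequence-similarity-versus-regulation summaries on top.

## Worked example

`examples/05_cross_species.py` simulates the default two-species scenario
(300 genes × 100 samples per species, four planted co-expression modules,
ortholog classes 90% conserved / 5% diverged / 5% unrelated, 10% of
conserved partners duplicated into one conserved `_a` and one diverged `_b`
copy), infers both networks at CLR threshold 2 and classifies every gene:

```
link conservation sp1->sp2: 0.85 (name-shuffled nulls never exceed 0.29)
neighbourhood tests: 290 ortholog pairs, 260 genes classified
categories: {'Conserved': 221, 'Conserved-and-Diverged': 30, 'Diverged': 8, 'None': 1}
genes with >= 2 orthologs: {'Conserved-and-Diverged': 30}
most sequence-similar ortholog is also most conserved: 15 of 30 conserved-and-diverged genes
```

Reading the numbers: 85% of co-expression links among eligible genes are
conserved, far above anything the 100 name-shuffled null networks reach.
All 30 duplicated genes are recovered as Conserved-and-Diverged — one
paralog copy kept the planted module, the other was rewired. Because the
generator flips a fair coin for which copy receives the higher BLAST
bit-score, sequence similarity picks the conserved copy in only 15 of the
30 cases — exactly the situation in which neighbourhood conservation, not
sequence, should choose the ortholog.

The other examples cover simulation (`01`), inference (`02`), degree fits,
centralities and tau (`03`), and motif enrichment (`04`). A thin CLI wraps
the library (`crossnet simulate`, `crossnet infer`, `crossnet run`); a full
configured pipeline writes every artefact with checksums into a manifest:

```bash
crossnet show-config > config.yaml
crossnet run --config config.yaml
```

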