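"""Cross-species conservation of links and network neighbourhoods.

Two species' thresholded networks are compared through an ortholog map.  A
link A–B in species S1 is conserved if some ortholog of A links to some
ortholog of B in S2.  A gene's neighbourhood is compared to an ortholog's by
mapping the ortholog's neighbours back to S1 and testing the overlap with
the gene's own neighbourhood against the hypergeometric distribution with
N = genes in S1, n = |neighbourhood of A|, k = |mapped neighbours of A'|
(distinct S1 genes) and x = overlap: the upper tail scores conservation, the
lower tail divergence.  Benjamini-Hochberg FDR is applied separately to the
conserved-tail and diverged-tail p-value families of a directional
comparison, and genes are categorized as Conserved, Conserved-and-Diverged,
Diverged or None.  Reciprocal, multi-ortholog, sequence-versus-regulation
and three-species core summaries refine the picture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .inference import GeneNetwork
from .io import OrthologMap

__all__ = [
    "NeighbourhoodTest",
    "ConservationReport",
    "eligible_genes",
    "link_conservation",
    "randomized_link_conservation",
    "neighbourhood_test",
    "compare_neighbourhoods",
    "classify_genes",
    "reciprocal_classify",
    "multi_ortholog_summary",
    "sequence_vs_regulation",
    "core_conservation",
]

CONSERVED = "Conserved"
DIVERGED = "Diverged"
BOTH = "Conserved-and-Diverged"
NONE = "None"
UNIQUE = "Uniquely conserved"


@dataclass
class NeighbourhoodTest:
    """Hypergeometric neighbourhood-overlap test for one ortholog pair."""

    gene: str
    ortholog: str
    N: int
    n: int
    k: int
    x: int
    p_conserved: float
    p_diverged: float
    bitscore: float = float("-inf")
    q_conserved: float = math.nan
    q_diverged: float = math.nan


@dataclass
class ConservationReport:
    """Directional comparison S1→S2: all tests plus per-gene categories."""

    species_from: str
    species_to: str
    tests: list[NeighbourhoodTest]
    category: dict[str, str] = field(default_factory=dict)
    fdr: float = 0.05

    def genes_in(self, *categories: str) -> set[str]:
        return {g for g, c in self.category.items() if c in categories}

    def fractions(self) -> dict[str, float]:
        n = len(self.category)
        if n == 0:
            return {}
        counts: dict[str, int] = {}
        for c in self.category.values():
            counts[c] = counts.get(c, 0) + 1
        return {c: counts.get(c, 0) / n for c in (CONSERVED, BOTH, DIVERGED, NONE, UNIQUE)}


# ---------------------------------------------------------------------------
# eligibility and link conservation


def eligible_genes(
    net1: GeneNetwork,
    net2: GeneNetwork,
    omap: OrthologMap,
    sp1: str,
    sp2: str,
) -> set[str]:
    """Genes connected in S1 with at least one ortholog connected in S2."""
    connected2 = net2.connected_genes()
    out = set()
    for gene in net1.connected_genes():
        if omap.orthologs(sp1, gene, sp2) & connected2:
            out.add(gene)
    return out


def link_conservation(
    net1: GeneNetwork,
    net2: GeneNetwork,
    omap: OrthologMap,
    sp1: str,
    sp2: str,
) -> tuple[float, list[tuple[str, str, bool]]]:
    """Fraction of S1 links (among eligible genes) conserved in S2.

    A link A–B is conserved if any ortholog of A links to any ortholog of B
    in S2.  Returns (fraction, per-link flags); fraction is NaN with zero
    eligible links.
    """
    eligible = eligible_genes(net1, net2, omap, sp1, sp2)
    flags: list[tuple[str, str, bool]] = []
    n_cons = 0
    for a, b in net1.graph.edges:
        if a not in eligible or b not in eligible:
            continue
        orth_a = omap.orthologs(sp1, a, sp2)
        orth_b = omap.orthologs(sp1, b, sp2)
        conserved = any(
            net2.graph.has_edge(oa, ob)
            for oa in orth_a
            for ob in orth_b
            if net2.graph.has_node(oa) and net2.graph.has_node(ob)
        )
        flags.append((a, b, conserved))
        n_cons += conserved
    fraction = n_cons / len(flags) if flags else math.nan
    return fraction, flags


def randomized_link_conservation(
    net1: GeneNetwork,
    net2: GeneNetwork,
    omap: OrthologMap,
    sp1: str,
    sp2: str,
    n_rand: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null link-conservation fractions from name-shuffled S1 networks.

    Each randomization permutes the gene labels of the S1 network (topology
    intact) and recomputes the conserved-link fraction.
    """
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    rng = np.random.default_rng(seed)
    nodes = list(net1.graph.nodes)
    fractions = np.empty(n_rand)
    for r in range(n_rand):
        perm = rng.permutation(len(nodes))
        mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
        import networkx as nx

        shuffled = GeneNetwork(
            graph=nx.relabel_nodes(net1.graph, mapping, copy=True),
            tf_ids={mapping.get(t, t) for t in net1.tf_ids},
            threshold=net1.threshold,
        )
        fractions[r], _ = link_conservation(shuffled, net2, omap, sp1, sp2)
    return fractions


# ---------------------------------------------------------------------------
# neighbourhood tests


def _mapped_neighbours(
    ortholog: str, net2: GeneNetwork, omap: OrthologMap, sp1: str, sp2: str
) -> set[str]:
    mapped: set[str] = set()
    for nbr in net2.neighbours(ortholog):
        mapped |= omap.orthologs(sp2, nbr, sp1)
    return mapped


def neighbourhood_test(
    gene: str,
    ortholog: str,
    net1: GeneNetwork,
    net2: GeneNetwork,
    omap: OrthologMap,
    sp1: str,
    sp2: str,
    N: int | None = None,
) -> NeighbourhoodTest:
    """Hypergeometric overlap test between a gene's neighbourhood and an
    ortholog's neighbourhood mapped back to S1.

    N defaults to the number of genes in the S1 network's universe
    (including isolated nodes).  The mapped neighbour set is de-duplicated.
    """
    if ortholog not in omap.orthologs(sp1, gene, sp2):
        raise ValueError(f"{ortholog!r} is not a predicted ortholog of {gene!r}")
    if N is None:
        N = net1.graph.number_of_nodes()
    nbh = net1.neighbours(gene)
    mapped = _mapped_neighbours(ortholog, net2, omap, sp1, sp2)
    n, k = len(nbh), len(mapped)
    x = len(nbh & mapped)
    p_cons = float(hypergeom.sf(x - 1, N, k, n))
    p_div = float(hypergeom.cdf(x, N, k, n))
    return NeighbourhoodTest(
        gene=gene,
        ortholog=ortholog,
        N=N,
        n=n,
        k=k,
        x=x,
        p_conserved=min(p_cons, 1.0),
        p_diverged=min(p_div, 1.0),
        bitscore=omap.get_bitscore(gene, ortholog),
    )


def compare_neighbourhoods(
    net1: GeneNetwork,
    net2: GeneNetwork,
    omap: OrthologMap,
    sp1: str,
    sp2: str,
    N: int | None = None,
) -> list[NeighbourhoodTest]:
    """All (eligible gene, connected ortholog) neighbourhood tests S1→S2."""
    connected2 = net2.connected_genes()
    tests = []
    for gene in sorted(eligible_genes(net1, net2, omap, sp1, sp2)):
        for orth in sorted(omap.orthologs(sp1, gene, sp2) & connected2):
            tests.append(
                neighbourhood_test(gene, orth, net1, net2, omap, sp1, sp2, N=N)
            )
    return tests


def _apply_fdr(tests: list[NeighbourhoodTest]) -> None:
    """BH correction, conserved and diverged tails as separate families."""
    if not tests:
        return
    qc = multipletests([t.p_conserved for t in tests], method="fdr_bh")[1]
    qd = multipletests([t.p_diverged for t in tests], method="fdr_bh")[1]
    for t, a, b in zip(tests, qc, qd):
        t.q_conserved = float(a)
        t.q_diverged = float(b)


def classify_genes(
    tests: list[NeighbourhoodTest],
    sp1: str = "S1",
    sp2: str = "S2",
    fdr: float = 0.05,
) -> ConservationReport:
    """Per-gene conservation categories from a directional test set.

    A gene is Conserved with at least one ortholog passing the conserved-tail
    FDR, Diverged with at least one passing the diverged tail,
    Conserved-and-Diverged with both (same or different orthologs), and None
    otherwise.
    """
    if not tests:
        raise ValueError("empty test set")
    _apply_fdr(tests)
    per_gene: dict[str, list[NeighbourhoodTest]] = {}
    for t in tests:
        per_gene.setdefault(t.gene, []).append(t)
    category = {}
    for gene, ts in per_gene.items():
        has_c = any(t.q_conserved < fdr for t in ts)
        has_d = any(t.q_diverged < fdr for t in ts)
        if has_c and has_d:
            category[gene] = BOTH
        elif has_c:
            category[gene] = CONSERVED
        elif has_d:
            category[gene] = DIVERGED
        else:
            category[gene] = NONE
    return ConservationReport(
        species_from=sp1, species_to=sp2, tests=tests, category=category, fdr=fdr
    )


# deterministic "most significant" orderings
def _cons_key(t: NeighbourhoodTest):
    return (t.p_conserved, -t.x, -t.bitscore, t.ortholog)


def _div_key(t: NeighbourhoodTest):
    return (t.p_diverged, t.x, -t.bitscore, t.ortholog)


def _best(tests: list[NeighbourhoodTest], key) -> NeighbourhoodTest:
    return min(tests, key=key)


def reciprocal_classify(
    report12: ConservationReport,
    report21: ConservationReport,
    fdr: float = 0.05,
) -> ConservationReport:
    """Reciprocal-best neighbourhood conservation.

    A gene A is reciprocally conserved iff its most significant conserved
    ortholog A' has A as its own most significant conserved ortholog and both
    directional tests pass the FDR; likewise for divergence.  Categories are
    Conserved, Diverged or None (both significant reciprocally → the
    Conserved-and-Diverged label is kept for completeness).
    """
    by_gene_12: dict[str, list[NeighbourhoodTest]] = {}
    for t in report12.tests:
        by_gene_12.setdefault(t.gene, []).append(t)
    by_gene_21: dict[str, list[NeighbourhoodTest]] = {}
    for t in report21.tests:
        by_gene_21.setdefault(t.gene, []).append(t)
    q21_cons = {(t.gene, t.ortholog): t.q_conserved for t in report21.tests}
    q21_div = {(t.gene, t.ortholog): t.q_diverged for t in report21.tests}

    category = {}
    for gene, ts in by_gene_12.items():
        best_c = _best(ts, _cons_key)
        cons = False
        if best_c.q_conserved < fdr and best_c.ortholog in by_gene_21:
            back = _best(by_gene_21[best_c.ortholog], _cons_key)
            cons = (
                back.ortholog == gene
                and q21_cons.get((best_c.ortholog, gene), 1.0) < fdr
            )
        best_d = _best(ts, _div_key)
        div = False
        if best_d.q_diverged < fdr and best_d.ortholog in by_gene_21:
            back = _best(by_gene_21[best_d.ortholog], _div_key)
            div = (
                back.ortholog == gene
                and q21_div.get((best_d.ortholog, gene), 1.0) < fdr
            )
        if cons and div:
            category[gene] = BOTH
        elif cons:
            category[gene] = CONSERVED
        elif div:
            category[gene] = DIVERGED
        else:
            category[gene] = NONE
    return ConservationReport(
        species_from=report12.species_from,
        species_to=report12.species_to,
        tests=report12.tests,
        category=category,
        fdr=fdr,
    )


def multi_ortholog_summary(
    report: ConservationReport,
    omap: OrthologMap,
    fdr: float | None = None,
) -> dict[str, str]:
    """Categories for genes with two or more predicted orthologs.

    Precedence: Uniquely conserved (every tested ortholog conserved, at least
    two) > Conserved-and-Diverged > Conserved > Diverged > None.
    """
    fdr = report.fdr if fdr is None else fdr
    sp1, sp2 = report.species_from, report.species_to
    per_gene: dict[str, list[NeighbourhoodTest]] = {}
    for t in report.tests:
        per_gene.setdefault(t.gene, []).append(t)
    out = {}
    for gene, ts in per_gene.items():
        if len(omap.orthologs(sp1, gene, sp2)) < 2:
            continue
        cons = [t for t in ts if t.q_conserved < fdr]
        div = [t for t in ts if t.q_diverged < fdr]
        if len(cons) == len(ts) and len(ts) >= 2 and not div:
            out[gene] = UNIQUE
        elif cons and div:
            out[gene] = BOTH
        elif cons:
            out[gene] = CONSERVED
        elif div:
            out[gene] = DIVERGED
        else:
            out[gene] = NONE
    return out


def sequence_vs_regulation(
    report: ConservationReport,
    omap: OrthologMap,
    fdr: float | None = None,
) -> dict:
    """Does the most sequence-similar ortholog have the most conserved
    regulation?

    Over genes with at least two predicted orthologs: among those with at
    least one significantly conserved ortholog, the fraction whose most
    conserved ortholog (smallest conserved-tail p; ties by larger overlap,
    higher bit-score, then ID) is also the highest-bit-score ortholog; the
    corresponding fraction for divergence; and, for genes with both a
    conserved and a diverged ortholog, the three-way split
    most-similar-is-most-conserved / most-diverged / not-agreeing.  Genes
    with missing bit-scores are excluded and counted.
    """
    fdr = report.fdr if fdr is None else fdr
    sp1, sp2 = report.species_from, report.species_to
    per_gene: dict[str, list[NeighbourhoodTest]] = {}
    for t in report.tests:
        per_gene.setdefault(t.gene, []).append(t)

    n_excluded = 0
    cons_agree = []
    div_agree = []
    overlap_split = {"conserved": 0, "diverged": 0, "not_agreeing": 0}
    rank_table = []
    for gene, ts in sorted(per_gene.items()):
        if len(omap.orthologs(sp1, gene, sp2)) < 2 or len(ts) < 2:
            continue
        has_c = any(t.q_conserved < fdr for t in ts)
        has_d = any(t.q_diverged < fdr for t in ts)
        if not (has_c or has_d):
            continue
        if any(not math.isfinite(t.bitscore) for t in ts):
            n_excluded += 1
            continue
        most_similar = max(ts, key=lambda t: (t.bitscore, t.ortholog))
        by_sim = sorted(ts, key=lambda t: (-t.bitscore, t.ortholog))
        if has_c:
            best_c = _best(ts, _cons_key)
            cons_agree.append(best_c.ortholog == most_similar.ortholog)
            rank_table.append(
                {
                    "gene": gene,
                    "n_orthologs": len(ts),
                    "similarity_rank_of_most_conserved": 1
                    + [t.ortholog for t in by_sim].index(best_c.ortholog),
                }
            )
        if has_d:
            best_d = _best(ts, _div_key)
            div_agree.append(best_d.ortholog == most_similar.ortholog)
        if has_c and has_d:
            best_c = _best(ts, _cons_key)
            best_d = _best(ts, _div_key)
            if most_similar.ortholog == best_c.ortholog:
                overlap_split["conserved"] += 1
            elif most_similar.ortholog == best_d.ortholog:
                overlap_split["diverged"] += 1
            else:
                overlap_split["not_agreeing"] += 1
    return {
        "frac_most_similar_is_most_conserved": (
            float(np.mean(cons_agree)) if cons_agree else math.nan
        ),
        "frac_most_similar_is_most_diverged": (
            float(np.mean(div_agree)) if div_agree else math.nan
        ),
        "overlap_split": overlap_split,
        "n_conserved_genes": len(cons_agree),
        "n_diverged_genes": len(div_agree),
        "n_excluded_missing_bitscore": n_excluded,
        "rank_table": rank_table,
    }


def core_conservation(
    reports: dict[tuple[str, str], ConservationReport]
) -> dict[str, dict[str, int]]:
    """Genes conserved/diverged in BOTH other species of a trio.

    ``reports`` maps (species_from, species_to) to directional reports for
    all ordered pairs of a three-species comparison.  For each species X with
    other species Y, Z: a gene is core-conserved if it has at least one
    conserved ortholog-neighbourhood in both Y and Z (counting
    Conserved-and-Diverged genes as conserved); likewise for divergence.
    """
    species = sorted({sp for pair in reports for sp in pair})
    if len(species) < 3:
        raise ValueError("core conservation needs three species")
    out: dict[str, dict[str, int]] = {}
    for x in species:
        others = [y for y in species if y != x]
        try:
            reps = [reports[(x, y)] for y in others]
        except KeyError as exc:
            raise ValueError(f"missing comparison {exc} for species {x!r}") from None
        cons_sets = [r.genes_in(CONSERVED, BOTH) for r in reps]
        div_sets = [r.genes_in(DIVERGED, BOTH) for r in reps]
        eligible = set.union(*(set(r.category) for r in reps))
        core_c = set.intersection(*cons_sets)
        core_d = set.intersection(*div_sets)
        out[x] = {
            "conserved": len(core_c - core_d),
            "diverged": len(core_d - core_c),
            "conserved_and_diverged": len(core_c & core_d),
            "none": len(eligible - core_c - core_d),
            "eligible": len(eligible),
        }
    return out
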