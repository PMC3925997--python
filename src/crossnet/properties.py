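"""Network properties and their cross-species conservation.

Covers degree-distribution model comparison (discrete power law vs Poisson),
node centralities (degree, average nearest-neighbour degree, betweenness),
GO-subnetwork statistics (density, connectivity, in/outgoing regulation
connectivity), the tau tissue-specificity index, hypergeometric GO
enrichment, and the top-decile + randomized-list procedure that scores
conservation of centralities and subnetwork statistics across species.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta
from scipy.stats import hypergeom, poisson
from statsmodels.stats.multitest import multipletests

from .inference import GeneNetwork
from .io import OrthologMap

__all__ = [
    "DegreeFit",
    "fit_degree_distribution",
    "compute_centralities",
    "centrality_conservation",
    "subnetwork_statistics",
    "statistic_conservation",
    "tau_scores",
    "go_enrichment",
    "top_fraction_set",
]

GO_SUBNET_MIN = 10
GO_SUBNET_MAX = 1000
LOGLIK_MARGIN = 2.0


# ---------------------------------------------------------------------------
# degree distribution fits


@dataclass
class DegreeFit:
    """Maximum-likelihood fits of a degree sample to power-law and Poisson.

    The power law is discrete, P(x) ∝ x^-alpha for x ≥ x_min with Hurwitz-zeta
    normalization and KS-minimizing x_min; lambda is the plain Poisson MLE
    (sample mean).  The classification compares total log-likelihood on the
    common support x ≥ max(1, x_min): scale_free if the power law leads by the
    margin, random if Poisson does, indeterminate otherwise.
    """

    degrees: np.ndarray
    alpha: float
    x_min: int
    lam: float
    loglik_powerlaw: float
    loglik_poisson: float
    classification: str  # scale_free | random | indeterminate

    @property
    def delta_loglik(self) -> float:
        return self.loglik_powerlaw - self.loglik_poisson


def _powerlaw_mle(tail: np.ndarray, x_min: int) -> tuple[float, float]:
    """MLE exponent and log-likelihood for the discrete power law on a tail."""
    n = len(tail)
    slog = float(np.log(tail).sum())

    def nll(a: float) -> float:
        return a * slog + n * math.log(zeta(a, x_min))

    res = minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded")
    return float(res.x), -float(res.fun)


def _powerlaw_ks(tail: np.ndarray, alpha: float, x_min: int) -> float:
    xs = np.arange(x_min, int(tail.max()) + 1)
    pmf = xs.astype(float) ** (-alpha) / zeta(alpha, x_min)
    cdf_model = np.cumsum(pmf)
    cdf_emp = np.searchsorted(np.sort(tail), xs, side="right") / len(tail)
    return float(np.max(np.abs(cdf_emp - cdf_model)))


def fit_degree_distribution(network: GeneNetwork) -> DegreeFit:
    """Fit the connected-node degree distribution and classify the network.

    Requires at least 50 connected nodes.  x_min is scanned over the observed
    unique degrees (KS-minimizing); Poisson is truncated to the same support
    for the likelihood comparison, using the full-sample mean as lambda.
    """
    degrees = np.array(
        [d for _, d in network.graph.degree() if d > 0], dtype=int
    )
    if len(degrees) < 50:
        raise ValueError("need at least 50 connected nodes to fit")
    lam = float(degrees.mean())
    if degrees.min() == degrees.max():
        return DegreeFit(degrees, math.nan, int(degrees[0]), lam, math.nan, math.nan,
                         "indeterminate")

    candidates = np.unique(degrees)
    # require a meaningful tail behind every candidate x_min, else the
    # likelihood comparison on the common support loses all power
    min_tail = max(10, len(degrees) // 5)
    candidates = [int(x) for x in candidates if (degrees >= x).sum() >= min_tail][:50]
    best = None
    for x_min in candidates:
        tail = degrees[degrees >= x_min]
        if tail.min() == tail.max():
            continue
        alpha, ll = _powerlaw_mle(tail, x_min)
        ks = _powerlaw_ks(tail, alpha, x_min)
        if best is None or ks < best[0]:
            best = (ks, x_min, alpha)
    if best is None:
        return DegreeFit(degrees, math.nan, int(degrees.min()), lam, math.nan,
                         math.nan, "indeterminate")
    _, x_min, alpha = best
    tail = degrees[degrees >= x_min]
    _, ll_pl = _powerlaw_mle(tail, x_min)
    # Poisson truncated to the common support x >= x_min
    log_tail_mass = math.log(max(poisson.sf(x_min - 1, lam), 1e-300))
    ll_pois = float(poisson.logpmf(tail, lam).sum() - len(tail) * log_tail_mass)
    delta = ll_pl - ll_pois
    if delta >= LOGLIK_MARGIN:
        cls = "scale_free"
    elif delta <= -LOGLIK_MARGIN:
        cls = "random"
    else:
        cls = "indeterminate"
    return DegreeFit(degrees, alpha, x_min, lam, ll_pl, ll_pois, cls)


# ---------------------------------------------------------------------------
# centralities


def compute_centralities(network: GeneNetwork, view: str = "coexpression") -> pd.DataFrame:
    """Degree, average nearest-neighbour degree and betweenness per gene.

    In the co-expression view edges are undirected.  In the regulation view a
    TF's degree is its out-degree and a target gene's its in-degree; avnn is
    averaged over a TF's out-neighbours and a gene's in-neighbours.
    Betweenness is unnormalized (raw shortest-path pair counts); avnn is NaN
    for unconnected nodes.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if view == "coexpression":
        g = network.graph
        deg = dict(g.degree())
        avnn = {
            n: (float(np.mean([deg[u] for u in g.neighbors(n)])) if deg[n] > 0 else math.nan)
            for n in g.nodes
        }
        btw = nx.betweenness_centrality(g, normalized=False)
    elif view == "regulation":
        dg = network.regulation_view()

        def node_degree(n: str) -> int:
            return dg.out_degree(n) if network.is_tf(n) else dg.in_degree(n)

        deg = {n: node_degree(n) for n in dg.nodes}
        avnn = {}
        for n in dg.nodes:
            nbrs = list(dg.successors(n)) if network.is_tf(n) else list(dg.predecessors(n))
            avnn[n] = float(np.mean([deg[u] for u in nbrs])) if nbrs else math.nan
        btw = nx.betweenness_centrality(dg, normalized=False)
    else:
        raise ValueError(f"unknown view {view!r}")
    return pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "avnn": pd.Series(avnn, dtype=float),
            "betweenness": pd.Series(btw, dtype=float),
        }
    ).sort_index()


def top_fraction_set(
    values: pd.Series, fraction: float, direction: str = "top"
) -> set[str]:
    """The exactly-⌈fraction·n⌉ most (least) extreme IDs, ties broken by ID."""
    if direction not in ("top", "bottom"):
        raise ValueError("direction must be 'top' or 'bottom'")
    values = values.dropna()
    n_pick = math.ceil(fraction * len(values))
    ascending = direction == "bottom"
    frame = values.rename("v").to_frame()
    frame["id"] = frame.index.astype(str)
    frame = frame.sort_values(["v", "id"], ascending=[ascending, True])
    return set(frame.index[:n_pick])


def centrality_conservation(
    tables: dict[str, pd.DataFrame],
    omap: OrthologMap,
    measure: str,
    direction: str = "top",
    fraction: float = 0.10,
    n_rand: int = 1000,
    seed: int = 0,
) -> dict[str, dict]:
    """Cross-species conservation of high (low) centrality.

    A gene is conserved if it is in the top (bottom) ``fraction`` of its own
    species' ranking and has at least one predicted ortholog in the top
    (bottom) fraction of every other species.  Unconnected genes (degree 0)
    are excluded from the rankings.  Significance comes from randomized gene
    lists of the same sizes: p = (r+1)/(n_rand+1), r counting randomizations
    with at least the observed number of conserved genes.
    """
    if len(tables) < 2:
        raise ValueError("need at least two species")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if n_rand < 100:
        warnings.warn("fewer than 100 randomizations gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    ranked: dict[str, pd.Series] = {}
    for sp, tab in tables.items():
        vals = tab.loc[tab["degree"] > 0, measure]
        ranked[sp] = vals.dropna()
    top: dict[str, set[str]] = {
        sp: top_fraction_set(vals, fraction, direction) for sp, vals in ranked.items()
    }

    def conserved_count(sets: dict[str, set[str]], sp: str) -> set[str]:
        others = [o for o in sets if o != sp]
        out = set()
        for gene in sets[sp]:
            if all(omap.orthologs(sp, gene, o) & sets[o] for o in others):
                out.add(gene)
        return out

    results: dict[str, dict] = {}
    for sp in tables:
        observed = conserved_count(top, sp)
        r = 0
        for _ in range(n_rand):
            rand_sets = {
                s: set(
                    rng.choice(ranked[s].index.to_numpy(), size=len(top[s]), replace=False)
                )
                for s in tables
            }
            if len(conserved_count(rand_sets, sp)) >= len(observed):
                r += 1
        results[sp] = {
            "conserved": observed,
            "top_set": top[sp],
            "fraction_conserved": len(observed) / len(top[sp]) if top[sp] else math.nan,
            "p_value": (r + 1) / (n_rand + 1),
        }
    return results


# ---------------------------------------------------------------------------
# GO subnetwork statistics


def subnetwork_statistics(
    network: GeneNetwork, go_map: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-GO-term statistics of the induced subnetworks.

    Only terms with 10–1000 connected annotated genes are kept.  Density is
    internal links over possible links; connectivity is external undirected
    links over internal links; ingoing/outgoing connectivity use the directed
    regulation view (edges entering/leaving the subnetwork over internal
    directed edges).  Ratios with zero internal links are NaN.
    """
    if not go_map:
        raise ValueError("empty GO map")
    connected = network.connected_genes()
    term_genes: dict[str, set[str]] = {}
    for gene, terms in go_map.items():
        if gene in connected:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    g = network.graph
    dg = network.regulation_view()
    rows = {}
    for term, genes in term_genes.items():
        m = len(genes)
        if not GO_SUBNET_MIN <= m <= GO_SUBNET_MAX:
            continue
        internal = g.subgraph(genes).number_of_edges()
        external = sum(1 for gene in genes for u in g.neighbors(gene) if u not in genes)
        din = dg.subgraph(genes).number_of_edges()
        ingoing = sum(1 for gene in genes for u in dg.predecessors(gene) if u not in genes)
        outgoing = sum(1 for gene in genes for u in dg.successors(gene) if u not in genes)
        rows[term] = {
            "n_connected": m,
            "density": internal / (m * (m - 1) / 2),
            "connectivity": external / internal if internal else math.nan,
            "ingoing": ingoing / din if din else math.nan,
            "outgoing": outgoing / din if din else math.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def statistic_conservation(
    stats: dict[str, pd.DataFrame],
    statistic: str,
    direction: str = "top",
    fraction: float = 0.10,
    n_rand: int = 1000,
    seed: int = 0,
) -> dict:
    """Conservation of a subnetwork statistic across species.

    A GO term is conserved if it ranks in the top (bottom) fraction in every
    species.  Randomized term lists of the same sizes give the empirical
    p-value; with no eligible terms the result is empty with p = NaN.
    """
    if len(stats) < 2:
        raise ValueError("need at least two species")
    if n_rand < 100:
        warnings.warn("fewer than 100 randomizations gives coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    ranked = {sp: tab[statistic].dropna() for sp, tab in stats.items()}
    if any(len(v) == 0 for v in ranked.values()):
        return {"conserved": set(), "p_value": math.nan, "fraction_conserved": math.nan}
    top = {sp: top_fraction_set(v, fraction, direction) for sp, v in ranked.items()}
    observed = set.intersection(*top.values())
    r = 0
    for _ in range(n_rand):
        rand_sets = [
            set(rng.choice(v.index.to_numpy(), size=len(top[sp]), replace=False))
            for sp, v in ranked.items()
        ]
        if len(set.intersection(*rand_sets)) >= len(observed):
            r += 1
    first = next(iter(top))
    return {
        "conserved": observed,
        "p_value": (r + 1) / (n_rand + 1),
        "fraction_conserved": len(observed) / len(top[first]) if top[first] else math.nan,
    }


# ---------------------------------------------------------------------------
# tissue specificity


def tau_scores(
    expr, sample_to_tissue: dict[str, str]
) -> pd.Series:
    """Tau tissue-specificity index per gene.

    Per-tissue mean expression profiles (floored at 0) give
    tau = Σ_i (1 − x_i / x_max) / (n_tissues − 1): 0 for uniform expression,
    1 for single-tissue expression.  All-zero genes are NaN.
    """
    tissues = sorted(set(sample_to_tissue.values()))
    if len(tissues) < 2:
        raise ValueError("need at least two tissues")
    cols = {
        t: [j for j, s in enumerate(expr.sample_ids) if sample_to_tissue.get(s) == t]
        for t in tissues
    }
    if any(not c for c in cols.values()):
        raise ValueError("every tissue needs at least one sample")
    means = np.stack(
        [expr.values[:, c].mean(axis=1) for t, c in cols.items()], axis=1
    )
    means = np.maximum(means, 0.0)
    xmax = means.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - means / xmax[:, None]).sum(axis=1) / (len(tissues) - 1)
    tau[xmax <= 0] = math.nan
    return pd.Series(tau, index=expr.gene_ids, name="tau")


# ---------------------------------------------------------------------------
# GO enrichment


def go_enrichment(
    gene_set: set[str],
    universe: set[str],
    go_map: dict[str, set[str]],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Upper-tail hypergeometric GO enrichment with multiplicity correction.

    For each term with annotated genes in the universe, tests whether the
    overlap with ``gene_set`` is larger than expected under uniform sampling.
    ``correction`` is 'bonferroni' or 'bh'.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in go_map.items():
        if gene in universe:
            for t in terms:
                term_genes.setdefault(t, set()).add(gene)
    n_univ, n_set = len(universe), len(gene_set)
    rows = {}
    for term, genes in term_genes.items():
        k = len(genes)
        x = len(genes & gene_set)
        p = float(hypergeom.sf(x - 1, n_univ, k, n_set))
        rows[term] = {"term_size": k, "overlap": x, "p": min(p, 1.0)}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if correction == "bonferroni":
        table["p_adj"] = np.minimum(table["p"] * len(table), 1.0)
    elif correction == "bh":
        table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table.sort_values("p")
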