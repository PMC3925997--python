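"""Co-expression network inference: B-spline mutual information and CLR.

The pipeline is MI → CLR → threshold.  Pairwise mutual information is
estimated with a B-spline binning estimator: each sample contributes soft
membership weights to ``n_bins`` bins via B-spline basis functions evaluated
on rank-scaled values, and plugin entropies are computed from the weighted
counts.  MI is normalized by the smaller marginal entropy, which bounds every
score in [0, 1] by construction.  The context likelihood of relatedness (CLR)
step background-corrects each pair's MI against the two genes' own MI score
distributions, combining the per-gene Z-scores as sqrt(z_i^2 + z_j^2);
thresholding the CLR matrix yields the co-expression network, and filtering
by annotated transcription factors yields the directed regulation network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.interpolate import BSpline
from scipy.special import xlogy
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "ScoreMatrix",
    "GeneNetwork",
    "bspline_mi",
    "mi_matrix",
    "clr_transform",
    "build_network",
    "default_n_bins",
]

_ZERO_ENTROPY = 1e-12


@dataclass
class ScoreMatrix:
    """Symmetric gene × gene score matrix (MI in [0,1] or CLR Z-scores ≥ 0).

    The diagonal carries no information and is excluded from all downstream
    use (set to 0).
    """

    gene_ids: list[str]
    scores: np.ndarray
    kind: str  # "MI" | "CLR"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.gene_ids)
        if self.scores.shape != (n, n):
            raise ValueError("score matrix shape does not match gene_ids")
        if self.kind not in ("MI", "CLR"):
            raise ValueError(f"unknown kind {self.kind!r}")

    def value(self, gene_a: str, gene_b: str) -> float:
        i = self.gene_ids.index(gene_a)
        j = self.gene_ids.index(gene_b)
        return float(self.scores[i, j])


@dataclass
class GeneNetwork:
    """Thresholded network with an undirected co-expression view and a
    derived directed regulation view.

    The co-expression view links every gene pair whose CLR score reached the
    threshold.  The regulation view keeps only links incident to annotated
    transcription factors, directed TF→gene; a TF–TF link is kept as a
    reciprocal pair of directed links (no one-way TF→TF direction is ever
    inferred).  Unconnected genes are retained as isolated nodes so the gene
    universe stays aligned across thresholds.
    """

    graph: nx.Graph
    tf_ids: set[str]
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_tf(self, gene: str) -> bool:
        return gene in self.tf_ids

    def neighbours(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def connected_genes(self) -> set[str]:
        return {n for n, d in self.graph.degree() if d > 0}

    def regulation_view(self) -> nx.DiGraph:
        """Directed TF→gene graph; TF–TF links appear in both directions."""
        dg = nx.DiGraph()
        dg.add_nodes_from(self.graph.nodes(data=True))
        for u, v, data in self.graph.edges(data=True):
            u_tf, v_tf = u in self.tf_ids, v in self.tf_ids
            if u_tf:
                dg.add_edge(u, v, **data)
            if v_tf:
                dg.add_edge(v, u, **data)
        return dg

    def edge_list(self) -> list[tuple[str, str, float, bool]]:
        """Edges in the data_io edge-list dialect (directed=1 iff TF-incident)."""
        rows = []
        for u, v, data in sorted(self.graph.edges(data=True)):
            directed = (u in self.tf_ids) or (v in self.tf_ids)
            rows.append((u, v, float(data.get("weight", 0.0)), directed))
        return rows


def default_n_bins(n_samples: int) -> int:
    """Square-root bin count, clamped to [4, 16]."""
    return int(np.clip(round(np.sqrt(n_samples)), 4, 16))


def _spline_weights(x: np.ndarray, n_bins: int, spline_order: int) -> np.ndarray:
    """Soft bin-membership weights, one row per sample, one column per bin.

    Values are rank-transformed and mapped to the knot domain
    [0, n_bins - spline_order + 1]; the knot vector is uniform with the first
    and last knot repeated ``spline_order`` times, so order 1 degenerates to
    hard histogram bins.  Rows sum to 1.
    """
    n = len(x)
    k = spline_order
    m = n_bins
    top = m - k + 1
    ranks = rankdata(x, method="average")
    if n > 1:
        z = (ranks - 1.0) / (n - 1.0) * top
    else:
        z = np.zeros(n)
    # keep the right endpoint inside the last knot interval
    z = np.minimum(z, np.nextafter(float(top), 0.0))
    knots = np.concatenate(
        [np.zeros(k - 1), np.arange(0, top + 1, dtype=float), np.full(k - 1, top)]
    )
    design = BSpline.design_matrix(z, knots, k - 1, extrapolate=False).toarray()
    return design


def _entropy(p: np.ndarray) -> float:
    return float(-np.sum(xlogy(p, p)))


def bspline_mi(
    x: np.ndarray, y: np.ndarray, n_bins: int = 10, spline_order: int = 3
) -> float:
    """Normalized B-spline mutual information of two sample vectors.

    Plugin entropies H(X), H(Y) and H(X,Y) are computed from the soft-binned
    weighted counts; MI = H(X) + H(Y) − H(X,Y) is divided by min(H(X), H(Y)),
    so the result lies in [0, 1].  Constant inputs have zero marginal entropy
    and score 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("need 1-D vectors of length >= 8")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not 1 <= spline_order <= n_bins:
        raise ValueError("spline_order must be in [1, n_bins]")
    wx = _spline_weights(x, n_bins, spline_order)
    wy = _spline_weights(y, n_bins, spline_order)
    return _mi_from_weights(wx, wy)


def _mi_from_weights(wx: np.ndarray, wy: np.ndarray) -> float:
    n = wx.shape[0]
    px = wx.sum(axis=0) / n
    py = wy.sum(axis=0) / n
    hx = _entropy(px)
    hy = _entropy(py)
    hmin = min(hx, hy)
    if hmin < _ZERO_ENTROPY:
        return 0.0
    pxy = (wx.T @ wy) / n
    hxy = _entropy(pxy.ravel())
    mi = hx + hy - hxy
    return float(np.clip(mi / hmin, 0.0, 1.0))


def mi_matrix(
    expr: ExpressionMatrix,
    n_bins: int | None = None,
    spline_order: int = 3,
) -> ScoreMatrix:
    """Normalized MI for every unordered gene pair of an expression matrix.

    ``n_bins`` defaults to the square-root rule (clamped to [4, 16]).  Genes
    with zero variance have zero marginal entropy and score 0 against every
    other gene, keeping the gene universe intact.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if expr.n_samples < 8:
        raise ValueError("need at least 8 samples for a stable MI estimate")
    bins = default_n_bins(expr.n_samples) if n_bins is None else n_bins
    g, n = expr.n_genes, expr.n_samples
    weights = np.empty((g, n, bins))
    for i in range(g):
        weights[i] = _spline_weights(expr.values[i], bins, spline_order)
    marg = weights.sum(axis=1) / n  # g x bins
    h = -np.sum(xlogy(marg, marg), axis=1)
    scores = np.zeros((g, g))
    for i in range(g):
        if h[i] < _ZERO_ENTROPY:
            continue
        # joint distributions of gene i against all later genes in one shot
        rest = np.arange(i + 1, g)
        ok = rest[h[rest] >= _ZERO_ENTROPY]
        if len(ok) == 0:
            continue
        joint = np.einsum("sb,gsc->gbc", weights[i], weights[ok]) / n
        hxy = -np.sum(xlogy(joint, joint), axis=(1, 2))
        mi = h[i] + h[ok] - hxy
        hmin = np.minimum(h[i], h[ok])
        scores[i, ok] = np.clip(mi / hmin, 0.0, 1.0)
        scores[ok, i] = scores[i, ok]
    return ScoreMatrix(
        gene_ids=list(expr.gene_ids),
        scores=scores,
        kind="MI",
        params={"n_bins": bins, "spline_order": spline_order},
    )


def clr_transform(mi: ScoreMatrix) -> ScoreMatrix:
    """Context-likelihood-of-relatedness background correction.

    For each gene i, the mean and standard deviation of its off-diagonal MI
    row define a background; z_i(j) = max(0, (MI_ij − μ_i)/σ_i) and
    CLR_ij = sqrt(z_i(j)² + z_j(i)²).  A gene with zero background spread
    contributes z ≡ 0.
    """
    if mi.kind != "MI":
        raise ValueError("clr_transform expects an MI matrix")
    g = len(mi.gene_ids)
    if g < 3:
        raise ValueError("CLR background undefined for fewer than 3 genes")
    scores = mi.scores
    mask = ~np.eye(g, dtype=bool)
    mu = scores.sum(axis=1) / (g - 1)
    var = (np.where(mask, (scores - mu[:, None]) ** 2, 0.0)).sum(axis=1) / (g - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (scores - mu[:, None]) / sd[:, None]
    z[sd < 1e-300] = 0.0
    np.maximum(z, 0.0, out=z)
    clr = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(clr, 0.0)
    return ScoreMatrix(
        gene_ids=list(mi.gene_ids), scores=clr, kind="CLR", params=dict(mi.params)
    )


def build_network(
    clr: ScoreMatrix, threshold: float, tf_ids: set[str] | None = None
) -> GeneNetwork:
    """Threshold a CLR matrix into a GeneNetwork (edge iff CLR ≥ threshold).

    The inclusive edge rule keeps ties at the threshold; every gene is kept
    as a node so isolated genes stay in the universe.  TF IDs outside the
    gene universe raise a warning and are ignored.
    """
    if clr.kind != "CLR":
        raise ValueError("build_network expects a CLR matrix")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    tf_ids = set(tf_ids or ())
    universe = set(clr.gene_ids)
    unknown = tf_ids - universe
    if unknown:
        warnings.warn(
            f"{len(unknown)} TF IDs not in gene universe ignored "
            f"(e.g. {sorted(unknown)[:3]})",
            stacklevel=2,
        )
        tf_ids &= universe
    graph = nx.Graph()
    for gid in clr.gene_ids:
        graph.add_node(gid, is_tf=gid in tf_ids)
    ii, jj = np.nonzero(np.triu(clr.scores >= threshold, k=1))
    for i, j in zip(ii, jj):
        graph.add_edge(
            clr.gene_ids[i], clr.gene_ids[j], weight=float(clr.scores[i, j])
        )
    return GeneNetwork(graph=graph, tf_ids=tf_ids, threshold=float(threshold))


def network_from_edges(
    edges: list[tuple[str, str, float, bool]],
    tf_ids: set[str],
    threshold: float,
    universe: set[str] | None = None,
) -> GeneNetwork:
    """Rebuild a GeneNetwork from a data_io edge list (undirected rows)."""
    graph = nx.Graph()
    if universe:
        for gid in sorted(universe):
            graph.add_node(gid, is_tf=gid in tf_ids)
    for src, dst, score, _ in edges:
        graph.add_node(src, is_tf=src in tf_ids)
        graph.add_node(dst, is_tf=dst in tf_ids)
        graph.add_edge(src, dst, weight=score)
    return GeneNetwork(graph=graph, tf_ids=set(tf_ids) & set(graph.nodes), threshold=threshold)
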