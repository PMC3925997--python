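"""Typed network motifs in gene regulation networks.

A regulation network has two node types (TF, gene) and two kinds of links:
reciprocal TF–TF links (no one-way TF→TF direction is ever inferred) and
directed TF→gene links.  Genes emit no links.  A motif class is a connected
typed graph over 3 or 4 nodes, identified up to type-preserving node
permutation; the canonical form is the minimal bit-string of the typed
adjacency matrix over all such permutations.

Motif counting is an induced-subgraph census: every connected node set of
the requested size is classified into exactly one class, so class counts sum
to the total number of connected induced subgraphs.  Enrichment is measured
as a Z-score of the observed count against counts in degree-preserving
randomized networks (TF→gene links rewired bipartitely, TF–TF links rewired
as an undirected graph, strata kept separate).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd

from .inference import GeneNetwork
from .properties import GO_SUBNET_MAX, GO_SUBNET_MIN, top_fraction_set

__all__ = [
    "MotifCatalog",
    "enumerate_motif_classes",
    "count_motifs",
    "randomize_regulation_network",
    "motif_zscores",
    "conserved_motifs",
    "canonical_code",
]

TF, GENE = 0, 1


@lru_cache(maxsize=65536)
def canonical_code(
    types: tuple[int, ...], edges: frozenset[tuple[int, int]]
) -> tuple:
    """Canonical form of a typed motif.

    ``types`` assigns TF/GENE per node; ``edges`` holds directed pairs
    (TF–TF links must appear in both directions).  The code is the minimum,
    over type-preserving node permutations, of (sorted types, adjacency
    bit-string).
    """
    n = len(types)
    target = tuple(sorted(types))
    best = None
    for perm in itertools.permutations(range(n)):
        # new position i holds the original node perm[i]
        if tuple(types[perm[i]] for i in range(n)) != target:
            continue
        bits = tuple(
            1 if (perm[i], perm[j]) in edges else 0
            for i in range(n)
            for j in range(n)
            if i != j
        )
        cand = (target, bits)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best


@dataclass
class MotifClass:
    code: tuple
    size: int
    n_tf: int
    name: str = ""


@dataclass
class MotifCatalog:
    """Exhaustive list of connected typed motif classes of one size."""

    size: int
    classes: list[MotifClass] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.classes)

    def index_of(self, code: tuple) -> int:
        lookup = getattr(self, "_lookup", None)
        if lookup is None:
            lookup = {c.code: i for i, c in enumerate(self.classes)}
            object.__setattr__(self, "_lookup", lookup)
        try:
            return lookup[code]
        except KeyError:
            raise KeyError("subgraph does not map to any catalog class") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]


def _valid_edge_sets(n_tf: int, n_gene: int):
    """All permitted edge sets: TF–TF undirected, TF→gene directed."""
    tf_pairs = list(itertools.combinations(range(n_tf), 2))
    tg_pairs = [(t, n_tf + g) for t in range(n_tf) for g in range(n_gene)]
    for tf_mask in range(1 << len(tf_pairs)):
        tf_sel = [p for i, p in enumerate(tf_pairs) if tf_mask >> i & 1]
        for tg_mask in range(1 << len(tg_pairs)):
            tg_sel = [p for i, p in enumerate(tg_pairs) if tg_mask >> i & 1]
            edges = set()
            for a, b in tf_sel:
                edges.add((a, b))
                edges.add((b, a))
            for t, g in tg_sel:
                edges.add((t, g))
            yield frozenset(edges)


def _is_connected(n: int, edges: frozenset[tuple[int, int]]) -> bool:
    if n == 1:
        return True
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        for u in adj[stack.pop()]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == n


_FFL_CODE = None
_BIFAN_CODE = None


def _famous_codes() -> tuple[tuple, tuple]:
    """Canonical codes of the two motifs singled out in the analysis:
    two connected TFs regulating the same gene, and the bi-fan."""
    global _FFL_CODE, _BIFAN_CODE
    if _FFL_CODE is None:
        _FFL_CODE = canonical_code(
            (TF, TF, GENE), frozenset({(0, 1), (1, 0), (0, 2), (1, 2)})
        )
        _BIFAN_CODE = canonical_code(
            (TF, TF, GENE, GENE), frozenset({(0, 2), (0, 3), (1, 2), (1, 3)})
        )
    return _FFL_CODE, _BIFAN_CODE


def enumerate_motif_classes(size: int) -> MotifCatalog:
    """All connected typed motif classes of the given size (3 or 4).

    Exhaustive over TF/gene type assignments and permitted edge sets, reduced
    to canonical representatives.  Size 2 is allowed as an internal helper
    (TF→gene and TF↔TF).
    """
    if size not in (2, 3, 4):
        raise ValueError("motif size must be 3 or 4 (2 for internal use)")
    ffl, bifan = _famous_codes()
    seen: dict[tuple, MotifClass] = {}
    for n_tf in range(size + 1):
        n_gene = size - n_tf
        types = tuple([TF] * n_tf + [GENE] * n_gene)
        for edges in _valid_edge_sets(n_tf, n_gene):
            if not _is_connected(size, edges):
                continue
            code = canonical_code(types, edges)
            if code not in seen:
                name = f"m{size}_tf{n_tf}_{len(seen)}"
                if code == ffl:
                    name = "ffl"
                elif code == bifan:
                    name = "bifan"
                seen[code] = MotifClass(code=code, size=size, n_tf=n_tf, name=name)
    classes = sorted(seen.values(), key=lambda c: c.code)
    return MotifCatalog(size=size, classes=classes)


# ---------------------------------------------------------------------------
# counting


def _regulation_skeleton(network: GeneNetwork) -> nx.Graph:
    """Undirected projection of the regulation view (TF-incident edges)."""
    g = nx.Graph()
    g.add_nodes_from(network.graph.nodes)
    for u, v in network.graph.edges:
        if u in network.tf_ids or v in network.tf_ids:
            g.add_edge(u, v)
    return g


def _connected_subsets(g: nx.Graph, k: int):
    """ESU enumeration of connected induced node sets of size k."""
    order = {n: i for i, n in enumerate(g.nodes)}
    adj = {n: set(g.neighbors(n)) for n in g.nodes}
    for v in g.nodes:
        ext = {u for u in adj[v] if order[u] > order[v]}
        yield from _esu_extend(adj, order, [v], ext, v, k)


def _esu_extend(adj, order, sub, extension, root, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    ext = set(extension)
    root_rank = order[root]
    sub_nbrs = set().union(*(adj[s] for s in sub))
    while ext:
        w = ext.pop()
        new_ext = set(ext)
        for u in adj[w]:
            if order[u] > root_rank and u not in sub and u not in sub_nbrs:
                new_ext.add(u)
        yield from _esu_extend(adj, order, sub + [w], new_ext, root, k)


def classify_subgraph(network: GeneNetwork, nodes: tuple[str, ...]) -> tuple:
    """Canonical code of the typed induced subgraph on ``nodes``."""
    idx = {n: i for i, n in enumerate(nodes)}
    types = tuple(TF if network.is_tf(n) else GENE for n in nodes)
    edges = set()
    for a, b in itertools.combinations(nodes, 2):
        if network.graph.has_edge(a, b):
            a_tf, b_tf = network.is_tf(a), network.is_tf(b)
            if a_tf and b_tf:
                edges.add((idx[a], idx[b]))
                edges.add((idx[b], idx[a]))
            elif a_tf:
                edges.add((idx[a], idx[b]))
            elif b_tf:
                edges.add((idx[b], idx[a]))
            # gene-gene links are absent from the regulation view
    return canonical_code(types, frozenset(edges))


def count_motifs(
    network: GeneNetwork,
    catalog: MotifCatalog,
    node_subset: set[str] | None = None,
) -> np.ndarray:
    """Census of connected induced typed subgraphs, one count per class.

    Each connected node set of the catalog's size is counted exactly once.
    With ``node_subset`` the census runs on the induced regulation subnetwork
    of those nodes.
    """
    skel = _regulation_skeleton(network)
    if node_subset is not None:
        missing = set(node_subset) - set(skel.nodes)
        if missing:
            raise ValueError(f"subset nodes not in network: {sorted(missing)[:3]}")
        skel = skel.subgraph(node_subset)
    counts = np.zeros(len(catalog), dtype=int)
    for nodes in _connected_subsets(skel, catalog.size):
        counts[catalog.index_of(classify_subgraph(network, nodes))] += 1
    return counts


# ---------------------------------------------------------------------------
# degree-preserving randomization


def randomize_regulation_network(
    network: GeneNetwork, seed: int, swaps_per_edge: int = 10
) -> GeneNetwork:
    """Degree-preserving rewiring of the regulation strata.

    TF→gene links are rewired with bipartite double-edge swaps (every TF
    keeps its out-degree, every gene its in-degree); TF–TF links are rewired
    as an undirected graph preserving TF–TF degrees.  Gene–gene co-expression
    links are untouched.  Strata with fewer than 2 edges are returned
    unchanged with a warning.
    """
    rng = np.random.default_rng(seed)
    tf_ids = network.tf_ids
    tftf: list[tuple[str, str]] = []
    tfg: list[tuple[str, str]] = []
    gg: list[tuple[str, str]] = []
    for u, v in network.graph.edges:
        u_tf, v_tf = u in tf_ids, v in tf_ids
        if u_tf and v_tf:
            tftf.append((u, v))
        elif u_tf:
            tfg.append((u, v))
        elif v_tf:
            tfg.append((v, u))
        else:
            gg.append((u, v))

    def swap_undirected(edges: list[tuple[str, str]]) -> list[tuple[str, str]]:
        if len(edges) < 2:
            warnings.warn("TF-TF stratum too small to rewire", stacklevel=3)
            return edges
        eset = {frozenset(e) for e in edges}
        edges = [tuple(e) for e in edges]
        m = len(edges)
        for _ in range(swaps_per_edge * m):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            (a, b), (c, d) = edges[i], edges[j]
            if rng.random() < 0.5:
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            new1, new2 = frozenset((a, d)), frozenset((c, b))
            if new1 in eset or new2 in eset:
                continue
            eset.discard(frozenset((a, b)))
            eset.discard(frozenset((c, d)))
            eset.update((new1, new2))
            edges[i], edges[j] = (a, d), (c, b)
        return edges

    def swap_bipartite(edges: list[tuple[str, str]]) -> list[tuple[str, str]]:
        if len(edges) < 2:
            warnings.warn("TF-gene stratum too small to rewire", stacklevel=3)
            return edges
        eset = set(edges)
        edges = list(edges)
        m = len(edges)
        for _ in range(swaps_per_edge * m):
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            (t1, g1), (t2, g2) = edges[i], edges[j]
            if t1 == t2 or g1 == g2:
                continue
            new1, new2 = (t1, g2), (t2, g1)
            if new1 in eset or new2 in eset:
                continue
            eset.discard((t1, g1))
            eset.discard((t2, g2))
            eset.update((new1, new2))
            edges[i], edges[j] = new1, new2
        return edges

    graph = nx.Graph()
    graph.add_nodes_from(network.graph.nodes(data=True))
    graph.add_edges_from(gg)
    graph.add_edges_from(swap_undirected(tftf))
    graph.add_edges_from(swap_bipartite(tfg))
    return GeneNetwork(graph=graph, tf_ids=set(tf_ids), threshold=network.threshold)


# ---------------------------------------------------------------------------
# enrichment and conservation


def motif_zscores(
    network: GeneNetwork,
    go_map: dict[str, set[str]],
    catalog: MotifCatalog,
    n_rand: int = 100,
    seed: int = 0,
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Per (GO term, motif class) enrichment Z-scores.

    Observed counts come from the induced regulation subnetwork of each GO
    term's connected genes (10–1000 rule); randomized counts are measured on
    the same gene sets in degree-preserving rewired networks.  Z is NaN where
    the randomized spread is zero.
    """
    connected = network.connected_genes()
    term_genes: dict[str, set[str]] = {}
    for gene, tset in go_map.items():
        if gene in connected:
            for t in tset:
                term_genes.setdefault(t, set()).add(gene)
    eligible = {
        t: gs
        for t, gs in term_genes.items()
        if GO_SUBNET_MIN <= len(gs) <= GO_SUBNET_MAX and (terms is None or t in terms)
    }
    obs = {t: count_motifs(network, catalog, gs) for t, gs in eligible.items()}
    rand_counts = {t: [] for t in eligible}
    rng = np.random.default_rng(seed)
    for _ in range(n_rand):
        rnet = randomize_regulation_network(network, seed=int(rng.integers(2**31)))
        for t, gs in eligible.items():
            rand_counts[t].append(count_motifs(rnet, catalog, gs))
    rows = []
    for t in sorted(eligible):
        rmat = np.array(rand_counts[t], dtype=float)
        mean = rmat.mean(axis=0)
        sd = rmat.std(axis=0, ddof=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (obs[t] - mean) / sd
        z[sd == 0] = np.nan
        for ci, cls in enumerate(catalog.classes):
            rows.append(
                {
                    "term": t,
                    "motif": cls.name,
                    "observed": int(obs[t][ci]),
                    "rand_mean": mean[ci],
                    "rand_sd": sd[ci],
                    "z": z[ci],
                }
            )
    return pd.DataFrame(rows).set_index(["term", "motif"])


def conserved_motifs(
    stats: dict[str, pd.DataFrame],
    top_fraction: float = 0.20,
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-species motif conservation over GO subnetworks.

    A GO term is conserved for a motif class if its Z-score ranks in the top
    ``top_fraction`` in every species; significance via randomized term lists
    (p = (r+1)/(n_rand+1)).
    """
    if len(stats) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(seed)
    motifs = sorted(
        set.intersection(*({m for _, m in tab.index} for tab in stats.values()))
    )
    rows = []
    for motif in motifs:
        ranked = {
            sp: tab.xs(motif, level="motif")["z"].dropna() for sp, tab in stats.items()
        }
        if any(len(v) == 0 for v in ranked.values()):
            rows.append({"motif": motif, "n_conserved": 0, "conserved": set(),
                         "p_value": np.nan})
            continue
        top = {sp: top_fraction_set(v, top_fraction, "top") for sp, v in ranked.items()}
        observed = set.intersection(*top.values())
        r = 0
        for _ in range(n_rand):
            rand_sets = [
                set(rng.choice(v.index.to_numpy(), size=len(top[sp]), replace=False))
                for sp, v in ranked.items()
            ]
            if len(set.intersection(*rand_sets)) >= len(observed):
                r += 1
        rows.append(
            {
                "motif": motif,
                "n_conserved": len(observed),
                "conserved": observed,
                "p_value": (r + 1) / (n_rand + 1),
            }
        )
    return pd.DataFrame(rows).set_index("motif")
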