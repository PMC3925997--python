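"""Shared fixtures: small planted studies and toy networks."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from crossnet.inference import GeneNetwork, build_network, clr_transform, mi_matrix
from crossnet.simulate import ScenarioSpec, simulate_study


@pytest.fixture(scope="session")
def study():
    """The default desk-scale planted scenario (seed 1), fully simulated."""
    spec = ScenarioSpec(seed=1)
    matrices, omap, annotations, truth = simulate_study(spec)
    return {
        "spec": spec,
        "matrices": matrices,
        "omap": omap,
        "annotations": annotations,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def study_networks(study):
    """CLR matrices and thresholded networks for the default scenario."""
    clrs = {}
    nets = {}
    for sp, expr in study["matrices"].items():
        clr = clr_transform(mi_matrix(expr))
        clrs[sp] = clr
        nets[sp] = {
            t: build_network(clr, t, study["annotations"][sp].tf_ids)
            for t in (2.0, 3.0, 5.0)
        }
    return {"clr": clrs, "networks": nets}


@pytest.fixture()
def toy_regulation_network():
    """Small fixed regulation network: 8 TFs, 22 genes, seeded random edges."""
    rng = np.random.default_rng(0)
    nodes = [f"T{i}" for i in range(8)] + [f"g{i}" for i in range(22)]
    tfs = {n for n in nodes if n.startswith("T")}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    import itertools

    for a, b in itertools.combinations(nodes, 2):
        if (a in tfs or b in tfs) and rng.random() < 0.12:
            g.add_edge(a, b)
    return GeneNetwork(graph=g, tf_ids=tfs, threshold=1.0)


def make_network(edges, tfs=(), nodes=()):
    """Build a GeneNetwork from bare edge tuples (test helper)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return GeneNetwork(graph=g, tf_ids=set(tfs), threshold=1.0)
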