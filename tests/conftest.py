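"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ksp.io_formats import KinaseSubstratePair, PhosphoSite
from ksp.network_scoring import IntegratedNetwork


def make_site(substrate="P1", position=10, peptide="AAAAAAASAAAAAAA"):
    return PhosphoSite(
        substrate_id=substrate,
        position=position,
        residue=peptide[7],
        peptide=peptide,
    )


def make_pair(kinase="K1", substrate="P1", position=10, peptide="AAAAAAASAAAAAAA"):
    return KinaseSubstratePair(
        kinase_id=kinase, site=make_site(substrate, position, peptide)
    )


def net_from_edges(edges, kinases=()):
    """Build an IntegratedNetwork from (u, v, weight) triples directly."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w))
    return IntegratedNetwork(g, kinases)


def random_connected_net(rng, max_nodes=12, kinases=("k",)):
    """Random connected integer-weighted graph for oracle comparisons."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.2, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.integers(1, 10))
        mapping = {i: f"n{i}" for i in g.nodes}
        g = nx.relabel_nodes(g, mapping)
        return IntegratedNetwork(g, kinases=set())


# -- independent oracles ------------------------------------------------------

def simple_path_oracle(graph: nx.Graph, k: str, n: str):
    """Brute-force enumeration of simple k->n paths of length 1..4 with
    edge-weight products, grouped by length."""
    terms = [0.0, 0.0, 0.0, 0.0]
    for path in nx.all_simple_paths(graph, k, n, cutoff=4):
        prod = 1.0
        for a, b in zip(path, path[1:]):
            prod *= graph[a][b]["weight"]
        terms[len(path) - 2] += prod
    return tuple(terms)


def literal_sum_oracle(graph: nx.Graph, k: str, n: str):
    """Direct evaluation of the nested neighbor sums as printed, with no
    exclusion of degenerate walks."""
    w = lambda a, b: graph[a][b]["weight"]
    nk = set(graph[k])
    nn = set(graph[n])
    ks0 = w(k, n) if n in nk else 0.0
    ks1 = sum(w(k, v) * w(v, n) for v in nk & nn)
    ks2 = sum(
        w(k, vp) * w(vp, vq) * w(vq, n)
        for vp in nk
        for vq in set(graph[vp]) & nn
    )
    ks3 = sum(
        w(k, vx) * w(vx, vc) * w(vc, vy) * w(vy, n)
        for vx in nk
        for vy in nn
        for vc in set(graph[vx]) & set(graph[vy])
    )
    return (ks0, ks1, ks2, ks3)


def auroc_pair_oracle(scores):
    """Concordant-pair fraction (ties count half) over all +/- pairs."""
    pos = [s for s, lab in scores if lab == 1]
    neg = [s for s, lab in scores if lab == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
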