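"""Network affinity scoring between kinases and proteins.

An integrated undirected weighted graph is built from kinase-substrate
pairs and PPI edges.  The affinity between a kinase ``k`` and a protein
``n`` is a weighted sum of four path-product terms:

* KS0 — the direct edge weight,
* KS1 — products over common neighbors (paths of length 2),
* KS2 — products over paths of length 3,
* KS3 — products over paths of length 4,

combined with a beta weight vector and damped by a degree-dependent
punitive factor applied to the kinase, so that heavily connected
(over-studied) kinases do not dominate the ranking.

Two walk semantics are provided.  ``simple`` (the default) restricts each
term to simple paths: intermediate nodes are pairwise distinct and exclude
both endpoints.  ``literal`` evaluates the nested neighbor sums exactly as
written, which admits degenerate walks revisiting the endpoints.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .io_formats import KinaseSubstratePair, PPIEdge, PhosphoSite

MODES = ("simple", "literal")

DEFAULT_BETA = (0.25, 0.225, 0.1875, 0.1875)


class UnknownNodeError(KeyError):
    """A queried node is absent from the network."""


@dataclass(frozen=True)
class BetaVector:
    """Non-negative weights for the KS0..KS3 terms.

    The default is used verbatim even though its components sum to 0.85,
    not 1; callers wanting a normalized vector can use :meth:`normalized`.
    """

    beta0: float = DEFAULT_BETA[0]
    beta1: float = DEFAULT_BETA[1]
    beta2: float = DEFAULT_BETA[2]
    beta3: float = DEFAULT_BETA[3]

    def __post_init__(self) -> None:
        if any(b < 0 for b in self.as_tuple()):
            raise ValueError(f"beta components must be >= 0, got {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.beta0, self.beta1, self.beta2, self.beta3)

    def normalized(self) -> "BetaVector":
        total = sum(self.as_tuple())
        if total == 0:
            raise ValueError("cannot normalize an all-zero beta vector")
        return BetaVector(*(b / total for b in self.as_tuple()))

    @classmethod
    def from_string(cls, text: str) -> "BetaVector":
        parts = [float(x) for x in text.replace(",", " ").split()]
        if len(parts) != 4:
            raise ValueError(f"expected 4 beta components, got {len(parts)}")
        return cls(*parts)


class IntegratedNetwork:
    """Weighted undirected graph over kinases and proteins.

    Wraps a :class:`networkx.Graph` whose edges carry positive ``weight``
    attributes, plus a kinase flag per node.
    """

    def __init__(self, graph: nx.Graph, kinases: Iterable[str]):
        self.graph = graph
        self.kinases = frozenset(k for k in kinases if k in graph)
        self._log_degree_range: tuple[float, float] | None = None
        # plain-dict adjacency is markedly faster than networkx views in
        # the inner scoring loops
        self._adj: dict[str, dict[str, float]] = {
            u: {v: d["weight"] for v, d in graph.adj[u].items()} for u in graph
        }

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def proteins(self) -> set[str]:
        """Non-kinase nodes."""
        return set(self.graph.nodes) - self.kinases

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def neighbors(self, node: str) -> set[str]:
        self._require(node)
        return set(self._adj[node])

    def degree(self, node: str) -> int:
        self._require(node)
        return len(self._adj[node])

    def weight(self, u: str, v: str) -> float:
        self._require(u)
        self._require(v)
        return self._adj[u].get(v, 0.0)

    def common_neighbors(self, u: str, v: str) -> set[str]:
        self._require(u)
        self._require(v)
        return set(self._adj[u]) & set(self._adj[v])

    def _require(self, node: str) -> None:
        if node not in self._adj:
            raise UnknownNodeError(node)

    def log_degree_range(self) -> tuple[float, float]:
        if self._log_degree_range is None:
            logs = [np.log2(len(nbrs)) for nbrs in self._adj.values()]
            self._log_degree_range = (min(logs), max(logs))
        return self._log_degree_range


def build_integrated_network(
    pairs: Sequence[KinaseSubstratePair],
    ppi: Sequence[PPIEdge],
    *,
    ppi_weight: float = 1.0,
) -> IntegratedNetwork:
    """Merge kinase-substrate pairs and PPI edges into one weighted graph.

    Kinase-substrate edge weight is the number of distinct phosphosites of
    that substrate catalyzed by the kinase; PPI edges weigh ``ppi_weight``.
    When an edge has both kinds of support the larger weight wins.  Only
    the largest connected component is kept (ties broken by the component
    containing the lexicographically smallest node).
    """
    if not pairs and not ppi:
        raise ValueError("cannot build a network from empty inputs")
    g = nx.Graph()
    site_counts: dict[tuple[str, str], set[int]] = {}
    kinases: set[str] = set()
    for pair in pairs:
        kinases.add(pair.kinase_id)
        key = (pair.kinase_id, pair.site.substrate_id)
        site_counts.setdefault(key, set()).add(pair.site.position)
    for (kinase, substrate), positions in site_counts.items():
        if kinase == substrate:  # autophosphorylation: no self-loops in G
            continue
        g.add_edge(kinase, substrate, weight=float(len(positions)))
    for edge in ppi:
        w = float(ppi_weight)
        if g.has_edge(edge.protein_a, edge.protein_b):
            w = max(w, g[edge.protein_a][edge.protein_b]["weight"])
        g.add_edge(edge.protein_a, edge.protein_b, weight=w)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot build a network from empty inputs")
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(c))
    )
    g = g.subgraph(components[0]).copy()
    return IntegratedNetwork(g, kinases)


def punitive_factor(net: IntegratedNetwork, node: str) -> float:
    """Degree penalty in [0.8, 1]: 1 for degree <= 2, else a log-degree
    interpolation reaching 0.8 at the maximum-degree node."""
    d = net.degree(node)
    if d <= 2:
        return 1.0
    lo, hi = net.log_degree_range()
    if hi == lo:  # degenerate uniform-degree network
        return 1.0
    return float(1.0 - 0.2 * (np.log2(d) - lo) / (hi - lo))


def ks_terms(
    net: IntegratedNetwork,
    kinase: str,
    protein: str,
    mode: str = "simple",
) -> tuple[float, float, float, float]:
    """Return (KS0, KS1, KS2, KS3) for a kinase-protein pair."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    net._require(kinase)
    net._require(protein)
    if kinase == protein:
        raise ValueError("kinase and protein must be distinct nodes")
    adj = net._adj
    k, n = kinase, protein
    wk, wn = adj[k], adj[n]

    ks0 = wk.get(n, 0.0)
    # common neighbors of k and n can never be k or n themselves
    ks1 = sum(wkv * wn[v] for v, wkv in wk.items() if v in wn)

    ks2 = 0.0
    ks3 = 0.0
    if mode == "literal":
        for vp, w_k_vp in wk.items():
            w_vp = adj[vp]
            for vq, w_vp_vq in w_vp.items():
                w_vq_n = wn.get(vq)
                if w_vq_n is not None:
                    ks2 += w_k_vp * w_vp_vq * w_vq_n
        for vx, w_k_vx in wk.items():
            w_vx = adj[vx]
            for vy, w_vy_n in wn.items():
                w_vy = adj[vy]
                if len(w_vx) > len(w_vy):
                    small, other = w_vy, w_vx
                else:
                    small, other = w_vx, w_vy
                s = 0.0
                for vc, w1 in small.items():
                    w2 = other.get(vc)
                    if w2 is not None:
                        s += w1 * w2
                ks3 += w_k_vx * w_vy_n * s
    else:
        excluded = {k, n}
        for a, w_k_a in wk.items():
            if a in excluded:
                continue
            w_a = adj[a]
            for b, w_a_b in w_a.items():
                if b in excluded or b == a:
                    continue
                w_b_n = wn.get(b)
                if w_b_n is not None:
                    ks2 += w_k_a * w_a_b * w_b_n
        for a, w_k_a in wk.items():
            if a in excluded:
                continue
            w_a = adj[a]
            for b, w_b_n in wn.items():
                if b in excluded or b == a:
                    continue
                w_b = adj[b]
                s = 0.0
                for c, w_a_c in w_a.items():
                    if c in excluded or c == a or c == b:
                        continue
                    w_c_b = w_b.get(c)
                    if w_c_b is not None:
                        s += w_a_c * w_c_b
                ks3 += w_k_a * w_b_n * s
    return (ks0, ks1, ks2, ks3)


def ksp_score(
    net: IntegratedNetwork,
    kinase: str,
    protein: str,
    beta: BetaVector | None = None,
    mode: str = "simple",
) -> float:
    """Affinity score: beta-weighted KS terms times the kinase's penalty."""
    beta = beta or BetaVector()
    terms = ks_terms(net, kinase, protein, mode=mode)
    b = beta.as_tuple()
    return sum(bi * ti for bi, ti in zip(b, terms)) * punitive_factor(net, kinase)


@dataclass
class KinaseAffinityGraph:
    """Bipartite kinase/protein graph whose edge weights are affinity scores.

    Only nonzero scores are stored.
    """

    kinases: frozenset[str]
    proteins: frozenset[str]
    weights: dict[tuple[str, str], float]
    by_protein: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kinases & self.proteins:
            raise ValueError("kinase and protein sets must be disjoint")
        if not self.by_protein:
            for (k, p), w in self.weights.items():
                self.by_protein.setdefault(p, {})[k] = w

    def kinase_scores(self, protein: str) -> dict[str, float]:
        """Affinity of every kinase to one protein (nonzero entries only)."""
        return dict(self.by_protein.get(protein, {}))


def build_affinity_graph(
    net: IntegratedNetwork,
    beta: BetaVector | None = None,
    mode: str = "simple",
) -> KinaseAffinityGraph:
    """Score every kinase against every non-kinase protein."""
    beta = beta or BetaVector()
    weights: dict[tuple[str, str], float] = {}
    proteins = sorted(net.proteins)
    for k in sorted(net.kinases):
        pd = punitive_factor(net, k)
        b = beta.as_tuple()
        for p in proteins:
            terms = ks_terms(net, k, p, mode=mode)
            score = sum(bi * ti for bi, ti in zip(b, terms)) * pd
            if score != 0.0:
                weights[(k, p)] = float(score)
    return KinaseAffinityGraph(
        kinases=frozenset(net.kinases),
        proteins=frozenset(proteins),
        weights=weights,
    )


def rank_candidates(scores: dict[str, float], top_k: int) -> list[tuple[str, float]]:
    """Sort descending by score, ties broken lexicographically by id."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def rank_kinases_network(
    graph: KinaseAffinityGraph,
    site: PhosphoSite,
    top_k: int = 10,
) -> list[tuple[str, float]]:
    """Rank kinases for a site by its substrate protein's affinity weights.

    A substrate absent from the graph yields an empty list and a warning.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    substrate = site.substrate_id
    if substrate not in graph.proteins:
        warnings.warn(
            f"substrate {substrate!r} is not in the affinity graph; "
            "no network ranking available",
            stacklevel=2,
        )
        return []
    return rank_candidates(graph.kinase_scores(substrate), top_k)


# -- persistence --------------------------------------------------------------

def save_network(net: IntegratedNetwork, out_dir: str | Path) -> None:
    """Persist as a weighted edge-list TSV plus a node-flag sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "wt") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            a, b = (u, v) if u <= v else (v, u)
            fh.write(f"{a}\t{b}\t{d['weight']:g}\n")
    with open(out / "nodes.tsv", "wt") as fh:
        fh.write("node\tis_kinase\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\t{int(node in net.kinases)}\n")


def load_network(in_dir: str | Path) -> IntegratedNetwork:
    src = Path(in_dir)
    g = nx.Graph()
    kinases: set[str] = set()
    with open(src / "nodes.tsv") as fh:
        next(fh)
        for line in fh:
            node, flag = line.rstrip("\n").split("\t")
            g.add_node(node)
            if flag == "1":
                kinases.add(node)
    with open(src / "edges.tsv") as fh:
        next(fh)
        for line in fh:
            a, b, w = line.rstrip("\n").split("\t")
            g.add_edge(a, b, weight=float(w))
    return IntegratedNetwork(g, kinases)


def save_affinity_graph(graph: KinaseAffinityGraph, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("kinase\tprotein\tksp_score\n")
        for (k, p), w in sorted(graph.weights.items()):
            fh.write(f"{k}\t{p}\t{w!r}\n")


def load_affinity_graph(path: str | Path) -> KinaseAffinityGraph:
    weights: dict[tuple[str, str], float] = {}
    kinases: set[str] = set()
    proteins: set[str] = set()
    with open(path) as fh:
        next(fh)
        for line in fh:
            k, p, w = line.rstrip("\n").split("\t")
            kinases.add(k)
            proteins.add(p)
            weights[(k, p)] = float(w)
    return KinaseAffinityGraph(
        kinases=frozenset(kinases), proteins=frozenset(proteins), weights=weights
    )
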