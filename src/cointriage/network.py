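"""Article-level co-occurrence network and its centralities.

Vertices are articles; an undirected edge joins two articles whenever some
sentence of each contains the *same* concept pair (identical canonical
names and pair type).  Each edge records the shared pairs and the pair
types that justify it.  A weaker criterion — any pair of the same type in
both articles — is available as ``edge_rule="same_type"``.

Two centralities rank vertices:

* **betweenness** — for vertex v, the sum over unordered vertex pairs
  {s, t} (endpoints excluded) of the fraction of shortest s–t paths that
  pass through v; raw σ-path units, no normalization, unreachable pairs
  contribute 0;
* **PageRank** — the stationary score of the random-surfer model,
  PR(V_i) = (1 − d)/N + d · Σ_{j ∈ In(V_i)} PR(V_j)/|Out(V_j)|, with every
  undirected edge counted as one in-link and one out-link at each endpoint
  and damping d = 0.85 by default.  Scores sum to 1.

Betweenness is delegated to networkx's Brandes implementation; PageRank is
a direct power iteration of the recurrence above so that the teleport
variant, the treatment of isolated (dangling) vertices and the convergence
report are exactly as documented.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .cooccur import ConceptPair

DEFAULT_DAMPING = 0.85
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


class PageRankConvergenceError(RuntimeError):
    def __init__(self, max_iter: int, residual: float):
        self.max_iter = max_iter
        self.residual = residual
        super().__init__(
            f"PageRank failed to converge within {max_iter} iterations "
            f"(final residual {residual:.3e})"
        )


@dataclass
class CooccurrenceNetwork:
    """Undirected graph over doc_ids with typed, pair-annotated edges."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_types(self, a: str, b: str) -> set[str]:
        return self.graph.edges[a, b]["types"]

    def shared_pairs(self, a: str, b: str) -> set[ConceptPair]:
        return self.graph.edges[a, b]["pairs"]

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    doc_pairs: Mapping[str, Counter], edge_rule: str = "shared_pair"
) -> CooccurrenceNetwork:
    """Build the co-occurrence network from per-document pair multisets.

    ``doc_pairs`` maps doc_id to the Counter of its concept pairs (as
    produced by :func:`cointriage.cooccur.extract_pairs`).  Every document
    becomes a vertex; with the default ``shared_pair`` rule an edge joins
    i ≠ j iff they contain at least one identical concept pair, annotated
    with the set of shared pairs and their types.  With ``same_type`` an
    edge only requires a pair of the same type in both documents.
    """
    if edge_rule not in ("shared_pair", "same_type"):
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    g = nx.Graph()
    g.add_nodes_from(doc_pairs.keys())

    # invert: pair (or pair type) -> documents containing it
    index: dict = {}
    for doc_id, pairs in doc_pairs.items():
        keys = (
            set(pairs.keys())
            if edge_rule == "shared_pair"
            else {p.pair_type for p in pairs}
        )
        for key in keys:
            index.setdefault(key, []).append(doc_id)

    for key, members in index.items():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                if not g.has_edge(a, b):
                    g.add_edge(a, b, types=set(), pairs=set())
                if edge_rule == "shared_pair":
                    g.edges[a, b]["types"].add(key.pair_type)
                    g.edges[a, b]["pairs"].add(key)
                else:
                    g.edges[a, b]["types"].add(key)
    return CooccurrenceNetwork(graph=g)


def betweenness(net: CooccurrenceNetwork) -> dict[str, float]:
    """Raw (unnormalized) betweenness centrality of every vertex.

    Unordered pairs, endpoints excluded, fractional credit for tied
    shortest paths; disconnected networks are fine (unreachable pairs
    contribute nothing).
    """
    return dict(nx.betweenness_centrality(net.graph, normalized=False))


def pagerank(
    net: CooccurrenceNetwork,
    d: float = DEFAULT_DAMPING,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[str, float]:
    """PageRank by power iteration on the undirected network.

    Each undirected edge is treated as a bidirectional link.  Iterates
    PR(V_i) = (1 − d)/N + d·Σ_{j ∈ In(V_i)} PR(V_j)/|Out(V_j)| from the
    uniform vector until the maximum absolute change drops below ``tol``.
    Isolated vertices have no out-links; their damped mass is redistributed
    uniformly over all vertices, which keeps Σ PR = 1.

    Raises :class:`PageRankConvergenceError` if ``max_iter`` sweeps do not
    reach ``tol``, reporting the final residual.
    """
    if not (0 < d < 1):
        raise ValueError(f"damping factor must be in (0, 1), got {d}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    g = net.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    degree = {v: g.degree(v) for v in nodes}
    dangling = [v for v in nodes if degree[v] == 0]
    pr = {v: 1.0 / n for v in nodes}
    base = (1.0 - d) / n
    for _ in range(max_iter):
        dangling_mass = sum(pr[v] for v in dangling)
        new = {v: base + d * dangling_mass / n for v in nodes}
        for v in nodes:
            if degree[v]:
                share = d * pr[v] / degree[v]
                for u in g.neighbors(v):
                    new[u] += share
        residual = max(abs(new[v] - pr[v]) for v in nodes)
        pr = new
        if residual < tol:
            return pr
    raise PageRankConvergenceError(max_iter, residual)


def write_edgelist_tsv(net: CooccurrenceNetwork, path) -> None:
    """Export edges as TSV: doc_a, doc_b, types, n_shared_pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_a\tdoc_b\ttypes\tn_shared_pairs\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            data = net.graph.edges[a, b]
            types = ",".join(sorted(data["types"]))
            fh.write(f"{a}\t{b}\t{types}\t{len(data.get('pairs', ()))}\n")


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    """Export the graph as GraphML (edge attributes flattened to strings)."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b, data in net.graph.edges(data=True):
        g.add_edge(
            a,
            b,
            types=",".join(sorted(data["types"])),
            n_shared_pairs=len(data.get("pairs", ())),
        )
    nx.write_graphml(g, path)


def write_centrality_csv(
    bet: Mapping[str, float], pr: Mapping[str, float], path
) -> None:
    """Export centralities as CSV: doc_id, betweenness, pagerank."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id,betweenness,pagerank\n")
        for doc_id in sorted(bet):
            fh.write(f"{doc_id},{bet[doc_id]:.10g},{pr[doc_id]:.10g}\n")
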