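"""Functional-network construction, clustering, and GO over-representation.

The network stage induces a subgraph over a query protein set (typically
the differentially abundant proteins) from a confidence-scored functional
edge table, keeping only edges above a medium-confidence score floor
(strictly > 0.4 by default, matching the STRING convention). Connectivity
is summarised, communities are found by deterministic greedy modularity
maximization, and flat term annotations are tested for over-representation
with the one-sided hypergeometric upper tail, reporting BH-adjusted
q-values alongside raw p-values and the up-regulated fraction per term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable, FunctionalEdge, ValidationError

__all__ = [
    "FunctionalNetwork",
    "ConnectivitySummary",
    "EnrichmentResult",
    "build_network",
    "connectivity_summary",
    "cluster_network",
    "go_overrepresentation",
]


@dataclass
class FunctionalNetwork:
    """A score-thresholded functional network over a query protein set.

    ``graph`` holds the mapped query proteins as nodes (including isolated
    ones) and the retained edges weighted by combined score; ``unmapped``
    lists query proteins absent from the edge vocabulary.
    """

    graph: nx.Graph
    unmapped: list[str]
    min_score: float

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes())


class ConnectivitySummary(NamedTuple):
    n_nodes: int
    n_connected: int  # nodes with degree >= 1
    mean_degree: float  # 2|E| / n_nodes (all mapped nodes)
    mean_degree_connected: float  # 2|E| / n_connected


def build_network(
    query: Iterable[str],
    edges: Sequence[FunctionalEdge],
    min_score: float = 0.4,
    directions: Mapping[str, str] | None = None,
) -> FunctionalNetwork:
    """Induce the thresholded functional subgraph on ``query``.

    The edge vocabulary is every protein appearing in ``edges`` (at any
    score); query proteins outside it are recorded as unmapped. Retained
    edges require both endpoints in the query and combined_score strictly
    greater than ``min_score``. Optional per-protein ``directions``
    (up/down/none) are attached as node attributes.
    """
    query = sorted(set(query))
    if not query:
        raise ValidationError("empty query set")
    vocabulary: set[str] = set()
    for e in edges:
        vocabulary.add(e.protein_a)
        vocabulary.add(e.protein_b)
    mapped = [q for q in query if q in vocabulary]
    unmapped = [q for q in query if q not in vocabulary]

    graph = nx.Graph()
    graph.add_nodes_from(mapped)
    qset = set(mapped)
    for e in sorted(edges, key=lambda e: e.pair):
        if e.combined_score > min_score and e.protein_a in qset and e.protein_b in qset:
            graph.add_edge(e.protein_a, e.protein_b, weight=e.combined_score)
    if directions:
        for node in graph.nodes():
            graph.nodes[node]["direction"] = directions.get(node, "none")
    return FunctionalNetwork(graph=graph, unmapped=unmapped, min_score=float(min_score))


def connectivity_summary(net: FunctionalNetwork) -> ConnectivitySummary:
    """Node/edge connectivity summary of the mapped network.

    ``mean_degree`` divides by all mapped nodes; ``mean_degree_connected``
    divides by nodes with at least one connection (both are reported since
    either convention is seen in the literature).
    """
    g = net.graph
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    n_connected = sum(1 for _, d in g.degree() if d >= 1)
    mean_degree = 2.0 * n_edges / n_nodes if n_nodes else 0.0
    mean_conn = 2.0 * n_edges / n_connected if n_connected else 0.0
    return ConnectivitySummary(n_nodes, n_connected, mean_degree, mean_conn)


def cluster_network(
    net: FunctionalNetwork, min_cluster_size: int = 3
) -> tuple[dict[str, int | None], int]:
    """Greedy modularity communities on the thresholded graph.

    The graph is rebuilt with lexicographically sorted node insertion so the
    community assignment is deterministic across runs and platforms.
    Communities of size >= ``min_cluster_size`` receive ids 1..k (ordered by
    decreasing size, then smallest member); smaller communities are labelled
    ``None`` (unclustered). Returns (labels, number of reported clusters).
    An edgeless network yields all-unclustered labels and 0 clusters.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes()))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in net.graph.edges()))
    labels: dict[str, int | None] = {node: None for node in g.nodes()}
    if g.number_of_edges() == 0:
        return labels, 0
    communities = nx.community.greedy_modularity_communities(g)
    communities = sorted(
        (sorted(c) for c in communities), key=lambda c: (-len(c), c[0])
    )
    cluster_id = 0
    for members in communities:
        if len(members) >= min_cluster_size:
            cluster_id += 1
            for node in members:
                labels[node] = cluster_id
    return labels, cluster_id


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics.

    k of n query proteins and K of N background proteins carry the term;
    p_value is the hypergeometric upper tail P(X >= k); q_value is the
    Benjamini-Hochberg adjusted p across tested terms (reported, not used
    for thresholding); up_fraction is the share of the k annotated query
    proteins that are up-regulated (None when directions were not given).
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    up_fraction: float | None
    over_represented: bool


def go_overrepresentation(
    query: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationTable,
    directions: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms in the query.

    For each term with K annotated proteins in the background (N) and k in
    the query (n), the one-sided upper-tail p-value P(X >= k) is computed;
    terms with p < alpha are flagged over-represented. Annotations outside
    the background are ignored; terms annotating no background protein are
    skipped with a warning. Results are sorted by (p_value, term_id).
    """
    background = set(background)
    query = set(query)
    if not query <= background:
        raise ValidationError("query must be a subset of background")
    N, n = len(background), len(query)
    names = annotations.term_names()
    by_term = annotations.proteins_by_term()
    raw: list[tuple[str, int, int]] = []
    for term_id, proteins in by_term.items():
        annotated = proteins & background
        K = len(annotated)
        if K == 0:
            warnings.warn(f"term {term_id!r} annotates no background protein; skipped",
                          stacklevel=2)
            continue
        k = len(annotated & query)
        raw.append((term_id, k, K))
    if not raw:
        return []
    pvals = [float(stats.hypergeom.sf(k - 1, N, K, n)) for _, k, K in raw]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for (term_id, k, K), p, q in zip(raw, pvals, qvals):
        up_fraction: float | None = None
        if directions is not None and k > 0:
            annotated_query = by_term[term_id] & query
            n_up = sum(1 for acc in annotated_query if directions.get(acc) == "up")
            up_fraction = n_up / k
        results.append(
            EnrichmentResult(
                term_id=term_id,
                term_name=names.get(term_id, ""),
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=min(p, 1.0),
                q_value=float(q),
                up_fraction=up_fraction,
                over_represented=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
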