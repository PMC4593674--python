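"""Protein-interaction networks and GO enrichment for selected-gene sets.

Interaction data is consumed from local edge-list files in the STRING
protein-links dialect (``protein1 protein2 combined_score``, scores
0–1000); there is no live-database dependency.  Operations cover
connectivity summaries of the selected-gene subnetwork, mapping curated
GO-category groups onto nodes, a label-permutation test for category
clustering, and classic one-sided Fisher GO enrichment against a gene
universe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .pipeline import bh_fdr

__all__ = [
    "load_edges",
    "connectivity_summary",
    "map_categories",
    "category_clustering",
    "fisher_enrichment",
    "propagate_annotations",
    "EnrichmentResult",
    "ConnectivitySummary",
]


def load_edges(source, min_score: int = 400) -> nx.Graph:
    """Load a STRING-style edge list into an undirected scored graph.

    ``source`` is a path to a whitespace/tab-separated file with columns
    (protein1, protein2, combined_score), or an equivalent DataFrame.
    Duplicate and reciprocal rows are merged keeping the maximum score;
    self-loops are dropped.  Edges below ``min_score`` are discarded
    (default 400, the conventional "medium confidence" cutoff).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    expected = {"protein1", "protein2", "combined_score"}
    if not expected <= set(df.columns):
        raise ValueError(f"edge table must have columns {sorted(expected)}")
    scores = pd.to_numeric(df["combined_score"], errors="raise")
    if ((scores < 0) | (scores > 1000)).any():
        raise ValueError("combined scores must lie in [0, 1000]")

    graph = nx.Graph()
    n_self = 0
    for a, b, s in zip(df["protein1"], df["protein2"], scores):
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        s = int(s)
        if s < min_score:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], s)
        else:
            graph.add_edge(a, b, score=s)
    graph.graph["n_self_loops_dropped"] = n_self
    graph.graph["min_score"] = min_score
    return graph


@dataclass
class ConnectivitySummary:
    """Connectivity of the focal-gene induced subgraph."""

    n_focal: int
    n_connected: int                      # focal nodes with >= 1 focal edge
    hubs: list[tuple[str, int]]           # (node, degree), degree-ranked
    components: list[set[str]] = field(default_factory=list)


def connectivity_summary(net: nx.Graph, focal_nodes: Iterable[str]) -> ConnectivitySummary:
    """Summarise interactions among the focal nodes.

    Degrees are computed in the subgraph induced by the focal set — the
    question is how many selected-gene products interact with at least one
    *other* selected-gene product.  Hub ties are broken lexicographically.
    """
    focal = set(focal_nodes)
    sub = net.subgraph(n for n in focal if n in net)
    degrees = {n: 0 for n in focal}
    degrees.update(dict(sub.degree()))
    connected = [n for n, d in degrees.items() if d >= 1]
    hubs = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    components = [set(c) for c in nx.connected_components(sub)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return ConnectivitySummary(
        n_focal=len(focal),
        n_connected=len(connected),
        hubs=hubs,
        components=components,
    )


def map_categories(
    nodes: Iterable[str],
    annotations: Mapping[str, set[str]],
    groups: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Label each node with every category group reachable via its GO terms.

    ``groups`` maps category names (e.g. "muscle", "nervous system") to GO
    term lists.  Nodes may carry several labels or none.
    """
    term_to_group: dict[str, set[str]] = {}
    for group, terms in groups.items():
        for t in terms:
            term_to_group.setdefault(t, set()).add(group)
    labeling: dict[str, set[str]] = {}
    for node in nodes:
        labels: set[str] = set()
        for t in annotations.get(node, ()):  # unannotated nodes allowed
            labels |= term_to_group.get(t, set())
        labeling[node] = labels
    return labeling


def category_clustering(
    net: nx.Graph,
    labeling: Mapping[str, set[str]],
    category: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for clustering of one category on the network.

    The observed statistic is the fraction of edges whose two endpoints both
    carry the category.  The null distribution shuffles the node label-sets
    over nodes; ``p = (1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    nodes = sorted(net.nodes())
    carries = np.array([category in labeling.get(n, set()) for n in nodes])
    if not carries.any():
        raise ValueError(f"category {category!r} absent from the labeling")
    index = {n: i for i, n in enumerate(nodes)}
    edges = np.array([(index[a], index[b]) for a, b in net.edges()])
    if edges.size == 0:
        raise ValueError("network has no edges")

    def frac(mask: np.ndarray) -> float:
        return float(np.mean(mask[edges[:, 0]] & mask[edges[:, 1]]))

    observed = frac(carries)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if frac(rng.permutation(carries)) >= observed:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return observed, p


@dataclass(frozen=True)
class EnrichmentResult:
    """One GO term's over-representation test."""

    term: str
    n_selected_in_term: int
    n_selected: int
    n_term_in_universe: int
    n_universe: int
    p_value: float
    q_value: float = math.nan


def propagate_annotations(
    annotations: Mapping[str, set[str]],
    term_parents: Mapping[str, Iterable[str]],
) -> dict[str, set[str]]:
    """Close annotations under the true-path rule.

    A gene annotated to a term is implicitly annotated to every ancestor of
    that term; ``term_parents`` maps each term to its direct parents.
    """
    ancestors: dict[str, set[str]] = {}

    def climb(term: str) -> set[str]:
        if term not in ancestors:
            ancestors[term] = set()  # placeholder guards against cycles
            out: set[str] = set()
            for parent in term_parents.get(term, ()):  # missing -> root
                out.add(parent)
                out |= climb(parent)
            ancestors[term] = out
        return ancestors[term]

    closed = {}
    for gene, terms in annotations.items():
        full = set(terms)
        for t in terms:
            full |= climb(t)
        closed[gene] = full
    return closed


def fisher_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, set[str]],
    *,
    term_parents: Mapping[str, Iterable[str]] | None = None,
) -> list[EnrichmentResult]:
    """Classic one-sided Fisher exact test per GO term.

    For each term annotated in the universe, tests over-representation of
    the term among selected genes via the hypergeometric upper tail;
    Benjamini–Hochberg q-values are computed across all tested terms.
    Unannotated universe genes are dropped from the universe.  Terms with no
    selected member are reported with p = 1.  True-path propagation is off
    by default; supply ``term_parents`` to close annotations over ancestors
    first.
    """
    if term_parents is not None:
        annotations = propagate_annotations(annotations, term_parents)
    universe = {g for g in universe if annotations.get(g)}
    selected = set(selected)
    if not selected:
        raise ValueError("empty selected set")
    if not selected <= set(annotations) or not selected <= universe:
        extra = selected - universe
        raise ValueError(f"selected genes outside the annotated universe: {sorted(extra)[:5]}")

    term_members: dict[str, set[str]] = {}
    for g in universe:
        for t in annotations[g]:
            term_members.setdefault(t, set()).add(g)

    N = len(universe)
    n = len(selected)
    results = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & selected)
        if k == 0 or K == N:
            p = 1.0
        else:
            p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, n, K, N, min(p, 1.0)))

    qvals = bh_fdr([r.p_value for r in results])
    return [
        EnrichmentResult(r.term, r.n_selected_in_term, r.n_selected,
                         r.n_term_in_universe, r.n_universe, r.p_value,
                         float(q))
        for r, q in zip(results, qvals)
    ]
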