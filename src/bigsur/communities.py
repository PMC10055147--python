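"""Signed correlation graphs and gene communities.

Significant gene-gene correlations form a graph whose edges carry signed
equivalent PCCs.  Community detection runs on the unweighted, sign-
stripped view (all nonzero weights treated as 1) using the walktrap
random-walk agglomeration (4 steps by default), cut at maximum
modularity.  A second pass re-runs walktrap within each community on
positive edges only, so that blocks held together solely by negative
(anti-correlation) links separate; a refinement pass then merges
community pairs whose positive cross-edge density is unusually high and
re-splits oversized communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SignedGeneGraph",
    "CommunitySet",
    "EnrichmentReport",
    "build_graph",
    "walktrap_communities",
    "split_by_sign",
    "refine_communities",
    "top_connected_features",
    "pair_enrichment",
    "DEFAULT_WALK_STEPS",
    "DEFAULT_MERGE_RATIO",
    "DEFAULT_MAX_COMMUNITY_SIZE",
]

DEFAULT_WALK_STEPS = 4
DEFAULT_MERGE_RATIO = 0.25
DEFAULT_MAX_COMMUNITY_SIZE = 2000


@dataclass
class SignedGeneGraph:
    """Signed significant-correlation graph over genes."""

    graph: nx.Graph  # edges carry 'weight' = signed equivalent PCC

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def unweighted_view(self) -> nx.Graph:
        """Sign-stripped, unweighted view consumed by community detection."""
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(self.graph.edges)
        return g

    def positive_view(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes)
        g.add_edges_from(
            (u, v) for u, v, w in self.graph.edges(data="weight") if w > 0
        )
        return g


@dataclass
class CommunitySet:
    """Partition of genes; labels contiguous from 0, largest community first."""

    assignment: dict

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values())) if self.assignment else 0

    def members(self, label: int) -> list:
        return [g for g, lab in self.assignment.items() if lab == label]

    def sizes(self) -> list[int]:
        counts: dict[int, int] = {}
        for lab in self.assignment.values():
            counts[lab] = counts.get(lab, 0) + 1
        return [counts[lab] for lab in sorted(counts)]


@dataclass
class EnrichmentReport:
    observed_fraction: float
    expected_fraction: float
    fold_enrichment: float


def _relabel(groups: list[list]) -> CommunitySet:
    """Order communities by descending size (ties: smallest first member in
    input order), assign contiguous labels from 0."""
    order_index = {}
    for grp in groups:
        for g in grp:
            order_index.setdefault(g, len(order_index))
    ranked = sorted(
        (grp for grp in groups if grp),
        key=lambda grp: (-len(grp), min(order_index[g] for g in grp)),
    )
    assignment = {}
    for label, grp in enumerate(ranked):
        for g in grp:
            assignment[g] = label
    return CommunitySet(assignment=assignment)


def build_graph(edges) -> SignedGeneGraph:
    """Build the signed graph from (gene_a, gene_b, weight) records.

    Accepts an iterable of triples or a DataFrame with columns gene_a,
    gene_b, weight.  Self-loops, zero weights and conflicting duplicate
    edges are rejected.
    """
    if hasattr(edges, "itertuples"):
        edges = [(r.gene_a, r.gene_b, r.weight) for r in edges.itertuples()]
    g = nx.Graph()
    for a, b, w in edges:
        if a == b:
            raise ValidationError(f"self-loop on gene {a!r}")
        if w == 0:
            raise ValidationError(f"zero-weight edge ({a!r}, {b!r})")
        if g.has_edge(a, b):
            if g[a][b]["weight"] != w:
                raise ValidationError(f"conflicting duplicate edge ({a!r}, {b!r})")
            continue
        g.add_edge(a, b, weight=float(w))
    return SignedGeneGraph(graph=g)


def _walktrap_partition(g: nx.Graph, steps: int) -> list[list]:
    """Walktrap partition of one graph, run per connected component.

    Restricting to components is sound: a maximum-modularity cut never
    joins disconnected vertex sets.  Deterministic given the graph (node
    order fixed by insertion order).
    """
    groups: list[list] = []
    for comp in nx.connected_components(g):
        nodes = [n for n in g.nodes if n in comp]  # preserve insertion order
        if len(nodes) <= 2:
            groups.append(nodes)
            continue
        index = {n: i for i, n in enumerate(nodes)}
        edges = [(index[u], index[v]) for u, v in g.subgraph(nodes).edges]
        graph = ig.Graph(n=len(nodes), edges=edges)
        clustering = graph.community_walktrap(steps=steps).as_clustering()
        for block in clustering:
            groups.append([nodes[i] for i in block])
    return groups


def walktrap_communities(g: nx.Graph, steps: int = DEFAULT_WALK_STEPS) -> CommunitySet:
    """Random-walk (walktrap) communities on an unweighted graph view."""
    if g.number_of_nodes() == 0:
        return CommunitySet(assignment={})
    return _relabel(_walktrap_partition(g, steps))


def split_by_sign(
    g: SignedGeneGraph, cs: CommunitySet, steps: int = DEFAULT_WALK_STEPS
) -> CommunitySet:
    """Re-cluster each community on its positive edges only.

    Communities internally connected only through negative links fall
    apart into anti-correlated subcommunities; genes with no positive
    neighbours inside their community become singletons.  Never merges
    existing communities.
    """
    pos = g.positive_view()
    groups: list[list] = []
    for label in range(cs.n_communities):
        members = cs.members(label)
        sub = pos.subgraph(members).copy()
        groups.extend(_walktrap_partition(sub, steps))
    return _relabel(groups)


def _cross_density(pos: nx.Graph, a: list, b: list) -> float:
    possible = len(a) * len(b)
    if possible == 0:
        return 0.0
    sa = set(a)
    present = sum(1 for u in b for v in pos.neighbors(u) if v in sa)
    return present / possible


def refine_communities(
    g: SignedGeneGraph,
    cs: CommunitySet,
    merge_ratio_threshold: float = DEFAULT_MERGE_RATIO,
    max_size: int = DEFAULT_MAX_COMMUNITY_SIZE,
    steps: int = DEFAULT_WALK_STEPS,
    max_iter: int = 100,
) -> CommunitySet:
    """Merge over-split communities; re-split oversized ones.

    Community pairs whose positive inter-community edge density (present
    cross edges / possible cross edges) exceeds the threshold are merged
    iteratively, densest pair first.  Afterwards communities larger than
    ``max_size`` get one extra walktrap pass on their positive subgraph.
    """
    pos = g.positive_view()
    groups = [cs.members(lab) for lab in range(cs.n_communities)]
    for iteration in range(max_iter + 1):
        if iteration == max_iter:
            raise ValidationError(
                f"refine_communities failed to settle after {max_iter} merges; "
                f"{len(groups)} communities remain"
            )
        best = None
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                d = _cross_density(pos, groups[i], groups[j])
                if d > merge_ratio_threshold and (best is None or d > best[0]):
                    best = (d, i, j)
        if best is None:
            break
        _, i, j = best
        groups[i] = groups[i] + groups[j]
        del groups[j]
    resplit: list[list] = []
    for grp in groups:
        if len(grp) > max_size:
            resplit.extend(_walktrap_partition(pos.subgraph(grp).copy(), steps))
        else:
            resplit.append(grp)
    return _relabel(resplit)


def top_connected_features(
    g: SignedGeneGraph,
    cs: CommunitySet,
    community_labels,
    k: int = 75,
) -> dict:
    """Per community, the k genes of highest within-community positive degree.

    Ties break by total absolute edge weight within the community, then by
    input order.  Returns {label: [gene, ...]}.
    """
    pos = g.positive_view()
    node_order = {n: i for i, n in enumerate(g.graph.nodes)}
    out = {}
    for label in community_labels:
        members = cs.members(label)
        if not members:
            raise ValidationError(f"unknown community label {label}")
        member_set = set(members)
        sub = pos.subgraph(members)

        def keyfn(gene):
            deg = sub.degree(gene) if gene in sub else 0
            wsum = sum(
                abs(w)
                for u, v, w in g.graph.edges(gene, data="weight")
                if (u in member_set and v in member_set)
            )
            return (-deg, -wsum, node_order.get(gene, len(node_order)))

        out[label] = sorted(members, key=keyfn)[:k]
    return out


def pair_enrichment(sig_pairs, reference_pairs, detected_genes) -> EnrichmentReport:
    """Fold enrichment of a reference pair set among significant pairs.

    observed = fraction of significant pairs found in the reference;
    expected = reference pairs restricted to detected genes over all
    m(m-1)/2 possible pairs; fold = observed / expected.
    """
    sig = {frozenset(p) for p in sig_pairs}
    if not sig:
        raise ValidationError("empty significant pair set")
    detected = set(detected_genes)
    for p in sig:
        if not p <= detected:
            raise ValidationError(f"significant pair {sorted(p)} outside detected genes")
    ref = {
        frozenset(p)
        for p in reference_pairs
        if frozenset(p) <= detected and len(frozenset(p)) == 2
    }
    m = len(detected)
    possible = m * (m - 1) // 2
    expected = len(ref) / possible if possible else 0.0
    if expected == 0:
        raise ValidationError("reference pair set empty after restriction to detected genes")
    observed = len(sig & ref) / len(sig)
    return EnrichmentReport(
        observed_fraction=observed,
        expected_fraction=expected,
        fold_enrichment=observed / expected,
    )
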