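"""Independent brute-force oracles used by the test suite.

The community oracle enumerates every partition of a small graph into
connected parts and returns the one of maximum Newman modularity.
Restricting to connected parts is sound: splitting a disconnected
community into its components never lowers modularity (internal edges are
kept while the squared degree-sum penalty strictly decreases), so some
maximum-modularity partition has only connected parts.
"""

from __future__ import annotations

import networkx as nx


def _connected_subsets(g, cur: frozenset, ext: tuple, banned: frozenset, allowed):
    """Yield all connected induced subsets reachable by growing ``cur``."""
    if not ext:
        yield cur
        return
    u, rest = ext[0], ext[1:]
    # branch 1: never include u
    yield from _connected_subsets(g, cur, rest, banned | {u}, allowed)
    # branch 2: include u, extending the frontier with its new neighbours
    new_ext = rest + tuple(
        w
        for w in g.neighbors(u)
        if w in allowed and w not in cur and w not in banned and w not in rest and w != u
    )
    yield from _connected_subsets(g, cur | {u}, new_ext, banned, allowed)


def connected_subsets_containing(g: nx.Graph, v, allowed: frozenset):
    """All subsets of ``allowed`` containing v that induce a connected graph."""
    ext = tuple(w for w in g.neighbors(v) if w in allowed and w != v)
    yield from _connected_subsets(g, frozenset([v]), ext, frozenset(), allowed)


def connected_partitions(g: nx.Graph, remaining: frozenset):
    """All partitions of ``remaining`` into connected parts."""
    if not remaining:
        yield []
        return
    v = min(remaining)
    for part in connected_subsets_containing(g, v, remaining):
        for rest in connected_partitions(g, remaining - part):
            yield [part] + rest


def max_modularity_partition(g: nx.Graph) -> list[set]:
    """Exhaustive maximum-modularity partition (small graphs only)."""
    edges = list(g.edges)
    m = len(edges)
    deg = dict(g.degree)
    best_q, best = -2.0, None
    for parts in connected_partitions(g, frozenset(g.nodes)):
        label = {}
        for i, p in enumerate(parts):
            for v in p:
                label[v] = i
        e_in = [0] * len(parts)
        for u, v in edges:
            if label[u] == label[v]:
                e_in[label[u]] += 1
        q = sum(
            e_in[i] / m - (sum(deg[v] for v in p) / (2 * m)) ** 2
            for i, p in enumerate(parts)
        )
        if q > best_q + 1e-12:
            best_q, best = q, [set(p) for p in parts]
    return best


def partition_as_sets(assignment: dict) -> set:
    """{label: members} -> canonical frozenset-of-frozensets form."""
    groups: dict = {}
    for node, lab in assignment.items():
        groups.setdefault(lab, set()).add(node)
    return {frozenset(s) for s in groups.values()}
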