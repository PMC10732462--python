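"""Phylogenetic-diversity (PD) maximising leaf subsampling.

PD of a leaf set is the total branch length of the minimal subtree spanning
it, computed on the unrooted topology. Greedy selection — start from a
maximally distant leaf pair, then repeatedly add the leaf farthest from the
current spanning subtree — is exactly optimal for PD on trees, so the greedy
subset matches exhaustive maximisation (which :func:`brute_force_max_pd`
provides as a testing oracle). Ties break lexicographically by leaf id so
results are reproducible; zero-length edges are allowed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from .core import PhyloTree


@dataclass(frozen=True)
class PDSubset:
    """A selected leaf set and the PD of its spanning subtree."""

    leaf_ids: frozenset[str]
    pd_value: float


def compute_pd(tree: PhyloTree, leaves: set[str] | frozenset[str]) -> float:
    """Total branch length of the minimal subtree spanning ``leaves``.

    An edge belongs to the spanning subtree exactly when selected leaves
    occur on both of its sides.
    """
    leaves = frozenset(leaves)
    if len(leaves) < 2:
        raise ValueError(f"need at least 2 leaves, got {len(leaves)}")
    missing = leaves - tree.leaf_set
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")
    adj, leaf_index = tree.adjacency()
    selected = {leaf_index[l] for l in leaves}
    total = len(leaves)
    # count selected leaves below each node of a rooted traversal from node 0
    order, parent, parent_w = _rooted_order(adj, root=0)
    count = {v: (1 if v in selected else 0) for v in adj}
    pd = 0.0
    for v in reversed(order):
        p = parent[v]
        if p is None:
            continue
        count[p] += count[v]
        if 0 < count[v] < total:
            pd += parent_w[v]
    return pd


def _rooted_order(adj, root: int):
    """Iterative preorder over the undirected tree rooted at ``root``."""
    parent: dict[int, int | None] = {root: None}
    parent_w: dict[int, float] = {root: 0.0}
    order: list[int] = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for nb, w in adj[v]:
            if nb != parent[v]:
                parent[nb] = v
                parent_w[nb] = w
                stack.append(nb)
    return order, parent, parent_w


def _distances_from(adj, source: int) -> dict[int, float]:
    dist = {source: 0.0}
    stack = [source]
    seen = {source}
    while stack:
        v = stack.pop()
        for nb, w in adj[v]:
            if nb not in seen:
                seen.add(nb)
                dist[nb] = dist[v] + w
                stack.append(nb)
    return dist


def _farthest_leaf(dist: dict[int, float], leaf_of: dict[int, str]) -> int:
    """Leaf node index maximising distance; ties -> lexicographically
    smallest leaf label."""
    return max(leaf_of, key=lambda v: (dist[v], _NegStr(leaf_of[v])))


class _NegStr(str):
    """String with reversed ordering, for 'max distance, min label' keys."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def select_max_pd_subset(tree: PhyloTree, k: int) -> PDSubset:
    """Select ``k`` leaves maximising PD, greedily (exactly optimal).

    Starts from a maximally distant leaf pair (found by the standard
    double-sweep from the lexicographically smallest leaf), then adds the
    leaf with the greatest distance to the current spanning subtree,
    breaking ties by leaf id.
    """
    n = tree.n_leaves
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    adj, leaf_index = tree.adjacency()
    leaf_of = {v: label for label, v in leaf_index.items()}

    start = leaf_index[min(leaf_index)]
    u = _farthest_leaf(_distances_from(adj, start), leaf_of)
    dist_u = _distances_from(adj, u)
    v = _farthest_leaf(dist_u, leaf_of)
    if u == v:  # single-leaf degenerate case is excluded by k >= 2 <= n
        raise AssertionError("degenerate diameter search")

    # grow the spanning subtree; d_sub = distance of each node to the subtree
    in_sub: set[int] = set()
    d_sub = {node: float("inf") for node in adj}
    toward: dict[int, int] = {}  # next hop toward the subtree

    def absorb(leaf_node: int) -> None:
        """Add the path from ``leaf_node`` to the subtree, relaxing outward."""
        path = []
        x = leaf_node
        while x not in in_sub and x in toward:
            path.append(x)
            x = toward[x]
        if x not in in_sub:  # first absorption: whole u..v path via parents
            path.append(x)
        frontier = []
        for node in path:
            in_sub.add(node)
            d_sub[node] = 0.0
            frontier.append(node)
        while frontier:
            y = frontier.pop()
            for nb, w in adj[y]:
                if nb not in in_sub and d_sub[y] + w < d_sub[nb]:
                    d_sub[nb] = d_sub[y] + w
                    toward[nb] = y
                    frontier.append(nb)

    # seed the subtree with the u..v path
    order, parent, parent_w = _rooted_order(adj, root=u)
    x = v
    while x is not None:
        in_sub.add(x)
        d_sub[x] = 0.0
        x = parent[x]
    frontier = list(in_sub)
    while frontier:
        y = frontier.pop()
        for nb, w in adj[y]:
            if nb not in in_sub and d_sub[y] + w < d_sub[nb]:
                d_sub[nb] = d_sub[y] + w
                toward[nb] = y
                frontier.append(nb)

    chosen = {leaf_of[u], leaf_of[v]}
    pd = dist_u[v]
    while len(chosen) < k:
        best = max(
            (node for node in leaf_of if leaf_of[node] not in chosen),
            key=lambda node: (d_sub[node], _NegStr(leaf_of[node])),
        )
        pd += d_sub[best]
        chosen.add(leaf_of[best])
        absorb(best)
    return PDSubset(frozenset(chosen), pd)


def brute_force_max_pd(tree: PhyloTree, k: int) -> PDSubset:
    """Exhaustive PD maximisation over all k-subsets (testing oracle).

    Guarded to <= 12 leaves; the deterministic tie-break keeps the
    lexicographically first maximising subset.
    """
    n = tree.n_leaves
    if n > 12:
        raise ValueError(f"brute force limited to 12 leaves, tree has {n}")
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    best: PDSubset | None = None
    for combo in itertools.combinations(sorted(tree.leaf_set), k):
        pd = compute_pd(tree, set(combo))
        if best is None or pd > best.pd_value:
            best = PDSubset(frozenset(combo), pd)
    assert best is not None
    return best
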