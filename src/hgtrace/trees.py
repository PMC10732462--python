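"""Bipartition machinery: support-based polytomy collapsing, weighted
Robinson–Foulds distances, and extraction of eukaryotic clades with their
sister composition.

All computations treat the tree as unrooted: a bipartition is the two-way
leaf split induced by one internal edge, stored in canonical orientation
(the side containing the lexicographically smallest leaf). A bifurcating
root contributes a single bipartition whose weight is the sum of the two
root-adjacent edge lengths.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import PhyloTree, TaxonRecord, _leafsets_below


@dataclass(frozen=True)
class Bipartition:
    """One internal-edge split in canonical orientation, with branch weight
    and optional support."""

    side_a: frozenset[str]
    weight: float
    support: int | None = None


@dataclass(frozen=True)
class CladeContext:
    """A clade, its stem support, and the composition of its sister clade."""

    clade_leaves: frozenset[str]
    stem_support: int | None
    sister_leaves: frozenset[str]
    sister_bacterial_fraction: float


def _canonical(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    smallest = min(all_leaves)
    return side if smallest in side else all_leaves - side


def _split_map(tree: PhyloTree, include_trivial: bool = False) -> dict[frozenset[str], Bipartition]:
    """Canonical split -> Bipartition, merging the duplicate split of a
    bifurcating root (weights add, support taken where present)."""
    all_leaves = tree.leaf_set
    out: dict[frozenset[str], Bipartition] = {}
    for node, below in _leafsets_below(tree.dendropy_tree):
        if node.parent_node is None:
            continue
        side = frozenset(below)
        trivial = len(side) <= 1 or len(side) >= len(all_leaves) - 1
        if trivial and not include_trivial:
            continue
        if len(side) == 0 or len(side) == len(all_leaves):
            continue
        key = _canonical(side, all_leaves)
        weight = float(node.edge.length)
        support = getattr(node, "support", None)
        if key in out:  # two root-adjacent edges describe the same split
            prev = out[key]
            support = prev.support if prev.support is not None else support
            weight += prev.weight
        out[key] = Bipartition(key, weight, support)
    return out


def extract_bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """All non-trivial bipartitions (pendant edges excluded)."""
    if tree.n_leaves < 4:
        raise ValueError(f"need at least 4 leaves, got {tree.n_leaves}")
    return set(_split_map(tree).values())


def collapse_low_support(tree: PhyloTree, threshold: int) -> PhyloTree:
    """Contract every internal edge whose support is strictly below
    ``threshold``; edges without a support value are retained."""
    if not 0 <= threshold <= 101:
        raise ValueError(f"threshold must lie in [0, 101], got {threshold}")
    out = tree.copy()
    doomed = []
    for node in out.dendropy_tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        sup = getattr(node, "support", None)
        if sup is not None and sup < threshold:
            doomed.append(node)
    for node in doomed:
        node.edge.collapse()
    return PhyloTree(out.dendropy_tree)


def _prune_to(tree: PhyloTree, keep: frozenset[str]) -> PhyloTree:
    out = tree.copy()
    dt = out.dendropy_tree
    dt.retain_taxa_with_labels(sorted(keep))
    # pruning can leave unifurcations; suppress them so splits are clean
    dt.suppress_unifurcations()
    return PhyloTree(dt)


def weighted_rf(tree1: PhyloTree, tree2: PhyloTree, prune_to_common: bool = True,
                shared_only: bool = False) -> float:
    """Weighted Robinson–Foulds distance.

    Sum over the union of the two trees' non-trivial bipartitions of the
    absolute branch-weight difference, a split absent from one tree
    contributing weight zero there. With ``shared_only=True`` the sum is
    restricted to splits present in both trees (count-style variant).
    """
    if prune_to_common:
        common = tree1.leaf_set & tree2.leaf_set
        if len(common) < 4:
            raise ValueError(f"only {len(common)} shared leaves; need >= 4")
        if common != tree1.leaf_set:
            tree1 = _prune_to(tree1, frozenset(common))
        if common != tree2.leaf_set:
            tree2 = _prune_to(tree2, frozenset(common))
    elif tree1.leaf_set != tree2.leaf_set:
        raise ValueError("leaf sets differ; use prune_to_common=True")
    if tree1.n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    s1 = {b.side_a: b.weight for b in _split_map(tree1).values()}
    s2 = {b.side_a: b.weight for b in _split_map(tree2).values()}
    keys = (set(s1) & set(s2)) if shared_only else (set(s1) | set(s2))
    return sum(abs(s1.get(k, 0.0) - s2.get(k, 0.0)) for k in keys)


def _prokaryote_set(taxa: Sequence[TaxonRecord]) -> set[str]:
    return {t.taxon_id for t in taxa if t.domain_of_life in ("bacteria", "archaea")}


def find_eukaryotic_clades(
    tree: PhyloTree,
    taxa: Sequence[TaxonRecord],
    leaf_to_taxon: Mapping[str, str] | None = None,
) -> list[CladeContext]:
    """All maximal all-eukaryotic bipartition sides, with stem support and
    sister composition.

    ``leaf_to_taxon`` maps leaf labels to taxon ids when they differ (e.g.
    sequence-labelled trees); by default leaf labels are taxon ids. Archaea
    count as prokaryotic context. Sister determination is local to the stem
    edge and independent of the input rooting: from the node across the stem
    edge, the neighbouring subtree richest in prokaryotes is taken as
    root-ward, and the remaining subtrees form the sister.
    """
    by_id = {t.taxon_id: t for t in taxa}
    leaf_to_taxon = dict(leaf_to_taxon or {})

    def taxon_of(leaf: str) -> TaxonRecord:
        tid = leaf_to_taxon.get(leaf, leaf)
        if tid not in by_id:
            raise ValueError(f"leaf {leaf!r} has no taxon record")
        return by_id[tid]

    leaves = tree.leaf_set
    euk_leaves = {l for l in leaves if taxon_of(l).is_eukaryote}
    if not euk_leaves:
        return []

    # enumerate every side of every edge (pendant edges included: a single
    # transferred leaf is still a reportable clade)
    dt = tree.dendropy_tree
    node_below: dict[int, frozenset[str]] = {}
    node_by_id = {}
    for node, below in _leafsets_below(dt):
        node_below[id(node)] = frozenset(below)
        node_by_id[id(node)] = node

    sides: dict[frozenset[str], tuple[int | None, object]] = {}
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = node_below[id(node)]
        sup = getattr(node, "support", None)
        if node.is_leaf() and sup is None:
            # pendant edges carry no support of their own; a singleton clade's
            # stem support is read from the adjacent supported edge
            sup = getattr(node.parent_node, "support", None)
        for side in (below, leaves - below):
            if side and side <= euk_leaves:
                prev = sides.get(side)
                if prev is None or (prev[0] is None and sup is not None):
                    sides[side] = (sup, node)

    maximal = [
        s for s in sides
        if not any(s < other for other in sides)
    ]

    def is_prok(leaf: str) -> bool:
        return not taxon_of(leaf).is_eukaryote

    contexts = []
    for side in sorted(maximal, key=lambda s: (len(s), sorted(s))):
        sup, node = sides[side]
        sister = _sister_leaves(node, node_below, leaves, side, is_prok)
        prok = {l for l in sister if is_prok(l)}
        frac = len(prok) / len(sister) if sister else 0.0
        contexts.append(CladeContext(side, sup, frozenset(sister), frac))
    return contexts


def _sister_leaves(stem_node, node_below, all_leaves: frozenset[str],
                   clade: frozenset[str], is_prok) -> frozenset[str]:
    """Leaves of the smallest clade across the stem edge, orienting away
    from the prokaryote-majority direction."""
    below = node_below[id(stem_node)]
    parent = stem_node.parent_node
    if clade == below:
        # neighbouring subtrees across the stem edge: siblings + the
        # "up" remainder beyond the parent
        neighbourhoods = [
            node_below[id(sib)] for sib in parent.child_nodes() if sib is not stem_node
        ]
        up = all_leaves - node_below[id(parent)]
        if up:
            neighbourhoods.append(frozenset(up))
    else:
        # clade is the complement side: the stem edge's other endpoint is
        # this node itself; its children are the neighbouring subtrees
        neighbourhoods = [node_below[id(ch)] for ch in stem_node.child_nodes()]
    if len(neighbourhoods) == 1:
        return frozenset(neighbourhoods[0])
    # root-ward = the prokaryote-majority direction: rank neighbourhoods by
    # prokaryote count, then size, then lexicographically for determinism
    def rank(s: frozenset[str]):
        return (sum(1 for l in s if is_prok(l)), len(s), sorted(s))
    rootward = max(neighbourhoods, key=rank)
    sister: set[str] = set()
    for s in neighbourhoods:
        if s is not rootward:
            sister |= s
    return frozenset(sister)
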