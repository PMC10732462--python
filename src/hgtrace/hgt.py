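"""The four-criterion horizontal-gene-transfer call, cross-tree robustness,
superfamily classification, and the supergroup-breadth ancestry heuristic.

A eukaryotic clade nested in bacterial context is trusted as an HGT
candidate only when all four criteria hold:

1. it branches adjacent to bacterial sequences with strong support
   (stem support strictly above 70 and a majority-bacterial sister);
2. it is a distinct subclade with at least 2 species from the same
   eukaryotic supergroup;
3. its sequences come from at least 2 different source studies;
4. a matching clade, itself passing 1–3, recurs in every replicate tree
   (one per alignment x reconstruction method).

The caller never decides transfer direction: candidates are reported as
"eukaryote nested in bacterial context", the most parsimonious reading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .core import CriteriaConfig, DomainHit, PhyloTree, TaxonRecord
from .simulate import CRITERIA
from .trees import CladeContext, find_eukaryotic_clades

#: diagnostic top-scoring domain -> superfamily
SUPERFAMILY_DOMAINS = {
    "PF18144": "eSMODS",   # SMODS, the bacteria-typical CD-NTase domain
    "PF10421": "OAS",      # OAS1-C
    "PF03281": "cGLR",     # Mab21, the cGAS catalytic domain
    "PF20300": "blSTING",  # Prok_STING on a eukaryotic sequence
}


@dataclass
class HGTCandidate:
    """A candidate transfer event with its per-criterion evaluation."""

    clade_leaves: frozenset[str]
    species_set: frozenset[str]
    supergroup_counts: dict[str, int]
    study_count: int
    stem_support: int | None
    sister_bacterial_fraction: float
    criteria_passed: dict[str, bool | None]
    robustness: tuple[int, int] = (0, 0)  # trees supporting / trees evaluated
    data_types: frozenset[str] = frozenset()  # surfaced, never filtered on

    def __post_init__(self) -> None:
        if set(self.criteria_passed) != set(CRITERIA):
            raise ValueError(f"criteria_passed must have exactly the keys {CRITERIA}")

    @property
    def passes_all(self) -> bool:
        return all(self.criteria_passed[c] is True for c in CRITERIA)


@dataclass(frozen=True)
class SuperfamilyCall:
    seq_id: str
    superfamily: str  # cGLR | OAS | eSMODS | blSTING | unclassified
    evidence: str


@dataclass(frozen=True)
class BreadthReport:
    """How many of the configured eukaryotic supergroups a clade spans."""

    count: int
    total: int
    supergroups: tuple[str, ...]
    broad: bool  # labelled heuristic: >= ceil(total/2) supergroups


def _resolve(leaf: str, by_id: Mapping[str, TaxonRecord],
             leaf_to_taxon: Mapping[str, str]) -> TaxonRecord:
    tid = leaf_to_taxon.get(leaf, leaf)
    if tid not in by_id:
        raise ValueError(f"leaf {leaf!r} has no taxon record")
    return by_id[tid]


def evaluate_criteria(
    context: CladeContext,
    taxa: Sequence[TaxonRecord],
    config: CriteriaConfig,
    leaf_to_taxon: Mapping[str, str] | None = None,
) -> HGTCandidate:
    """Evaluate criteria 1–3 on one clade context (criterion 4 needs the
    other trees and is filled by :func:`call_hgt_candidates`).

    Criterion 1 holds when the stem support strictly exceeds
    ``config.support_min`` and at least half the sister leaves are
    prokaryotic; 2 when some supergroup contributes at least
    ``min_species_same_supergroup`` distinct species; 3 when the clade's
    species span at least ``min_studies`` studies.
    """
    by_id = {t.taxon_id: t for t in taxa}
    leaf_to_taxon = dict(leaf_to_taxon or {})
    records = [_resolve(l, by_id, leaf_to_taxon) for l in context.clade_leaves]
    species = frozenset(r.taxon_id for r in records)
    supergroup_counts: dict[str, int] = {}
    for tid in species:
        sg = by_id[tid].supergroup
        if by_id[tid].is_eukaryote:
            supergroup_counts[sg] = supergroup_counts.get(sg, 0) + 1
    studies = {by_id[tid].study_id for tid in species if by_id[tid].is_eukaryote}
    data_types = frozenset(
        by_id[tid].data_type for tid in species if by_id[tid].is_eukaryote
    )
    c1 = (
        context.stem_support is not None
        and context.stem_support > config.support_min
        and context.sister_bacterial_fraction >= 0.5
    )
    c2 = bool(supergroup_counts) and max(supergroup_counts.values()) >= \
        config.min_species_same_supergroup
    c3 = len(studies) >= config.min_studies
    return HGTCandidate(
        clade_leaves=context.clade_leaves,
        species_set=species,
        supergroup_counts=supergroup_counts,
        study_count=len(studies),
        stem_support=context.stem_support,
        sister_bacterial_fraction=context.sister_bacterial_fraction,
        criteria_passed={
            "c1_support_adjacency": c1,
            "c2_species_supergroup": c2,
            "c3_studies": c3,
            "c4_robustness": None,
        },
        data_types=data_types,
    )


def _clades_match(a: frozenset[str], b: frozenset[str],
                  config: CriteriaConfig) -> bool:
    if config.clade_match_mode == "exact_species_set":
        return a == b
    union = len(a | b)
    return union > 0 and len(a & b) / union >= config.jaccard_min


def call_hgt_candidates(
    trees: Sequence[PhyloTree],
    taxa: Sequence[TaxonRecord],
    config: CriteriaConfig,
    leaf_to_taxon: Mapping[str, str] | None = None,
) -> list[HGTCandidate]:
    """Find eukaryotic clades on the first (reference) tree, evaluate
    criteria 1–3, and fill criterion 4 from the other trees.

    Criterion 4 holds when a clade with a matching species set (per
    ``config.clade_match_mode``), itself passing criteria 1–3, exists in
    every other tree (``require_all_trees``; else a majority of them).
    Candidates failing criteria are reported with their flags, never
    silently dropped.
    """
    if not trees:
        raise ValueError("need at least one tree")
    ref = trees[0]
    for other in trees[1:]:
        if not (ref.leaf_set & other.leaf_set):
            raise ValueError("trees have disjoint leaf sets")

    def passing_species_sets(tree: PhyloTree) -> list[frozenset[str]]:
        out = []
        for ctx in find_eukaryotic_clades(tree, taxa, leaf_to_taxon):
            cand = evaluate_criteria(ctx, taxa, config, leaf_to_taxon)
            if all(cand.criteria_passed[c] for c in CRITERIA[:3]):
                out.append(cand.species_set)
        return out

    others = [passing_species_sets(t) for t in trees[1:]]
    candidates = []
    for ctx in find_eukaryotic_clades(ref, taxa, leaf_to_taxon):
        cand = evaluate_criteria(ctx, taxa, config, leaf_to_taxon)
        supporting = sum(
            1 for sets in others
            if any(_clades_match(cand.species_set, s, config) for s in sets)
        )
        n_others = len(others)
        if n_others == 0:
            c4 = all(cand.criteria_passed[c] for c in CRITERIA[:3])
        elif config.require_all_trees:
            c4 = supporting == n_others
        else:
            c4 = supporting >= math.ceil(n_others / 2)
        # a clade failing 1-3 on the reference tree cannot be a robust call
        c4 = c4 and all(cand.criteria_passed[c] for c in CRITERIA[:3])
        cand.criteria_passed["c4_robustness"] = c4
        cand.robustness = (supporting, n_others)
        candidates.append(cand)
    return candidates


def classify_superfamily(
    seq_id: str,
    domains: Sequence[DomainHit],
    clade_label: str | None = None,
    is_eukaryote: bool = True,
) -> SuperfamilyCall:
    """Assign a superfamily from the top-scoring diagnostic domain.

    Among the sequence's hits to the diagnostic accessions, the one with the
    lowest E-value (ties to the higher score) decides: SMODS -> eSMODS,
    OAS1-C -> OAS, Mab21 -> cGLR, Prok_STING on a eukaryotic sequence ->
    blSTING. A ``clade_label`` that contradicts the domain call downgrades
    it to unclassified with a conflict note. No domains at all is not an
    error, just unclassified.
    """
    mine = [d for d in domains
            if d.seq_id == seq_id and d.domain_acc in SUPERFAMILY_DOMAINS]
    if not mine:
        return SuperfamilyCall(seq_id, "unclassified", "no diagnostic domain")
    top = min(mine, key=lambda d: (d.e_value, -d.score, d.domain_acc))
    call = SUPERFAMILY_DOMAINS[top.domain_acc]
    if call == "blSTING" and not is_eukaryote:
        return SuperfamilyCall(
            seq_id, "unclassified",
            f"Prok_STING ({top.domain_acc}) on a non-eukaryotic sequence",
        )
    if clade_label is not None and clade_label != call:
        return SuperfamilyCall(
            seq_id, "unclassified",
            f"conflict: top domain {top.domain_acc} says {call}, "
            f"clade says {clade_label}",
        )
    evidence = f"top domain {top.domain_acc}"
    if clade_label is not None:
        evidence += f"; clade {clade_label}"
    return SuperfamilyCall(seq_id, call, evidence)


def assess_supergroup_breadth(
    clade_leaves: frozenset[str] | set[str],
    taxa: Sequence[TaxonRecord],
    total_supergroups: int = 12,
    leaf_to_taxon: Mapping[str, str] | None = None,
) -> BreadthReport:
    """Count the distinct eukaryotic supergroups represented in a clade.

    A clade spanning at least half the configured supergroups (count >=
    ceil(total/2)) is flagged broad — compatible with presence in the last
    eukaryotic common ancestor. This is a labelled heuristic, not an
    ancestral-state inference.
    """
    by_id = {t.taxon_id: t for t in taxa}
    leaf_to_taxon = dict(leaf_to_taxon or {})
    groups = sorted({
        rec.supergroup
        for leaf in clade_leaves
        for rec in [_resolve(leaf, by_id, leaf_to_taxon)]
        if rec.is_eukaryote
    })
    count = len(groups)
    return BreadthReport(
        count=count, total=total_supergroups, supergroups=tuple(groups),
        broad=count >= math.ceil(total_supergroups / 2),
    )
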