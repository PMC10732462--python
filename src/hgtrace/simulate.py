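"""Synthetic data: mixed bacterial/eukaryotic trees with planted HGT clades,
taxon metadata, bootstrap-style supports, domain tables and profile-derived
sequences.

The generator emulates the shape of the real inputs — a large prokaryotic
backbone with one monophyletic eukaryotic clade, eukaryotes labelled with
one of 12 supergroups and a source study, ultrafast-bootstrap-style integer
supports — so that every downstream stage (clade extraction, the
four-criterion HGT call, catalog analytics, the iterative search) is
testable without any external database. Trees come from a constant-rate
birth–death process; the domain-of-life monophyly of the backbone is
enforced by simulating the bacterial and eukaryotic subtrees separately and
joining them at the root, which avoids rejection sampling. No sequence
evolution is simulated along the tree.

All generators are pure functions of their parameters and seed.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .core import (
    AMINO_ACIDS,
    DomainHit,
    PhyloTree,
    SequenceRecord,
    TaxonRecord,
    node_label,
    _leafsets_below,
)
from .search import ProfileModel

#: the four HGT criteria, in the order they are stated
CRITERIA = (
    "c1_support_adjacency",
    "c2_species_supergroup",
    "c3_studies",
    "c4_robustness",
)

#: 12 eukaryotic supergroup names used by the synthetic taxon tables
SUPERGROUPS_12 = (
    "Metazoa", "Fungi", "Amoebozoa", "Archaeplastida", "Cryptista",
    "Haptista", "Stramenopila", "Alveolata", "Rhizaria", "Discoba",
    "Metamonada", "Ancyromonadida",
)

NOISE_DOMAIN_ACC = "PF99999"


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the backbone simulation.

    Defaults give a desk-scale backbone (60 bacteria, 30 eukaryotes) with a
    mildly extinct birth–death process and high supports everywhere except
    where a test plants low ones.
    """

    n_bacteria: int = 60
    n_eukaryotes: int = 30
    birth_rate: float = 1.0
    death_rate: float = 0.2
    support_high_range: tuple[int, int] = (85, 100)
    support_low_range: tuple[int, int] = (40, 65)
    study_pool: tuple[str, ...] = ("study_A", "study_B", "study_C")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bacteria < 2 or self.n_eukaryotes < 2:
            raise ValueError("need at least 2 leaves on each side of the backbone")
        if self.n_bacteria + self.n_eukaryotes < 4:
            raise ValueError("n_bacteria + n_eukaryotes must be >= 4")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative with birth_rate > 0")
        if self.death_rate >= self.birth_rate:
            raise ValueError("death_rate must be strictly below birth_rate")
        for lo, hi in (self.support_high_range, self.support_low_range):
            if not 0 <= lo <= hi <= 100:
                raise ValueError("support ranges must lie within [0, 100]")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one planted HGT clade: which species were grafted
    where, and which of the four criteria the construction satisfies."""

    clade_species: frozenset[str]
    donor_label: str
    satisfies: dict[str, bool] = field(compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.clade_species:
            raise ValueError("clade_species must be non-empty")
        if set(self.satisfies) != set(CRITERIA):
            raise ValueError(f"satisfies must have exactly the keys {CRITERIA}")


# ---------------------------------------------------------------------------
# Backbone simulation
# ---------------------------------------------------------------------------

def _bd_subtree(n: int, params: SimulationParams, rng: random.Random,
                prefix: str) -> str:
    tree = birthdeath.birth_death_tree(
        birth_rate=params.birth_rate, death_rate=params.death_rate,
        num_extant_tips=n, rng=rng, repeat_until_success=True,
    )
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"{prefix}{i:04d}"
    tree.seed_node.edge.length = None
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip().rstrip(";")


def simulate_backbone_tree(params: SimulationParams) -> tuple[PhyloTree, list[TaxonRecord]]:
    """A birth–death backbone: ``n_bacteria`` bacterial leaves (B0001...)
    and one monophyletic clade of ``n_eukaryotes`` eukaryotic leaves
    (E0001...), joined at the root. Eukaryotes get supergroups round-robin
    from the 12-name list, studies round-robin from ``study_pool`` and
    alternating genome/transcriptome data types. Internal edges carry
    supports from ``support_high_range``. Reproducible given ``params.seed``.
    """
    rng = random.Random(params.seed)
    bact = _bd_subtree(params.n_bacteria, params, rng, "B")
    euk = _bd_subtree(params.n_eukaryotes, params, rng, "E")
    tree = PhyloTree.from_string(f"({bact}:1.0,{euk}:1.0);")
    tree = assign_supports(tree, set(), params)

    taxa: list[TaxonRecord] = []
    for label in sorted(tree.leaf_labels):
        if label.startswith("B"):
            taxa.append(TaxonRecord(label, f"Bacterium {label}", "bacteria",
                                    "", "bacterial_survey", "genome"))
    euks = sorted(l for l in tree.leaf_labels if l.startswith("E"))
    for i, label in enumerate(euks):
        taxa.append(TaxonRecord(
            label, f"Eukaryote {label}", "eukaryote",
            SUPERGROUPS_12[i % len(SUPERGROUPS_12)],
            params.study_pool[i % len(params.study_pool)],
            "genome" if i % 2 == 0 else "transcriptome",
        ))
    return tree, taxa


def assign_supports(tree: PhyloTree, low_edges: set[frozenset[str]],
                    params: SimulationParams) -> PhyloTree:
    """Assign integer supports to all internal edges: ``low_edges``
    (identified by the leaf set below the edge) draw from
    ``support_low_range``, all others from ``support_high_range``.
    Reproducible given ``params.seed``."""
    out = tree.copy()
    dt = out.dendropy_tree
    rng = random.Random(params.seed * 1_000_003 + 12345)
    internal_sides: set[frozenset[str]] = set()
    for node, below in _leafsets_below(dt):
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(below)
        internal_sides.add(side)
        lo, hi = (params.support_low_range if side in low_edges
                  else params.support_high_range)
        node.support = rng.randint(lo, hi)
    unknown = set(low_edges) - internal_sides
    if unknown:
        raise ValueError(
            f"low_edges contains {len(unknown)} set(s) that are not internal "
            f"edges of the tree"
        )
    return out


# ---------------------------------------------------------------------------
# Planting an HGT clade
# ---------------------------------------------------------------------------

def bacterial_internal_edges(tree: PhyloTree, taxa: list[TaxonRecord],
                             min_size: int = 2,
                             max_size: int | None = None) -> list[frozenset[str]]:
    """Internal edges whose below-side is all-bacterial with min_size to
    max_size leaves — the valid grafting targets — in deterministic order.

    ``max_size`` defaults to half the bacterial leaves: grafting into an
    edge that subtends nearly the whole backbone would not model a clade
    nested within bacteria (the sister would be the rest of the tree, not a
    local bacterial clade)."""
    bact = {t.taxon_id for t in taxa if t.domain_of_life != "eukaryote"}
    if max_size is None:
        max_size = max(min_size, len(bact) // 2)
    sides = []
    for node, below in _leafsets_below(tree.dendropy_tree):
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(below)
        if min_size <= len(side) <= max_size and side <= bact:
            sides.append(side)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


def plant_hgt_clade(
    tree: PhyloTree,
    taxa: list[TaxonRecord],
    n_species: int,
    supergroup: str,
    n_studies: int,
    target_bacterial_edge: frozenset[str],
    seed: int,
    stem_support: int | None = None,
    support_high_range: tuple[int, int] = (85, 100),
) -> tuple[PhyloTree, list[TaxonRecord], PlantedTruth]:
    """Graft a new eukaryotic clade of ``n_species`` leaves onto a bacterial
    edge.

    All grafted species carry ``supergroup`` and are spread over
    ``n_studies`` studies; the clade's branch lengths are scaled to the mean
    edge length of the local bacterial subtree so the graft is not trivially
    long. Stem support comes from ``support_high_range`` unless
    ``stem_support`` overrides it. Returns the new tree, the taxon records
    of the grafted species, and the construction's ground truth.
    """
    if n_species < 1 or n_studies < 1:
        raise ValueError("n_species and n_studies must be >= 1")
    by_id = {t.taxon_id: t for t in taxa}
    euks_in_target = {
        l for l in target_bacterial_edge
        if l in by_id and by_id[l].is_eukaryote
    }
    if euks_in_target:
        raise ValueError(
            f"target edge lies inside the eukaryotic clade "
            f"(contains {sorted(euks_in_target)[:3]})"
        )
    rng = random.Random(seed)
    out = tree.copy()
    dt = out.dendropy_tree

    target_node = None
    for node, below in _leafsets_below(dt):
        if frozenset(below) == target_bacterial_edge and node.parent_node is not None:
            target_node = node
            break
    if target_node is None:
        raise ValueError("target_bacterial_edge is not an edge of the tree")

    local_lengths = [
        n.edge.length for n in target_node.preorder_iter()
        if n.edge.length is not None
    ]
    scale = float(np.mean(local_lengths)) if local_lengths else 1.0
    if scale <= 0:
        scale = 1.0

    existing = set(out.leaf_labels)
    new_labels = []
    i = 1
    while len(new_labels) < n_species:
        label = f"H{i:04d}"
        if label not in existing:
            new_labels.append(label)
        i += 1

    # split the target edge in half and hang the clade from the midpoint
    parent = target_node.parent_node
    full = target_node.edge.length
    mid = parent.new_child(edge_length=full / 2.0)
    parent.remove_child(target_node)
    mid.add_child(target_node)
    target_node.edge.length = full / 2.0

    stem = stem_support if stem_support is not None else rng.randint(*support_high_range)
    if n_species == 1:
        # a pendant stem carries no support of its own; the adjacent
        # eukaryote+bacteria edge (mid) holds it instead, which is also where
        # clade extraction reads the stem support of singleton clades
        mid.support = stem
        taxon = dt.taxon_namespace.new_taxon(new_labels[0])
        mid.new_child(taxon=taxon, edge_length=scale)
    else:
        mid.support = rng.randint(*support_high_range)
        clade_root = mid.new_child(edge_length=scale)
        clade_root.support = stem
        # caterpillar topology with locally-scaled branch lengths
        cursor = clade_root
        remaining = list(new_labels)
        while remaining:
            label = remaining.pop(0)
            taxon = dt.taxon_namespace.new_taxon(label)
            cursor.new_child(taxon=taxon,
                             edge_length=scale * rng.uniform(0.5, 1.5))
            if len(remaining) > 1:
                nxt = cursor.new_child(edge_length=scale * rng.uniform(0.3, 0.8))
                nxt.support = rng.randint(*support_high_range)
                cursor = nxt

    new_taxa = [
        TaxonRecord(
            label, f"Transferred eukaryote {label}", "eukaryote", supergroup,
            f"hgt_study_{j % n_studies + 1}",
            "genome" if j % 2 == 0 else "transcriptome",
        )
        for j, label in enumerate(new_labels)
    ]
    # n_species caps the number of studies actually represented
    truth = PlantedTruth(
        clade_species=frozenset(new_labels),
        donor_label=f"bacterial_edge[{min(target_bacterial_edge)}+{len(target_bacterial_edge)}]",
        satisfies={
            "c1_support_adjacency": stem > 70,
            "c2_species_supergroup": n_species >= 2,
            "c3_studies": min(n_studies, n_species) >= 2,
            "c4_robustness": True,
        },
    )
    return PhyloTree(dt), new_taxa, truth


# ---------------------------------------------------------------------------
# Replicate trees (alignment x method stand-ins)
# ---------------------------------------------------------------------------

def jitter_tree(tree: PhyloTree, seed: int, length_jitter: float = 0.2) -> PhyloTree:
    """A replicate with every branch length multiplied by a uniform factor
    in [1 - length_jitter, 1 + length_jitter]; topology and supports kept."""
    rng = random.Random(seed)
    out = tree.copy()
    for node in out.dendropy_tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.edge.length * rng.uniform(
                1 - length_jitter, 1 + length_jitter
            )
    return out


def scatter_clade(tree: PhyloTree, clade_leaves: frozenset[str],
                  taxa: list[TaxonRecord], seed: int) -> PhyloTree:
    """A replicate in which the given clade does NOT recur: its leaves are
    detached and re-grafted, each next to a different bacterial leaf, so no
    two of them remain sisters."""
    rng = random.Random(seed)
    out = tree.copy()
    dt = out.dendropy_tree
    bact = sorted(
        {t.taxon_id for t in taxa if t.domain_of_life != "eukaryote"}
        & tree.leaf_set
    )
    if len(bact) < len(clade_leaves):
        raise ValueError("not enough bacterial leaves to scatter onto")
    hosts = rng.sample(bact, len(clade_leaves))
    dt.prune_taxa_with_labels(sorted(clade_leaves))
    dt.suppress_unifurcations()
    for leaf_label, host in zip(sorted(clade_leaves), hosts):
        host_node = next(
            l for l in dt.leaf_node_iter() if node_label(l) == host
        )
        parent = host_node.parent_node
        full = host_node.edge.length or 1.0
        mid = parent.new_child(edge_length=full / 2.0)
        mid.support = 95
        parent.remove_child(host_node)
        mid.add_child(host_node)
        host_node.edge.length = full / 2.0
        taxon = dt.taxon_namespace.new_taxon(leaf_label)
        mid.new_child(taxon=taxon, edge_length=full / 2.0)
    return PhyloTree(dt)


@dataclass(frozen=True)
class HGTScenario:
    """A full planted-transfer benchmark instance: replicate trees, the
    combined taxon table, and the planted ground truth."""

    trees: tuple[PhyloTree, ...]
    taxa: tuple[TaxonRecord, ...]
    truth: PlantedTruth


def build_hgt_scenario(
    seed: int,
    n_bacteria: int = 24,
    n_eukaryotes: int = 10,
    n_species: int = 3,
    n_studies: int = 2,
    supergroup: str = "Amoebozoa",
    n_replicates: int = 4,
    ablation: str | None = None,
) -> HGTScenario:
    """Backbone + one planted clade + jittered replicate trees.

    ``ablation`` turns exactly one construction flag off:
    ``"species"`` (1 species), ``"studies"`` (1 study), ``"support"`` (low
    stem support), ``"replicate"`` (the clade scattered in the last tree).
    """
    if ablation not in (None, "species", "studies", "support", "replicate"):
        raise ValueError(f"unknown ablation {ablation!r}")
    params = SimulationParams(n_bacteria=n_bacteria, n_eukaryotes=n_eukaryotes,
                              seed=seed)
    backbone, taxa = simulate_backbone_tree(params)
    if ablation == "species":
        n_species = 1
    if ablation == "studies":
        n_studies = 1
    stem_support = 55 if ablation == "support" else 99
    targets = bacterial_internal_edges(backbone, taxa, min_size=2)
    target = targets[random.Random(seed + 7).randrange(len(targets))]
    planted, new_taxa, truth = plant_hgt_clade(
        backbone, taxa, n_species, supergroup, n_studies, target,
        seed=seed + 11, stem_support=stem_support,
    )
    all_taxa = list(taxa) + new_taxa
    trees = [planted]
    for r in range(1, n_replicates):
        if ablation == "replicate" and r == n_replicates - 1:
            trees.append(scatter_clade(planted, truth.clade_species,
                                       all_taxa, seed=seed + 100 + r))
        else:
            trees.append(jitter_tree(planted, seed=seed + 100 + r))
    satisfies = dict(truth.satisfies)
    # robustness (criterion 4) is defined over clades that themselves pass
    # criteria 1-3 in the replicate trees, so any ablation voids it
    satisfies["c4_robustness"] = (
        ablation is None
        and all(satisfies[c] for c in CRITERIA[:3])
    )
    truth = PlantedTruth(truth.clade_species, truth.donor_label, satisfies)
    return HGTScenario(tuple(trees), tuple(all_taxa), truth)


# ---------------------------------------------------------------------------
# Profile-derived sequences and domain tables
# ---------------------------------------------------------------------------

def synthetic_family(
    seed: int,
    n_seed_rows: int = 8,
    length: int = 25,
    n_substitutions: int = 4,
    n_members: int = 50,
    n_decoys: int = 50,
    generation_alpha: float = 0.05,
):
    """A complete synthetic search problem: seed alignment, database, taxa
    and ground-truth labels.

    The seed alignment is ``n_seed_rows`` variants of one random ancestral
    sequence, each with ``n_substitutions`` random substitutions — a tight
    family, as a profile seed would be. Members of the database are sampled
    from a sharp profile of that alignment (``generation_alpha``; real
    homologs track the family consensus far more closely than a
    heavily-smoothed emission model would suggest), decoys from the
    background. Returns (alignment, database, taxa, labels).
    """
    from .core import Alignment
    from .search import build_profile

    rng = random.Random(seed)
    ancestor = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
    rows = []
    for i in range(n_seed_rows):
        variant = list(ancestor)
        for _ in range(n_substitutions):
            pos = rng.randrange(length)
            variant[pos] = rng.choice(AMINO_ACIDS)
        rows.append((f"seed{i:03d}", "".join(variant)))
    aln = Alignment(rows)
    sharp = build_profile(aln, pseudocount_alpha=generation_alpha)
    database, labels = generate_profile_sequences(
        sharp, n_members, n_decoys, seed=seed + 1
    )
    taxa = [
        TaxonRecord(s.taxon_id, s.taxon_id, "eukaryote",
                    SUPERGROUPS_12[i % len(SUPERGROUPS_12)], "study_A",
                    "genome")
        for i, s in enumerate(database)
    ]
    return aln, database, taxa, labels

def generate_profile_sequences(
    profile: ProfileModel,
    n_members: int,
    n_decoys: int,
    seed: int,
    flank_range: tuple[int, int] = (5, 20),
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Members sampled column-wise from the profile's emissions, embedded in
    random background flanks; decoys drawn entirely from the background.
    Returns the records and a seq_id -> {"member", "decoy"} label map."""
    rng = np.random.default_rng(seed)
    L = len(profile)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}

    def flank(n: int) -> str:
        return "".join(rng.choice(alphabet, size=n, p=profile.background))

    for i in range(n_members):
        core = "".join(
            alphabet[rng.choice(20, p=profile.emissions[j])] for j in range(L)
        )
        left, right = rng.integers(*flank_range), rng.integers(*flank_range)
        sid = f"member_{i:04d}"
        records.append(SequenceRecord(sid, f"taxon_m{i:04d}",
                                      flank(left) + core + flank(right)))
        labels[sid] = "member"
    for i in range(n_decoys):
        left, right = rng.integers(*flank_range), rng.integers(*flank_range)
        sid = f"decoy_{i:04d}"
        records.append(SequenceRecord(sid, f"taxon_d{i:04d}",
                                      flank(int(left) + L + int(right))))
        labels[sid] = "decoy"
    return records, labels


def generate_domain_table(
    seqs: list[SequenceRecord],
    family_map: dict[str, list[str]],
    seed: int,
) -> list[DomainHit]:
    """One DomainHit per mapped domain, E-values well below the 1e-3
    threshold and ordered so the first listed accession is the top hit; one
    above-threshold noise row per sequence."""
    unknown = set(family_map) - {s.seq_id for s in seqs}
    if unknown:
        raise ValueError(f"family_map keys not among sequences: {sorted(unknown)}")
    rng = random.Random(seed)
    hits: list[DomainHit] = []
    for seq in seqs:
        length = len(seq.residues)
        for j, acc in enumerate(family_map.get(seq.seq_id, [])):
            e = 10 ** (-9 + 1.2 * j + 0.5 * rng.random())
            start = rng.randint(0, max(0, length - 2))
            end = min(length, start + max(2, length // 2))
            hits.append(DomainHit(seq.seq_id, acc, e,
                                  score=120.0 - 10 * j + rng.random(),
                                  env_from=start, env_to=end))
        noise_e = 10 ** rng.uniform(-2.5, -1)  # always above 1e-3
        hits.append(DomainHit(seq.seq_id, NOISE_DOMAIN_ACC, noise_e,
                              score=5.0 + rng.random(),
                              env_from=0, env_to=max(1, length // 3)))
    return hits
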