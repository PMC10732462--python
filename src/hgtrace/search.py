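"""Iterative profile homology search.

The search engine is an ungapped position-specific scoring matrix (PSSM):
per-column emission probabilities with Laplace pseudocounts, scored as the
best ungapped-window sum of log2 odds against a background distribution.
It is an order-preserving stand-in for a full profile HMM: the pipeline's
contracts (E-value thresholding, per-species caps, balanced seeds, the
iterate-until-saturation loop, in-group filtering) are what is under test,
not forward/Viterbi statistics. E-values are empirical, calibrated against
a decoy set: e(s) = D * (1 - F̂(s)) with an add-one rule, monotone
non-increasing in the score and strictly positive.
"""
from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import (
    AA_INDEX,
    AMINO_ACIDS,
    GAP,
    Alignment,
    CriteriaConfig,
    DomainHit,
    PhyloTree,
    SequenceRecord,
    TaxonRecord,
)

UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


# ---------------------------------------------------------------------------
# Alignment trimming and profile construction
# ---------------------------------------------------------------------------

def trim_gappy_columns(aln: Alignment, keep_fraction: float) -> Alignment:
    """Keep exactly the columns whose non-gap fraction is >= keep_fraction.

    The same rule as gap-threshold alignment trimming (a column survives at
    threshold 0.2 when at least 20% of its rows are residues); row order is
    preserved.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError(f"keep_fraction must lie in (0, 1], got {keep_fraction}")
    n_rows = len(aln.rows)
    keep = [
        j for j in range(aln.length)
        if sum(1 for _, row in aln.rows if row[j] != GAP) / n_rows >= keep_fraction
    ]
    if not keep:
        raise ValueError(
            "no columns survive trimming; lower keep_fraction "
            f"(all {aln.length} columns are below {keep_fraction:g} occupancy)"
        )
    return Alignment([(sid, "".join(row[j] for j in keep)) for sid, row in aln.rows])


@dataclass(frozen=True)
class ProfileModel:
    """Per-column emission probabilities with matching log2-odds.

    ``emissions`` has shape (length, 20) over the canonical amino-acid
    order; ``X`` residues are scored as log-odds 0 (uninformative).
    """

    emissions: np.ndarray
    background: np.ndarray
    pseudocount_alpha: float
    log_odds: np.ndarray
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 20:
            raise ValueError("emissions must have shape (length, 20)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each column's emissions must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        expected = np.log2(self.emissions / self.background)
        if not np.allclose(self.log_odds, expected, atol=1e-9):
            raise ValueError("log_odds inconsistent with emissions/background")

    def __len__(self) -> int:
        return self.emissions.shape[0]


def build_profile(
    aln: Alignment,
    pseudocount_alpha: float = 1.0,
    background: np.ndarray | None = None,
    gap_keep_fraction: float = 0.2,
) -> ProfileModel:
    """Build a PSSM from an alignment.

    Majority-gap columns are first removed by :func:`trim_gappy_columns` at
    ``gap_keep_fraction``; each surviving column's emissions follow the
    Laplace rule (count + alpha) / (non-gap count + 20 * alpha). ``X``
    residues are ignored in the counts.
    """
    if pseudocount_alpha <= 0:
        raise ValueError("pseudocount_alpha must be positive")
    background = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    aln = trim_gappy_columns(aln, gap_keep_fraction)
    L = aln.length
    emissions = np.empty((L, 20))
    for j in range(L):
        counts = np.zeros(20)
        n = 0
        for _, row in aln.rows:
            ch = row[j]
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
                n += 1
        emissions[j] = (counts + pseudocount_alpha) / (n + 20 * pseudocount_alpha)
    log_odds = np.log2(emissions / background)
    return ProfileModel(emissions, background, pseudocount_alpha, log_odds)


# ---------------------------------------------------------------------------
# Scoring and E-value calibration
# ---------------------------------------------------------------------------

def _encode(residues: str) -> np.ndarray:
    return np.fromiter((AA_INDEX.get(ch, -1) for ch in residues), dtype=np.int64,
                       count=len(residues))


def score_sequence(profile: ProfileModel, seq: SequenceRecord | str) -> float:
    """Best ungapped-window log-odds sum of the profile along the sequence."""
    residues = seq if isinstance(seq, str) else seq.residues
    L = len(profile)
    if len(residues) < L:
        raise ValueError(
            f"sequence length {len(residues)} shorter than profile length {L}"
        )
    codes = _encode(residues)
    n_windows = len(residues) - L + 1
    cols = np.arange(L)
    best = -np.inf
    # per-window gather; X (code -1) scores 0
    lo = profile.log_odds
    for start in range(n_windows):
        window = codes[start:start + L]
        valid = window >= 0
        s = lo[cols[valid], window[valid]].sum()
        if s > best:
            best = s
    return float(best)


def consensus_sequence(profile: ProfileModel) -> str:
    """The per-column argmax-emission string (achieves the maximal score
    for its length)."""
    return "".join(AMINO_ACIDS[i] for i in profile.emissions.argmax(axis=1))


@dataclass(frozen=True)
class EValueCalibration:
    """Empirical E-values from a decoy score distribution.

    Within the decoy score range, e(s) = db_size * (#decoys >= s + 1) /
    (n_decoys + 1) — the add-one empirical rule. Above the largest decoy
    score the add-one floor db_size/(n+1) is far too coarse to reach small
    cutoffs at desk scale, so the tail is extended exponentially,
    e(s) = floor * exp(-lambda * (s - s_max)), with lambda fitted to the
    decoys' upper-decile excesses. The mapping is monotone non-increasing,
    strictly positive, at most db_size/(n+1) above all decoys and ~db_size
    below them all.
    """

    decoy_scores: np.ndarray  # sorted ascending
    db_size: int
    tail_lambda: float

    def e_value(self, score: float) -> float:
        n = len(self.decoy_scores)
        s_max = float(self.decoy_scores[-1])
        if score > s_max:
            floor = self.db_size / (n + 1)
            return floor * math.exp(-self.tail_lambda * (score - s_max))
        n_ge = n - int(np.searchsorted(self.decoy_scores, score, side="left"))
        return self.db_size * (n_ge + 1) / (n + 1)

    def __call__(self, score: float) -> float:
        return self.e_value(score)


def _fit_tail_lambda(scores: np.ndarray) -> float:
    """Exponential rate of the decoy upper tail (peaks over the 90th
    percentile); falls back to 1 when the tail is degenerate."""
    u = float(np.quantile(scores, 0.9))
    excess = scores[scores > u] - u
    if len(excess) == 0 or float(excess.mean()) <= 0:
        return 1.0
    return 1.0 / float(excess.mean())


def calibrate_evalue(
    profile: ProfileModel,
    decoys: Sequence[SequenceRecord],
    db_size: int,
) -> EValueCalibration:
    """Score ``decoys`` (>= 100 required) under the profile and return the
    empirical score -> E-value mapping for a database of ``db_size``."""
    if len(decoys) < 100:
        raise ValueError(f"need at least 100 decoys, got {len(decoys)}")
    if db_size <= 0:
        raise ValueError("db_size must be positive")
    scores = np.sort([
        score_sequence(profile, d) for d in decoys if len(d.residues) >= len(profile)
    ])
    if len(scores) < 100:
        raise ValueError("fewer than 100 decoys reach the profile length")
    return EValueCalibration(scores, db_size, _fit_tail_lambda(scores))


# ---------------------------------------------------------------------------
# Database search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchHit:
    seq_id: str
    taxon_id: str
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValueError(f"hit {self.seq_id!r}: e_value must be positive")


@dataclass
class SearchRoundResult:
    """One round of the iterative search: the passing hits, which of them
    are new, and whether an out-of-family sequence was recovered."""

    round_index: int
    hits: list[SearchHit]
    new_seq_ids: frozenset[str]
    contamination_flag: bool = False
    stop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")
        hit_ids = {h.seq_id for h in self.hits}
        if not set(self.new_seq_ids) <= hit_ids:
            raise ValueError("new_seq_ids must be a subset of the hit ids")


def search_database(
    profile: ProfileModel,
    seqs: Sequence[SequenceRecord],
    taxa: Sequence[TaxonRecord],
    config: CriteriaConfig,
    calibration: EValueCalibration,
) -> list[SearchHit]:
    """Score every database sequence, keep hits below the E-value cutoff and
    cap each species' contribution at ``hit_cap_per_species`` (best E-values
    first, ties to the lexicographically smaller seq_id). Sequences shorter
    than the profile cannot be scored and yield no hit.
    """
    known_taxa = {t.taxon_id for t in taxa}
    passing: list[SearchHit] = []
    for seq in seqs:
        if seq.taxon_id not in known_taxa:
            raise ValueError(f"sequence {seq.seq_id!r}: unknown taxon {seq.taxon_id!r}")
        if len(seq.residues) < len(profile):
            continue
        s = score_sequence(profile, seq)
        e = calibration.e_value(s)
        if e < config.domain_evalue_max:
            passing.append(SearchHit(seq.seq_id, seq.taxon_id, s, e))
    by_taxon: dict[str, list[SearchHit]] = {}
    for hit in passing:
        by_taxon.setdefault(hit.taxon_id, []).append(hit)
    out: list[SearchHit] = []
    for taxon in sorted(by_taxon):
        ranked = sorted(by_taxon[taxon], key=lambda h: (h.e_value, h.seq_id))
        out.extend(ranked[: config.hit_cap_per_species])
    return sorted(out, key=lambda h: (h.e_value, h.seq_id))


def combine_balanced_seed(
    bacterial: tuple[Sequence[SequenceRecord], PhyloTree],
    eukaryotic: tuple[Sequence[SequenceRecord], PhyloTree],
    config: CriteriaConfig,
) -> list[SequenceRecord]:
    """Diversity-balanced seed: each side independently downsampled to
    ``seed_k_each`` leaves by greedy PD maximisation, then concatenated
    (bacterial first). A side already at or below the target is kept whole.
    """
    from .diversity import select_max_pd_subset

    out: list[SequenceRecord] = []
    for seqs, tree in (bacterial, eukaryotic):
        ids = {s.seq_id for s in seqs}
        if ids != tree.leaf_set:
            extra = sorted(ids ^ tree.leaf_set)
            raise ValueError(f"tree/sequence id mismatch: {extra[:5]}")
        if len(seqs) <= config.seed_k_each:
            out.extend(seqs)
        else:
            chosen = select_max_pd_subset(tree, config.seed_k_each).leaf_ids
            out.extend(s for s in seqs if s.seq_id in chosen)
    return out


# ---------------------------------------------------------------------------
# The iterate-until-saturation loop
# ---------------------------------------------------------------------------

def align_to_profile(profile: ProfileModel, seq: SequenceRecord) -> str:
    """The best-scoring ungapped window, as an aligned row of the profile's
    length (the stand-in for hmmalign --trim)."""
    residues = seq.residues
    L = len(profile)
    if len(residues) < L:
        raise ValueError("sequence shorter than profile")
    codes = _encode(residues)
    cols = np.arange(L)
    best_start, best = 0, -np.inf
    for start in range(len(residues) - L + 1):
        window = codes[start:start + L]
        valid = window >= 0
        s = profile.log_odds[cols[valid], window[valid]].sum()
        if s > best:
            best, best_start = s, start
    return residues[best_start:best_start + L]


def make_decoys(
    database: Sequence[SequenceRecord], seed: int, minimum: int = 100,
) -> list[SequenceRecord]:
    """Residue-shuffled copies of database sequences (composition-preserving
    null model), replicated until at least ``minimum`` decoys exist."""
    rng = random.Random(seed)
    decoys: list[SequenceRecord] = []
    rounds = -(-minimum // max(len(database), 1))
    for r in range(max(rounds, 1)):
        for seq in database:
            shuffled = list(seq.residues)
            rng.shuffle(shuffled)
            decoys.append(
                SequenceRecord(f"decoy_{r}_{seq.seq_id}", seq.taxon_id,
                               "".join(shuffled))
            )
    return decoys


SearchBackend = Callable[[int, Alignment], list[SearchHit]]


def iterate_search(
    seed_aln: Alignment,
    database: Sequence[SequenceRecord],
    taxa: Sequence[TaxonRecord],
    outgroup_ids: set[str],
    config: CriteriaConfig,
    max_rounds: int,
    backend: SearchBackend | None = None,
    decoy_seed: int = 0,
) -> list[SearchRoundResult]:
    """Iterate profile build -> search -> extend alignment until saturation.

    Each round rebuilds the profile from the current hit alignment, searches
    the database, and folds the new hits (their best windows) into the
    alignment. Termination, recorded as ``stop_reason`` on the final round:

    * ``"saturated"`` — no sequence outside the cumulative hit set appears;
    * ``"contamination"`` — a hit belongs to ``outgroup_ids`` (the search
      has drifted into a neighbouring gene family);
    * ``"max_rounds"`` — the round budget is exhausted first.

    A scripted ``backend`` (round_index, alignment) -> hits replaces the
    built-in PSSM search when supplied, for contract testing.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    current = trim_gappy_columns(seed_aln, config.gap_keep_fraction)
    seed_ids = set(current.ids)
    cumulative: set[str] = set()
    decoys = None if backend is not None else make_decoys(database, decoy_seed)
    by_id = {s.seq_id: s for s in database}

    results: list[SearchRoundResult] = []
    for round_index in range(1, max_rounds + 1):
        if backend is not None:
            hits = backend(round_index, current)
        else:
            profile = build_profile(
                current, gap_keep_fraction=config.gap_keep_fraction
            )
            calibration = calibrate_evalue(profile, decoys, db_size=len(database))
            hits = search_database(profile, database, taxa, config, calibration)
        hit_ids = {h.seq_id for h in hits}
        new_ids = frozenset(hit_ids - seed_ids - cumulative)
        contaminated = bool(hit_ids & set(outgroup_ids))
        result = SearchRoundResult(round_index, list(hits), new_ids,
                                   contamination_flag=contaminated)
        results.append(result)
        if contaminated:
            result.stop_reason = "contamination"
            break
        if not new_ids:
            result.stop_reason = "saturated"
            break
        cumulative |= new_ids
        if backend is None:
            rows = list(current.rows)
            for sid in sorted(new_ids):
                seq = by_id.get(sid)
                if seq is not None and len(seq.residues) >= current.length:
                    rows.append((sid, align_to_profile(profile, seq)))
            current = Alignment(rows)
    else:
        results[-1].stop_reason = "max_rounds"
    return results


# ---------------------------------------------------------------------------
# Phase-4 in-group filtering
# ---------------------------------------------------------------------------

def filter_ingroup(
    hits: Sequence[SearchHit],
    tree: PhyloTree,
    domains: Sequence[DomainHit],
    family_domains: set[str],
    outgroup_ids: set[str],
    reference_ids: set[str] | None = None,
) -> tuple[list[SearchHit], list[tuple[str, str]]]:
    """Drop hits lacking every family domain or clustering with the outgroup.

    A hit is removed when (a) none of its predicted domains is in
    ``family_domains`` (rule ``no_family_domain``) or (b) after rooting the
    tree at the outgroup's median leaf, the hit falls outside the smallest
    clade containing all reference in-group leaves (rule
    ``outside_ingroup_clade``). ``reference_ids`` defaults to the tree
    leaves that are neither outgroup members nor hits (the seed members).
    Returns the retained hits and a (seq_id, rule) removal log.
    """
    leaf_set = tree.leaf_set
    missing = set(outgroup_ids) - leaf_set
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if not outgroup_ids:
        raise ValueError("outgroup_ids must be non-empty")
    hit_ids = {h.seq_id for h in hits}
    missing_hits = hit_ids - leaf_set
    if missing_hits:
        raise ValueError(f"hit ids not in tree: {sorted(missing_hits)}")
    if reference_ids is None:
        reference_ids = leaf_set - set(outgroup_ids) - hit_ids
    domains_by_seq: dict[str, set[str]] = {}
    for d in domains:
        domains_by_seq.setdefault(d.seq_id, set()).add(d.domain_acc)

    removal_log: list[tuple[str, str]] = []
    survivors: list[SearchHit] = []
    ingroup_clade = _ingroup_clade(tree, outgroup_ids, reference_ids)
    for hit in hits:
        if not (domains_by_seq.get(hit.seq_id, set()) & family_domains):
            removal_log.append((hit.seq_id, "no_family_domain"))
            continue
        if ingroup_clade is not None and hit.seq_id not in ingroup_clade:
            removal_log.append((hit.seq_id, "outside_ingroup_clade"))
            continue
        survivors.append(hit)
    return survivors, removal_log


def _ingroup_clade(
    tree: PhyloTree, outgroup_ids: set[str], reference_ids: set[str],
) -> frozenset[str] | None:
    """Leaves of the smallest clade spanning ``reference_ids`` once the tree
    is rooted at the outgroup's median leaf; None when no reference leaves
    exist (the tree rule is then vacuous)."""
    if not reference_ids:
        return None
    work = tree.copy()
    dt = work.dendropy_tree
    median_leaf = sorted(outgroup_ids)[len(outgroup_ids) // 2]
    node = next(
        l for l in dt.leaf_node_iter()
        if (l.taxon.label if l.taxon else l.label) == median_leaf
    )
    dt.reroot_at_edge(node.edge, update_bipartitions=False)
    mrca = dt.mrca(taxa=[
        l.taxon for l in dt.leaf_node_iter()
        if (l.taxon.label if l.taxon else l.label) in reference_ids
    ])
    return frozenset(
        (l.taxon.label if l.taxon else l.label) for l in mrca.leaf_iter()
    )
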