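"""Shared domain types and file I/O for the HGT-tracing pipeline.

Conventions used throughout the package:

* Sequences are amino acids over the 20-letter alphabet plus ``X``;
  ambiguity codes (B, Z, U, O) are mapped to ``X`` on input, with a warning.
* Coordinates are 0-based half-open internally; 1-based closed only at the
  display boundary (:func:`to_display_coords` / :func:`from_display_coords`).
* Newick internal-node labels, when numeric, are read as integer support
  values in [0, 100] attached to the edge above that node (the convention of
  ultrafast-bootstrap tree files).
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("hgtrace")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
AMBIGUOUS_RESIDUES = {"B": "X", "Z": "X", "U": "X", "O": "X"}
GAP = "-"
DOMAINS_OF_LIFE = ("bacteria", "archaea", "eukaryote")

TAXON_TABLE_COLUMNS = (
    "taxon_id", "name", "domain_of_life", "supergroup", "study_id", "data_type",
)
DOMAIN_TABLE_COLUMNS = (
    "seq_id", "domain_acc", "e_value", "score", "env_from", "env_to",
)


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonRecord:
    """One organism: identity, domain of life, supergroup and data provenance.

    ``supergroup`` is non-empty exactly for eukaryotes; ``study_id`` records
    the data-source study, and ``data_type`` is ``genome`` or
    ``transcriptome``.
    """

    taxon_id: str
    name: str
    domain_of_life: str
    supergroup: str = ""
    study_id: str = ""
    data_type: str = "genome"

    def __post_init__(self) -> None:
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise ValueError(
                f"taxon {self.taxon_id!r}: unknown domain_of_life "
                f"{self.domain_of_life!r} (expected one of {DOMAINS_OF_LIFE})"
            )
        if self.domain_of_life == "eukaryote" and not self.supergroup:
            raise ValueError(
                f"taxon {self.taxon_id!r}: eukaryote must have a supergroup"
            )
        if self.domain_of_life != "eukaryote" and self.supergroup:
            raise ValueError(
                f"taxon {self.taxon_id!r}: supergroup must be empty for "
                f"{self.domain_of_life}"
            )
        if self.data_type not in ("genome", "transcriptome"):
            raise ValueError(
                f"taxon {self.taxon_id!r}: data_type must be 'genome' or "
                f"'transcriptome', got {self.data_type!r}"
            )

    @property
    def is_eukaryote(self) -> bool:
        return self.domain_of_life == "eukaryote"


@dataclass(frozen=True)
class SequenceRecord:
    """A gap-free amino-acid sequence tied to a taxon."""

    seq_id: str
    taxon_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.seq_id!r}: empty residues")
        bad = set(self.residues) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(
                f"sequence {self.seq_id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered multiple alignment: equal-length rows of residues and '-'."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must have at least one row")
        lengths = {len(r) for _, r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate alignment row ids: {dupes}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def column(self, j: int) -> str:
        return "".join(row[j] for _, row in self.rows)


@dataclass(frozen=True)
class DomainHit:
    """One predicted protein domain on a sequence (hmmscan-style row).

    ``env_from``/``env_to`` are 0-based half-open coordinates.
    """

    seq_id: str
    domain_acc: str
    e_value: float
    score: float
    env_from: int
    env_to: int

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValueError(
                f"domain hit {self.seq_id}/{self.domain_acc}: e_value must be "
                f"positive, got {self.e_value}"
            )
        if not (0 <= self.env_from < self.env_to):
            raise ValueError(
                f"domain hit {self.seq_id}/{self.domain_acc}: need "
                f"0 <= env_from < env_to, got [{self.env_from}, {self.env_to})"
            )


@dataclass
class CriteriaConfig:
    """Numeric thresholds of the pipeline, in one serialisable bundle.

    Defaults encode the study conditions: hits accepted below E-value 1e-3
    with at most 10 per species, 50+50 diversity-balanced seeds, a final
    bacterial downsample to 500, alignment columns kept when >= 20% of rows
    are residues, supports strictly below 70 collapsed, HGT calls demanding
    stem support strictly above 70, >= 2 species from one supergroup,
    >= 2 source studies, and recurrence in every replicate tree.
    """

    support_min: int = 70
    min_species_same_supergroup: int = 2
    min_studies: int = 2
    require_all_trees: bool = True
    clade_match_mode: str = "exact_species_set"
    jaccard_min: float = 0.8
    domain_evalue_max: float = 1e-3
    hit_cap_per_species: int = 10
    seed_k_each: int = 50
    final_k_bacteria: int = 500
    gap_keep_fraction: float = 0.2
    collapse_support_lt: int = 70

    def __post_init__(self) -> None:
        for name in ("support_min", "min_species_same_supergroup", "min_studies",
                     "hit_cap_per_species", "seed_k_each", "final_k_bacteria",
                     "collapse_support_lt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.gap_keep_fraction <= 1:
            raise ValueError("gap_keep_fraction must lie in (0, 1]")
        if not 0 < self.domain_evalue_max:
            raise ValueError("domain_evalue_max must be strictly positive")
        if not 0 < self.jaccard_min <= 1:
            raise ValueError("jaccard_min must lie in (0, 1]")
        if self.clade_match_mode not in ("exact_species_set", "jaccard"):
            raise ValueError(
                f"unknown clade_match_mode {self.clade_match_mode!r}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CriteriaConfig":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "CriteriaConfig":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------

class PhyloTree:
    """A leaf-labelled tree with branch lengths and integer edge supports.

    Thin wrapper over a :class:`dendropy.Tree`. Branch lengths default to 0
    when absent; each non-leaf, non-root node may carry ``support`` (an int
    in [0, 100]) interpreted as the support of the edge above it.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._normalize()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_string(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy parse errors carry position info
            raise NewickParseError(f"invalid Newick: {exc}") from exc
        return cls(dtree)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls.from_string(Path(path).read_text())

    def _normalize(self) -> None:
        seen: set[str] = set()
        for node in self._tree.preorder_node_iter():
            if node.edge.length is None:
                node.edge.length = 0.0
            if node.edge.length < 0:
                raise ValueError(
                    f"negative branch length {node.edge.length} on edge above "
                    f"{node_label(node)!r}"
                )
            if node.is_leaf():
                label = node_label(node)
                if label is None:
                    raise ValueError("leaf without a label")
                if label in seen:
                    raise ValueError(f"duplicate leaf label {label!r}")
                seen.add(label)
                continue
            if not hasattr(node, "support"):
                node.support = _parse_support(node.label)
                if node.support is not None:
                    node.label = None

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        tree = self._tree
        for node in tree.preorder_internal_node_iter():
            sup = getattr(node, "support", None)
            if sup is not None:
                node.label = str(int(sup))
        out = tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier="",
        ).strip()
        for node in tree.preorder_internal_node_iter():
            if getattr(node, "support", None) is not None:
                node.label = None
        return out + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_string(self.to_newick())

    # -- accessors ----------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> list[str]:
        return [node_label(l) for l in self._tree.leaf_node_iter()]

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self._tree.leaf_nodes())

    def total_branch_length(self) -> float:
        return sum(
            node.edge.length
            for node in self._tree.preorder_node_iter()
            if node.parent_node is not None
        )

    def supports(self) -> dict[frozenset[str], int]:
        """Map each supported internal edge (as the leaf set below it) to its
        support value."""
        out: dict[frozenset[str], int] = {}
        for node, below in _leafsets_below(self._tree):
            sup = getattr(node, "support", None)
            if sup is not None and not node.is_leaf():
                out[frozenset(below)] = sup
        return out

    def adjacency(self) -> tuple[dict[int, list[tuple[int, float]]], dict[str, int]]:
        """Undirected adjacency over integer node ids, plus leaf-label index.

        The root keeps its (possibly degree-2) place; path metrics are
        unaffected because its two incident edge lengths add.
        """
        index: dict[int, int] = {}
        adj: dict[int, list[tuple[int, float]]] = {}
        leaf_index: dict[str, int] = {}
        for i, node in enumerate(self._tree.preorder_node_iter()):
            index[id(node)] = i
            adj[i] = []
            if node.is_leaf():
                leaf_index[node_label(node)] = i
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            a, b = index[id(parent)], index[id(node)]
            w = float(node.edge.length)
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj, leaf_index

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"


def node_label(node: dendropy.Node) -> str | None:
    if node.taxon is not None:
        return node.taxon.label
    return node.label


def _parse_support(label: str | None) -> int | None:
    if label is None:
        return None
    try:
        value = float(label)
    except ValueError:
        return None
    if not 0 <= value <= 100:
        return None
    return int(round(value))


def _leafsets_below(dtree: dendropy.Tree):
    """Yield (node, leaf-label set below node) in postorder."""
    below: dict[int, set[str]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {node_label(node)}
        else:
            s: set[str] = set()
            for child in node.child_nodes():
                s |= below[id(child)]
            below[id(node)] = s
        yield node, below[id(node)]


def parse_newick(path: str | Path) -> PhyloTree:
    """Read a single-tree Newick file (numeric internal labels = supports)."""
    return PhyloTree.from_file(path)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _clean_residues(seq_id: str, raw: str) -> str:
    residues = raw.upper()
    replaced = sorted(set(residues) & set(AMBIGUOUS_RESIDUES))
    if replaced:
        warnings.warn(
            f"sequence {seq_id!r}: ambiguous residues {replaced} mapped to X",
            stacklevel=3,
        )
        for orig in replaced:
            residues = residues.replace(orig, "X")
    return residues


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA. The header token before the first whitespace is
    the seq_id; a second token, when present, is the taxon_id (else the
    taxon_id defaults to the seq_id)."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        desc_tokens = rec.description.split()
        taxon_id = desc_tokens[1] if len(desc_tokens) > 1 else seq_id
        records.append(
            SequenceRecord(seq_id, taxon_id, _clean_residues(seq_id, str(rec.seq)))
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.seq_id, description=r.taxon_id)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA (rows may contain '-')."""
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        _clean_residues(rec.id, residues.replace(GAP, ""))  # warn on ambiguity
        rows.append((rec.id, _merge_gaps(residues)))
    if not rows:
        raise ValueError(f"no alignment rows in {path}")
    return Alignment(rows)


def _merge_gaps(residues: str) -> str:
    out = []
    for ch in residues:
        if ch == GAP:
            out.append(ch)
        else:
            out.append(AMBIGUOUS_RESIDUES.get(ch, ch))
    return "".join(out)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(row), id=sid, description="") for sid, row in aln.rows]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tabular metadata
# ---------------------------------------------------------------------------

def read_taxon_table(path: str | Path) -> list[TaxonRecord]:
    """Read the taxon metadata TSV (header row naming the six fields)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TAXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxon table missing column(s): {missing}")
    records: list[TaxonRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            rec = TaxonRecord(
                taxon_id=row.taxon_id, name=row.name,
                domain_of_life=row.domain_of_life, supergroup=row.supergroup,
                study_id=row.study_id, data_type=row.data_type,
            )
        except ValueError as exc:
            raise ValueError(f"taxon table row {i}: {exc}") from exc
        if rec.taxon_id in seen:
            raise ValueError(f"taxon table row {i}: duplicate taxon_id {rec.taxon_id!r}")
        seen.add(rec.taxon_id)
        records.append(rec)
    return records


def write_taxon_table(taxa: Sequence[TaxonRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(t) for t in taxa], columns=list(TAXON_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_domain_table(path: str | Path, evalue_max: float | None = 1e-3) -> list[DomainHit]:
    """Read a domain-scan TSV, dropping rows at or above ``evalue_max``.

    The number of excluded rows is logged. Pass ``evalue_max=None`` to keep
    every row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table missing column(s): {missing}")
    hits: list[DomainHit] = []
    excluded = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            hit = DomainHit(
                seq_id=row.seq_id, domain_acc=row.domain_acc,
                e_value=float(row.e_value), score=float(row.score),
                env_from=int(row.env_from), env_to=int(row.env_to),
            )
        except ValueError as exc:
            raise ValueError(f"domain table row {i}: {exc}") from exc
        if evalue_max is not None and hit.e_value >= evalue_max:
            excluded += 1
            continue
        hits.append(hit)
    if excluded:
        logger.info("domain table %s: excluded %d row(s) at E-value >= %g",
                    path, excluded, evalue_max)
    return hits


def write_domain_table(hits: Sequence[DomainHit], path: str | Path) -> None:
    pd.DataFrame([asdict(h) for h in hits], columns=list(DOMAIN_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

def to_display_coords(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based closed."""
    if not 0 <= start0 < end0:
        raise ValueError(f"need 0 <= start < end, got [{start0}, {end0})")
    return start0 + 1, end0


def from_display_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based closed -> 0-based half-open."""
    if not 1 <= start1 <= end1:
        raise ValueError(f"need 1 <= start <= end, got [{start1}, {end1}]")
    return start1 - 1, end1
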