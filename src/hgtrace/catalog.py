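"""Presence/absence catalog construction and its summaries: absence counts,
co-occurrence (Venn) tabulations, and collectors curves.

The catalog is a binary species x gene-family matrix (1 = at least one
homolog found, 0 = none), the encoding used by published supplementary
catalogs; hit counts live in the search logs, not here.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TaxonRecord
from .search import SearchHit, SearchRoundResult


@dataclass
class PresenceCatalog:
    """Binary presence flags, species (rows) by gene family (columns)."""

    species: list[str]
    families: list[str]
    matrix: np.ndarray  # int array of 0/1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (len(self.species), len(self.families)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.species)} species x {len(self.families)} families"
            )
        bad = set(np.unique(self.matrix)) - {0, 1}
        if bad:
            raise ValueError(f"matrix entries must be 0/1, found {sorted(bad)}")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids")
        if len(set(self.families)) != len(self.families):
            raise ValueError("duplicate family names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.species, columns=self.families)

    def write(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "taxon_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "PresenceCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy())

    def presence_set(self, family: str) -> frozenset[str]:
        j = self.families.index(family)
        return frozenset(
            s for s, v in zip(self.species, self.matrix[:, j]) if v == 1
        )


@dataclass(frozen=True)
class CollectorsCurve:
    """Cumulative distinct homologs per search round (a plateau means the
    iterative search saturated)."""

    rounds: tuple[int, ...]
    cumulative_hits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.rounds) != len(self.cumulative_hits):
            raise ValueError("rounds and cumulative_hits lengths differ")
        if any(b < a for a, b in zip(self.cumulative_hits, self.cumulative_hits[1:])):
            raise ValueError("cumulative_hits must be non-decreasing")


def build_presence_catalog(
    hits_by_family: Mapping[str, Sequence[SearchHit]],
    taxa: Sequence[TaxonRecord],
) -> PresenceCatalog:
    """Entry (species, family) = 1 iff that family has >= 1 hit in that
    species; every catalog species keeps its row even when all-zero."""
    species = [t.taxon_id for t in taxa]
    index = {s: i for i, s in enumerate(species)}
    families = list(hits_by_family)
    matrix = np.zeros((len(species), len(families)), dtype=int)
    for j, fam in enumerate(families):
        for hit in hits_by_family[fam]:
            if hit.taxon_id not in index:
                raise ValueError(
                    f"hit {hit.seq_id!r} references unknown taxon {hit.taxon_id!r}"
                )
            matrix[index[hit.taxon_id], j] = 1
    return PresenceCatalog(species, families, matrix)


def tabulate_absences(catalog: PresenceCatalog) -> tuple[int, list[str]]:
    """Count (and list) the species with no homolog in any family."""
    empty = catalog.matrix.sum(axis=1) == 0
    ids = [s for s, e in zip(catalog.species, empty) if e]
    return len(ids), ids


def cooccurrence_counts(
    catalog: PresenceCatalog,
    families: Sequence[str],
    stratum: Iterable[str] | None = None,
) -> dict[frozenset[str], int]:
    """Counts of every region of the Venn partition over ``families``,
    restricted to ``stratum`` (default: all species).

    Keys are the non-empty family subsets (frozensets); the value of key R
    counts species present in exactly the families of R. Region counts sum
    to the number of stratum species with at least one family present.
    """
    if not families:
        raise ValueError("families must be non-empty")
    missing = [f for f in families if f not in catalog.families]
    if missing:
        raise ValueError(f"families not in catalog: {missing}")
    stratum_set = set(catalog.species) if stratum is None else set(stratum)
    unknown = stratum_set - set(catalog.species)
    if unknown:
        raise ValueError(f"stratum species not in catalog: {sorted(unknown)[:5]}")
    present = {f: catalog.presence_set(f) for f in families}
    counts: dict[frozenset[str], int] = {}
    from itertools import combinations
    for r in range(1, len(families) + 1):
        for combo in combinations(families, r):
            region = frozenset(combo)
            n = sum(
                1 for s in stratum_set
                if all(s in present[f] for f in region)
                and all(s not in present[f] for f in set(families) - region)
            )
            counts[region] = n
    return counts


def collectors_curve(rounds: Sequence[SearchRoundResult]) -> CollectorsCurve:
    """Cumulative count of distinct newly recovered sequences per round."""
    indices = [r.round_index for r in rounds]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError(f"rounds out of order: {indices}")
    seen: set[str] = set()
    cumulative = []
    for r in rounds:
        seen |= set(r.new_seq_ids)
        cumulative.append(len(seen))
    return CollectorsCurve(tuple(indices), tuple(cumulative))


def import_supplementary_catalog(
    path: str | Path,
    tab: str,
    species_column: str | None = None,
    family_columns: Sequence[str] | None = None,
) -> PresenceCatalog:
    """Read a presence/absence catalog from one tab of a spreadsheet.

    The tab must have one species-id column (``species_column``, default:
    the first column) and binary 0/1 flag columns (``family_columns``,
    default: every other column). Non-binary cells are rejected with their
    location; a missing tab raises an error listing the available tabs.
    """
    xls = pd.ExcelFile(path, engine="openpyxl")
    if tab not in xls.sheet_names:
        raise ValueError(
            f"tab {tab!r} not found; available tabs: {list(xls.sheet_names)}"
        )
    df = xls.parse(tab)
    if species_column is None:
        species_column = df.columns[0]
    if species_column not in df.columns:
        raise ValueError(f"species column {species_column!r} not in tab {tab!r}")
    if family_columns is None:
        family_columns = [c for c in df.columns if c != species_column]
    missing = [c for c in family_columns if c not in df.columns]
    if missing:
        raise ValueError(f"family column(s) not in tab {tab!r}: {missing}")
    species = df[species_column].astype(str).tolist()
    matrix = np.zeros((len(species), len(family_columns)), dtype=int)
    for j, col in enumerate(family_columns):
        for i, v in enumerate(df[col].tolist()):
            if v not in (0, 1):
                raise ValueError(
                    f"non-binary cell in tab {tab!r}, column {col!r}, "
                    f"row {i + 2}: {v!r}"
                )
            matrix[i, j] = int(v)
    return PresenceCatalog(species, list(family_columns), matrix)
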