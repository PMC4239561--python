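"""Homology sets and the fractionation-resistance score.

After a whole-genome doubling (WGD) every ancestral gene is present in two
(or, after a triplication, three) copies in each descendant lineage.  Most
copies are subsequently lost again -- *fractionation*.  A homology set groups
the surviving copies of one ancestral gene across the surveyed species.  Its
fractionation resistance is

    F = N + 1

where N is the number of species that still carry the set in duplicate.  A
set reduced to a single copy (or none) in every species has F = 1; over S
species F ranges from 1 to S + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "HomologySet",
    "GeneRecord",
    "read_homology_sets",
    "write_homology_sets",
    "compute_F",
    "compute_all_F",
    "gene_index",
]


@dataclass
class HomologySet:
    """One ancestral gene at the WGD event and its surviving copies.

    ``members`` maps species id to the list of retained gene ids in that
    species.  A fully fractionated species contributes a single id; a species
    with no surviving copy contributes an empty list (legal, and common).
    ``F`` is filled in by :func:`compute_F`.
    """

    set_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    F: int | None = None

    def copy_count(self, species_id: str) -> int:
        return len(self.members.get(species_id, ()))

    def genes(self) -> Iterator[tuple[str, str]]:
        """Yield ``(species_id, gene_id)`` for every retained copy."""
        for species_id, gene_ids in self.members.items():
            for gene_id in gene_ids:
                yield species_id, gene_id

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.members.values())


@dataclass(frozen=True)
class GeneRecord:
    """Per-gene view of a homology set (for gene-level expression analyses)."""

    gene_id: str
    species_id: str
    set_id: str


def read_homology_sets(
    path: str | Path, species_list: Sequence[str] | None = None
) -> list[HomologySet]:
    """Parse a homology-set table.

    The file is tab-separated with header ``set_id<TAB>species1<TAB>...``;
    each cell holds comma-separated gene ids, empty for total loss in that
    species.  ``species_list``, when given, must match the file's species
    columns (order-insensitively); an unexpected column is an error.

    Raises ``ValueError`` on a duplicated set id or a gene id occurring in
    more than one set (each surviving copy descends from exactly one
    ancestral gene).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "set_id":
        raise ValueError(f"first column must be 'set_id', got {df.columns[0]!r}")
    species = list(df.columns[1:])
    if species_list is not None:
        unknown = set(species) - set(species_list)
        if unknown:
            raise ValueError(f"unknown species column(s): {sorted(unknown)}")
        missing = set(species_list) - set(species)
        if missing:
            raise ValueError(f"species missing from file: {sorted(missing)}")

    sets: list[HomologySet] = []
    seen_sets: set[str] = set()
    seen_genes: set[str] = set()
    for row in df.itertuples(index=False):
        set_id = row[0]
        if set_id in seen_sets:
            raise ValueError(f"duplicate set_id {set_id!r}")
        seen_sets.add(set_id)
        members: dict[str, list[str]] = {}
        for sp, cell in zip(species, row[1:]):
            gene_ids = [g for g in str(cell).split(",") if g] if cell else []
            for g in gene_ids:
                if g in seen_genes:
                    raise ValueError(
                        f"gene {g!r} occurs in more than one homology set"
                    )
                seen_genes.add(g)
            members[sp] = gene_ids
        sets.append(HomologySet(set_id=set_id, members=members))
    return sets


def write_homology_sets(
    sets: Iterable[HomologySet], path: str | Path, species: Sequence[str]
) -> None:
    """Write sets in the same TSV dialect :func:`read_homology_sets` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_id\t" + "\t".join(species) + "\n")
        for hs in sets:
            cells = [",".join(hs.members.get(sp, [])) for sp in species]
            fh.write(hs.set_id + "\t" + "\t".join(cells) + "\n")


def compute_F(hset: HomologySet, duplicate_threshold: int = 2) -> int:
    """Fractionation resistance F = N + 1 of one homology set.

    N counts the species retaining at least ``duplicate_threshold`` copies
    ("still in duplicate").  The threshold defaults to 2; after a
    triplication a species may retain 3 copies, which also counts.  The
    result is stored on ``hset.F`` and returned.
    """
    if duplicate_threshold < 2:
        raise ValueError("duplicate_threshold must be >= 2")
    n = sum(
        1 for gene_ids in hset.members.values() if len(gene_ids) >= duplicate_threshold
    )
    hset.F = n + 1
    return hset.F


def compute_all_F(
    sets: Iterable[HomologySet], duplicate_threshold: int = 2
) -> list[HomologySet]:
    """Assign F to every set; returns the (same) list for chaining.

    Asserts the range invariant 1 <= F <= S + 1 on the whole collection.
    """
    sets = list(sets)
    n_species = max((len(hs.members) for hs in sets), default=0)
    for hs in sets:
        compute_F(hs, duplicate_threshold)
        assert 1 <= hs.F <= n_species + 1
    return sets


def gene_index(sets: Iterable[HomologySet]) -> list[GeneRecord]:
    """Flatten a collection of sets into one record per retained gene."""
    return [
        GeneRecord(gene_id=g, species_id=sp, set_id=hs.set_id)
        for hs in sets
        for sp, g in hs.genes()
    ]
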