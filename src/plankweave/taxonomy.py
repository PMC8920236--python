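"""Ranked taxonomy and per-survey counted taxa lists.

The integrated dataset records taxa on a fixed six-rank ladder
(Phylum > Class > Order > Family > Genus > Species).  Each survey counts a
taxon/life-stage either at its own rank or lumped into a higher-rank
"spp." category, and the set of counted categories changes through time
(taxa added, promoted to finer resolution, or temporarily dropped).  This
module answers the central bookkeeping question of the integration: *at
what rank does survey S count taxon X, life stage L, size class Z, in
year Y?*
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import IntegrityError, InputError, LookupError_, RankError

__all__ = [
    "Rank",
    "RANKS",
    "NOT_COUNTED",
    "TaxonNode",
    "TaxonomyTree",
    "TaxaListEntry",
    "TaxaList",
    "build_taxonomy",
    "ancestor_at_level",
    "counted_rank",
    "read_taxonomy_csv",
    "write_taxonomy_csv",
    "read_taxa_lists_csv",
    "write_taxa_lists_csv",
]


class Rank(enum.IntEnum):
    """The six-rank ladder; larger value = finer (lower) rank."""

    Phylum = 0
    Class = 1
    Order = 2
    Family = 3
    Genus = 4
    Species = 5

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


RANKS: tuple[Rank, ...] = tuple(Rank)

#: Sentinel returned by :func:`counted_rank` when no category covers the query.
NOT_COUNTED = None


def _as_rank(level) -> Rank:
    if isinstance(level, Rank):
        return level
    try:
        return Rank[str(level)]
    except KeyError:
        raise InputError(f"unknown taxonomic rank: {level!r}") from None


@dataclass(frozen=True)
class TaxonNode:
    """One taxon with its full ancestor ladder.

    ``names[r]`` holds the ancestor name at rank ``r`` for every rank at or
    above ``level``; ranks below ``level`` are empty.  ``taxname`` equals
    ``names[level]``.  Life-stage independent.
    """

    taxname: str
    level: Rank
    names: tuple[str, ...]  # one entry per Rank, "" below level

    def __post_init__(self):
        if len(self.names) != len(RANKS):
            raise InputError(f"{self.taxname}: rank ladder must have {len(RANKS)} entries")
        for r in RANKS:
            name = self.names[r]
            if r <= self.level and not name:
                raise InputError(f"{self.taxname}: empty required rank {r.name}")
            if r > self.level and name:
                raise InputError(f"{self.taxname}: rank {r.name} below level {self.level.name} must be empty")
        if self.names[self.level] != self.taxname:
            raise InputError(
                f"{self.taxname}: taxname must equal the name at its own level "
                f"(got {self.names[self.level]!r} at {self.level.name})"
            )

    @classmethod
    def from_ladder(cls, taxname: str, level, **ranks: str) -> "TaxonNode":
        """Build a node from keyword ranks, e.g. ``phylum="Arthropoda"``."""
        lvl = _as_rank(level)
        names = tuple(ranks.get(r.name.lower(), "") or "" for r in RANKS)
        return cls(taxname=taxname, level=lvl, names=names)


class TaxonomyTree:
    """Lookup structure over a consistent set of :class:`TaxonNode`."""

    def __init__(self, nodes: dict[str, TaxonNode]):
        self._nodes = nodes

    def __contains__(self, taxname: str) -> bool:
        return taxname in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self):
        return iter(self._nodes.values())

    def node(self, taxname: str) -> TaxonNode:
        try:
            return self._nodes[taxname]
        except KeyError:
            raise LookupError_(f"unknown taxon: {taxname!r}") from None

    def ancestor_at_level(self, taxname: str, level) -> str:
        lvl = _as_rank(level)
        node = self.node(taxname)
        if lvl > node.level:
            raise RankError(
                f"{taxname} is a {node.level.name}-level taxon; no ancestor at finer rank {lvl.name}"
            )
        return node.names[lvl]

    def is_descendant(self, taxname: str, ancestor: str) -> bool:
        """True when ``ancestor`` lies on ``taxname``'s ladder (self included)."""
        node = self.node(taxname)
        anc = self.node(ancestor)
        return node.names[anc.level] == anc.taxname

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                **{r.name: (n.names[r] or pd.NA) for r in RANKS},
                "Level": n.level.name,
                "Taxname": n.taxname,
            }
            for n in self._nodes.values()
        ]
        return pd.DataFrame(rows, columns=[r.name for r in RANKS] + ["Level", "Taxname"])


def build_taxonomy(nodes: Iterable[TaxonNode]) -> TaxonomyTree:
    """Assemble nodes into a tree, rejecting inconsistent parentage.

    Consistency means no name has two parents: for every rank r > Phylum,
    the name at r determines the name at r-1 across all nodes, and a
    taxname maps to a single ladder.
    """
    node_map: dict[str, TaxonNode] = {}
    parent_of: dict[tuple[Rank, str], str] = {}
    for node in nodes:
        prev = node_map.get(node.taxname)
        if prev is not None and prev != node:
            raise IntegrityError(f"duplicate taxname with conflicting ancestry: {node.taxname}")
        node_map[node.taxname] = node
        for r in RANKS[1:]:
            if r > node.level:
                break
            child, parent = node.names[r], node.names[r - 1]
            seen = parent_of.setdefault((r, child), parent)
            if seen != parent:
                raise IntegrityError(
                    f"{child} ({r.name}) has two parents: {seen!r} and {parent!r}"
                )
    if not node_map:
        raise InputError("taxonomy requires at least one node")
    return TaxonomyTree(node_map)


def ancestor_at_level(tree: TaxonomyTree, taxname: str, level) -> str:
    """Name of ``taxname``'s ancestor at ``level`` (identity at its own rank)."""
    return tree.ancestor_at_level(taxname, level)


@dataclass(frozen=True)
class TaxaListEntry:
    """One survey x size-class x (taxon, life stage) counted interval.

    ``end_year`` open (None) means counted to present.  ``restart_year``
    models a category dropped after ``end_year`` and re-added later: the
    years [end_year+1, restart_year-1] are a NOT_COUNTED gap.  ``intro_year``
    is set for non-native taxa and drives both the zero-retention rule
    before introduction and the time-lag exception of the temporal
    resolution correction.
    """

    survey: str
    size_class: str
    taxname: str
    lifestage: str
    start_year: int
    end_year: Optional[int] = None
    restart_year: Optional[int] = None
    intro_year: Optional[int] = None

    def __post_init__(self):
        if self.end_year is not None and self.start_year > self.end_year:
            raise InputError(f"{self.taxname}: start_year > end_year")
        if self.restart_year is not None:
            if self.end_year is None:
                raise InputError(f"{self.taxname}: restart_year requires end_year")
            if self.restart_year <= self.end_year:
                raise InputError(f"{self.taxname}: restart_year must exceed end_year")

    def counted_in(self, year: int) -> bool:
        if self.start_year <= year and (self.end_year is None or year <= self.end_year):
            return True
        return self.restart_year is not None and year >= self.restart_year

    @property
    def category(self) -> tuple[str, str]:
        return (self.taxname, self.lifestage)


class TaxaList:
    """Collection of :class:`TaxaListEntry` with category/year queries."""

    def __init__(self, entries: Iterable[TaxaListEntry]):
        self.entries: list[TaxaListEntry] = list(entries)
        self._by_key: dict[tuple[str, str, str, str], list[TaxaListEntry]] = {}
        for e in self.entries:
            self._by_key.setdefault((e.survey, e.size_class, e.taxname, e.lifestage), []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def entries_for(self, survey, size_class, taxname, lifestage) -> list[TaxaListEntry]:
        return self._by_key.get((survey, size_class, taxname, lifestage), [])

    def has_category(self, survey, size_class, taxname, lifestage) -> bool:
        return bool(self.entries_for(survey, size_class, taxname, lifestage))

    def active(self, survey, size_class, taxname, lifestage, year: int) -> bool:
        return any(e.counted_in(year) for e in self.entries_for(survey, size_class, taxname, lifestage))

    def active_in_range(self, survey, size_class, taxname, lifestage, years: Iterable[int]) -> bool:
        return any(self.active(survey, size_class, taxname, lifestage, y) for y in years)

    def surveys(self) -> list[str]:
        return sorted({e.survey for e in self.entries})

    def categories(self, survey: str, size_class: str, years: Optional[Iterable[int]] = None) -> set[tuple[str, str]]:
        """Categories a survey counts in a size class (optionally: active in any given year)."""
        out = set()
        years = list(years) if years is not None else None
        for e in self.entries:
            if e.survey != survey or e.size_class != size_class:
                continue
            if years is None or any(e.counted_in(y) for y in years):
                out.add(e.category)
        return out


def counted_rank(
    lists: TaxaList,
    tree: TaxonomyTree,
    survey: str,
    size_class: str,
    taxname: str,
    lifestage: str,
    year: int,
):
    """Lowest rank at which ``survey`` counts the taxon in ``year``.

    Walks upward from the taxon's own rank; the first rank whose ancestor
    name (paired with the same life stage) is on the survey's active list
    is the resolution at which organisms of this taxon land.  Returns
    :data:`NOT_COUNTED` when no category covers it.
    """
    node = tree.node(taxname)
    for r in range(node.level, Rank.Phylum - 1, -1):
        rank = Rank(r)
        if lists.active(survey, size_class, node.names[rank], lifestage, year):
            return rank
    return NOT_COUNTED


# ---------------------------------------------------------------------------
# CSV interfaces (taxonomy.csv, taxa_lists.csv); missing values are "NA".

_SURVEY_YEAR_COLUMNS = {
    # column-name stems used in the published wide layout; kept for reading
    # real files, the long layout below is what the package writes.
}


def write_taxonomy_csv(tree: TaxonomyTree, path) -> None:
    tree.to_frame().to_csv(path, index=False, na_rep="NA")


def read_taxonomy_csv(path) -> TaxonomyTree:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False, dtype=str)
    nodes = []
    for _, row in df.iterrows():
        lvl = _as_rank(row["Level"])
        names = tuple((row[r.name] if pd.notna(row[r.name]) else "") for r in RANKS)
        nodes.append(TaxonNode(taxname=row["Taxname"], level=lvl, names=names))
    return build_taxonomy(nodes)


_TAXA_LIST_COLUMNS = [
    "Survey", "SizeClass", "Taxname", "Lifestage",
    "StartYear", "EndYear", "RestartYear", "Intro",
]


def write_taxa_lists_csv(lists: TaxaList, path) -> None:
    rows = [
        {
            "Survey": e.survey, "SizeClass": e.size_class,
            "Taxname": e.taxname, "Lifestage": e.lifestage,
            "StartYear": e.start_year, "EndYear": e.end_year,
            "RestartYear": e.restart_year, "Intro": e.intro_year,
        }
        for e in lists
    ]
    pd.DataFrame(rows, columns=_TAXA_LIST_COLUMNS).to_csv(path, index=False, na_rep="NA")


def read_taxa_lists_csv(path) -> TaxaList:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=False)

    def _opt(v):
        return None if pd.isna(v) else int(v)

    return TaxaList(
        TaxaListEntry(
            survey=str(r["Survey"]), size_class=str(r["SizeClass"]),
            taxname=str(r["Taxname"]), lifestage=str(r["Lifestage"]),
            start_year=int(r["StartYear"]), end_year=_opt(r["EndYear"]),
            restart_year=_opt(r["RestartYear"]), intro_year=_opt(r["Intro"]),
        )
        for _, r in df.iterrows()
    )
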