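"""Ranked taxonomies, lineages, and the training-set taxonomy file dialect.

The unit of both training labels and predictions is a :class:`RankedLineage`:
an ordered list of (rank, taxon) pairs from domain down to genus, with gaps
allowed (many reference hierarchies omit intermediate ranks — e.g. a phylum
with no defined classes).  Species is deliberately *not* a rank: it is
metadata used only to build species-exclusion tables for leave-k-out tests.

Taxon names carry a ``<rank>__`` prefix after normalization so that the rank
of every path component is recoverable from predicted paths, and so that the
same name used at two levels (a real occurrence in bacterial taxonomy, e.g.
a phylum and a class sharing a name) stays unambiguous.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from .errors import ParseError, TaxonomyError

RANK_PREFIX_SEP = "__"

#: default pattern stripped from species names (subspecies designations)
SUBSPECIES_PATTERN = re.compile(r"\s+(subsp|subspecies|str|strain)\.?\s+.*$")


class Rank(enum.IntEnum):
    """The six ranks evaluated, totally ordered by depth (domain shallowest)."""

    DOMAIN = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise TaxonomyError(f"unknown rank label: {label!r}") from None


#: ranks in depth order, shallow to deep
RANKS: tuple[Rank, ...] = tuple(Rank)


def split_prefix(name: str) -> tuple[Optional[Rank], str]:
    """Split a ``rank__Name`` taxon into (rank, bare name); rank None if absent."""
    head, sep, tail = name.partition(RANK_PREFIX_SEP)
    if sep:
        try:
            return Rank.from_label(head), tail
        except TaxonomyError:
            return None, name
    return None, name


def strip_prefix(name: str) -> str:
    return split_prefix(name)[1]


@dataclass(frozen=True)
class RankedLineage:
    """Ordered (rank, taxon-name) pairs, strictly increasing in depth.

    ``species`` is optional metadata (used for leave-k-out exclusion only).
    Taxon names are expected to carry their ``rank__`` prefix; use
    :func:`normalize_lineage` to produce one from raw components.
    """

    entries: tuple[tuple[Rank, str], ...]
    species: Optional[str] = None

    def __post_init__(self) -> None:
        depths = [int(r) for r, _ in self.entries]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise TaxonomyError(
                f"lineage ranks must strictly increase in depth: {self.entries}"
            )

    def __iter__(self) -> Iterator[tuple[Rank, str]]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def has_rank(self, rank: Rank) -> bool:
        return any(r is rank for r, _ in self.entries)

    def name_at(self, rank: Rank) -> Optional[str]:
        for r, name in self.entries:
            if r is rank:
                return name
        return None

    @property
    def deepest_rank(self) -> Optional[Rank]:
        return self.entries[-1][0] if self.entries else None

    def to_string(self) -> str:
        """Canonical mothur-style lineage string with trailing semicolon."""
        return "".join(f"{name};" for _, name in self.entries)

    @classmethod
    def from_prefixed_names(
        cls, names: Sequence[str], species: Optional[str] = None
    ) -> "RankedLineage":
        entries = []
        for name in names:
            rank, _ = split_prefix(name)
            if rank is None:
                raise TaxonomyError(f"taxon {name!r} lacks a rank prefix")
            entries.append((rank, name))
        return cls(tuple(entries), species=species)


def normalize_species(name: str, pattern: re.Pattern = SUBSPECIES_PATTERN) -> str:
    """Strip subspecies/strain suffixes and surrounding whitespace."""
    return pattern.sub("", name.strip())


def _is_excluded_component(bare_name: str) -> bool:
    low = bare_name.lower()
    return low.startswith("unclassified") or low.endswith("incertae_sedis")


def normalize_lineage(
    raw: Sequence[tuple[str, Rank]],
    species: Optional[str] = None,
) -> RankedLineage:
    """Normalize raw (name, rank) components into a :class:`RankedLineage`.

    Components whose name begins with "unclassified" (case-insensitive) or
    ends with "incertae_sedis" are dropped; surviving names receive a
    ``rank__`` prefix (idempotent: already-prefixed names are untouched).
    Two components claiming the same rank is an error.
    """
    seen: set[Rank] = set()
    entries: list[tuple[Rank, str]] = []
    for name, rank in raw:
        if not name:
            raise TaxonomyError("empty taxon name")
        existing, bare = split_prefix(name)
        if existing is not None and existing is not rank:
            raise TaxonomyError(
                f"component {name!r} is prefixed {existing.label} but assigned"
                f" rank {rank.label}"
            )
        if _is_excluded_component(bare):
            continue
        if rank in seen:
            raise TaxonomyError(f"two components claim rank {rank.label}")
        seen.add(rank)
        entries.append((rank, f"{rank.label}{RANK_PREFIX_SEP}{bare}"))
    entries.sort(key=lambda e: int(e[0]))
    sp = normalize_species(species) if species else None
    return RankedLineage(tuple(entries), species=sp)


def trim_to_genus(lineage: RankedLineage) -> RankedLineage:
    """Drop information below genus: clears the species annotation.

    Training taxonomies are trimmed to genus before classifier training
    (genus is the highest-resolution level evaluated); the species stays
    available on the original lineage for exclusion tables.
    """
    entries = tuple(e for e in lineage.entries if e[0] <= Rank.GENUS)
    if entries == lineage.entries and lineage.species is None:
        return lineage
    return RankedLineage(entries, species=None)


@dataclass(frozen=True)
class TrainingRecord:
    id: str
    sequence: str
    lineage: RankedLineage


@dataclass(frozen=True)
class TrainingSet:
    """Sequences with ranked lineages sharing one taxonomy.

    ``region_label`` is free text naming the gene region the sequences cover
    (e.g. "V4/100nt-forward").
    """

    records: tuple[TrainingRecord, ...]
    region_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise TaxonomyError(f"duplicate sequence ID: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TrainingRecord]:
        return iter(self.records)

    def __getitem__(self, index):
        return self.records[index]

    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def by_id(self) -> dict[str, TrainingRecord]:
        return {r.id: r for r in self.records}

    def subset(self, keep_ids: Iterable[str]) -> "TrainingSet":
        keep = set(keep_ids)
        return TrainingSet(
            tuple(r for r in self.records if r.id in keep),
            region_label=self.region_label,
        )

    def with_sequences(self, seqs: Mapping[str, str]) -> "TrainingSet":
        missing = [r.id for r in self.records if r.id not in seqs]
        if missing:
            raise TaxonomyError(f"no sequence provided for IDs: {missing[:5]}")
        return TrainingSet(
            tuple(replace(r, sequence=seqs[r.id].upper()) for r in self.records),
            region_label=self.region_label,
        )


class SynonymMap:
    """Optional user-supplied equivalences between taxon names.

    Comparison strips rank prefixes first; default (empty map) is exact,
    case-sensitive string match.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        groups: dict[str, set[str]] = {}
        for a, b in pairs:
            a, b = strip_prefix(a), strip_prefix(b)
            group = groups.get(a) or groups.get(b) or {a, b}
            group.update((a, b))
            for name in group:
                groups[name] = group

        self._groups = groups

    def equivalent(self, a: str, b: str) -> bool:
        a, b = strip_prefix(a), strip_prefix(b)
        if a == b:
            return True
        return b in self._groups.get(a, ())


# ---------------------------------------------------------------------------
# Taxonomy tree


@dataclass
class TaxonNode:
    name: str  # prefixed
    rank: Optional[Rank]  # None for the synthetic root
    parent: Optional["TaxonNode"] = None
    children: dict[str, "TaxonNode"] = field(default_factory=dict)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TaxonNode({self.name!r})"


class TaxonomyTree:
    """Shared hierarchy underlying a training set; paths may omit ranks."""

    def __init__(self) -> None:
        self.root = TaxonNode(name="<root>", rank=None)
        self._index: dict[tuple[Rank, str], TaxonNode] = {}

    @classmethod
    def from_lineages(cls, lineages: Iterable[RankedLineage]) -> "TaxonomyTree":
        tree = cls()
        for lin in lineages:
            tree.add_lineage(lin)
        return tree

    def add_lineage(self, lineage: RankedLineage) -> None:
        node = self.root
        for rank, name in lineage.entries:
            child = node.children.get(name)
            if child is None:
                child = TaxonNode(name=name, rank=rank, parent=node)
                node.children[name] = child
                self._index.setdefault((rank, name), child)
            elif child.rank is not rank:
                raise TaxonomyError(
                    f"taxon {name!r} appears at ranks {child.rank} and {rank}"
                )
            node = child

    def find(self, rank: Rank, name: str) -> TaxonNode:
        try:
            return self._index[(rank, name)]
        except KeyError:
            raise TaxonomyError(f"unknown taxon: {rank.label} {name!r}") from None

    def lineage_of(self, node: TaxonNode) -> RankedLineage:
        entries = []
        while node is not None and node.rank is not None:
            entries.append((node.rank, node.name))
            node = node.parent
        return RankedLineage(tuple(reversed(entries)))

    def genus_nodes(self) -> list[TaxonNode]:
        return [n for (r, _), n in sorted(self._index.items()) if r is Rank.GENUS]

    def __contains__(self, key: tuple[Rank, str]) -> bool:
        return key in self._index


def ranks_omitted_below(tree: TaxonomyTree, node: TaxonNode) -> set[Rank]:
    """Ranks that can never be predicted at/under ``node``.

    A rank deeper than the node's own rank is omitted when no descendant of
    the node carries it — e.g. a phylum with no child taxa omits class
    through genus, and a phylum whose classes parent genera directly omits
    order and family.
    """
    if node.rank is None:
        raise TaxonomyError("ranks_omitted_below requires a named taxon node")
    if (node.rank, node.name) not in tree:
        raise TaxonomyError(f"node {node.name!r} is not part of this tree")
    present: set[Rank] = set()
    stack = list(node.children.values())
    while stack:
        n = stack.pop()
        present.add(n.rank)
        stack.extend(n.children.values())
    return {r for r in RANKS if r > node.rank and r not in present}


# ---------------------------------------------------------------------------
# Taxonomy table dialect (mothur-style TSV)


@dataclass(frozen=True)
class TaxonomyDialect:
    """How to interpret a ``seqID<TAB>taxon1;taxon2;…;`` table.

    When components carry ``rank__`` prefixes, ranks come from the prefixes;
    otherwise they are assigned positionally from ``positional_ranks``.
    ``species_column`` reads the species from a third TSV column if present.
    """

    positional_ranks: tuple[Rank, ...] = RANKS
    species_column: bool = False


CANONICAL_DIALECT = TaxonomyDialect()


def parse_taxonomy_table(
    path, dialect: TaxonomyDialect = CANONICAL_DIALECT
) -> TrainingSet:
    """Parse a taxonomy TSV into a sequence-less :class:`TrainingSet`.

    Sequences are attached separately via :meth:`TrainingSet.with_sequences`.
    """
    records: list[TrainingRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected ID<TAB>lineage")
            seq_id, lineage_str = fields[0].strip(), fields[1].strip()
            if not seq_id:
                raise ParseError(f"line {lineno}: empty sequence ID")
            if seq_id in seen:
                raise ParseError(f"line {lineno}: duplicate ID {seq_id!r}")
            seen.add(seq_id)
            species = fields[2].strip() if dialect.species_column and len(fields) > 2 else None
            components = [c for c in lineage_str.split(";") if c.strip()]
            raw: list[tuple[str, Rank]] = []
            for i, comp in enumerate(components):
                comp = comp.strip()
                rank, _ = split_prefix(comp)
                if rank is None:
                    if i >= len(dialect.positional_ranks):
                        raise ParseError(
                            f"line {lineno}: component {comp!r} has no rank prefix"
                            f" and exceeds the positional rank order"
                        )
                    rank = dialect.positional_ranks[i]
                raw.append((comp, rank))
            try:
                lineage = normalize_lineage(raw, species=species)
            except TaxonomyError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            records.append(TrainingRecord(id=seq_id, sequence="", lineage=lineage))
    return TrainingSet(tuple(records))


def write_taxonomy_table(ts: TrainingSet, path, include_species: bool = False) -> None:
    """Write the canonical prefixed dialect (round-trips byte-identically)."""
    with open(path, "w") as fh:
        for rec in ts.records:
            line = f"{rec.id}\t{rec.lineage.to_string()}"
            if include_species:
                line += f"\t{rec.lineage.species or ''}"
            fh.write(line + "\n")
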