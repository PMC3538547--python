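"""Synthetic taxonomy / alignment / query generator.

Gives every pipeline stage a self-contained test surface with controlled
structure: a balanced ranked hierarchy (optionally with lineages that skip
the order and family ranks, exercising the coverage gap correction),
sequences that diverge along the hierarchy with a tunable between-genus
divergence, designated *confusable* genus pairs whose ancestors differ at
only a small per-site rate q (the knob for classification difficulty),
insertion events that create gapped alignment columns, and truth-labelled
query reads from trained or held-out (novel) species.

The substitution process is per-site uniform replacement (Jukes-Cantor
flavoured) applied independently along each lineage edge.  It is not a
biological model of rRNA evolution — no rate heterogeneity, secondary
structure or back-mutation bookkeeping — but it produces exactly the
statistical structure the evaluation framework consumes: word-composition
signal that decays with taxonomic distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .amplicons import AlignedSet
from .errors import FixtureError
from .taxonomy import (
    Rank,
    RankedLineage,
    TaxonomyTree,
    TrainingRecord,
    TrainingSet,
    normalize_lineage,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: per-level substitution rates as multiples of between_genus_divergence
_EDGE_SCALE = {
    Rank.PHYLUM: 1.0,
    Rank.CLASS: 0.5,
    Rank.ORDER: 0.25,
    Rank.FAMILY: 0.25,
    Rank.GENUS: 1.0,
}
_SPECIES_SCALE = 0.2
_COPY_SCALE = 0.05


@dataclass(frozen=True)
class FixtureSpec:
    """Study-condition parameters for the synthetic data generator."""

    n_phyla: int = 2
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 1
    genera_per_family: int = 4
    species_per_genus: int = 3
    seqs_per_species: int = 2
    seq_len: int = 300
    between_genus_divergence: float = 0.10
    confusable_pairs: tuple[tuple[str, str], ...] = ()
    confusable_divergence: float = 0.01
    gap_lineage_fraction: float = 0.0
    indel_rate: float = 0.0
    queries_per_species: int = 1
    query_divergence: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_phyla",
            "classes_per_phylum",
            "orders_per_class",
            "families_per_order",
            "genera_per_family",
            "species_per_genus",
            "seqs_per_species",
            "seq_len",
            "queries_per_species",
        ):
            if getattr(self, name) < 1:
                raise FixtureError(f"{name} must be >= 1")
        for name in (
            "between_genus_divergence",
            "confusable_divergence",
            "gap_lineage_fraction",
            "indel_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise FixtureError(f"{name} must be in [0, 1], got {value}")

    @property
    def n_genera(self) -> int:
        return (
            self.n_phyla
            * self.classes_per_phylum
            * self.orders_per_class
            * self.families_per_order
            * self.genera_per_family
        )


@dataclass(frozen=True)
class QuerySet:
    """Truth-labelled queries; ``novel_species`` marks held-out species."""

    aligned: AlignedSet
    records: TrainingSet
    novel_species: frozenset[str]


@dataclass(frozen=True)
class _SimState:
    tree: TaxonomyTree
    aligned: AlignedSet
    training: TrainingSet
    query_aligned: AlignedSet
    queries: TrainingSet
    species_names: tuple[str, ...]


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each site with probability p by a different uniform base."""
    out = seq.copy()
    mask = rng.random(len(seq)) < p
    if mask.any():
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


@lru_cache(maxsize=4)
def _simulate(spec: FixtureSpec) -> _SimState:
    rng_tax = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    rng_seq = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    rng_query = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))

    # ---- taxonomy -------------------------------------------------------
    pad = max(2, len(str(spec.n_genera)))
    genus_paths: list[tuple[str, ...]] = []  # bare names root->genus
    gi = 0
    for p in range(spec.n_phyla):
        for c in range(spec.classes_per_phylum):
            for o in range(spec.orders_per_class):
                for f in range(spec.families_per_order):
                    for g in range(spec.genera_per_family):
                        gi += 1
                        genus_paths.append(
                            (
                                "Bacteria",
                                f"P{p + 1}",
                                f"C{p + 1}_{c + 1}",
                                f"O{p + 1}_{c + 1}_{o + 1}",
                                f"F{p + 1}_{c + 1}_{o + 1}_{f + 1}",
                                f"G{gi:0{pad}d}",
                            )
                        )
    n_gap = int(round(spec.gap_lineage_fraction * len(genus_paths)))
    gap_idx = set(
        rng_tax.choice(len(genus_paths), size=n_gap, replace=False).tolist()
    )

    lineages: list[RankedLineage] = []
    for i, path in enumerate(genus_paths):
        if i in gap_idx:
            raw = [
                (path[0], Rank.DOMAIN),
                (path[1], Rank.PHYLUM),
                (path[2], Rank.CLASS),
                (path[5], Rank.GENUS),
            ]
        else:
            raw = list(zip(path, (Rank.DOMAIN,) + tuple(Rank)[1:]))
        lineages.append(normalize_lineage(raw))
    tree = TaxonomyTree.from_lineages(lineages)

    # ---- ancestral sequences -------------------------------------------
    d = spec.between_genus_divergence
    root = rng_seq.integers(0, 4, size=spec.seq_len).astype(np.uint8)
    anchors: dict[tuple[str, ...], np.ndarray] = {(): root}

    def anchor_for(path_prefix: tuple[str, ...], rank: Rank) -> np.ndarray:
        if path_prefix not in anchors:
            parent = anchor_for(path_prefix[:-1], Rank(rank - 1)) if rank > Rank.PHYLUM else root
            anchors[path_prefix] = _mutate(parent, d * _EDGE_SCALE[rank], rng_seq)
        return anchors[path_prefix]

    genus_anc: dict[str, np.ndarray] = {}
    genus_lineage: dict[str, RankedLineage] = {}
    for i, path in enumerate(genus_paths):
        bare_genus = path[5]
        genus_lineage[bare_genus] = lineages[i]
        if i in gap_idx:
            parent = anchor_for(path[1:3], Rank.CLASS)
        else:
            parent = anchor_for(path[1:5], Rank.FAMILY)
        genus_anc[bare_genus] = _mutate(parent, d * _EDGE_SCALE[Rank.GENUS], rng_seq)

    for a, b in spec.confusable_pairs:
        if a not in genus_anc or b not in genus_anc:
            raise FixtureError(f"confusable pair names unknown genus: ({a}, {b})")
        genus_anc[b] = _mutate(genus_anc[a], spec.confusable_divergence, rng_seq)

    # ---- species, training copies, queries ------------------------------
    species_anc: dict[str, np.ndarray] = {}
    species_lineage: dict[str, RankedLineage] = {}
    species_order: list[str] = []
    train_rows: list[tuple[str, np.ndarray, RankedLineage]] = []
    tid = 0
    for path in genus_paths:
        bare_genus = path[5]
        lin = genus_lineage[bare_genus]
        for s in range(spec.species_per_genus):
            sp_name = f"{bare_genus}_sp{s + 1}"
            species_order.append(sp_name)
            species_anc[sp_name] = _mutate(
                genus_anc[bare_genus], d * _SPECIES_SCALE, rng_seq
            )
            sp_lin = RankedLineage(lin.entries, species=sp_name)
            species_lineage[sp_name] = sp_lin
            for _ in range(spec.seqs_per_species):
                tid += 1
                seq = _mutate(species_anc[sp_name], d * _COPY_SCALE, rng_seq)
                train_rows.append((f"t{tid:06d}", seq, sp_lin))

    q_div = (
        spec.query_divergence
        if spec.query_divergence is not None
        else d * _COPY_SCALE
    )
    query_rows: list[tuple[str, np.ndarray, RankedLineage]] = []
    qid = 0
    for sp_name in species_order:
        for _ in range(spec.queries_per_species):
            qid += 1
            seq = _mutate(species_anc[sp_name], q_div, rng_query)
            query_rows.append((f"q{qid:06d}", seq, species_lineage[sp_name]))

    # ---- insertion events create gapped alignment columns ---------------
    n_events = int(rng_seq.binomial(spec.seq_len, spec.indel_rate))
    events = []  # (position, carrier genus bare name, inserted base index)
    genus_names = [p[5] for p in genus_paths]
    for _ in range(n_events):
        pos = int(rng_seq.integers(0, spec.seq_len + 1))
        carrier = genus_names[int(rng_seq.integers(0, len(genus_names)))]
        base = int(rng_seq.integers(0, 4))
        events.append((pos, carrier, base))
    events.sort(key=lambda e: e[0], reverse=True)

    def aligned_string(seq: np.ndarray, genus: str) -> str:
        chars = list(_to_str(seq))
        for pos, carrier, base in events:
            chars.insert(pos, _to_str(np.array([base], dtype=np.uint8)) if carrier == genus else "-")
        return "".join(chars)

    def build(rows) -> tuple[AlignedSet, TrainingSet]:
        aligned_rows = []
        records = []
        for rid, seq, lin in rows:
            genus_bare = lin.name_at(Rank.GENUS).split("__", 1)[1]
            row = aligned_string(seq, genus_bare)
            aligned_rows.append((rid, row))
            # carrier sequences own their inserted bases: the unaligned
            # sequence is the degapped alignment row
            records.append(
                TrainingRecord(id=rid, sequence=row.replace("-", ""), lineage=lin)
            )
        return (
            AlignedSet.from_rows(aligned_rows),
            TrainingSet(tuple(records), region_label="synthetic"),
        )

    aligned, training = build(train_rows)
    query_aligned, queries = build(query_rows)
    return _SimState(
        tree=tree,
        aligned=aligned,
        training=training,
        query_aligned=query_aligned,
        queries=queries,
        species_names=tuple(species_order),
    )


def gen_taxonomy(spec: FixtureSpec) -> TaxonomyTree:
    """Balanced ranked hierarchy; a ``gap_lineage_fraction`` of genera hang
    directly under their class, omitting order and family."""
    return _simulate(spec).tree


def gen_alignment(
    spec: FixtureSpec, tree: Optional[TaxonomyTree] = None
) -> tuple[AlignedSet, TrainingSet]:
    """Aligned training sequences plus their truth lineages (deterministic
    per seed; ``tree`` defaults to the spec's own taxonomy)."""
    state = _simulate(spec)
    return state.aligned, state.training


def gen_queries(
    spec: FixtureSpec,
    tree: Optional[TaxonomyTree] = None,
    holdout: frozenset[str] | set[str] = frozenset(),
) -> QuerySet:
    """Truth-labelled query sequences from every species.

    ``holdout`` names species the caller will withhold from training; they
    are flagged as novel in the returned set (the generator emits queries
    for all species either way, so the same call serves both the trained-
    species and novel-species scenarios).
    """
    state = _simulate(spec)
    unknown = set(holdout) - set(state.species_names)
    if unknown:
        raise FixtureError(f"holdout names unknown species: {sorted(unknown)[:5]}")
    return QuerySet(
        aligned=state.query_aligned,
        records=state.queries,
        novel_species=frozenset(holdout),
    )


def species_names(spec: FixtureSpec) -> tuple[str, ...]:
    return _simulate(spec).species_names
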