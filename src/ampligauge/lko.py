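"""Leave-k-out precision experiments with species-level exclusion.

For every test sequence, *all* training sequences annotated as the same
species are removed before classification — a stricter setting than
leave-one-out, designed to mimic the classification of novel species.
Highly redundant training sets are first reduced to a non-redundant form:
sequences are clustered at 100% identity (exact string equality, every
mismatch and gap counted) and within each cluster one representative per
genus is kept.  When an excluded sequence was a cluster's representative,
the representative slot is re-filled from the remaining members, so
same-genus different-species sequences are never lost from training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import LkoError
from .nbc import (
    ClassificationResult,
    DEFAULT_WORD_SIZE,
    WordModel,
    classify,
    derive_seed,
    extract_words,
    train,
)
from .taxonomy import Rank, RankedLineage, TrainingSet


@dataclass(frozen=True)
class ExclusionTable:
    """Test-sequence ID -> same-species training-sequence IDs.

    Tests whose species has no training sequence go to
    ``absent_species_ids`` and are classified as one batch against the
    unmodified (non-redundant) training set.
    """

    rows: dict[str, tuple[str, ...]]
    absent_species_ids: tuple[str, ...]


@dataclass(frozen=True)
class RedundancyClusters:
    """Partition of training IDs into groups with byte-identical sequences."""

    clusters: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class LkoConfig:
    word_size: int = DEFAULT_WORD_SIZE
    bootstrap_iters: int = 100
    repeats: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise LkoError("repeats must be >= 1")


@dataclass(frozen=True)
class LkoRecord:
    repeat: int
    test_id: str
    reference: RankedLineage
    result: ClassificationResult
    #: IDs excluded for this test (same species); empty for absent-species tests
    excluded_ids: tuple[str, ...]
    #: IDs of the effective (non-redundant) training set used — shared tuples
    training_ids: tuple[str, ...]


@dataclass
class LkoRun:
    config: LkoConfig
    records: list[LkoRecord]
    repeat_seeds: tuple[int, ...]
    region_label: str = ""

    def by_repeat(self, repeat: int) -> list[LkoRecord]:
        return [r for r in self.records if r.repeat == repeat]


def build_exclusion_table(test: TrainingSet, train_set: TrainingSet) -> ExclusionTable:
    """Relate test sequences to same-species training sequences by exact
    match on the normalized species name."""
    by_species: dict[str, list[str]] = {}
    for rec in train_set.records:
        if rec.lineage.species:
            by_species.setdefault(rec.lineage.species, []).append(rec.id)
    rows: dict[str, tuple[str, ...]] = {}
    absent: list[str] = []
    for rec in test.records:
        if not rec.lineage.species:
            raise LkoError(f"test record {rec.id!r} lacks a species annotation")
        same = by_species.get(rec.lineage.species)
        if same:
            rows[rec.id] = tuple(same)
        else:
            absent.append(rec.id)
    return ExclusionTable(rows=rows, absent_species_ids=tuple(absent))


def cluster_identical(train_set: TrainingSet) -> RedundancyClusters:
    """Equivalence classes under exact sequence equality, ordered by first
    occurrence; members keep input order (the representative tie-break)."""
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in train_set.records:
        if rec.sequence not in groups:
            groups[rec.sequence] = []
            order.append(rec.sequence)
        groups[rec.sequence].append(rec.id)
    return RedundancyClusters(clusters=tuple(tuple(groups[s]) for s in order))


def _nonredundant_ids(
    clusters: RedundancyClusters,
    genus_of: dict[str, str],
    available: Optional[set[str]] = None,
) -> set[str]:
    keep: set[str] = set()
    for cluster in clusters.clusters:
        seen_genera: set[str] = set()
        for member in cluster:
            if available is not None and member not in available:
                continue
            genus = genus_of[member]
            if genus not in seen_genera:
                seen_genera.add(genus)
                keep.add(member)
    return keep


def build_nonredundant_set(
    train_set: TrainingSet, clusters: RedundancyClusters
) -> TrainingSet:
    """Within each cluster keep one representative per genus (identical
    sequences from *different* genera are all retained — they are distinct
    taxonomic evidence).  Representative = first member in input order."""
    genus_of = _genus_map(train_set)
    keep = _nonredundant_ids(clusters, genus_of)
    return train_set.subset(keep)


def _genus_map(ts: TrainingSet) -> dict[str, str]:
    genus_of: dict[str, str] = {}
    for rec in ts.records:
        genus = rec.lineage.name_at(Rank.GENUS)
        if genus is None:
            raise LkoError(f"record {rec.id!r} has no genus annotation")
        genus_of[rec.id] = genus
    return genus_of


def run_lko(
    test: TrainingSet,
    train_set: TrainingSet,
    clusters: Optional[RedundancyClusters] = None,
    cfg: LkoConfig = LkoConfig(),
) -> LkoRun:
    """Run the full leave-k-out experiment.

    Absent-species tests are classified against the original non-redundant
    training set; every other test is classified against the non-redundant
    set rebuilt from (full set − same-species IDs) using the precomputed
    clusters.  Repeats differ only in bootstrap seeds (nothing else in the
    procedure is stochastic).
    """
    if clusters is None:
        clusters = cluster_identical(train_set)
    genus_of = _genus_map(train_set)
    all_ids = set(train_set.ids())
    excl = build_exclusion_table(test, train_set)
    test_by_id = test.by_id()

    # word sets are shared across all retrained models
    word_sets = {
        rec.id: extract_words(rec.sequence, cfg.word_size)
        for rec in train_set.records
    }
    repeat_seeds = tuple(
        derive_seed(cfg.base_seed, f"repeat:{r}") for r in range(cfg.repeats)
    )

    records: list[LkoRecord] = []

    def _classify_group(
        model: WordModel,
        test_ids: list[str],
        excluded: tuple[str, ...],
        training_ids: tuple[str, ...],
    ) -> None:
        for r, rseed in enumerate(repeat_seeds):
            for tid in test_ids:
                rec = test_by_id[tid]
                result = classify(
                    rec.sequence,
                    model,
                    bootstrap_iters=cfg.bootstrap_iters,
                    seed=derive_seed(rseed, tid),
                    query_id=tid,
                )
                records.append(
                    LkoRecord(
                        repeat=r,
                        test_id=tid,
                        reference=rec.lineage,
                        result=result,
                        excluded_ids=excluded,
                        training_ids=training_ids,
                    )
                )

    # absent-species batch: classified against the original non-redundant set
    original_nr_ids = _nonredundant_ids(clusters, genus_of)
    original_nr = train_set.subset(original_nr_ids)
    model0 = train(original_nr, cfg.word_size, word_sets=word_sets)
    if excl.absent_species_ids:
        _classify_group(
            model0,
            list(excl.absent_species_ids),
            excluded=(),
            training_ids=tuple(original_nr.ids()),
        )

    # group remaining tests by their excluded-ID set (one model per species)
    groups: dict[tuple[str, ...], list[str]] = {}
    for tid, same_species in excl.rows.items():
        groups.setdefault(same_species, []).append(tid)

    for same_species, test_ids in groups.items():
        available = all_ids - set(same_species)
        nr_ids = _nonredundant_ids(clusters, genus_of, available=available)
        subset = train_set.subset(nr_ids)
        model = train(subset, cfg.word_size, word_sets=word_sets)
        _classify_group(
            model,
            test_ids,
            excluded=same_species,
            training_ids=tuple(subset.ids()),
        )

    return LkoRun(
        config=cfg,
        records=records,
        repeat_seeds=repeat_seeds,
        region_label=train_set.region_label,
    )
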