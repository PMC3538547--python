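"""Merging classifications of two regions of the same molecule.

When two fragments of one 16S rRNA gene are classified independently, the
combined call keeps the entire taxonomic path of whichever prediction has
the higher confidence at R, the deepest rank predicted by both (usually
genus).  Equal confidences with *different* taxa at R are discarded; a
query covering only one region is skipped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Union

from .errors import CombineError
from .nbc import ClassificationResult
from .taxonomy import Rank


class CombineStatus(enum.Enum):
    DISCARDED = "discarded"
    SKIPPED = "skipped"


DISCARDED = CombineStatus.DISCARDED
SKIPPED = CombineStatus.SKIPPED


@dataclass(frozen=True)
class CombinedResult:
    query_id: str
    chosen_source: str  # "A" | "B"
    result: ClassificationResult  # the chosen prediction, full path
    rank_used: Rank  # deepest rank present in both inputs


def combine(
    pred_a: Optional[ClassificationResult],
    pred_b: Optional[ClassificationResult],
) -> Union[CombinedResult, CombineStatus]:
    """Combine two predictions for the same query.

    Ties at the comparison rank with the *same* taxon keep prediction A
    (either path names the same taxon at R; A is the stable choice).
    """
    if pred_a is None or pred_b is None:
        return SKIPPED
    if pred_a.failed or pred_b.failed or not pred_a.entries or not pred_b.entries:
        return SKIPPED
    if pred_a.query_id != pred_b.query_id:
        raise CombineError(
            f"mismatched query IDs: {pred_a.query_id!r} vs {pred_b.query_id!r}"
        )

    ranks_a = {r for r, _, _ in pred_a.entries}
    ranks_b = {r for r, _, _ in pred_b.entries}
    common = ranks_a & ranks_b
    if not common:
        return DISCARDED
    rank = max(common)

    conf_a = pred_a.confidence_at(rank)
    conf_b = pred_b.confidence_at(rank)
    if conf_a > conf_b:
        source, chosen = "A", pred_a
    elif conf_b > conf_a:
        source, chosen = "B", pred_b
    else:
        if pred_a.name_at(rank) != pred_b.name_at(rank):
            return DISCARDED
        source, chosen = "A", pred_a
    return CombinedResult(
        query_id=pred_a.query_id,
        chosen_source=source,
        result=chosen,
        rank_used=rank,
    )


@dataclass(frozen=True)
class CombineReport:
    combined: int
    discarded: int
    skipped: int

    @property
    def discard_fraction(self) -> float:
        total = self.combined + self.discarded
        return self.discarded / total if total else 0.0


def combine_batch(
    preds_a: Mapping[str, ClassificationResult],
    preds_b: Mapping[str, ClassificationResult],
) -> tuple[list[CombinedResult], CombineReport]:
    """Combine two keyed prediction sets; only queries present in both
    regions enter the combined set."""
    combined: list[CombinedResult] = []
    discarded = skipped = 0
    for qid in preds_a.keys() | preds_b.keys():
        out = combine(preds_a.get(qid), preds_b.get(qid))
        if out is SKIPPED:
            skipped += 1
        elif out is DISCARDED:
            discarded += 1
        else:
            combined.append(out)
    combined.sort(key=lambda c: c.query_id)
    return combined, CombineReport(
        combined=len(combined), discarded=discarded, skipped=skipped
    )
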