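"""In-silico amplicon excision from a multiple sequence alignment.

Primer pairs are specified by the alignment columns they cover on a named
reference sequence (1-based, inclusive); no primer-sequence search or
mismatch model is involved — the framework assumes ideal, bias-free
amplification.  To avoid missing insertion states adjacent to the primers,
the window is widened by one flanking column per side before the inclusion
test; the flanking columns are then stripped again, so the emitted amplicon
is the degapped content of the original window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from Bio import AlignIO

from .errors import AmpliconError

log = logging.getLogger(__name__)

GAP_CHARS = "-."


@dataclass(frozen=True)
class AlignedSet:
    """Rows of an alignment; all strings share ``column_count`` columns."""

    rows: tuple[tuple[str, str], ...]
    column_count: int
    gap_chars: str = GAP_CHARS

    def __post_init__(self) -> None:
        for seq_id, seq in self.rows:
            if len(seq) != self.column_count:
                raise AmpliconError(
                    f"row {seq_id!r} has {len(seq)} columns, expected"
                    f" {self.column_count}"
                )

    @classmethod
    def from_rows(cls, rows, gap_chars: str = GAP_CHARS) -> "AlignedSet":
        rows = tuple((i, s.upper()) for i, s in rows)
        if not rows:
            return cls(rows=(), column_count=0, gap_chars=gap_chars)
        return cls(rows=rows, column_count=len(rows[0][1]), gap_chars=gap_chars)

    @classmethod
    def from_fasta(cls, path, gap_chars: str = GAP_CHARS) -> "AlignedSet":
        aln = AlignIO.read(path, "fasta")
        return cls.from_rows(((rec.id, str(rec.seq)) for rec in aln), gap_chars)

    def row(self, seq_id: str) -> str:
        for rid, seq in self.rows:
            if rid == seq_id:
                return seq
        raise AmpliconError(f"sequence {seq_id!r} not in alignment")

    def degap(self, seq: str) -> str:
        return seq.translate(str.maketrans("", "", self.gap_chars))


@dataclass(frozen=True)
class PrimerWindow:
    """Alignment columns covered by a primer pair on a reference row."""

    reference_id: str
    first_col: int  # 1-based column of the forward primer's first base
    last_col: int  # 1-based column of the reverse primer's last base

    def __post_init__(self) -> None:
        if not (1 <= self.first_col <= self.last_col):
            raise AmpliconError(
                f"invalid window columns {self.first_col}..{self.last_col}"
            )


@dataclass(frozen=True)
class AmpliconSet:
    amplicons: tuple[tuple[str, str], ...]
    window: PrimerWindow
    flank_note: str = "one flanking column per side included then stripped"
    #: (id, reason) for rows not retained, for the extraction report
    excluded: tuple[tuple[str, str], ...] = ()

    def __len__(self) -> int:
        return len(self.amplicons)

    def lengths(self) -> list[int]:
        return [len(s) for _, s in self.amplicons]


def extract_amplicons(msa: AlignedSet, window: PrimerWindow) -> AmpliconSet:
    """Excise the amplicon for ``window`` from every covering row of ``msa``.

    A row is retained only if its sequence begins at or before the widened
    window's first column and ends at or after its last column; the emitted
    string is the degapped content of columns ``first_col..last_col``.
    Widened columns outside the alignment are clamped with a warning.
    """
    if window.last_col > msa.column_count:
        raise AmpliconError(
            f"window column {window.last_col} exceeds alignment width"
            f" {msa.column_count}"
        )
    ref = msa.row(window.reference_id)
    gaps = set(msa.gap_chars)
    if ref[window.first_col - 1] in gaps or ref[window.last_col - 1] in gaps:
        raise AmpliconError(
            "reference sequence is gapped at a primer window boundary"
        )

    widened_first = window.first_col - 1
    widened_last = window.last_col + 1
    if widened_first < 1:
        log.warning("widened window clamped to alignment start")
        widened_first = 1
    if widened_last > msa.column_count:
        log.warning("widened window clamped to alignment end")
        widened_last = msa.column_count

    kept: list[tuple[str, str]] = []
    excluded: list[tuple[str, str]] = []
    for seq_id, seq in msa.rows:
        first_base = next((i for i, c in enumerate(seq, 1) if c not in gaps), None)
        last_base = next(
            (i for i in range(len(seq), 0, -1) if seq[i - 1] not in gaps), None
        )
        if first_base is None:
            excluded.append((seq_id, "all-gap row"))
            continue
        if first_base > widened_first or last_base < widened_last:
            excluded.append((seq_id, "does not span widened window"))
            continue
        sub = seq[window.first_col - 1 : window.last_col]
        kept.append((seq_id, msa.degap(sub)))
    return AmpliconSet(
        amplicons=tuple(kept), window=window, excluded=tuple(excluded)
    )


@dataclass(frozen=True)
class LengthPolicy:
    """Length-filtration rule: absolute bounds or a band around the median.

    Default keeps amplicons within [50%, 150%] of the median length; the
    exact criterion used on the original reference snapshots is not
    published, so the band is configurable and the removal fraction is
    always reported.
    """

    min_len: Optional[int] = None
    max_len: Optional[int] = None
    median_band: Optional[tuple[float, float]] = (0.5, 1.5)


@dataclass(frozen=True)
class LengthFilterReport:
    kept: int
    removed_ids: tuple[str, ...]

    @property
    def removed(self) -> int:
        return len(self.removed_ids)

    @property
    def removed_fraction(self) -> float:
        total = self.kept + self.removed
        return self.removed / total if total else 0.0


def filter_amplicon_lengths(
    amps: AmpliconSet, policy: LengthPolicy = LengthPolicy()
) -> tuple[AmpliconSet, LengthFilterReport]:
    if not amps.amplicons:
        return amps, LengthFilterReport(kept=0, removed_ids=())
    lo, hi = 0.0, float("inf")
    if policy.median_band is not None:
        med = median(amps.lengths())
        lo = max(lo, policy.median_band[0] * med)
        hi = min(hi, policy.median_band[1] * med)
    if policy.min_len is not None:
        lo = max(lo, policy.min_len)
    if policy.max_len is not None:
        hi = min(hi, policy.max_len)
    kept, removed = [], []
    for seq_id, seq in amps.amplicons:
        (kept if lo <= len(seq) <= hi else removed).append((seq_id, seq))
    report = LengthFilterReport(
        kept=len(kept), removed_ids=tuple(i for i, _ in removed)
    )
    filtered = AmpliconSet(
        amplicons=tuple(kept),
        window=amps.window,
        flank_note=amps.flank_note,
        excluded=amps.excluded + tuple((i, "length filter") for i, _ in removed),
    )
    if report.removed:
        log.info(
            "length filter removed %d/%d amplicons (%.2f%%)",
            report.removed,
            report.kept + report.removed,
            100 * report.removed_fraction,
        )
    return filtered, report
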