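"""Short-read simulation from amplicons.

Single reads take the first (forward) or last (reverse) X bases of each
amplicon.  Paired reads fuse the first and last X bases with a run of ten
N's in between; when the amplicon is no longer than 2X the amplicon itself
is used unchanged (the read pair would overlap and reconstruct it).  Reads
carry no sequencing errors — the framework evaluates best-case designs.

The same operations trim *training* sequences down to the region that will
be sequenced (see :func:`trim_training_set`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .amplicons import AmpliconSet
from .errors import ReadSimError
from .taxonomy import TrainingSet

UNAMBIGUOUS = frozenset("ACGTU")

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadConfig:
    """Read-construction parameters.

    ``x`` is the read length in bases (100 and 120 are the configurations
    of interest for current short-read platforms).  ``mode`` is one of
    ``single-forward``, ``single-reverse`` or ``paired``.  Reverse reads
    are the literal last X bases; set ``revcomp`` to reverse-complement
    them (off by default — classifier training uses the same convention).
    """

    x: int = 100
    mode: str = "paired"
    spacer_len: int = 10
    max_ambiguous: int = 10
    revcomp: bool = False

    def __post_init__(self) -> None:
        if self.x < 1:
            raise ReadSimError("read length x must be >= 1")
        if self.spacer_len < 0:
            raise ReadSimError("spacer_len must be >= 0")
        if self.mode not in ("single-forward", "single-reverse", "paired"):
            raise ReadSimError(f"unknown read mode {self.mode!r}")


@dataclass(frozen=True)
class SimRead:
    """A simulated read; ``spacer_span`` marks the inserted N-run (if any)
    as a 0-based half-open interval, so downstream steps can exclude it by
    construction rather than by pattern matching."""

    id: str
    sequence: str
    mode: str
    spacer_span: Optional[tuple[int, int]] = None

    def ambiguous_count(self) -> int:
        """Non-ACGT(U) characters outside the inserted spacer."""
        lo, hi = self.spacer_span if self.spacer_span else (0, 0)
        return sum(
            1
            for i, c in enumerate(self.sequence)
            if not (lo <= i < hi) and c.upper() not in UNAMBIGUOUS
        )


def make_single_read(amplicon: str, cfg: ReadConfig, read_id: str = "read") -> SimRead:
    if not amplicon:
        raise ReadSimError(f"empty amplicon for {read_id!r}")
    if cfg.mode == "single-forward":
        seq = amplicon[: cfg.x]
    elif cfg.mode == "single-reverse":
        seq = amplicon[-cfg.x :]
        if cfg.revcomp:
            seq = reverse_complement(seq)
    else:
        raise ReadSimError("make_single_read requires a single-* mode")
    return SimRead(id=read_id, sequence=seq, mode=cfg.mode)


def make_paired_read(amplicon: str, cfg: ReadConfig, read_id: str = "read") -> SimRead:
    if not amplicon:
        raise ReadSimError(f"empty amplicon for {read_id!r}")
    if cfg.mode != "paired":
        raise ReadSimError("make_paired_read requires mode 'paired'")
    if len(amplicon) <= 2 * cfg.x:
        return SimRead(id=read_id, sequence=amplicon, mode=cfg.mode)
    fused = amplicon[: cfg.x] + "N" * cfg.spacer_len + amplicon[-cfg.x :]
    return SimRead(
        id=read_id,
        sequence=fused,
        mode=cfg.mode,
        spacer_span=(cfg.x, cfg.x + cfg.spacer_len),
    )


def make_read(amplicon: str, cfg: ReadConfig, read_id: str = "read") -> SimRead:
    if cfg.mode == "paired":
        return make_paired_read(amplicon, cfg, read_id)
    return make_single_read(amplicon, cfg, read_id)


def ambiguity_filter(
    reads: Iterable[SimRead], cfg: ReadConfig
) -> tuple[list[SimRead], list[SimRead]]:
    """Drop reads with more than ``cfg.max_ambiguous`` ambiguous characters,
    not counting the inserted spacer run.  Returns (kept, removed)."""
    kept, removed = [], []
    for read in reads:
        (removed if read.ambiguous_count() > cfg.max_ambiguous else kept).append(read)
    return kept, removed


def simulate_reads(
    amps: AmpliconSet, cfg: ReadConfig, apply_filter: bool = True
) -> tuple[list[SimRead], list[SimRead]]:
    """Construct reads for every amplicon; returns (kept, removed)."""
    reads = [make_read(seq, cfg, read_id=seq_id) for seq_id, seq in amps.amplicons]
    if apply_filter:
        return ambiguity_filter(reads, cfg)
    return reads, []


def trim_training_set(ts: TrainingSet, cfg: ReadConfig) -> TrainingSet:
    """Trim training sequences to the region that will be classified, using
    the same read-construction rules applied to queries."""
    records = tuple(
        replace(rec, sequence=make_read(rec.sequence, cfg, rec.id).sequence)
        for rec in ts.records
    )
    return TrainingSet(records, region_label=ts.region_label or cfg.mode)
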