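"""Readers and writers for the package's external text formats.

FASTA (plain and aligned) goes through Biopython; tables are TSV via
pandas or plain line writing.  The classification TSV dialect is:
``query_id`` then one column per rank holding ``taxon(confidence)`` plus a
full ``lineage`` string column.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calibrate import ThresholdTable, format_threshold
from .errors import ParseError
from .nbc import ClassificationResult
from .readsim import SimRead
from .taxonomy import (
    RANKS,
    Rank,
    RankedLineage,
    TrainingSet,
)

_CELL_RE = re.compile(r"^(?P<name>.+)\((?P<conf>\d{1,3})\)$")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(pairs: Iterable[tuple[str, str]], path) -> None:
    records = (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in pairs)
    SeqIO.write(records, str(path), "fasta")


def write_reads_fasta(reads: Iterable[SimRead], path) -> None:
    write_fasta(((r.id, r.sequence) for r in reads), path)


# ---------------------------------------------------------------------------
# classification TSV

CLASSIFICATION_COLUMNS = ["query_id", *(r.label for r in RANKS), "lineage"]


def write_classifications(results: Sequence[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for res in results:
            cells = [res.query_id]
            for rank in RANKS:
                conf = res.confidence_at(rank)
                name = res.name_at(rank)
                cells.append(f"{name}({conf})" if name is not None else "")
            cells.append(res.lineage.to_string())
            fh.write("\t".join(cells) + "\n")


def read_classifications(path) -> list[ClassificationResult]:
    results = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CLASSIFICATION_COLUMNS:
            raise ParseError(f"unexpected classification header in {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(CLASSIFICATION_COLUMNS):
                raise ParseError(f"line {lineno}: wrong column count")
            qid = cells[0]
            entries = []
            for rank, cell in zip(RANKS, cells[1:-1]):
                if not cell:
                    continue
                m = _CELL_RE.match(cell)
                if not m:
                    raise ParseError(f"line {lineno}: malformed cell {cell!r}")
                entries.append((rank, m.group("name"), int(m.group("conf"))))
            winning = next(
                (n for r, n, _ in reversed(entries) if r is Rank.GENUS), None
            )
            results.append(
                ClassificationResult(
                    query_id=qid,
                    entries=tuple(entries),
                    winning_genus=winning,
                    failed=not entries,
                    reason=None if entries else "no prediction",
                )
            )
    return results


# ---------------------------------------------------------------------------
# truth tables (queries with reference lineages)


def write_truth(records: TrainingSet, path, novel: frozenset[str] = frozenset()) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlineage\tspecies\tnovel\n")
        for rec in records:
            fh.write(
                f"{rec.id}\t{rec.lineage.to_string()}\t{rec.lineage.species or ''}"
                f"\t{int((rec.lineage.species or '') in novel)}\n"
            )


# ---------------------------------------------------------------------------
# thresholds


def write_thresholds(table: ThresholdTable, path) -> None:
    frame = table.to_frame()
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    config: dict,
    seeds: dict,
    inputs: Optional[dict[str, str]] = None,
    version: str = "0.1.0",
) -> Path:
    """One manifest per output directory: version, config hash, input
    checksums, seeds, timestamp."""
    out_dir = Path(out_dir)
    manifest = {
        "tool_version": version,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "input_checksums": inputs or {},
        "seeds": seeds,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return path
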