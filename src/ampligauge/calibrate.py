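"""Threshold calibration and coverage from leave-k-out results.

Predictions are scored per rank: true when predicted and reference taxa
match (or are synonymous), false when they differ or when the rank exists
only in the prediction; a rank absent from the prediction scores neither
way.  The false prediction rate is FPR = FP / (TP + FP).

Thresholds: TP/FP counts are binned by confidence into the 21 intervals
[0-4], [5-9], ..., [95-99], [100].  For a desired FPR e, each non-empty
bin gets the binomial probability of observing at most its TP true
predictions if the true FPR were e; scanning from the [100] bin downward,
the first bin with probability <= alpha (0.05) stops the scan and the bin
above it becomes the threshold — a conservative choice that holds even if
every prediction fell exactly at the threshold bin.  The final threshold
per desired FPR is the median over repeated leave-k-out runs (even counts
round to the larger, more conservative bin).

Coverage (on query reads): the fraction of sequences predicted at a rank
with confidence >= threshold, where the denominator excludes sequences
classified into parts of the hierarchy that omit the rank entirely, and
the numerator requires the thresholds of all coarser ranks to pass as well
(predictions confident at a fine rank but not at a coarser one carry high
error and are excluded).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import bdtr

from .errors import CalibrationError
from .lko import LkoRun
from .nbc import ClassificationResult
from .taxonomy import Rank, RankedLineage, SynonymMap, TaxonomyTree

#: lower bounds of the 21 confidence intervals
BIN_LOWER: tuple[int, ...] = tuple(range(0, 100, 5)) + (100,)
N_BINS = len(BIN_LOWER)

#: sentinel threshold when even the [100] bin cannot guarantee the FPR;
#: +inf orders above every attainable threshold, which the conservative
#: median relies on
UNATTAINABLE = math.inf

#: default grid of desired false-prediction rates (range 0.001-0.95)
DEFAULT_FPR_GRID: tuple[float, ...] = (
    0.001, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 0.75, 0.95,
)

Threshold = Union[int, float]  # int bin lower bound, or UNATTAINABLE

#: ranks evaluated for precision/coverage (domain is never scored)
EVAL_RANKS: tuple[Rank, ...] = (
    Rank.PHYLUM, Rank.CLASS, Rank.ORDER, Rank.FAMILY, Rank.GENUS,
)


class Outcome(enum.Enum):
    TP = "TP"
    FP = "FP"
    NEITHER = "NEITHER"


def bin_index(confidence: int) -> int:
    if not 0 <= confidence <= 100:
        raise CalibrationError(f"confidence {confidence} outside 0..100")
    return 20 if confidence == 100 else confidence // 5


def score_prediction(
    pred: ClassificationResult,
    ref: RankedLineage,
    rank: Rank,
    synonyms: Optional[SynonymMap] = None,
) -> Outcome:
    pred_name = pred.name_at(rank)
    if pred_name is None:
        return Outcome.NEITHER
    ref_name = ref.name_at(rank)
    if ref_name is None:
        # rank included only in the prediction: the sequence belongs to no
        # currently defined taxon at this rank
        return Outcome.FP
    synonyms = synonyms or SynonymMap()
    return Outcome.TP if synonyms.equivalent(pred_name, ref_name) else Outcome.FP


def fpr(tp: int, fp: int) -> Optional[float]:
    """FP / (TP + FP); None when no predictions were made at the rank."""
    total = tp + fp
    if total == 0:
        return None
    return fp / total


@dataclass
class ConfidenceHistogram:
    """Per-rank TP/FP counts over the 21 confidence intervals."""

    rank: Rank
    tp: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, dtype=np.int64))
    fp: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, dtype=np.int64))

    def add(self, outcome: Outcome, confidence: int) -> None:
        i = bin_index(confidence)
        if outcome is Outcome.TP:
            self.tp[i] += 1
        elif outcome is Outcome.FP:
            self.fp[i] += 1


def bin_confidences(
    run: LkoRun,
    rank: Rank,
    synonyms: Optional[SynonymMap] = None,
) -> list[ConfidenceHistogram]:
    """One histogram per repeat; NEITHER outcomes are excluded."""
    hists = [ConfidenceHistogram(rank=rank) for _ in range(run.config.repeats)]
    for rec in run.records:
        if rec.result.failed:
            continue
        outcome = score_prediction(rec.result, rec.reference, rank, synonyms)
        if outcome is Outcome.NEITHER:
            continue
        conf = rec.result.confidence_at(rank)
        hists[rec.repeat].add(outcome, conf)
    return hists


@dataclass(frozen=True)
class ThresholdRequest:
    e: float  # desired FPR
    alpha: float = 0.05
    rank: Optional[Rank] = None

    def __post_init__(self) -> None:
        if not 0 < self.e < 1:
            raise CalibrationError(f"desired FPR must be in (0,1), got {self.e}")


def pick_threshold(hist: ConfidenceHistogram, req: ThresholdRequest) -> Threshold:
    """Conservative confidence threshold for one histogram.

    Bins with no predictions carry no evidence and are skipped.  Returns a
    bin lower bound in {0,5,...,95,100}, or UNATTAINABLE when the [100]
    bin itself fails the binomial criterion.
    """
    for i in range(N_BINS - 1, -1, -1):
        n = int(hist.tp[i] + hist.fp[i])
        if n == 0:
            continue
        p = bdtr(int(hist.tp[i]), n, 1.0 - req.e)
        if p <= req.alpha:
            return UNATTAINABLE if i == N_BINS - 1 else BIN_LOWER[i + 1]
    return 0


def median_threshold(cts: Sequence[Threshold]) -> Threshold:
    """Median over repeats; UNATTAINABLE sorts above 100, and even counts
    take the larger middle value (the conservative choice)."""
    if not cts:
        raise CalibrationError("median_threshold of an empty list")
    ordered = sorted(cts)
    return ordered[len(ordered) // 2]


@dataclass(frozen=True)
class ThresholdEntry:
    rank: Rank
    e: float
    ct: Threshold
    low_count: bool
    per_repeat: tuple[Threshold, ...]


@dataclass
class ThresholdTable:
    entries: dict[tuple[Rank, float], ThresholdEntry]
    alpha: float
    e_grid: tuple[float, ...]

    def ct(self, rank: Rank, e: float) -> Threshold:
        return self.entries[(rank, e)].ct

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": ent.rank.label,
                "desired_fpr": ent.e,
                "confidence_threshold": format_threshold(ent.ct),
                "low_count": ent.low_count,
            }
            for ent in self.entries.values()
        ]
        return pd.DataFrame(
            rows, columns=["rank", "desired_fpr", "confidence_threshold", "low_count"]
        )


def format_threshold(ct: Threshold) -> str:
    return "unattainable" if ct == UNATTAINABLE else str(int(ct))


def parse_threshold(text: str) -> Threshold:
    return UNATTAINABLE if text == "unattainable" else int(text)


def calibrate_thresholds(
    run: LkoRun,
    e_grid: Sequence[float] = DEFAULT_FPR_GRID,
    alpha: float = 0.05,
    ranks: Sequence[Rank] = EVAL_RANKS,
    synonyms: Optional[SynonymMap] = None,
) -> ThresholdTable:
    """Per-(rank, desired FPR) thresholds: per-repeat binomial selection,
    then the conservative median across repeats.  The low-count flag marks
    thresholds whose own interval held fewer than 10 predictions (median
    across repeats) — too little evidence to trust the calibration."""
    entries: dict[tuple[Rank, float], ThresholdEntry] = {}
    for rank in ranks:
        hists = bin_confidences(run, rank, synonyms)
        for e in e_grid:
            req = ThresholdRequest(e=e, alpha=alpha, rank=rank)
            per_repeat = tuple(pick_threshold(h, req) for h in hists)
            ct = median_threshold(per_repeat)
            low_count = False
            if ct != UNATTAINABLE:
                i = bin_index(int(ct))
                counts = [int(h.tp[i] + h.fp[i]) for h in hists]
                low_count = median(counts) < 10
            entries[(rank, e)] = ThresholdEntry(
                rank=rank, e=e, ct=ct, low_count=low_count, per_repeat=per_repeat
            )
    return ThresholdTable(entries=entries, alpha=alpha, e_grid=tuple(e_grid))


# ---------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class CoverageReport:
    rank: Rank
    ct: Threshold
    n: int  # predictions at rank passing ct and all coarser thresholds
    s: int  # sequences with any prediction
    gap_excluded: int  # sequences whose predicted lineage omits the rank
    inconsistent_excluded: int  # passed ct but failed a coarser threshold
    value: float


def coverage(
    results: Sequence[ClassificationResult],
    rank: Rank,
    ct: Threshold,
    tree: Optional[TaxonomyTree] = None,
    thresholds_above: Optional[Mapping[Rank, Threshold]] = None,
) -> CoverageReport:
    """Gap-corrected coverage with the rank-consistency exclusion.

    The ``tree`` parameter is accepted for symmetry with callers that hold
    one, but gap detection reads directly off each predicted lineage: the
    classifier always reports the winning genus's full path, so a missing
    rank in the prediction is exactly a hierarchy gap.
    """
    thresholds_above = thresholds_above or {}
    s = 0
    gap_excluded = 0
    n = 0
    inconsistent = 0
    for res in results:
        if res.failed or not res.entries:
            continue
        s += 1
        conf = res.confidence_at(rank)
        if conf is None:
            gap_excluded += 1
            continue
        if ct == UNATTAINABLE or conf < ct:
            continue
        consistent = True
        for coarser, coarser_ct in thresholds_above.items():
            if coarser >= rank:
                continue
            coarser_conf = res.confidence_at(coarser)
            if coarser_conf is None:
                continue  # hierarchy omits the coarser rank on this path
            if coarser_ct == UNATTAINABLE or coarser_conf < coarser_ct:
                consistent = False
                break
        if consistent:
            n += 1
        else:
            inconsistent += 1
    denom = s - gap_excluded
    if denom <= 0:
        raise CalibrationError(
            f"coverage denominator is {denom} at rank {rank.label}"
        )
    return CoverageReport(
        rank=rank,
        ct=ct,
        n=n,
        s=s,
        gap_excluded=gap_excluded,
        inconsistent_excluded=inconsistent,
        value=n / denom,
    )


def restrict_to_ids(
    results: Sequence[ClassificationResult], ids: Iterable[str]
) -> list[ClassificationResult]:
    """Optional region-overlap restriction: keep only queries covered by
    every region under comparison (fair cross-region comparisons)."""
    keep = set(ids)
    return [r for r in results if r.query_id in keep]


def evaluate_coverage_grid(
    results: Sequence[ClassificationResult],
    table: ThresholdTable,
    ranks: Sequence[Rank] = EVAL_RANKS,
    tree: Optional[TaxonomyTree] = None,
) -> dict[tuple[Rank, float], CoverageReport]:
    """Coverage for every (rank, desired FPR) in a threshold table, with
    the rank-consistency rule applied using the same-e thresholds of all
    coarser ranks."""
    out: dict[tuple[Rank, float], CoverageReport] = {}
    for e in table.e_grid:
        cts = {rank: table.ct(rank, e) for rank in ranks if (rank, e) in table.entries}
        for rank in ranks:
            if (rank, e) not in table.entries:
                continue
            above = {r: c for r, c in cts.items() if r < rank}
            out[(rank, e)] = coverage(
                results, rank, cts[rank], tree=tree, thresholds_above=above
            )
    return out


# ---------------------------------------------------------------------------
# Summary tables and the FPR-vs-coverage curve

SUMMARY_COLUMNS = [
    "configuration",
    "rank",
    "confidence",
    "Interval_TP",
    "Interval_FP",
    "Interval_precision",
    "Interval_FPR",
    "threshold_for_FPR",
    "Env_coverage",
    "Cumulative_TP",
    "Cumulative_FP",
    "Cumulative_precision",
    "Cumulative_FPR",
]


def write_summary(
    run: LkoRun,
    thresholds: Optional[ThresholdTable] = None,
    env_results: Optional[Sequence[ClassificationResult]] = None,
    configuration: str = "",
    ranks: Sequence[Rank] = EVAL_RANKS,
    synonyms: Optional[SynonymMap] = None,
    path=None,
) -> pd.DataFrame:
    """Per-(rank, confidence-interval) summary: median interval TP/FP over
    repeats, interval and cumulative precision/FPR (percent), thresholds
    marked with the desired FPRs they serve, and coverage of the query set
    at each confidence value."""
    rows = []
    if not run.records:
        frame = pd.DataFrame(columns=SUMMARY_COLUMNS)
        if path is not None:
            frame.to_csv(path, sep="\t", index=False)
        return frame
    for rank in ranks:
        hists = bin_confidences(run, rank, synonyms)
        tp_med = np.median([h.tp for h in hists], axis=0) if hists else np.zeros(N_BINS)
        fp_med = np.median([h.fp for h in hists], axis=0) if hists else np.zeros(N_BINS)
        cum_tp = np.cumsum(tp_med[::-1])[::-1]
        cum_fp = np.cumsum(fp_med[::-1])[::-1]
        marks: dict[int, list[float]] = {}
        if thresholds is not None:
            for (r, e), ent in thresholds.entries.items():
                if r is rank and ent.ct != UNATTAINABLE:
                    marks.setdefault(bin_index(int(ent.ct)), []).append(e)
        for i, c in enumerate(BIN_LOWER):
            itp, ifp = float(tp_med[i]), float(fp_med[i])
            i_fpr = fpr(itp, ifp)
            c_fpr = fpr(float(cum_tp[i]), float(cum_fp[i]))
            env_cov = ""
            if env_results is not None:
                try:
                    env_cov = round(100 * coverage(env_results, rank, c).value, 2)
                except CalibrationError:
                    env_cov = ""
            rows.append(
                {
                    "configuration": configuration,
                    "rank": rank.label,
                    "confidence": c,
                    "Interval_TP": itp,
                    "Interval_FP": ifp,
                    "Interval_precision": "" if i_fpr is None else round(100 * (1 - i_fpr), 2),
                    "Interval_FPR": "" if i_fpr is None else round(100 * i_fpr, 2),
                    "threshold_for_FPR": ",".join(
                        str(e) for e in sorted(marks.get(i, []))
                    ),
                    "Env_coverage": env_cov,
                    "Cumulative_TP": float(cum_tp[i]),
                    "Cumulative_FP": float(cum_fp[i]),
                    "Cumulative_precision": "" if c_fpr is None else round(100 * (1 - c_fpr), 2),
                    "Cumulative_FPR": "" if c_fpr is None else round(100 * c_fpr, 2),
                }
            )
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def fpr_coverage_curve(
    thresholds: ThresholdTable,
    coverages: Mapping[tuple[Rank, float], CoverageReport],
    ranks: Sequence[Rank] = EVAL_RANKS,
) -> pd.DataFrame:
    """Pairs (desired FPR, coverage at its threshold) per rank, truncated
    after the first point where the threshold reaches 0 (beyond it the
    curve is flat).  Unattainable thresholds contribute zero coverage."""
    rows = []
    for rank in ranks:
        done = False
        for e in thresholds.e_grid:
            if done or (rank, e) not in thresholds.entries:
                continue
            ct = thresholds.ct(rank, e)
            if ct == UNATTAINABLE:
                value = 0.0
            else:
                value = coverages[(rank, e)].value
            rows.append(
                {
                    "rank": rank.label,
                    "desired_fpr": e,
                    "confidence_threshold": format_threshold(ct),
                    "coverage": value,
                }
            )
            if ct == 0:
                done = True
    return pd.DataFrame(
        rows, columns=["rank", "desired_fpr", "confidence_threshold", "coverage"]
    )


def plot_fpr_coverage(curve: pd.DataFrame, path) -> None:
    """Plain desired-FPR vs coverage plot, one line per rank."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for rank, grp in curve.groupby("rank", sort=False):
        ax.plot(grp["desired_fpr"], grp["coverage"], marker="o", label=rank)
    ax.set_xlabel("desired FPR")
    ax.set_ylabel("coverage")
    ax.set_xscale("log")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
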