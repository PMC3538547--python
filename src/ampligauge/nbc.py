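"""Word-based naïve Bayesian taxonomic classifier with bootstrap confidence.

The classifier assigns a query to the genus G maximising the joint
log-probability of the query's distinct valid 8-mers w:

    score(G) = sum_w log p(w|G),
    p(w|G)   = (m(w) + P(w)) / (M + 1),
    P(w)     = (n(w) + 0.5) / (N + 1),

where m(w) is the number of training sequences of genus G containing w,
M the number of training sequences of G, n(w) the number of training
sequences (overall) containing w, and N the total number of training
sequences.  Bootstrap confidence resamples floor(W/8) (minimum 1) of the
W distinct words with replacement, re-runs the argmax, and reports per
taxon the percentage of trials whose winning genus lies under that taxon
— so confidence at a parent taxon is always at least that of any child.

Words containing non-ACGT characters (including the N-spacer of fused
paired reads) are skipped; U is read as T.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .errors import ClassifierError
from .readsim import SimRead
from .taxonomy import Rank, RankedLineage, TrainingSet, trim_to_genus

DEFAULT_WORD_SIZE = 8
#: bootstrap subsample is one word per this many distinct words
BOOTSTRAP_WORD_FRACTION = 8

_U_TO_T = str.maketrans("Uu", "Tt")
_VALID = frozenset("ACGT")

MODEL_FORMAT_VERSION = 1


def extract_words(sequence: str, word_size: int = DEFAULT_WORD_SIZE) -> set[str]:
    """Distinct valid words (k-mers over ACGT, U read as T) of a sequence."""
    seq = sequence.upper().translate(_U_TO_T)
    words = set()
    for i in range(len(seq) - word_size + 1):
        w = seq[i : i + word_size]
        if _VALID.issuperset(w):
            words.add(w)
    return words


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ClassificationResult:
    """Per-rank predictions with integer bootstrap confidences (0-100).

    ``entries`` follows the winning genus's lineage; ranks the hierarchy
    omits on that lineage are simply absent.  ``genus_trial_counts`` keeps
    the raw bootstrap tally (genus name -> number of winning trials) for
    auditability; it sums to the number of bootstrap iterations.
    """

    query_id: str
    entries: tuple[tuple[Rank, str, int], ...] = ()
    winning_genus: Optional[str] = None
    failed: bool = False
    reason: Optional[str] = None
    genus_trial_counts: Optional[dict[str, int]] = None

    def has_rank(self, rank: Rank) -> bool:
        return any(r is rank for r, _, _ in self.entries)

    def name_at(self, rank: Rank) -> Optional[str]:
        for r, name, _ in self.entries:
            if r is rank:
                return name
        return None

    def confidence_at(self, rank: Rank) -> Optional[int]:
        for r, _, conf in self.entries:
            if r is rank:
                return conf
        return None

    @property
    def lineage(self) -> RankedLineage:
        return RankedLineage(tuple((r, n) for r, n, _ in self.entries))


@dataclass
class WordModel:
    """Trained word-count model over genera.

    Counts are stored raw; log conditionals are formed per query from the
    query's own words, so incremental edits to the counts (as leave-k-out
    retraining performs) stay cheap.
    """

    word_size: int
    genera: tuple[str, ...]
    genus_word_counts: list[dict[str, int]]  # m(w) per genus
    genus_seq_counts: np.ndarray  # M per genus
    doc_freq: dict[str, int]  # n(w) over all training sequences
    n_sequences: int  # N
    genus_lineages: dict[str, RankedLineage]
    _genus_index: dict[str, int] = field(default_factory=dict, repr=False)
    _taxon_members: Optional[dict[tuple[Rank, str], np.ndarray]] = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if not self._genus_index:
            self._genus_index = {g: i for i, g in enumerate(self.genera)}

    def genus_index(self, genus: str) -> int:
        return self._genus_index[genus]

    def taxon_members(self) -> dict[tuple[Rank, str], np.ndarray]:
        """Map each taxon to the indices of genera whose lineage passes
        through it (used to aggregate bootstrap tallies up the hierarchy)."""
        if self._taxon_members is None:
            members: dict[tuple[Rank, str], list[int]] = {}
            for i, genus in enumerate(self.genera):
                for rank, name in self.genus_lineages[genus].entries:
                    members.setdefault((rank, name), []).append(i)
            self._taxon_members = {
                k: np.asarray(v, dtype=np.intp) for k, v in members.items()
            }
        return self._taxon_members

    # -- persistence (versioned JSON text) --------------------------------

    def to_json(self) -> str:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "word_size": self.word_size,
            "n_sequences": self.n_sequences,
            "genera": list(self.genera),
            "genus_seq_counts": [int(m) for m in self.genus_seq_counts],
            "genus_word_counts": self.genus_word_counts,
            "doc_freq": self.doc_freq,
            "genus_lineages": {
                g: {
                    "entries": [[r.label, n] for r, n in lin.entries],
                }
                for g, lin in self.genus_lineages.items()
            },
            "training_checksum": self.training_checksum(),
        }
        return json.dumps(payload)

    def training_checksum(self) -> str:
        blob = json.dumps(
            [self.n_sequences, sorted(self.doc_freq.items())], sort_keys=True
        )
        return f"{zlib.crc32(blob.encode()):08x}"

    @classmethod
    def from_json(cls, text: str) -> "WordModel":
        payload = json.loads(text)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ClassifierError(
                f"unsupported model format {payload.get('format_version')!r}"
            )
        lineages = {
            g: RankedLineage(
                tuple((Rank.from_label(r), n) for r, n in d["entries"])
            )
            for g, d in payload["genus_lineages"].items()
        }
        return cls(
            word_size=payload["word_size"],
            genera=tuple(payload["genera"]),
            genus_word_counts=[dict(d) for d in payload["genus_word_counts"]],
            genus_seq_counts=np.asarray(payload["genus_seq_counts"], dtype=np.int64),
            doc_freq=dict(payload["doc_freq"]),
            n_sequences=payload["n_sequences"],
            genus_lineages=lineages,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "WordModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train(
    ts: TrainingSet,
    word_size: int = DEFAULT_WORD_SIZE,
    word_sets: Optional[dict[str, set[str]]] = None,
) -> WordModel:
    """Train a :class:`WordModel` from a training set.

    Every record must carry a genus; sequences shorter than ``word_size``
    are an error.  ``word_sets`` may supply precomputed per-sequence word
    sets (leave-k-out retrains many models over the same sequences).
    """
    genera: list[str] = []
    genus_index: dict[str, int] = {}
    genus_word_counts: list[dict[str, int]] = []
    genus_seq_counts: list[int] = []
    doc_freq: dict[str, int] = {}
    genus_lineages: dict[str, RankedLineage] = {}

    for rec in ts.records:
        genus = rec.lineage.name_at(Rank.GENUS)
        if genus is None:
            raise ClassifierError(f"record {rec.id!r} has no genus annotation")
        if word_sets is not None:
            words = word_sets[rec.id]
        else:
            if len(rec.sequence) < word_size:
                raise ClassifierError(
                    f"sequence {rec.id!r} is shorter than word size {word_size}"
                )
            words = extract_words(rec.sequence, word_size)
        if not words and len(rec.sequence) < word_size:
            raise ClassifierError(
                f"sequence {rec.id!r} is shorter than word size {word_size}"
            )
        gi = genus_index.get(genus)
        if gi is None:
            gi = len(genera)
            genus_index[genus] = gi
            genera.append(genus)
            genus_word_counts.append({})
            genus_seq_counts.append(0)
            genus_lineages[genus] = trim_to_genus(rec.lineage)
        genus_seq_counts[gi] += 1
        counts = genus_word_counts[gi]
        for w in words:
            counts[w] = counts.get(w, 0) + 1
            doc_freq[w] = doc_freq.get(w, 0) + 1

    if not genera:
        raise ClassifierError("cannot train on an empty training set")
    return WordModel(
        word_size=word_size,
        genera=tuple(genera),
        genus_word_counts=genus_word_counts,
        genus_seq_counts=np.asarray(genus_seq_counts, dtype=np.int64),
        doc_freq=doc_freq,
        n_sequences=len(ts.records),
        genus_lineages=genus_lineages,
    )


def _word_log_likelihoods(model: WordModel, words: Sequence[str]) -> np.ndarray:
    """(G, W) matrix of log p(w|G) for the query's words."""
    n_genera = len(model.genera)
    priors = np.array(
        [
            (model.doc_freq.get(w, 0) + 0.5) / (model.n_sequences + 1)
            for w in words
        ]
    )
    m = np.empty((n_genera, len(words)), dtype=np.float64)
    for j, w in enumerate(words):
        m[:, j] = [gc.get(w, 0) for gc in model.genus_word_counts]
    log_denom = np.log(model.genus_seq_counts + 1).reshape(-1, 1)
    return np.log(m + priors) - log_denom


def _argmax_with_ties(scores: np.ndarray, rng: np.random.Generator) -> int:
    best = scores.max()
    tied = np.flatnonzero(scores >= best)
    if len(tied) == 1:
        return int(tied[0])
    return int(rng.choice(tied))


def classify(
    query: Union[SimRead, str],
    model: WordModel,
    bootstrap_iters: int = 100,
    seed: int = 0,
    query_id: Optional[str] = None,
) -> ClassificationResult:
    """Classify one read, returning per-rank predictions with confidences.

    The point assignment uses all distinct valid words; each bootstrap
    trial redraws floor(W/8) (>=1) words with replacement.  Equal-scoring
    genera are broken uniformly at random under the seeded stream, so the
    result is bit-identical across runs for a given seed.
    """
    if isinstance(query, SimRead):
        sequence, qid = query.sequence, query.id
    else:
        sequence, qid = query, query_id or "query"
    if bootstrap_iters < 1:
        raise ClassifierError("bootstrap_iters must be >= 1")

    words = sorted(extract_words(sequence, model.word_size))
    if not words:
        return ClassificationResult(
            query_id=qid, failed=True, reason="no valid words"
        )

    rng = np.random.default_rng(seed)
    loglik = _word_log_likelihoods(model, words)
    point_winner = _argmax_with_ties(loglik.sum(axis=1), rng)

    n_words = len(words)
    subsample = max(1, n_words // BOOTSTRAP_WORD_FRACTION)
    draws = rng.integers(0, n_words, size=(bootstrap_iters, subsample))
    counts = np.zeros((bootstrap_iters, n_words))
    np.add.at(counts, (np.arange(bootstrap_iters)[:, None], draws), 1.0)
    trial_scores = counts @ loglik.T  # (iters, G)

    best = trial_scores.max(axis=1)
    is_best = trial_scores >= best[:, None]
    winners = np.argmax(is_best, axis=1)
    multi = np.flatnonzero(is_best.sum(axis=1) > 1)
    for t in multi:
        winners[t] = rng.choice(np.flatnonzero(is_best[t]))

    tally = np.bincount(winners, minlength=len(model.genera))
    members = model.taxon_members()
    genus_name = model.genera[point_winner]
    lineage = model.genus_lineages[genus_name]
    entries = []
    for rank, name in lineage.entries:
        share = tally[members[(rank, name)]].sum() / bootstrap_iters
        entries.append((rank, name, _round_half_up(100.0 * share)))

    return ClassificationResult(
        query_id=qid,
        entries=tuple(entries),
        winning_genus=genus_name,
        genus_trial_counts={
            model.genera[i]: int(c) for i, c in enumerate(tally) if c
        },
    )


def derive_seed(base_seed: int, token: Union[int, str]) -> int:
    """Stable per-item seed below 2**31, permutation-invariant for string
    tokens (derived from content, not position)."""
    if isinstance(token, str):
        token = zlib.crc32(token.encode())
    mix = np.random.SeedSequence([int(base_seed), int(token)])
    return int(mix.generate_state(1)[0] % (2**31))


def classify_batch(
    queries: Iterable[Union[SimRead, tuple[str, str]]],
    model: WordModel,
    bootstrap_iters: int = 100,
    seed: int = 0,
) -> list[ClassificationResult]:
    """Classify many reads; per-query seeds derive from the query ID, so a
    permuted input yields the identically permuted output and failures are
    recorded per query rather than raised."""
    results = []
    for q in queries:
        read = q if isinstance(q, SimRead) else SimRead(id=q[0], sequence=q[1], mode="single-forward")
        results.append(
            classify(
                read,
                model,
                bootstrap_iters=bootstrap_iters,
                seed=derive_seed(seed, read.id),
            )
        )
    return results
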