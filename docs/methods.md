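# Methods

This note documents the models, procedures and numerical choices behind
`ampligauge`, and what its synthetic test conditions do and do not show
about real amplicon data.

## Scope and assumptions

The framework evaluates *best-case* study designs: amplification is
assumed ideal (primers universal, no bias — amplicons are excised by
alignment coordinates, not by primer search), and simulated reads carry
no sequencing errors or quality scores. Measured precision and coverage
are therefore upper bounds; real data adds error and filtering losses,
which affect paired-end designs more than single-end ones (a pair fails
QC if either mate does).

## Taxonomy model

Lineages are ordered (rank, name) pairs over domain → genus. Species is
metadata, not a rank: it exists only to drive leave-k-out exclusion, and
training taxonomies are trimmed to genus (the highest resolution
evaluated). Names are prefixed `rank__` so that predicted paths remain
rank-decodable and a name used at two levels (which happens in real
bacterial taxonomies) stays unambiguous. Components beginning with
"unclassified" or ending with "incertae_sedis" are dropped during
normalization — they are placeholders, not taxa. Hierarchies may omit
ranks (e.g. a phylum with no defined classes); such gaps make some ranks
unpredictable for sequences classified beneath them, which the coverage
denominator corrects for.

Taxon comparison is exact, case-sensitive string match after prefix
stripping; an optional user-supplied synonym map can declare
equivalences. Species identity for exclusion is exact match on the
normalized species name, with subspecies/strain suffixes stripped by a
configurable pattern.

## Amplicon extraction

Primer windows are 1-based inclusive alignment columns on a named
reference row. The window is widened by one column per side before the
inclusion test — a row is kept only if its sequence starts at/before the
widened first column and ends at/after the widened last column — then
the flanking columns are stripped and the remaining columns degapped.
If the widened window would leave the alignment, it is clamped to the
boundary with a warning (otherwise amplicons at the alignment edge would
be impossible). Length filtration defaults to keeping amplicons within
50–150% of the median length; the band is configurable and the removal
fraction is always reported.

## Read construction

Single reads are the literal first (forward) or last (reverse) X bases;
reverse reads are *not* reverse-complemented by default (training uses
the same convention, so the classifier sees a consistent strand), with a
`revcomp` switch available. Paired reads fuse the first and last X bases
around ten N's; amplicons ≤ 2X pass through unchanged. The spacer
position is recorded on the read, so the ambiguity filter (> 10
non-ACGT/U characters ⇒ drop) excludes it by construction rather than by
pattern matching, and classifier words overlapping it are invalid anyway
(they contain N). Read direction per region is configuration, not
auto-optimized. The same operations trim training sequences to the
region being classified (`trim_training_set`).

## Classifier

Word size 8, distinct words only, U read as T. Training counts, per
genus G, the number of sequences containing each word (m(w)), the genus
sequence count M, the overall per-word document frequency n(w), and the
total sequence count N. Scores use

    P(w)   = (n(w) + 0.5) / (N + 1)
    p(w|G) = (m(w) + P(w)) / (M + 1)
    score(G) = Σ_w log p(w|G)

Bootstrap trials redraw ⌊W/8⌋ (minimum 1) of the W distinct words with
replacement and re-run the argmax; confidence at a taxon is the
percentage of trials whose winning genus lies beneath it, rounded half
up to an integer — hence parent confidence ≥ any child's, and the genus
tally sums to the trial count. Numerical choices: equal-scoring genera
are broken uniformly at random under the seeded stream (deterministic
per seed); a query with no valid word is recorded as a failure, not an
exception. Per-query seeds in batch classification derive from the
query ID (CRC32 mixed into a seed sequence), so results are independent
of input order and stable under parallel execution.

## Leave-k-out

An exclusion table relates each test sequence to all same-species
training sequences. Tests whose species is absent from training are
classified in one batch against the unmodified (non-redundant) set.
Redundancy removal clusters sequences at 100% identity — implemented as
exact string equality, which counts every mismatch and gap — and keeps,
per cluster, one representative per genus (first in input order, a
deterministic stand-in for an unspecified external tool's behaviour).
For each excluded species the non-redundant set is rebuilt from the
remaining sequences using the precomputed clusters, so a genus's other
species re-enter the representative slot when the excluded sequence held
it; the test is strict about species, never accidentally strict about
genera. Repeats differ only in bootstrap seeds — nothing else in the
procedure is stochastic. Each run record keeps the effective training ID
set, making the no-species-overlap invariant auditable after the fact.

## Calibration

Confidence intervals are [0–4], [5–9], …, [95–99] and the single-value
interval [100]. For desired FPR e, each non-empty bin gets
`p = BinomialCDF(TP; TP+FP, 1−e)` — the probability of at most TP true
predictions if the true FPR were exactly e. Scanning from [100]
downward, the first bin with p ≤ α (default 0.05) stops the scan and the
bin above it is the threshold; this is conservative even if every
accepted prediction fell exactly at the threshold bin. If no bin fails
the threshold is 0; if [100] itself fails the target is unattainable
(represented as +∞ so it orders above every threshold). Bins with no
predictions are skipped: the binomial test is undefined at n = 0 and an
empty bin is absence of evidence, not failure. The final threshold per
(rank, e) is the median over repeats, with even counts rounded to the
*larger* middle value — again the conservative direction. Thresholds
whose own interval held fewer than 10 predictions (median over repeats)
are flagged low-count. The default FPR grid is
{0.001, 0.005, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 0.75,
0.95}; only the range was externally fixed, the grid is configurable.

Scoring: a prediction at rank R is true when both prediction and
reference carry R and the names match (or are synonymous); false when
the names differ *or* R appears only in the prediction; when R is absent
from the prediction it counts neither way (it still counts in coverage
denominators).

## Coverage

Coverage at rank R and threshold c is n / (S − gaps): n counts sequences
predicted at R with confidence ≥ c that also pass the thresholds of all
coarser ranks (a sequence confident at genus but not at phylum is more
often wrong than right, so it is excluded and tallied); S counts
sequences with any prediction; gaps counts sequences whose predicted
lineage sits where the hierarchy omits R. An optional ID-intersection
filter restricts scoring to queries covered by every region under
comparison, for fair cross-region curves. The FPR-vs-coverage curve
pairs each desired FPR with the coverage at its threshold and is
truncated after the threshold first reaches 0 (beyond that the curve is
flat by construction); unattainable thresholds contribute zero coverage.

## Two-region combination

For a query classified in regions A and B, R is the deepest rank both
predict; the full path of the higher-confidence prediction at R is
copied. Equal confidence with different taxa at R discards the query;
equal confidence with the same taxon keeps A's path (order-stable given
fixed region labels — externally unspecified, decided here). Queries
covering only one region are skipped.

## Synthetic data generator

The generator emulates the statistical structure the framework consumes:
a balanced ranked hierarchy, optionally with a fraction of genera
attached directly under their class (omitting order and family, which
exercises the coverage gap correction); sequences evolved from a root by
per-site uniform substitution along lineage edges (edge rates, as
multiples of the between-genus divergence d: phylum 1.0, class 0.5,
order 0.25, family 0.25, genus 1.0; species 0.2·d, sequence copies and
queries 0.05·d); designated confusable genus pairs whose ancestors
differ at a small rate q — the knob for classification difficulty;
insertion events that create gapped alignment columns carried by one
genus. Defaults (d = 0.10, 250–300 nt sequences, 2–3 species per genus,
2 sequences per species) give well-separated genera with realistic
within-genus redundancy at the scale a desk-top evaluation can afford;
test and acceptance runs state their sizes explicitly (up to 200
species × 2 sequences for the exclusion audit, 10 genera × 3 species ×
2 sequences with three confusable pairs for the calibration recovery).

This process is deliberately not a biological model: no rate
heterogeneity, secondary structure, GC bias or chimeras. Passing tests
demonstrate that the machinery — exclusion, dedup, binomial calibration,
gap correction — behaves correctly and that calibrated thresholds
control held-out error *under these conditions*; they do not predict the
absolute precision or coverage of any real region/primer/training-set
combination, which depends on real databases and error profiles.

## Determinism

Every stochastic step flows from one base seed through named seed
derivations (repeat index, query ID, stage label), all below 2^31.
Pipeline reruns with an identical configuration are byte-identical and
are served from cache when the config hash matches the run manifest.

## Known limitations

- Primer matching, thermodynamics and amplification bias are out of
  scope; primers are alignment coordinates.
- The classifier implements the standard word-bootstrap algorithm with
  explicit choices for details its descriptions leave open (tie-breaks,
  rounding, subsample size floor); other implementations may differ at
  the margin.
- Coverage gap detection reads off the predicted lineage (the classifier
  always reports the winning genus's full path), which is equivalent to
  consulting the hierarchy; a classifier that truncated paths would need
  the tree-based variant (`ranks_omitted_below`).
- The unattainable-threshold sentinel participates in medians as +∞;
  a mixed repeat set therefore resolves to a finite threshold only when
  more than half the repeats found one — intended, but worth knowing.
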