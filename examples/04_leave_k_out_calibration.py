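"""Calibrate rank-specific confidence thresholds for a target error rate.

A species-exclusion leave-k-out experiment scores each prediction true or
false per rank; the binomial procedure then picks, for each desired false
prediction rate, the lowest confidence threshold that guarantees it.  Two
of the genera are nearly identical, so the genus threshold is pushed up
while coarser ranks stay permissive.
"""

from ampligauge import (
    FixtureSpec,
    LkoConfig,
    ReadConfig,
    Rank,
    calibrate_thresholds,
    gen_alignment,
    run_lko,
    trim_training_set,
)
from ampligauge.calibrate import format_threshold

spec = FixtureSpec(
    n_phyla=2,
    genera_per_family=5,
    species_per_genus=3,
    seqs_per_species=2,
    seq_len=250,
    confusable_pairs=(("G02", "G03"), ("G06", "G07")),
    confusable_divergence=0.004,
    seed=42,
)
_, reference = gen_alignment(spec)
reads = trim_training_set(reference, ReadConfig(x=100, mode="single-forward"))
run = run_lko(reads, reads, cfg=LkoConfig(repeats=10, bootstrap_iters=100, base_seed=7))
table = calibrate_thresholds(run)

print("rank      CT@1%  CT@5%  CT@10%")
for rank in (Rank.PHYLUM, Rank.FAMILY, Rank.GENUS):
    cts = [format_threshold(table.ct(rank, e)) for e in (0.01, 0.05, 0.10)]
    print(f"{rank.label:<9} {cts[0]:>5} {cts[1]:>6} {cts[2]:>7}")
# a genus threshold of 95-100 at 5% desired FPR means only near-unanimous
# bootstrap calls are trustworthy there, while family and phylum can accept
# every prediction (threshold 0) at the same error budget.
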