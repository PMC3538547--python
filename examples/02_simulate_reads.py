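"""Build single and fused paired-end reads from an amplicon.

A paired read of length X fuses the first and last X bases around a run of
ten N's; an amplicon no longer than 2X is used unchanged because the two
reads would overlap and reconstruct it.  Reads with more than ten
ambiguous characters (spacer excluded) are filtered out.
"""

from ampligauge import ReadConfig, ambiguity_filter, make_paired_read, make_single_read

amplicon = "ACGT" * 62 + "GT"  # 250 nt

fwd = make_single_read(amplicon, ReadConfig(x=100, mode="single-forward"), "demo")
pair = make_paired_read(amplicon, ReadConfig(x=100, mode="paired"), "demo")
print(f"forward read: {len(fwd.sequence)} nt (first 100 bases)")
print(f"paired read:  {len(pair.sequence)} nt, spacer at {pair.spacer_span}")
print(f"spacer run:   {pair.sequence[100:110]}")

kept, removed = ambiguity_filter([pair], ReadConfig(x=100, mode="paired"))
print(f"after ambiguity filter: kept {len(kept)}, removed {len(removed)}")
# the ten spacer N's are excluded from the ambiguity count by construction,
# so a clean paired read always survives the filter.
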