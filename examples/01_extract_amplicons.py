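"""Excise in-silico amplicons for a primer window from a small alignment.

Primers are located by alignment columns on a reference row; a row only
yields an amplicon when it spans one column beyond the window on each side
(so insertions adjacent to the primers are never silently lost).
"""

from ampligauge import AlignedSet, PrimerWindow, extract_amplicons

msa = AlignedSet.from_rows(
    [
        ("ref", "ACGTACGTACGTACGTACGT"),
        ("full", "ACGAACGTAC--ACGTACGT"),  # internal deletion
        ("late", "------GTACGTACGTACGT"),  # starts inside the window
    ]
)
window = PrimerWindow(reference_id="ref", first_col=5, last_col=16)
amps = extract_amplicons(msa, window)

for seq_id, seq in amps.amplicons:
    print(f"{seq_id}\t{seq}\t({len(seq)} nt)")
for seq_id, reason in amps.excluded:
    print(f"{seq_id}\texcluded: {reason}")

# 'ref' and 'full' yield degapped amplicons from columns 5..16; 'late'
# is excluded because its sequence begins after the widened window start,
# so we cannot know whether it truly covers the amplified region.
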