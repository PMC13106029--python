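"""Predict host targets of a fungal sRNA and call cleavability.

Scores every transcript window with the plant-miRNA penalty scheme (mismatch
1, G:U wobble 0.5, gap 2, doubled at sRNA positions 2-12) and keeps sites with
score <= 4.5 and duplex free-energy ratio >= 0.7.  A G:U wobble opposite sRNA
positions 10-11 leaves a site bound but blocks AGO-mediated slicing.
"""

from ckrna import FastaRecord, predict_targets, revcomp, to_rna

srna = "TGAGGTAGTGGGTTGTATAGT"  # 21 nt, 5'-U after RNA folding
perfect = revcomp(srna)
wobbled = perfect[:11] + "T" + perfect[12:]  # G:U opposite sRNA position 10

transcripts = [
    FastaRecord("tx_perfect", "CGAT" * 20 + perfect + "TTGA" * 20),
    FastaRecord("tx_wobble", "AGGT" * 20 + wobbled + "CCTA" * 20),
    FastaRecord("tx_unrelated", "ACGTTGCA" * 40),
]

hits = predict_targets({"sRNA-1": srna}, transcripts)
print(f"sRNA {to_rna(srna)}: {len(hits)} predicted sites\n")
for h in hits:
    states = "".join({"WC": "|", "GU": "o", "MM": ".", "GAP": "-"}[s] for s in h.alignment.pair_states)
    print(f"{h.transcript_id}: site at {h.site_start}, score={h.score}, ratio={h.energy_ratio:.3f}")
    print(f"  sRNA 5'-{to_rna(srna)}-3'")
    print(f"        {states}   (| WC, o G:U wobble)")
    print(f"  cleavable={h.cleavable}" + (f", slice site at transcript pos {h.cleavage_pos}" if h.cleavable else " (wobble at 10-11 blocks slicing)"))
    print()

# The perfect site scores 0 with ratio 1.0 and is cleavable between the bases
# opposite sRNA positions 10/11; the wobbled site still binds (score 1.0) but
# is called non-cleavable; the unrelated transcript yields no hit.
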