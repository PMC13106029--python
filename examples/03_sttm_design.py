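"""Design a quadruple STTM construct and scrambled control sites.

A short tandem target mimic (STTM) sequesters an sRNA with a binding site that
carries a 3-nt bulge opposite sRNA positions 10-11: the duplex still forms but
cannot be sliced, so the sRNA is titrated away.  Scrambled controls permute a
target site's bases so composition is preserved but recognition is lost.
"""

from ckrna import design_sttm, revcomp, scramble_site, to_rna
from ckrna.targets import align_duplex, score_alignment

srnas = {
    "sRNA-8": "TAAGGTCGTTTGGCAATCGTA",
    "sRNA-11": "TGCGATCCGGATTACTTGGAT",
    "sRNA-15": "TGCGATCCGGATAACTTGGAT",  # single-nucleotide variant of sRNA-11
    "sRNA-23": "TTGACCGGTACGTTAACGGTA",
}

construct = design_sttm(srnas)
print(f"quadruple STTM: {len(construct.mimics)} mimic sites, {len(construct.sequence)} nt total")
for v in construct.validation:
    print(
        f"  {v['srna_id']}: mimic {to_rna(v['mimic'])} "
        f"binding_score={v['binding_score']} cleavable={v['cleavable']}"
    )
print(f"construct 5'->3':\n{to_rna(construct.sequence)}\n")

site = revcomp(srnas["sRNA-8"])
scrambled = scramble_site(site, seed=1, cognate_srna=srnas["sRNA-8"])
print(f"target site      {to_rna(site)}  score={score_alignment(align_duplex(srnas['sRNA-8'], site))}")
print(f"scrambled (rs)   {to_rna(scrambled)}  score={score_alignment(align_duplex(srnas['sRNA-8'], scrambled))}")

# Every mimic binds its sRNA perfectly outside the bulge (score 0) yet is
# non-cleavable; the scrambled site keeps the base composition but its
# alignment score rises far above the 4.5 reporting cutoff.
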