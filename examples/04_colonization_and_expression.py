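"""Quantify mycorrhizal colonization (Trouvelot) and gene expression (ddCt).

Root fragments are scored under the microscope with an ordinal colonization
intensity (0-5) and arbuscule/vesicle abundance classes (0-3); the Trouvelot
indices summarize frequency (F%), intensity (M%), and arbuscule/vesicle
abundance (A%, V%) of the whole root system.  Relative transcript levels use
the plain 2^(-ddCt) method against a reference gene and control condition.
"""

from ckrna import FragmentScore, QpcrMeasurement, ddct_fold_change, trouvelot_indices

# 10 root fragments of an STTM-expressing root system: weak colonization
sttm_fragments = [
    FragmentScore("f1", 0, 0, 0), FragmentScore("f2", 1, 0, 0),
    FragmentScore("f3", 2, 1, 0), FragmentScore("f4", 0, 0, 0),
    FragmentScore("f5", 3, 1, 1), FragmentScore("f6", 1, 0, 0),
    FragmentScore("f7", 0, 0, 0), FragmentScore("f8", 2, 1, 0),
    FragmentScore("f9", 1, 1, 0), FragmentScore("f10", 0, 0, 0),
]
# matched empty-vector controls: strong colonization
ev_fragments = [
    FragmentScore("g1", 5, 3, 1), FragmentScore("g2", 4, 3, 2),
    FragmentScore("g3", 5, 2, 1), FragmentScore("g4", 3, 2, 0),
    FragmentScore("g5", 4, 3, 1), FragmentScore("g6", 5, 3, 2),
    FragmentScore("g7", 2, 1, 0), FragmentScore("g8", 4, 2, 1),
    FragmentScore("g9", 5, 3, 1), FragmentScore("g10", 3, 2, 1),
]

for label, frags in (("empty vector", ev_fragments), ("STTM", sttm_fragments)):
    r = trouvelot_indices(frags)
    print(f"{label:12s} F%={r.F_pct:5.1f}  M%={r.M_pct:5.2f}  A%={r.A_pct:5.2f}  V%={r.V_pct:5.2f}")

# sRNA target gene, measured against a reference gene in mock vs colonized roots
measurements = [
    QpcrMeasurement("m1", "defense_gene", "ubiquitin", 26.1, 21.0, "mock"),
    QpcrMeasurement("m2", "defense_gene", "ubiquitin", 25.9, 20.8, "mock"),
    QpcrMeasurement("a1", "defense_gene", "ubiquitin", 27.6, 21.1, "AM"),
    QpcrMeasurement("a2", "defense_gene", "ubiquitin", 27.4, 20.9, "AM"),
]
fold = ddct_fold_change(measurements, control_condition="mock")
print(f"\ndefense_gene fold change (AM vs mock): {fold['defense_gene']:.3f}")

# Colonization indices drop in STTM roots (the sequestered sRNAs can no longer
# silence host defence), and the defence transcript is ~3x lower in colonized
# roots than mock here (fold < 1 means silenced during symbiosis).
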