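"""The generator's manifest must be verifiable against the emitted artifacts
by independent scans, and everything must be a pure function of the seed."""

import json

import numpy as np
import pytest

from ckrna.seqio import revcomp
from ckrna.simulate import SimulationConfig, Simulator, simulate_world, write_world

TINY = dict(host_genome_bp=80_000, background_reads_per_library=20_000, fungus_genome_bp=60_000)


def test_config_validation():
    with pytest.raises(ValueError, match="25 RPM"):
        SimulationConfig(planted_rpm_range=(20.0, 100.0))
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(size_distribution={21: 0.5})
    with pytest.raises(ValueError, match="40,000"):
        SimulationConfig(fungal_reads_range=(5_000, 6_000))
    with pytest.raises(ValueError, match="genome too small"):
        simulate_world(SimulationConfig(seed=0, fungus_genome_bp=8_000, **{k: v for k, v in TINY.items() if k != "fungus_genome_bp"}))


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=5, **TINY)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    write_world(simulate_world(cfg), d1)
    write_world(simulate_world(cfg), d2)
    for name in ("host.fasta", "fungus.fasta", "fungus.gff3", "cds.fasta", "manifest.json", "AM_1.fastq", "mock_1.fastq"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_different_seeds_differ():
    w1 = simulate_world(SimulationConfig(seed=1, **TINY))
    w2 = simulate_world(SimulationConfig(seed=2, **TINY))
    assert w1.fungus.contigs[0].sequence != w2.fungus.contigs[0].sequence
    assert {p.sequence for p in w1.manifest.planted}.isdisjoint(
        {p.sequence for p in w2.manifest.planted}
    )


def test_tandem_repeat_family_has_four_copies(small_world):
    tandem = [f for f in small_world.fungus.features if f.subtype == "tandem"]
    assert len(tandem) == 4
    assert {f.name for f in tandem} == {"F1"}
    # the emitted genome really contains four identical unit copies
    g = small_world.fungus.contigs[0].sequence
    unit = g[tandem[0].start : tandem[0].end]
    assert sum(1 for f in tandem if g[f.start : f.end] == unit) == 4


def test_fungal_annotation_covers_every_feature_class(small_world):
    classes = {f.feature_class for f in small_world.fungus.features}
    assert classes == {"rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA"}
    subtypes = {f.subtype for f in small_world.fungus.features if f.feature_class == "repeat"}
    assert subtypes == {"transposon", "simple_inverted", "tandem"}


def test_planted_srnas_never_match_host_genome(small_world):
    host = small_world.host.contigs[0].sequence
    for p in small_world.manifest.planted:
        assert p.sequence not in host
        assert revcomp(p.sequence) not in host


def test_manifest_loci_verified_by_independent_scan(small_world):
    g = small_world.fungus.contigs[0].sequence
    for p in small_world.manifest.planted:
        found = []
        start = 0
        while True:
            i = g.find(p.sequence, start)
            if i < 0:
                break
            found.append(i)
            start = i + 1
        assert found == sorted(l.start for l in p.loci)
    pair = [p for p in small_world.manifest.planted if len(p.loci) == 4]
    assert len(pair) == 2
    a, b = (p.sequence for p in pair)
    assert len(a) == len(b)
    assert sum(x != y for x, y in zip(a, b)) == 1  # the single-nucleotide pair


def test_manifest_counts_match_emitted_libraries(small_world):
    libs = {l.sample_id: l for l in small_world.libraries}
    for p in small_world.manifest.planted:
        for lib in small_world.am_libraries:
            assert libs[lib.sample_id].reads[p.sequence] == p.counts[lib.sample_id]
            assert p.rpm[lib.sample_id] > 25.0
        for lib in small_world.mock_libraries:
            assert p.sequence not in libs[lib.sample_id].reads
    for d in small_world.manifest.decoys:
        for sid, c in d.am_counts.items():
            assert libs[sid].reads[d.sequence] == c
        for sid, c in d.mock_counts.items():
            assert libs[sid].reads[d.sequence] == c


def test_decoy_construction_matches_violated_filters(small_world):
    by_filter = {d.violated_filter: d for d in small_world.manifest.decoys}
    host = small_world.host.contigs[0].sequence
    fungus = small_world.fungus.contigs[0].sequence
    assert len(by_filter["size"].sequence) == 19
    assert not 21 <= len(by_filter["size"].sequence) <= 24
    assert by_filter["size"].sequence in fungus
    assert min(by_filter["rpm"].am_counts.values()) == 1
    assert sum(by_filter["present_in_mock"].mock_counts.values()) == 1
    nm = by_filter["no_perfect_fungal_match"].sequence
    assert nm not in fungus and revcomp(nm) not in fungus and nm not in host
    mh = by_filter["matches_host"].sequence
    assert mh in fungus and mh in host


def test_no_species_contains_the_adapter_seed(small_world):
    seed8 = small_world.config.adapter[:8]
    for lib in small_world.libraries:
        assert not any(seed8 in seq for seq in lib.reads)


def test_library_design_mock_vs_am(small_world):
    cfg = small_world.config
    assert len(small_world.am_libraries) == cfg.n_am
    assert len(small_world.mock_libraries) == cfg.n_mock
    f_lo, f_hi = cfg.fungal_reads_range
    for lib in small_world.am_libraries:
        total_f = small_world.manifest.fungal_totals[lib.sample_id]
        assert f_lo <= total_f <= f_hi
        assert lib.total_after_preprocess >= cfg.background_reads_per_library


def test_five_prime_u_bias_of_fungal_reads(small_world):
    """Read-weighted 5'-U fraction tracks the configured bias within 3 SDs
    (effective sample size corrected for species clustering)."""
    frac = small_world.config.five_prime_u_fraction
    host_reads = set()
    for lib in small_world.mock_libraries:
        host_reads.update(lib.reads)
    for lib in small_world.am_libraries:
        counts = np.array(
            [c for seq, c in lib.reads.items() if seq not in host_reads], dtype=float
        )
        useq = np.array(
            [seq[0] == "T" for seq, c in lib.reads.items() if seq not in host_reads], dtype=float
        )
        total = counts.sum()
        observed = (counts * useq).sum() / total
        n_eff = total**2 / (counts**2).sum()
        sd = np.sqrt(frac * (1 - frac) / n_eff)
        assert abs(observed - frac) < 3 * sd + 1e-3


def test_planted_target_designs(small_world):
    designs = [t.design for t in small_world.manifest.planted_targets]
    n = len(small_world.manifest.planted)
    for d in ("perfect", "sub_cutoff", "wobble_10_11", "non_target"):
        assert designs.count(d) == n
    tx = {r.id: r.sequence for r in small_world.transcripts}
    for t in small_world.manifest.planted_targets:
        assert tx[t.transcript_id][t.position : t.position + len(t.site)] == t.site
        if t.design == "perfect":
            srna = next(p.sequence for p in small_world.manifest.planted if p.srna_id == t.srna_id)
            assert t.site == revcomp(srna)


def test_sequencing_errors_never_rescue_filters():
    cfg = SimulationConfig(seed=3, error_rate=0.001, **TINY)
    w = simulate_world(cfg)
    for lib in w.am_libraries:
        assert lib.total_after_preprocess > 0
        assert all(c >= 1 for c in lib.reads.values())
    # errored copies are singleton variants: totals are conserved per library
    w0 = simulate_world(SimulationConfig(seed=3, error_rate=0.0, **TINY))
    for l0, l1 in zip(w0.libraries, w.libraries):
        assert l0.total_after_preprocess == l1.total_after_preprocess


def test_manifest_json_round_trip(tmp_path, small_world):
    path = tmp_path / "manifest.json"
    small_world.manifest.write_json(path)
    data = json.loads(path.read_text())
    assert data["seed"] == small_world.config.seed
    assert len(data["planted"]) == small_world.config.n_planted_ck_srnas
    assert {d["violated_filter"] for d in data["decoys"]} == set(small_world.config.decoys)
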