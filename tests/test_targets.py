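"""Duplex alignment, scoring, energy ratio, cleavage, STTM and scrambling."""

import numpy as np
import pytest

from ckrna.seqio import revcomp
from ckrna.targets import (
    DEFAULT_ENERGY_MODEL,
    WC_STACK,
    EnergyModel,
    _encode,
    _ungapped,
    _window_scores,
    align_duplex,
    call_cleavage,
    design_sttm,
    duplex_energy,
    energy_ratio,
    enumerate_alignments,
    perfect_site,
    predict_targets,
    score_alignment,
    scramble_site,
    sttm_mimic,
)

from .oracles import oracle_best_score


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _site_with_mm(srna, site, i):
    k = len(srna) - i
    return site[:k] + srna[i - 1] + site[k + 1 :]


def _site_with_gu(srna, site, i):
    k = len(srna) - i
    return site[:k] + {"G": "T", "T": "G"}[srna[i - 1]] + site[k + 1 :]


@pytest.fixture
def srna21():
    # fixed 21-mer with G/T available at positions used in the edits below
    return "TGAGGTAGTGGGTTGTATAGT"


# ---------------------------------------------------------------------------
# alignment + scoring closed forms

def test_perfect_duplex_scores_zero(srna21):
    aln = align_duplex(srna21, perfect_site(srna21))
    assert score_alignment(aln) == 0.0
    assert set(aln.pair_states) == {"WC"}
    assert aln.n_gaps == 0


def test_single_gu_outside_seed_scores_half(srna21):
    site = _site_with_gu(srna21, perfect_site(srna21), 15)
    aln = align_duplex(srna21, site)
    assert score_alignment(aln) == 0.5
    assert aln.pair_states[14] == "GU"


def test_single_seed_mismatch_scores_two(srna21):
    site = _site_with_mm(srna21, perfect_site(srna21), 5)
    aln = align_duplex(srna21, site)
    assert score_alignment(aln) == 2.0
    assert aln.pair_states[4] == "MM"


def test_gu_detection_is_positionally_correct(srna21):
    # sRNA G across from site T and sRNA U(T) across from site G both wobble
    for i in (2, 6, 10):
        if srna21[i - 1] in "GT":
            site = _site_with_gu(srna21, perfect_site(srna21), i)
            aln = align_duplex(srna21, site)
            assert aln.pair_states[i - 1] == "GU"
            assert score_alignment(aln) == 1.0  # 0.5 doubled in the 2-12 region


def test_alignment_length_contracts(srna21):
    with pytest.raises(ValueError):
        align_duplex(srna21, "ACGT")
    with pytest.raises(ValueError):
        enumerate_alignments(srna21, perfect_site(srna21) + "AC")


def test_align_duplex_matches_exhaustive_oracle():
    rng = np.random.default_rng(123)
    for _ in range(80):
        n = int(rng.integers(16, 29))
        srna = _rand_seq(rng, n)
        base = perfect_site(srna) if rng.random() < 0.5 else _rand_seq(rng, n)
        m = n + int(rng.integers(-1, 2))
        if len(base) > m:
            site = base[: m]
        elif len(base) < m:
            site = base + _rand_seq(rng, m - len(base))
        else:
            site = base
        # sprinkle random edits
        site = list(site)
        for _ in range(int(rng.integers(0, 4))):
            site[int(rng.integers(0, m))] = str(rng.choice(list("ACGT")))
        site = "".join(site)
        got = score_alignment(align_duplex(srna, site))
        assert got == pytest.approx(oracle_best_score(srna, site)), (srna, site)


def test_stored_alignment_rescores_identically(srna21):
    rng = np.random.default_rng(9)
    for _ in range(20):
        site = _rand_seq(rng, 21 + int(rng.integers(-1, 2)))
        aln = align_duplex(srna21, site)
        assert score_alignment(aln) == score_alignment(align_duplex(aln.srna, aln.site))


def test_window_scan_agrees_with_per_window_alignment(srna21):
    rng = np.random.default_rng(77)
    tx = _rand_seq(rng, 150) + perfect_site(srna21) + _rand_seq(rng, 60)
    codes = _encode(tx)
    for m, scores in _window_scores(srna21, codes).items():
        for t in range(0, len(tx) - m + 1, 7):
            direct = score_alignment(align_duplex(srna21, tx[t : t + m]))
            assert scores[t] == pytest.approx(direct), (m, t)


# ---------------------------------------------------------------------------
# energy model

def test_perfect_duplex_energy_equals_hand_summed_stacks(srna21):
    aln = _ungapped(srna21, perfect_site(srna21))
    hand = sum(WC_STACK[srna21[i : i + 2]] for i in range(len(srna21) - 1))
    assert duplex_energy(aln) == pytest.approx(hand)
    assert duplex_energy(aln) < 0


def test_unpaired_alignment_energy_is_initiation_only(srna21):
    site = srna21[::-1]  # every position faces its own base: all mismatches
    aln = _ungapped(srna21, site)
    assert set(aln.pair_states) == {"MM"}
    model = EnergyModel(initiation=4.09)
    assert duplex_energy(aln, model) == pytest.approx(4.09)
    assert duplex_energy(aln) == pytest.approx(0.0)


def test_any_single_edit_strictly_weakens_the_duplex():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        srna = _rand_seq(rng, int(rng.integers(18, 25)))
        perfect = perfect_site(srna)
        e_perfect = duplex_energy(_ungapped(srna, perfect))
        i = int(rng.integers(1, len(srna) + 1))
        variant = _site_with_mm(srna, perfect, i)
        assert duplex_energy(align_duplex(srna, variant)) > e_perfect
        if srna[i - 1] in "GT":
            wobbled = _site_with_gu(srna, perfect, i)
            assert duplex_energy(align_duplex(srna, wobbled)) > e_perfect


def test_stacking_terms_must_be_negative():
    with pytest.raises(ValueError):
        EnergyModel(gu_stack=0.2)


def test_energy_ratio_definition(srna21):
    assert energy_ratio(srna21, perfect_site(srna21)) == 1.0
    scrambled = scramble_site(perfect_site(srna21), 3, srna21)
    assert energy_ratio(srna21, scrambled) < 0.7


def test_energy_ratio_monotone_under_added_mismatches(srna21):
    site = perfect_site(srna21)
    last = 1.0
    for i in (3, 7, 12, 16, 20):
        site = _site_with_mm(srna21, site, i)
        ratio = energy_ratio(srna21, site)
        assert 0.0 <= ratio <= last
        last = ratio


# ---------------------------------------------------------------------------
# cleavage

def test_cleavage_rules(srna21):
    perfect = perfect_site(srna21)
    aln = align_duplex(srna21, perfect)
    cleavable, pos = call_cleavage(aln, site_start=100)
    assert cleavable
    assert pos == 100 + len(srna21) - 10  # base opposite sRNA position 10
    wob10 = align_duplex(srna21, _site_with_gu(srna21, perfect, 10))
    assert call_cleavage(wob10) == (False, None)
    mm3 = align_duplex(srna21, _site_with_mm(srna21, perfect, 3))
    assert call_cleavage(mm3)[0] is True
    # configurable positions
    assert call_cleavage(mm3, positions=(3, 4))[0] is False


# ---------------------------------------------------------------------------
# prediction scan

def test_predict_targets_monotone_in_cutoffs(small_world):
    srnas = {p.srna_id: p.sequence for p in small_world.manifest.planted[:4]}
    tx = small_world.transcripts[:20]
    strict = predict_targets(srnas, tx)
    loose = predict_targets(srnas, tx, score_cutoff=float("inf"), ratio_cutoff=0.0)
    strict_keys = {(h.srna_id, h.transcript_id) for h in strict}
    loose_keys = {(h.srna_id, h.transcript_id) for h in loose}
    assert strict_keys <= loose_keys
    assert len(loose) >= len(strict)


def test_predicted_hits_match_manifest(small_world):
    srnas = {p.srna_id: p.sequence for p in small_world.manifest.planted}
    hits = predict_targets(srnas, small_world.transcripts)
    got = {(h.srna_id, h.transcript_id) for h in hits}
    expected = {
        (sid, t.transcript_id)
        for t in small_world.manifest.planted_targets
        for sid in t.expected_hit_srnas
    }
    assert got == expected
    by_key = {(h.srna_id, h.transcript_id): h for h in hits}
    for t in small_world.manifest.planted_targets:
        if t.design == "non_target":
            assert (t.srna_id, t.transcript_id) not in got
            continue
        h = by_key[(t.srna_id, t.transcript_id)]
        assert h.site_start < t.position + len(t.site) and t.position < h.site_end
        if t.design == "perfect":
            assert h.score == 0.0 and h.energy_ratio == 1.0 and h.cleavable
        if t.design == "wobble_10_11":
            assert not h.cleavable


def test_predict_targets_empty_transcriptome_warns():
    assert predict_targets({"x": "T" * 21}, []) == []


# ---------------------------------------------------------------------------
# STTM design

def test_sttm_mimic_inserts_bulge_opposite_10_11(srna21):
    mimic = sttm_mimic(srna21)
    n = len(srna21)
    assert len(mimic) == n + 3
    rc = revcomp(srna21)
    assert mimic == rc[: n - 10] + "CTA" + rc[n - 10 :]


def test_sttm_construct_arithmetic(small_world):
    srnas = {p.srna_id: p.sequence for p in small_world.manifest.planted[:4]}
    construct = design_sttm(srnas)
    assert len(construct.mimics) == 4
    expected_len = sum(len(s) + 3 for s in srnas.values()) + 3 * 48
    assert len(construct.sequence) == expected_len
    for mimic in construct.mimics:
        assert construct.sequence.count(mimic) == 1
    assert all(v["binding_ok"] and not v["cleavable"] for v in construct.validation)


def test_sttm_rejects_duplicates_and_bad_counts(srna21):
    with pytest.raises(ValueError, match="duplicate"):
        design_sttm([("a", srna21), ("b", srna21)])
    with pytest.raises(ValueError):
        design_sttm([])


def test_single_srna_sttm_length(srna21):
    construct = design_sttm({"a": srna21})
    assert len(construct.sequence) == 24


# ---------------------------------------------------------------------------
# scrambled controls

def test_scramble_preserves_composition_and_kills_recognition(srna21):
    site = perfect_site(srna21)
    scrambled = scramble_site(site, 5, srna21)
    assert sorted(scrambled) == sorted(site)
    assert score_alignment(align_duplex(srna21, scrambled)) > 4.5
    # deterministic given the seed
    assert scramble_site(site, 5, srna21) == scrambled


def test_scramble_degenerate_site_errors():
    with pytest.raises(ValueError, match="scramble"):
        scramble_site("A" * 21, 0, "T" * 21)


def test_scrambled_manifest_sites_are_not_predicted(small_world):
    planted = small_world.manifest.planted[:3]
    for i, p in enumerate(planted):
        site = perfect_site(p.sequence)
        scrambled = scramble_site(site, 100 + i, p.sequence)
        from ckrna.seqio import FastaRecord

        hits = predict_targets({p.srna_id: p.sequence}, [FastaRecord("t", scrambled)])
        assert hits == []
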