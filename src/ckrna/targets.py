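"""Plant-miRNA-style target prediction for candidate cross-kingdom sRNAs.

Model
-----
An sRNA (5'->3') is aligned antiparallel to a transcript site (sense, 5'->3').
Each sRNA position is in one of four pair states: Watson-Crick (WC), G:U wobble
(GU), mismatch (MM) or gap (GAP).  The penalty score is

    score = sum over positions of  {MM: 1.0, GU: 0.5, GAP: 2.0}
            x 2 for sRNA positions 2-12 (the seed-proximal region)

and a site passes if ``score <= score_cutoff`` (default 4.5) and the duplex
free-energy ratio ``E(observed) / E(perfect complement) >= ratio_cutoff``
(default 0.7).  AGO-mediated cleavage of the transcript between the bases
opposite sRNA positions 10 and 11 requires WC pairing at both positions; a G:U
wobble there leaves the site bound but non-cleavable, which is exactly the
property exploited by short tandem target mimics (STTMs).

Alignment space (kept deliberately small so it can be exhaustively enumerated):
equal-length duplexes are ungapped; a site one base longer carries exactly one
*internal* 1-nt site bulge; a site one base shorter leaves exactly one sRNA
position unpaired.  Ties are broken toward fewer gaps, then the leftmost gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .seqio import FastaRecord, revcomp, to_dna

logger = logging.getLogger(__name__)

WC_STATE, GU_STATE, MM_STATE, GAP_STATE = "WC", "GU", "MM", "GAP"

PENALTY = {MM_STATE: 1.0, GU_STATE: 0.5, GAP_STATE: 2.0, WC_STATE: 0.0}
SEED_START, SEED_END = 2, 12  # sRNA positions with doubled penalties (1-based)

SCORE_CUTOFF = 4.5
RATIO_CUTOFF = 0.7

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pos_weight(i: int) -> float:
    """Penalty weight of sRNA position ``i`` (1-based from the 5' end)."""
    return 2.0 if SEED_START <= i <= SEED_END else 1.0


def _gap_weight(j: int) -> float:
    """Weight of a site bulge between sRNA positions ``j`` and ``j+1``."""
    return 2.0 if SEED_START <= j + 1 <= SEED_END else 1.0


def pair_state(srna_base: str, site_base: str) -> str:
    """Pair state of an sRNA base against the transcript base it faces."""
    if site_base == _COMP[srna_base]:
        return WC_STATE
    if (srna_base == "G" and site_base == "T") or (srna_base == "T" and site_base == "G"):
        return GU_STATE
    return MM_STATE


# ---------------------------------------------------------------------------
# Energy model

#: RNA/RNA nearest-neighbor Watson-Crick stack free energies (kcal/mol, 37 C),
#: Turner/Xia-style values, keyed by the sRNA-strand dinucleotide 5'->3' in the
#: internal DNA alphabet (T stands for U).
WC_STACK = {
    "AA": -0.93, "TT": -0.93,
    "AT": -1.10,
    "TA": -1.33,
    "CT": -2.08, "AG": -2.08,
    "CA": -2.11, "TG": -2.11,
    "GT": -2.24, "AC": -2.24,
    "GA": -2.35, "TC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}


@dataclass(frozen=True)
class EnergyModel:
    """Simplified nearest-neighbor duplex model.

    Stacking is summed over consecutive paired sRNA positions with no
    intervening bulge; stacks of two WC pairs use the embedded table, stacks
    involving a G:U pair get a flat penalized value, and mismatched or unpaired
    positions contribute nothing.  The GU stack term is deliberately weaker
    than the weakest WC stack so that any single edit to a perfect duplex
    strictly raises (weakens) the energy.  The initiation term defaults to 0:
    energies are hybridization energies relative to the open strands, so a site
    with no complementarity sits at 0 and its energy ratio clamps to 0.
    """

    wc_stack: dict = field(default_factory=lambda: dict(WC_STACK))
    gu_stack: float = -0.45
    initiation: float = 0.0

    def __post_init__(self):
        if any(v > 0 for v in self.wc_stack.values()) or self.gu_stack > 0:
            raise ValueError("stacking terms must be <= 0")


DEFAULT_ENERGY_MODEL = EnergyModel()


# ---------------------------------------------------------------------------
# Duplex alignment

@dataclass(frozen=True)
class DuplexAlignment:
    """One sRNA-site duplex.

    ``pair_states[i-1]`` is the state of sRNA position ``i`` (1-based, 5'->3').
    ``site_partner[i-1]`` is the 0-based index into ``site`` of the transcript
    base facing that position (``None`` for a GAP).  ``site_bulge_after = j``
    records a site bulge of ``site_bulge_len`` bases between sRNA positions
    ``j`` and ``j+1``.
    """

    srna: str
    site: str
    pair_states: tuple[str, ...]
    site_partner: tuple[int | None, ...]
    site_bulge_after: int | None = None
    site_bulge_len: int = 1

    @property
    def n_gaps(self) -> int:
        n = sum(1 for s in self.pair_states if s == GAP_STATE)
        if self.site_bulge_after is not None:
            n += 1
        return n


def _ungapped(srna: str, site: str) -> DuplexAlignment:
    n = len(srna)
    states = tuple(pair_state(srna[i], site[n - 1 - i]) for i in range(n))
    partners = tuple(n - 1 - i for i in range(n))
    return DuplexAlignment(srna, site, states, partners)


def _site_bulged(srna: str, site: str, kb: int) -> DuplexAlignment:
    """Site one base longer; ``kb`` is the 0-based bulged site index (internal)."""
    n = len(srna)
    states, partners = [], []
    for i in range(1, n + 1):  # sRNA positions 5'->3'
        # site index k pairing sRNA position i: k = n-i for i <= n-kb-? derive
        # from the antiparallel layout: site positions > kb pair i = n+1-k,
        # site positions < kb pair i = n-k.
        k = n - i if n - i < kb else n + 1 - i
        states.append(pair_state(srna[i - 1], site[k]))
        partners.append(k)
    j = n - kb  # bulge lies between sRNA positions j and j+1
    return DuplexAlignment(srna, site, tuple(states), tuple(partners), site_bulge_after=j)


def _srna_gapped(srna: str, site: str, g: int) -> DuplexAlignment:
    """Site one base shorter; sRNA position ``g`` (1-based) is unpaired."""
    n = len(srna)
    states, partners = [], []
    for i in range(1, n + 1):
        if i == g:
            states.append(GAP_STATE)
            partners.append(None)
            continue
        k = n - i if i > g else n - 1 - i
        states.append(pair_state(srna[i - 1], site[k]))
        partners.append(k)
    return DuplexAlignment(srna, site, tuple(states), tuple(partners))


def enumerate_alignments(srna: str, site: str) -> list[DuplexAlignment]:
    """All admissible (<= 1 gap) alignments of ``srna`` against ``site``."""
    n, m = len(srna), len(site)
    if m == n:
        return [_ungapped(srna, site)]
    if m == n + 1:
        return [_site_bulged(srna, site, kb) for kb in range(1, n)]
    if m == n - 1:
        return [_srna_gapped(srna, site, g) for g in range(1, n + 1)]
    raise ValueError(f"site length {m} incompatible with sRNA length {n} (|diff| must be <= 1)")


def score_alignment(alignment: DuplexAlignment) -> float:
    """Penalty score: MM=1, GU=0.5, GAP=2, doubled at sRNA positions 2-12."""
    score = 0.0
    for i, state in enumerate(alignment.pair_states, start=1):
        score += PENALTY[state] * _pos_weight(i)
    if alignment.site_bulge_after is not None:
        score += PENALTY[GAP_STATE] * _gap_weight(alignment.site_bulge_after)
    return score


def _alignment_sort_key(alignment: DuplexAlignment) -> tuple:
    if alignment.site_bulge_after is not None:
        gap_pos = alignment.site_bulge_after
    else:
        gap_pos = next((i for i, s in enumerate(alignment.pair_states, 1) if s == GAP_STATE), 0)
    return (score_alignment(alignment), alignment.n_gaps, gap_pos)


def align_duplex(srna: str, site: str) -> DuplexAlignment:
    """Minimum-score alignment of an sRNA to a target site.

    Both sequences are 5'->3' (the site in transcript sense); lengths must be
    15-34 nt and differ by at most one.  Deterministic tie-break: fewest gaps,
    then leftmost gap.
    """
    srna, site = to_dna(srna), to_dna(site)
    for name, seq in (("srna", srna), ("site", site)):
        if not 15 <= len(seq) <= 34:
            raise ValueError(f"{name} length {len(seq)} outside [15, 34]")
    return min(enumerate_alignments(srna, site), key=_alignment_sort_key)


# ---------------------------------------------------------------------------
# Duplex energy and free-energy ratio

def duplex_energy(alignment: DuplexAlignment, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """Sum of nearest-neighbor stacks over adjacent paired positions + initiation."""
    energy = model.initiation
    paired = (WC_STATE, GU_STATE)
    for i in range(len(alignment.pair_states) - 1):
        a, b = alignment.pair_states[i], alignment.pair_states[i + 1]
        if a not in paired or b not in paired:
            continue
        if alignment.site_bulge_after == i + 1:  # bulge between positions i+1 and i+2
            continue
        if a == WC_STATE and b == WC_STATE:
            energy += model.wc_stack[alignment.srna[i : i + 2]]
        else:
            energy += model.gu_stack
    return energy


def perfect_site(srna: str) -> str:
    """The perfectly complementary transcript site for an sRNA."""
    return revcomp(to_dna(srna))


def energy_ratio(srna: str, site: str, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> float:
    """E(observed best duplex) / E(perfect-complement duplex), clamped to [0, 1]."""
    srna = to_dna(srna)
    e_perfect = duplex_energy(_ungapped(srna, perfect_site(srna)), model)
    if e_perfect >= 0:
        raise ValueError(f"degenerate sRNA {srna!r}: perfect-duplex energy {e_perfect} >= 0")
    e_obs = duplex_energy(align_duplex(srna, site), model)
    return min(1.0, max(0.0, e_obs / e_perfect))


# ---------------------------------------------------------------------------
# Cleavability

def call_cleavage(
    alignment: DuplexAlignment,
    site_start: int = 0,
    positions: tuple[int, int] = (10, 11),
) -> tuple[bool, int | None]:
    """Cleavability of a bound site.

    Cleavable iff the sRNA positions in ``positions`` (default 10 and 11) are
    both Watson-Crick paired and no site bulge interrupts them.  The returned
    coordinate is the transcript position (``site_start`` + site index) of the
    base opposite sRNA position ``positions[0]``; cleavage occurs between that
    base and the one 5' of it (opposite ``positions[1]``).
    """
    p10, p11 = positions
    states = alignment.pair_states
    ok = states[p10 - 1] == WC_STATE and states[p11 - 1] == WC_STATE
    if alignment.site_bulge_after is not None and p10 <= alignment.site_bulge_after < p11:
        ok = False
    if not ok:
        return False, None
    return True, site_start + alignment.site_partner[p10 - 1]


# ---------------------------------------------------------------------------
# Transcriptome scanning

@dataclass
class TargetHit:
    """One predicted sRNA-transcript interaction passing both cutoffs."""

    srna_id: str
    srna: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    site: str
    alignment: DuplexAlignment
    score: float
    energy_ratio: float
    cleavable: bool
    cleavage_pos: int | None

    @property
    def site_end(self) -> int:
        return self.site_start + len(self.site)


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.intp, count=len(seq))


def _penalty_row(srna: str, i: int) -> list[float]:
    """Weighted penalty of sRNA position ``i`` against each transcript base."""
    w = _pos_weight(i)
    return [w * PENALTY[pair_state(srna[i - 1], b)] for b in _BASES]


def _diag_sum(A: np.ndarray, rows: range, width: int) -> np.ndarray:
    """sum over k in rows of A[k, t+k] for window starts t in [0, width)."""
    out = np.zeros(width)
    for k in rows:
        out += A[k, k : k + width]
    return out


def _window_scores(srna: str, codes: np.ndarray) -> dict[int, np.ndarray]:
    """Minimum alignment score for every window of length n-1, n, n+1.

    Returns a mapping from site length to the per-offset score array; entry
    ``[t]`` equals ``score_alignment(align_duplex(srna, T[t:t+m]))``.
    """
    n, N = len(srna), len(codes)
    out: dict[int, np.ndarray] = {}

    M0 = np.array([_penalty_row(srna, n - k) for k in range(n)])  # ungapped rows
    A0 = M0[np.arange(n)[:, None], codes[None, :]]

    if N >= n:
        out[n] = _diag_sum(A0, range(n), N - n + 1)

    if N >= n + 1:  # one internal site bulge
        W = N - n
        M1 = np.array([_penalty_row(srna, n + 1 - k) if 1 <= k <= n else [0.0] * 4 for k in range(n + 1)])
        A1 = M1[np.arange(n + 1)[:, None], codes[None, :]]
        left = np.zeros(W)
        rights = [None] * (n + 1)
        acc = np.zeros(W)
        for kb in range(n - 1, 0, -1):  # suffix sums: k = kb+1 .. n
            acc = acc + A1[kb + 1, kb + 1 : kb + 1 + W]
            rights[kb] = acc
        best = np.full(W, np.inf)
        for kb in range(1, n):
            left = left + A0[kb - 1, kb - 1 : kb - 1 + W]
            gap = PENALTY[GAP_STATE] * _gap_weight(n - kb)
            np.minimum(best, left + rights[kb] + gap, out=best)
        out[n + 1] = best

    if N >= n - 1 and n >= 2:  # one unpaired sRNA position
        W = N - n + 2
        M2 = np.array([_penalty_row(srna, n - 1 - k) if k <= n - 2 else [0.0] * 4 for k in range(max(n - 1, 1))])
        A2 = M2[np.arange(M2.shape[0])[:, None], codes[None, :]]
        # prefix over A0 rows (pairs with i > g), suffix over A2 rows (i < g)
        prefixes = [np.zeros(W)]
        acc = np.zeros(W)
        for k in range(n - 1):
            acc = acc + A0[k, k : k + W]
            prefixes.append(acc)
        suffixes = [None] * n
        acc = np.zeros(W)
        suffixes[n - 1] = acc  # g = n: no i < g rows beyond k range
        for k in range(n - 2, -1, -1):
            acc = acc + A2[k, k : k + W]
            suffixes[k] = acc
        best = np.full(W, np.inf)
        for g in range(1, n + 1):
            gap = PENALTY[GAP_STATE] * _pos_weight(g)
            np.minimum(best, prefixes[n - g] + suffixes[n - g] + gap, out=best)
        out[n - 1] = best

    return out


def predict_targets(
    srnas: dict[str, str] | Sequence[tuple[str, str]],
    transcripts: Sequence[FastaRecord],
    score_cutoff: float = SCORE_CUTOFF,
    ratio_cutoff: float = RATIO_CUTOFF,
    model: EnergyModel = DEFAULT_ENERGY_MODEL,
) -> list[TargetHit]:
    """Scan every transcript window (site lengths len-1, len, len+1) per sRNA.

    Emits hits with ``score <= score_cutoff`` and ``energy_ratio >=
    ratio_cutoff``, keeping the best hit (lowest score, then highest ratio,
    then leftmost) per cluster of overlapping windows on a transcript, sorted
    by (score, -ratio).
    """
    if isinstance(srnas, dict):
        srna_items = list(srnas.items())
    else:
        srna_items = list(srnas)
    if not transcripts:
        logger.warning("predict_targets: empty transcriptome")
        return []
    hits: list[TargetHit] = []
    eps = 1e-9
    for srna_id, srna in srna_items:
        srna = to_dna(srna)
        raw_hits: dict[str, list[TargetHit]] = {}
        for rec in transcripts:
            if len(rec) < len(srna) - 1:
                continue
            codes = _encode(rec.sequence)
            per_tx: list[TargetHit] = []
            for m, scores in _window_scores(srna, codes).items():
                if not 15 <= m <= 34:
                    continue
                for t in np.nonzero(scores <= score_cutoff + eps)[0]:
                    site = rec.sequence[t : t + m]
                    aln = align_duplex(srna, site)
                    score = score_alignment(aln)
                    ratio = energy_ratio(srna, site, model)
                    if ratio < ratio_cutoff:
                        continue
                    cleavable, cpos = call_cleavage(aln, site_start=int(t))
                    per_tx.append(
                        TargetHit(srna_id, srna, rec.id, int(t), site, aln, score, ratio, cleavable, cpos)
                    )
            if per_tx:
                raw_hits[rec.id] = _dedupe_clusters(per_tx)
        for tx_hits in raw_hits.values():
            hits.extend(tx_hits)
    hits.sort(key=lambda h: (h.score, -h.energy_ratio, h.srna_id, h.transcript_id, h.site_start))
    return hits


def _dedupe_clusters(hits: list[TargetHit]) -> list[TargetHit]:
    """Keep the best hit per cluster of mutually overlapping windows."""
    hits = sorted(hits, key=lambda h: h.site_start)
    out: list[TargetHit] = []
    cluster: list[TargetHit] = []
    cluster_end = -1
    for h in hits:
        if cluster and h.site_start >= cluster_end:
            out.append(min(cluster, key=lambda x: (x.score, -x.energy_ratio, x.site_start)))
            cluster = []
        cluster.append(h)
        cluster_end = max(cluster_end, h.site_end)
    if cluster:
        out.append(min(cluster, key=lambda x: (x.score, -x.energy_ratio, x.site_start)))
    return out


# ---------------------------------------------------------------------------
# STTM design

#: Widely used 48-nt spacer joining STTM mimic sites.
STTM_SPACER = "GTTGTTGTTGTTATGGTCTAATTTAAATATGGTCTAAAGAAGAAGAAT"

#: Bases inserted as the non-cleavable bulge between the positions opposite
#: sRNA nucleotides 10 and 11.
STTM_BULGE = "CTA"


@dataclass
class SttmConstruct:
    """A short tandem target mimic transcript sequestering one or more sRNAs."""

    srnas: list[tuple[str, str]]  # (id, sequence)
    mimics: list[str]
    spacer: str
    sequence: str
    validation: list[dict]


def sttm_mimic(srna: str) -> str:
    """Mimic site: reverse complement with a 3-nt bulge between the bases
    opposite sRNA positions 10 and 11 (binding-competent, non-cleavable)."""
    srna = to_dna(srna)
    n = len(srna)
    rc = revcomp(srna)
    return rc[: n - 10] + STTM_BULGE + rc[n - 10 :]


def design_sttm(
    srnas: dict[str, str] | Sequence[tuple[str, str]],
    spacer: str = STTM_SPACER,
    score_cutoff: float = SCORE_CUTOFF,
) -> SttmConstruct:
    """Join one bulged mimic per sRNA with spacers into a tandem construct.

    Each mimic is validated with the module's own calls: the bulged duplex is
    non-cleavable, while the pairing excluding the bulge is a perfect duplex
    (binding score 0 <= ``score_cutoff``).
    """
    items = list(srnas.items()) if isinstance(srnas, dict) else list(srnas)
    if not 1 <= len(items) <= 8:
        raise ValueError("design_sttm takes 1-8 sRNAs")
    if len({seq for _sid, seq in items}) != len(items):
        raise ValueError("duplicate input sRNAs")
    mimics, validation = [], []
    for sid, seq in items:
        seq = to_dna(seq)
        mimic = sttm_mimic(seq)
        # pairing excluding the bulge is the perfect complement
        aln = align_duplex(seq, perfect_site(seq))
        binding_score = score_alignment(aln)
        bulged = replace(aln, site_bulge_after=10, site_bulge_len=len(STTM_BULGE))
        cleavable, _ = call_cleavage(bulged)
        validation.append(
            {
                "srna_id": sid,
                "mimic": mimic,
                "binding_score": binding_score,
                "binding_ok": binding_score <= score_cutoff,
                "cleavable": cleavable,
            }
        )
        mimics.append(mimic)
    sequence = spacer.join(mimics) if len(mimics) > 1 else mimics[0]
    return SttmConstruct(items, mimics, spacer, sequence, validation)


# ---------------------------------------------------------------------------
# Scrambled controls

def scramble_site(
    site: str,
    seed: int,
    cognate_srna: str,
    score_cutoff: float = SCORE_CUTOFF,
    max_tries: int = 200,
) -> str:
    """Seeded uniform permutation of a target site that abolishes recognition.

    The permutation is redrawn (bounded retries) until the alignment score
    against the cognate sRNA exceeds ``score_cutoff``; base composition is
    preserved exactly.  Low-complexity sites that cannot be decomplementarized
    raise a ``ValueError``.
    """
    site = to_dna(site)
    if len(site) < 15:
        raise ValueError("site must be at least 15 nt")
    rng = np.random.default_rng(seed)
    bases = list(site)
    for _ in range(max_tries):
        perm = rng.permutation(len(bases))
        scrambled = "".join(bases[i] for i in perm)
        if score_alignment(align_duplex(cognate_srna, scrambled)) > score_cutoff:
            return scrambled
    raise ValueError(f"could not scramble site {site!r} away from its cognate sRNA in {max_tries} tries")
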