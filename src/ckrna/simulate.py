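"""Synthetic study generator: toy host/fungus genomes, annotated features,
host transcripts carrying graded target sites, and mock/AM AGO co-IP read
libraries with a machine-readable ground-truth manifest.

The generator emulates the design of an AGO co-IP cross-kingdom sRNA screen:

* five colonized (AM) and three mock libraries of ~1e6 reads each;
* a host-read background drawn from annotated host loci (miRNA-like 21-nt
  5'-U species plus fragments), present in every library;
* fungus-derived sRNAs present only in AM libraries, sized 21-24 nt with a
  configurable 5'-U bias, drawn mostly from repeat annotation, with the
  per-library fungal-mapped total serving as the RPM denominator;
* planted cross-kingdom sRNAs above the RPM cutoff in every AM library
  (including a single-nucleotide pair encoded at four repeat loci), plus one
  decoy per selection filter, each violating exactly that filter;
* host transcripts carrying perfect, sub-cutoff, position-10 wobble and
  non-target sites for every planted sRNA.

All background species are rejected/redrawn against the planted and decoy
sequences and the adapter seed, so every manifest claim holds by construction.
Everything derives deterministically from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import targets as tp
from .pipeline import Locus
from .seqio import (
    AnnotatedGenome,
    FastaRecord,
    FeatureInterval,
    ReadLibrary,
    revcomp,
    write_fasta,
    write_gff3,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)

#: Default read-length distribution (15-34 nt): dominant 21-nt peak with a
#: 21-24 shoulder and a minor 17-nt component of unassigned origin.
DEFAULT_SIZE_DISTRIBUTION = {
    15: 0.010, 16: 0.010, 17: 0.050, 18: 0.015, 19: 0.015, 20: 0.030,
    21: 0.400, 22: 0.200, 23: 0.120, 24: 0.080, 25: 0.015, 26: 0.010,
    27: 0.010, 28: 0.010, 29: 0.005, 30: 0.005, 31: 0.005, 32: 0.005,
    33: 0.0025, 34: 0.0025,
}

DECOY_FILTERS = ("size", "rpm", "present_in_mock", "no_perfect_fungal_match", "matches_host")

#: Feature-class mixture for fungal background sRNA loci (repeat-dominated,
#: mRNA second, mirroring the typical origin of cross-kingdom sRNAs).
FUNGAL_CLASS_WEIGHTS = {
    "repeat": 0.50, "mRNA": 0.22, "intergenic": 0.12,
    "rRNA": 0.06, "tRNA": 0.04, "snRNA": 0.03, "snoRNA": 0.03,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 0
    host_genome_bp: int = 200_000
    fungus_genome_bp: int = 100_000
    n_mock: int = 3
    n_am: int = 5
    n_planted_ck_srnas: int = 12
    planted_rpm_range: tuple[float, float] = (50.0, 500.0)
    five_prime_u_fraction: float = 0.8
    size_distribution: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_DISTRIBUTION))
    adapter: str = "AGATCGGAAGAGCACACGTCT"
    #: host-background reads per library (fungal reads come on top in AM libs)
    background_reads_per_library: int = 960_000
    #: per-AM-library fungal-mapped read total, drawn uniformly from this range;
    #: must stay >= 40,000 so that a single read sits at or below 25 RPM and the
    #: strict ">25 RPM" rule is exercisable with integer counts
    fungal_reads_range: tuple[int, int] = (40_500, 44_000)
    decoys: tuple[str, ...] = DECOY_FILTERS
    n_host_mirnas: int = 40
    n_host_fragment_species: int = 2000
    n_transcripts: int = 60
    #: substitution error rate per base; 0 by default because the analysis is
    #: perfect-match based (errored copies must never rescue failed filters)
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.planted_rpm_range[0] <= 25:
            raise ValueError("planted_rpm_range low bound must exceed the 25 RPM cutoff")
        total = sum(self.size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size_distribution must sum to 1 (got {total})")
        if not all(15 <= k <= 34 for k in self.size_distribution):
            raise ValueError("size_distribution keys must lie in 15-34")
        if self.fungal_reads_range[0] < 40_000:
            raise ValueError(
                "fungal_reads_range low bound must be >= 40,000 so one read is <= 25 RPM"
            )
        if len(self.adapter) < 8:
            raise ValueError("adapter must be at least 8 nt")
        unknown = set(self.decoys) - set(DECOY_FILTERS)
        if unknown:
            raise ValueError(f"unknown decoy filters: {sorted(unknown)}")
        if self.n_am < 1:
            raise ValueError("need at least one AM library")


# ---------------------------------------------------------------------------
# Ground truth

@dataclass
class PlantedSRNA:
    srna_id: str
    sequence: str
    loci: list[Locus]
    counts: dict[str, int]  # per AM library
    rpm: dict[str, float]   # realized, against the per-library fungal total


@dataclass
class Decoy:
    decoy_id: str
    sequence: str
    violated_filter: str
    am_counts: dict[str, int]
    mock_counts: dict[str, int]


@dataclass
class PlantedTarget:
    transcript_id: str
    position: int  # 0-based site start on the transcript
    design: str    # perfect | sub_cutoff | wobble_10_11 | non_target
    srna_id: str
    site: str
    #: planted sRNA ids expected to register this site as a hit (evaluated at
    #: build time directly on the designed site with the duplex scorer)
    expected_hit_srnas: list[str] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    seed: int
    planted: list[PlantedSRNA]
    decoys: list[Decoy]
    planted_targets: list[PlantedTarget]
    fungal_totals: dict[str, int]          # per AM library
    composition: dict[str, dict[str, float]]  # per AM library, feature-class fractions
    conditions: dict[str, str]             # sample_id -> mock | AM

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedWorld:
    config: SimulationConfig
    host: AnnotatedGenome
    fungus: AnnotatedGenome
    transcripts: list[FastaRecord]
    libraries: list[ReadLibrary]
    manifest: GroundTruthManifest

    @property
    def am_libraries(self) -> list[ReadLibrary]:
        return [l for l in self.libraries if l.condition == "AM"]

    @property
    def mock_libraries(self) -> list[ReadLibrary]:
        return [l for l in self.libraries if l.condition == "mock"]


# ---------------------------------------------------------------------------
# Helpers

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


class _Allocator:
    """Hands out non-overlapping placement slots inside intergenic gaps."""

    def __init__(self, gaps: list[tuple[int, int]], margin: int = 12):
        self._free = [(s, e) for s, e in gaps if e - s > 2 * margin + 40]
        self._margin = margin

    def place(self, length: int, rng: np.random.Generator) -> int:
        for idx in rng.permutation(len(self._free)):
            s, e = self._free[idx]
            if e - s >= length + 2 * self._margin:
                pos = s + self._margin
                self._free[idx] = (pos + length + self._margin, e)
                return pos
        raise ValueError("genome too small to place all simulated elements")


def _mutate_one(seq: str, rng: np.random.Generator, lo: int, hi: int) -> str:
    """Substitute one base at a position in [lo, hi] (1-based, inclusive)."""
    pos = int(rng.integers(lo, hi + 1)) - 1
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[rng.integers(0, 3)] + seq[pos + 1 :]


class _LengthSampler:
    def __init__(self, dist: dict[int, float], subset=None):
        items = [(k, v) for k, v in sorted(dist.items()) if subset is None or k in subset]
        total = sum(v for _k, v in items)
        self.values = np.array([k for k, _v in items])
        self.probs = np.array([v / total for _k, v in items])

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.choice(self.values, size=n, p=self.probs)


# ---------------------------------------------------------------------------
# The generator

class Simulator:
    """Builds one deterministic synthetic study from a :class:`SimulationConfig`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        (self._r_host, self._r_fungus, self._r_planted, self._r_decoy,
         self._r_tx, self._r_lib, self._r_misc) = [np.random.default_rng(c) for c in ss.spawn(7)]
        self._adapter_seed = config.adapter[:8]
        self._reserved: set[str] = set()  # planted + decoy sequences
        self._build()

    # -- assembly -----------------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        self._len_all = _LengthSampler(cfg.size_distribution)
        self._len_2124 = _LengthSampler(cfg.size_distribution, subset=range(21, 25))
        self._len_off = _LengthSampler(
            cfg.size_distribution, subset=[k for k in cfg.size_distribution if not 21 <= k <= 24]
        )
        self._decoy_host_seq = self._fresh_seq(self._r_decoy, 22, host_check=False)
        self._build_host()
        self._build_fungus()
        self._build_transcriptome()
        self._build_libraries()

    def _fresh_seq(
        self,
        rng: np.random.Generator,
        length: int,
        host_check: bool = True,
        force_wobble_pos10: bool = False,
    ) -> str:
        """A random sequence passing the planting constraints."""
        for _ in range(200):
            seq = _random_seq(rng, length)
            if rng.random() < self.config.five_prime_u_fraction:
                seq = "T" + seq[1:]
            elif seq[0] == "T":
                seq = rng.choice(["A", "C", "G"]) + seq[1:]
            if force_wobble_pos10 and seq[9] not in "GT":
                seq = seq[:9] + ("G" if rng.random() < 0.5 else "T") + seq[10:]
            if self._adapter_seed in seq or seq in self._reserved:
                continue
            if host_check and self._occurs_in_host(seq):
                continue
            return seq
        raise RuntimeError("could not draw a fresh planted sequence")

    def _occurs_in_host(self, seq: str) -> bool:
        g = self._host_seq
        return seq in g or revcomp(seq) in g

    def _build_host(self) -> None:
        cfg = self.config
        rng = self._r_host
        backbone = list(_random_seq(rng, cfg.host_genome_bp))
        features: list[FeatureInterval] = []
        cursor = 500
        for i in range(cfg.n_transcripts):
            length = int(rng.integers(250, 401))
            if cursor + length + 600 > cfg.host_genome_bp:
                raise ValueError("host genome too small for the requested transcript loci")
            features.append(
                FeatureInterval("host_1", cursor, cursor + length, "+", "mRNA", name=f"cds_{i:04d}")
            )
            cursor += length + int(rng.integers(300, 700))
        gaps = self._gaps(features, cfg.host_genome_bp)
        alloc = _Allocator(gaps)
        # miRNA-like loci (positions tracked internally; not in the closed
        # annotation set used for fungal read assignment)
        self._mirna_seqs: list[str] = []
        for _ in range(cfg.n_host_mirnas):
            seq = _random_seq(rng, 21)
            if rng.random() < cfg.five_prime_u_fraction:
                seq = "T" + seq[1:]
            if self._adapter_seed in seq:
                continue
            pos = alloc.place(21, rng)
            backbone[pos : pos + 21] = seq
            self._mirna_seqs.append(seq)
        # embed the matches-host decoy copy
        pos = alloc.place(len(self._decoy_host_seq), rng)
        backbone[pos : pos + len(self._decoy_host_seq)] = self._decoy_host_seq
        self._host_seq = "".join(backbone)
        self.host = AnnotatedGenome(
            label="host",
            contigs=[FastaRecord("host_1", self._host_seq)],
            features=features,
        )

    @staticmethod
    def _gaps(features: list[FeatureInterval], length: int) -> list[tuple[int, int]]:
        ivs = sorted((f.start, f.end) for f in features)
        gaps, prev = [], 0
        for s, e in ivs:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < length:
            gaps.append((prev, length))
        return gaps

    def _build_fungus(self) -> None:
        cfg = self.config
        rng = self._r_fungus
        backbone = list(_random_seq(rng, cfg.fungus_genome_bp))
        plan: list[tuple[str, str, int, str | None]] = []  # (class, subtype, length, payload)
        te_unit = _random_seq(rng, 400)
        for i in range(3):  # one family of identical dispersed copies
            plan.append(("repeat", "transposon", 400, te_unit))
        for i in range(24):  # diverged family members (independent sequence)
            plan.append(("repeat", "transposon", 500, None))
        for i in range(2):
            arm = _random_seq(rng, 60)
            plan.append(("repeat", "simple_inverted", 150, arm + _random_seq(rng, 30) + revcomp(arm)))
        plan += [("rRNA", "", 500, None)] * 2
        plan += [("tRNA", "", 75, None)] * 3
        plan += [("snRNA", "", 150, None)] * 2
        plan += [("snoRNA", "", 130, None)] * 2
        plan += [("mRNA", "", 700, None)] * 8

        # the four-copy tandem family F1 carries the single-nucleotide sRNA pair
        pair_len = int(self._len_2124.draw(self._r_planted, 1)[0])
        seq_a = self._fresh_seq(self._r_planted, pair_len, force_wobble_pos10=True)
        for _ in range(50):
            seq_b = _mutate_one(seq_a, self._r_planted, 13, pair_len - 2)
            if not self._occurs_in_host(seq_b) and self._adapter_seed not in seq_b:
                break
        unit = _random_seq(rng, 140)
        off_a, off_b = 8, 8 + pair_len + 10
        unit = unit[:off_a] + seq_a + unit[off_a + pair_len : off_b] + seq_b + unit[off_b + pair_len :]
        plan += [("repeat", "tandem", 140, unit)] * 4
        self._reserved.update({seq_a, seq_b})

        order = self._r_fungus.permutation(len(plan))
        features: list[FeatureInterval] = []
        cursor = 400
        tandem_starts: list[int] = []
        counters: dict[str, int] = {}
        for idx in order:
            fclass, subtype, length, payload = plan[idx]
            if cursor + length + 500 > cfg.fungus_genome_bp:
                raise ValueError("fungus genome too small for the requested features")
            if payload is not None:
                backbone[cursor : cursor + length] = payload
            key = subtype or fclass
            counters[key] = counters.get(key, 0) + 1
            name = "F1" if subtype == "tandem" else f"{key}_{counters[key]}"
            features.append(FeatureInterval("fungus_1", cursor, cursor + length, "+", fclass, subtype, name))
            if subtype == "tandem":
                tandem_starts.append(cursor)
            cursor += length + int(rng.integers(400, 900))

        gaps = self._gaps(features, cfg.fungus_genome_bp)
        alloc = _Allocator(gaps)

        # single-locus planted sRNAs
        self.planted: list[PlantedSRNA] = []
        lengths = self._len_2124.draw(self._r_planted, cfg.n_planted_ck_srnas)
        singles_needed = cfg.n_planted_ck_srnas - 2
        single_info: list[tuple[str, int]] = []
        for j in range(singles_needed):
            seq = self._fresh_seq(self._r_planted, int(lengths[j]), force_wobble_pos10=True)
            pos = alloc.place(len(seq), self._r_planted)
            backbone[pos : pos + len(seq)] = seq
            self._reserved.add(seq)
            single_info.append((seq, pos))

        # fungal copies of decoys that need perfect fungal loci
        self._decoy_seqs: dict[str, str] = {}
        for filt in ("size", "rpm", "present_in_mock"):
            if filt not in cfg.decoys:
                continue
            length = 19 if filt == "size" else int(self._len_2124.draw(self._r_decoy, 1)[0])
            seq = self._fresh_seq(self._r_decoy, length)
            pos = alloc.place(length, self._r_decoy)
            backbone[pos : pos + length] = seq
            self._decoy_seqs[filt] = seq
            self._reserved.add(seq)
        if "matches_host" in cfg.decoys:
            seq = self._decoy_host_seq
            pos = alloc.place(len(seq), self._r_decoy)
            backbone[pos : pos + len(seq)] = seq
            self._decoy_seqs["matches_host"] = seq
            self._reserved.add(seq)

        self._fungus_seq = "".join(backbone)
        self.fungus = AnnotatedGenome(
            label="fungus",
            contigs=[FastaRecord("fungus_1", self._fungus_seq)],
            features=features,
        )

        # the unassigned decoy matches neither genome
        if "no_perfect_fungal_match" in cfg.decoys:
            for _ in range(200):
                seq = self._fresh_seq(self._r_decoy, int(self._len_2124.draw(self._r_decoy, 1)[0]))
                if seq not in self._fungus_seq and revcomp(seq) not in self._fungus_seq:
                    self._decoy_seqs["no_perfect_fungal_match"] = seq
                    self._reserved.add(seq)
                    break
            else:
                raise RuntimeError("could not draw an unmappable decoy")

        # planted sRNA records with loci
        def _loci(seq: str) -> list[Locus]:
            out = []
            for start in tandem_starts:
                for off in (off_a, off_b):
                    if self._fungus_seq[start + off : start + off + len(seq)] == seq:
                        out.append(Locus("fungus_1", start + off, start + off + len(seq), "+"))
            return out

        pair_ids = []
        for tag, seq in (("a", seq_a), ("b", seq_b)):
            sid = f"ck{len(self.planted) + 1:02d}"
            pair_ids.append(sid)
            self.planted.append(PlantedSRNA(sid, seq, _loci(seq), {}, {}))
        for seq, pos in single_info:
            sid = f"ck{len(self.planted) + 1:02d}"
            self.planted.append(
                PlantedSRNA(sid, seq, [Locus("fungus_1", pos, pos + len(seq), "+")], {}, {})
            )

    # -- transcriptome ------------------------------------------------------

    def _site_opposite(self, srna: str, i: int) -> int:
        """Site index opposite sRNA position ``i`` in an ungapped duplex."""
        return len(srna) - i

    def _make_site(self, srna: str, design: str, rng: np.random.Generator) -> str:
        perfect = tp.perfect_site(srna)
        n = len(srna)
        if design == "perfect":
            return perfect

        def _with_mm(site: str, i: int) -> str:
            k = self._site_opposite(srna, i)
            return site[:k] + srna[i - 1] + site[k + 1 :]  # same base as sRNA => always MM

        def _with_gu(site: str, i: int) -> str:
            k = self._site_opposite(srna, i)
            partner = {"G": "T", "T": "G"}[srna[i - 1]]
            return site[:k] + partner + site[k + 1 :]

        if design == "wobble_10_11":
            return _with_gu(perfect, 10)

        if design == "sub_cutoff":
            gu_pos = [i for i in range(13, n - 1) if srna[i - 1] in "GT"]
            attempts = []
            if gu_pos:
                attempts.append(_with_gu(perfect, gu_pos[0]))
                if len(gu_pos) > 1:
                    attempts.append(_with_gu(_with_mm(perfect, n - 3), gu_pos[0]))
            attempts.append(_with_mm(perfect, 14))
            attempts.append(_with_mm(_with_mm(perfect, 14), n - 3))
            for site in attempts:
                score = tp.score_alignment(tp.align_duplex(srna, site))
                ratio = tp.energy_ratio(srna, site)
                if 0 < score <= tp.SCORE_CUTOFF and ratio >= tp.RATIO_CUTOFF:
                    return site
            raise RuntimeError("could not construct a sub-cutoff site")

        if design == "non_target":
            same_len = [p.sequence for p in self.planted if len(p.sequence) == n]
            for attempt in range(50):
                site = tp.scramble_site(perfect, int(rng.integers(0, 2**31 - 1)), srna)
                if all(
                    tp.score_alignment(tp.align_duplex(other, site)) > tp.SCORE_CUTOFF
                    for other in same_len
                ):
                    return site
            raise RuntimeError("could not construct a non-target site")
        raise ValueError(f"unknown site design {design!r}")

    def _build_transcriptome(self) -> None:
        rng = self._r_tx
        records: list[FastaRecord] = []
        mrnas = [f for f in self.host.features if f.feature_class == "mRNA"]
        seqs = {f.name: self._host_seq[f.start : f.end] for f in mrnas}
        designs = ("perfect", "sub_cutoff", "wobble_10_11", "non_target")
        self.planted_targets: list[PlantedTarget] = []
        jobs = [(p, d) for p in self.planted for d in designs]
        if len(jobs) > len(mrnas):
            raise ValueError("not enough transcripts to host all planted target sites")
        for (planted, design), feat in zip(jobs, mrnas):
            tx = seqs[feat.name]
            site = self._make_site(planted.sequence, design, rng)
            pos = int(rng.integers(15, len(tx) - len(site) - 15))
            tx = tx[:pos] + site + tx[pos + len(site) :]
            seqs[feat.name] = tx
            expected = []
            if design != "non_target":
                for other in self.planted:
                    if abs(len(other.sequence) - len(site)) > 1:
                        continue
                    if len(other.sequence) != len(site):
                        continue
                    score = tp.score_alignment(tp.align_duplex(other.sequence, site))
                    ratio = tp.energy_ratio(other.sequence, site)
                    if score <= tp.SCORE_CUTOFF and ratio >= tp.RATIO_CUTOFF:
                        expected.append(other.srna_id)
            self.planted_targets.append(
                PlantedTarget(feat.name, pos, design, planted.srna_id, site, expected)
            )
        for feat in mrnas:
            records.append(FastaRecord(feat.name, seqs[feat.name], description="host CDS"))
        self.transcripts = records

    # -- libraries ----------------------------------------------------------

    def _class_position_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per feature class: start positions with 5'-T and 5'-non-T bases."""
        L = len(self._fungus_seq)
        arr = np.frombuffer(self._fungus_seq.encode(), dtype=np.uint8)
        by_class: dict[str, list[np.ndarray]] = {}
        for f in self.fungus.features:
            if f.end - f.start < 40:
                continue
            by_class.setdefault(f.feature_class, []).append(np.arange(f.start, f.end - 34))
        gaps = self._gaps(self.fungus.features, L)
        by_class["intergenic"] = [np.arange(s, e - 34) for s, e in gaps if e - s > 60]
        out = {}
        for cls, chunks in by_class.items():
            pos = np.concatenate(chunks)
            is_t = arr[pos] == ord("T")
            out[cls] = (pos[is_t], pos[~is_t])
        return out

    def _draw_fungal_windows(
        self,
        rng: np.random.Generator,
        n: int,
        sampler: _LengthSampler,
        seen: set[str],
        class_pos: dict[str, tuple[np.ndarray, np.ndarray]],
    ) -> list[tuple[str, str]]:
        """Draw ``n`` unique (sequence, feature_class) fungal background species."""
        cfg = self.config
        classes = [c for c in FUNGAL_CLASS_WEIGHTS if c in class_pos]
        probs = np.array([FUNGAL_CLASS_WEIGHTS[c] for c in classes])
        probs = probs / probs.sum()
        genome = self._fungus_seq
        out: list[tuple[str, str]] = []
        # the 5'-base flag is drawn once per species and kept through retries,
        # so window collisions cannot bias the realized 5'-U fraction
        cls_idx = rng.choice(len(classes), size=n, p=probs)
        lens = sampler.draw(rng, n)
        is_u = rng.random(n) < cfg.five_prime_u_fraction
        for ci, length, u in zip(cls_idx, lens, is_u):
            cls = classes[int(ci)]
            length = int(length)
            for attempt in range(120):
                if attempt and attempt % 8 == 0:  # pool may be near-exhausted
                    cls = classes[int(rng.choice(len(classes), p=probs))]
                    length = int(sampler.draw(rng, 1)[0])
                t_pos, o_pos = class_pos[cls]
                pool = t_pos if (u and len(t_pos)) or not len(o_pos) else o_pos
                p = int(pool[rng.integers(0, len(pool))])
                seq = genome[p : p + length]
                if seq in seen or seq in self._reserved or self._adapter_seed in seq:
                    continue
                seen.add(seq)
                out.append((seq, cls))
                break
            else:
                raise RuntimeError("window drawing failed to converge")
        return out

    def _host_species(self) -> tuple[list[str], np.ndarray]:
        cfg = self.config
        rng = self._r_misc
        frag_sampler = self._len_all
        species = list(self._mirna_seqs)
        seen = set(species)
        genome = self._host_seq
        L = len(genome)
        while len(species) < len(self._mirna_seqs) + cfg.n_host_fragment_species:
            need = len(self._mirna_seqs) + cfg.n_host_fragment_species - len(species)
            lens = frag_sampler.draw(rng, need + 16)
            starts = rng.integers(0, L - 34, size=need + 16)
            for p, length in zip(starts, lens):
                seq = genome[int(p) : int(p) + int(length)]
                if seq in seen or seq in self._reserved or self._adapter_seed in seq:
                    continue
                seen.add(seq)
                species.append(seq)
                if len(species) == len(self._mirna_seqs) + cfg.n_host_fragment_species:
                    break
        n_mir = len(self._mirna_seqs)
        w = np.empty(len(species))
        w[:n_mir] = 0.6 / np.arange(1, n_mir + 1)  # Zipf-like miRNA abundances
        w[:n_mir] *= 0.6 / w[:n_mir].sum()
        w[n_mir:] = 0.4 / (len(species) - n_mir)
        return species, w / w.sum()

    def _build_libraries(self) -> None:
        cfg = self.config
        host_species, host_probs = self._host_species()
        class_pos = self._class_position_arrays()
        sample_ids = [f"AM_{i+1}" for i in range(cfg.n_am)] + [f"mock_{i+1}" for i in range(cfg.n_mock)]
        conditions = {s: ("AM" if s.startswith("AM") else "mock") for s in sample_ids}
        decoy_am: dict[str, dict[str, int]] = {f: {} for f in self._decoy_seqs}
        decoy_mock: dict[str, dict[str, int]] = {f: {} for f in self._decoy_seqs}
        fungal_totals: dict[str, int] = {}
        composition: dict[str, dict[str, float]] = {}
        libraries: list[ReadLibrary] = []
        global_c: set[str] = set()

        lib_rngs = [np.random.default_rng(c) for c in np.random.SeedSequence(
            entropy=(self.config.seed, 917)).spawn(len(sample_ids))]

        for lib_i, sample_id in enumerate(sample_ids):
            rng = lib_rngs[lib_i]
            reads: dict[str, int] = {}
            host_counts = rng.multinomial(cfg.background_reads_per_library, host_probs)
            for seq, c in zip(host_species, host_counts):
                if c:
                    reads[seq] = reads.get(seq, 0) + int(c)

            if conditions[sample_id] == "mock":
                if "present_in_mock" in self._decoy_seqs and lib_i == cfg.n_am:  # first mock library
                    seq = self._decoy_seqs["present_in_mock"]
                    reads[seq] = reads.get(seq, 0) + 1
                    decoy_mock["present_in_mock"][sample_id] = 1
                lib = ReadLibrary(sample_id, "mock", reads)
                libraries.append(lib)
                continue

            # --- AM library: fungal component
            F = int(rng.integers(*cfg.fungal_reads_range))
            fungal_counts: dict[str, int] = {}
            comp_counts: dict[str, int] = {}

            def _add(seq: str, count: int, cls: str) -> None:
                fungal_counts[seq] = fungal_counts.get(seq, 0) + count
                comp_counts[cls] = comp_counts.get(cls, 0) + count

            for planted in self.planted:
                rpm_target = rng.uniform(*cfg.planted_rpm_range)
                c = max(2, round(rpm_target * F / 1e6))
                cls = "repeat" if len(planted.loci) > 1 else "intergenic"
                _add(planted.sequence, c, cls)
                planted.counts[sample_id] = c
            for filt, seq in self._decoy_seqs.items():
                if filt == "rpm" and lib_i == 0:
                    c = 1  # 1e6/F <= 24.7 RPM: fails the strict >25 rule here
                else:
                    c = int(rng.integers(3, 9))
                if filt in ("size", "rpm", "present_in_mock"):
                    _add(seq, c, "intergenic")
                else:
                    # not fungal-mapped; counted in the library but not in F
                    reads[seq] = reads.get(seq, 0) + c
                decoy_am[filt][sample_id] = c

            seen: set[str] = set(fungal_counts)
            n_c = 30
            for seq, cls in self._draw_fungal_windows(rng, n_c, self._len_2124, seen, class_pos):
                if seq in global_c:
                    continue
                global_c.add(seq)
                _add(seq, int(rng.integers(2, 6)), cls)
            n_b = 5000
            for seq, cls in self._draw_fungal_windows(rng, n_b, self._len_off, seen, class_pos):
                _add(seq, int(rng.integers(2, 7)), cls)
            n_a = F - sum(fungal_counts.values())
            if n_a < 0:
                raise ValueError("fungal_reads_range too small for the planted load")
            for seq, cls in self._draw_fungal_windows(rng, n_a, self._len_all, seen, class_pos):
                _add(seq, 1, cls)

            total_f = sum(fungal_counts.values())
            assert total_f == F
            fungal_totals[sample_id] = F
            for planted in self.planted:
                planted.rpm[sample_id] = planted.counts[sample_id] * 1e6 / F
            composition[sample_id] = {
                cls: comp_counts.get(cls, 0) / F
                for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA", "intergenic")
            }
            for seq, c in fungal_counts.items():
                reads[seq] = reads.get(seq, 0) + c
            if cfg.error_rate > 0:
                self._apply_errors(reads, rng)
            libraries.append(ReadLibrary(sample_id, "AM", reads))

        decoys = [
            Decoy(f"decoy_{filt}", seq, filt, decoy_am[filt], decoy_mock[filt])
            for filt, seq in self._decoy_seqs.items()
        ]
        self.libraries = libraries
        self.manifest = GroundTruthManifest(
            seed=cfg.seed,
            planted=self.planted,
            decoys=decoys,
            planted_targets=self.planted_targets,
            fungal_totals=fungal_totals,
            composition=composition,
            conditions=conditions,
        )

    def _apply_errors(self, reads: dict[str, int], rng: np.random.Generator) -> None:
        """Move a binomial share of each species' copies to 1-substitution variants."""
        for seq in list(reads):
            n_err = rng.binomial(reads[seq], min(1.0, self.config.error_rate * len(seq)))
            for _ in range(n_err):
                variant = _mutate_one(seq, rng, 1, len(seq))
                if variant == seq or self._adapter_seed in variant:
                    continue
                reads[seq] -= 1
                reads[variant] = reads.get(variant, 0) + 1
        for seq in [s for s, c in reads.items() if c == 0]:
            del reads[seq]

    def world(self) -> SimulatedWorld:
        return SimulatedWorld(
            config=self.config,
            host=self.host,
            fungus=self.fungus,
            transcripts=self.transcripts,
            libraries=self.libraries,
            manifest=self.manifest,
        )


# ---------------------------------------------------------------------------
# Public operations

def simulate_world(config: SimulationConfig) -> SimulatedWorld:
    """Build the complete synthetic study (genomes, transcripts, libraries, truth)."""
    return Simulator(config).world()


def simulate_genomes(config: SimulationConfig) -> tuple[AnnotatedGenome, AnnotatedGenome]:
    w = simulate_world(config)
    return w.host, w.fungus


def simulate_transcriptome(config: SimulationConfig) -> tuple[list[FastaRecord], list[PlantedTarget]]:
    w = simulate_world(config)
    return w.transcripts, w.manifest.planted_targets


def simulate_libraries(config: SimulationConfig) -> tuple[list[ReadLibrary], GroundTruthManifest]:
    w = simulate_world(config)
    return w.libraries, w.manifest


def write_world(world: SimulatedWorld, outdir: str | Path, junk_read_fraction: float = 0.003) -> dict:
    """Write the study to disk: genomes (FASTA/GFF3), CDS FASTA, per-library
    FASTQ with the adapter appended, a TSV sample sheet and the JSON manifest.

    ``junk_read_fraction`` adds adapter-less reads that preprocessing must
    reject, so raw totals exceed clipped totals.  Returns the file map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = world.config
    write_fasta(world.host.contigs, outdir / "host.fasta")
    write_fasta(world.fungus.contigs, outdir / "fungus.fasta")
    write_gff3(world.host.features, outdir / "host.gff3")
    write_gff3(world.fungus.features, outdir / "fungus.gff3")
    write_fasta(world.transcripts, outdir / "cds.fasta")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(cfg.seed, 271828)))
    entries = []
    seed8 = cfg.adapter[:8]
    for lib in world.libraries:
        reads = []
        for seq, count in lib.reads.items():
            reads.extend([seq + cfg.adapter] * count)
        n_junk = int(len(reads) * junk_read_fraction)
        added = 0
        while added < n_junk:
            junk = _random_seq(rng, int(rng.integers(36, 51)))
            if seed8 in junk:
                continue
            reads.append(junk)
            added += 1
        order = rng.permutation(len(reads))
        fq = outdir / f"{lib.sample_id}.fastq"
        with open(fq, "w") as fh:
            for i, j in enumerate(order, 1):
                seq = reads[j]
                fh.write(f"@{lib.sample_id}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        entries.append((lib.sample_id, lib.condition, fq.name))
    write_sample_sheet(entries, outdir / "samples.tsv")
    world.manifest.write_json(outdir / "manifest.json")
    files = {
        "host_fasta": "host.fasta", "fungus_fasta": "fungus.fasta",
        "host_gff3": "host.gff3", "fungus_gff3": "fungus.gff3",
        "cds_fasta": "cds.fasta", "sample_sheet": "samples.tsv",
        "manifest": "manifest.json",
    }
    return files
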