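"""Read preprocessing, subtractive origin classification and candidate selection.

The analysis logic mirrors an AGO co-IP cross-kingdom sRNA screen: reads are
adapter-clipped and collapsed, mapped *perfect-match only* to the host and the
fungal genome on both strands, and a read is called fungal only if it has at
least one perfect fungal locus and no perfect host locus (subtractive
classification).  Candidate cross-kingdom sRNAs are then the fungal-exclusive
sequences of 21-24 nt with strictly more than ``min_rpm`` reads per million of
the fungal-mapped total in *every* colonized (AM) library and zero raw reads in
every mock library.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .seqio import (
    FEATURE_CLASSES,
    AnnotatedGenome,
    FeatureInterval,
    ReadLibrary,
    read_fastq,
    revcomp,
)

logger = logging.getLogger(__name__)

MIN_READ_LEN = 15
MAX_READ_LEN = 34

ORIGIN_HOST = "host"
ORIGIN_FUNGAL = "fungal"
ORIGIN_AMBIGUOUS = "ambiguous"
ORIGIN_UNASSIGNED = "unassigned"
ORIGINS = (ORIGIN_HOST, ORIGIN_FUNGAL, ORIGIN_AMBIGUOUS, ORIGIN_UNASSIGNED)


class Locus(NamedTuple):
    """A perfect full-length occurrence; coordinates are always forward-strand."""

    contig: str
    start: int
    end: int
    strand: str


# ---------------------------------------------------------------------------
# Adapter clipping and collapsing

class ClipResult(NamedTuple):
    insert: str | None
    reason: str | None  # None on success; "no_adapter" / "too_short" / "too_long"


def clip_adapter(
    read: str,
    adapter: str,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> ClipResult:
    """Clip the 3' adapter from a raw read by its first exact 8-nt seed match.

    The insert is the prefix before the first occurrence of the adapter's
    first 8 nucleotides.  Reads with no seed occurrence, or with an insert
    outside ``[min_len, max_len]``, are rejected with a reason.
    """
    if len(adapter) < 8:
        raise ValueError("adapter must be at least 8 nt for seed matching")
    seed = adapter[:8]
    pos = read.find(seed)
    if pos < 0:
        return ClipResult(None, "no_adapter")
    if pos < min_len:
        return ClipResult(None, "too_short")
    if pos > max_len:
        return ClipResult(None, "too_long")
    return ClipResult(read[:pos], None)


@dataclass
class ClipStats:
    total_raw: int = 0
    kept: int = 0
    rejected: Counter = field(default_factory=Counter)


def collapse(
    inserts: Iterable[str],
    sample_id: str,
    condition: str,
    total_raw: int | None = None,
) -> ReadLibrary:
    """Aggregate an insert stream into unique-sequence counts."""
    counts: Counter[str] = Counter()
    n = 0
    for seq in inserts:
        counts[seq] += 1
        n += 1
    return ReadLibrary(
        sample_id=sample_id,
        condition=condition,
        reads=dict(counts),
        total_raw=total_raw if total_raw is not None else n,
    )


def preprocess_fastq(
    path,
    adapter: str,
    sample_id: str,
    condition: str,
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
) -> tuple[ReadLibrary, ClipStats]:
    """FASTQ -> adapter-clipped, collapsed :class:`ReadLibrary`."""
    stats = ClipStats()
    counts: Counter[str] = Counter()
    for read in read_fastq(path):
        stats.total_raw += 1
        insert, reason = clip_adapter(read, adapter, min_len, max_len)
        if insert is None:
            stats.rejected[reason] += 1
        else:
            counts[insert] += 1
            stats.kept += 1
    lib = ReadLibrary(sample_id=sample_id, condition=condition, reads=dict(counts), total_raw=stats.total_raw)
    return lib, stats


# ---------------------------------------------------------------------------
# Exact-match mapping

class MappingIndex:
    """Exact-match lookup over both strands for query lengths 15-34 nt.

    A 15-mer seed dictionary over the forward strands is extended and verified
    for each query; reverse-complement occurrences are found by querying the
    reverse complement and are reported on the minus strand with forward-strand
    coordinates.  Hits are exactly the full-length perfect occurrences.
    """

    SEED_LEN = MIN_READ_LEN

    def __init__(self, genome: AnnotatedGenome):
        self.label = genome.label
        self._contigs: list[tuple[str, str]] = [(c.id, c.sequence) for c in genome.contigs]
        index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        k = self.SEED_LEN
        for ci, (_name, seq) in enumerate(self._contigs):
            for i in range(len(seq) - k + 1):
                index[seq[i : i + k]].append((ci, i))
        self._index = dict(index)

    def _occurrences(self, query: str) -> list[tuple[int, int]]:
        n = len(query)
        hits = []
        seeds = self._index.get(query[: self.SEED_LEN])
        if seeds:
            contigs = self._contigs
            for ci, pos in seeds:
                if contigs[ci][1][pos : pos + n] == query:
                    hits.append((ci, pos))
        return hits

    def map_exact(self, query: str) -> list[Locus]:
        """All perfect full-length loci of ``query`` on either strand."""
        n = len(query)
        if not MIN_READ_LEN <= n <= MAX_READ_LEN:
            raise ValueError(f"query length {n} outside [{MIN_READ_LEN}, {MAX_READ_LEN}]")
        contigs = self._contigs
        loci = [Locus(contigs[ci][0], pos, pos + n, "+") for ci, pos in self._occurrences(query)]
        loci += [Locus(contigs[ci][0], pos, pos + n, "-") for ci, pos in self._occurrences(revcomp(query))]
        if len(loci) > 1:
            loci = sorted(set(loci))  # dedupe by (contig, start, strand)
        return loci


def build_index(genome: AnnotatedGenome) -> MappingIndex:
    return MappingIndex(genome)


def map_exact(query: str, index: MappingIndex) -> list[Locus]:
    return index.map_exact(query)


# ---------------------------------------------------------------------------
# Origin classification

class ReadOrigin(NamedTuple):
    origin: str
    host_loci: tuple[Locus, ...]
    fungal_loci: tuple[Locus, ...]


@dataclass
class OriginClassification:
    """Per-unique-read origin calls for one library, plus read-weighted totals."""

    sample_id: str
    per_read: dict[str, ReadOrigin]
    origin_counts: dict[str, int]  # read-weighted
    total_reads: int

    @property
    def fungal_total(self) -> int:
        return self.origin_counts[ORIGIN_FUNGAL]

    @property
    def fungal_fraction(self) -> float:
        """Fungal-mapped reads over the post-preprocess library total."""
        return self.fungal_total / self.total_reads if self.total_reads else 0.0


def classify_origin(
    library: ReadLibrary,
    host_index: MappingIndex,
    fungal_index: MappingIndex,
) -> OriginClassification:
    """Subtractive classification: host if any perfect host locus, fungal if
    perfect fungal loci only, ambiguous if both genomes match, else unassigned."""
    per_read: dict[str, ReadOrigin] = {}
    counts = {o: 0 for o in ORIGINS}
    for seq, count in library.reads.items():
        host_loci = tuple(host_index.map_exact(seq))
        fungal_loci = tuple(fungal_index.map_exact(seq))
        if host_loci and fungal_loci:
            origin = ORIGIN_AMBIGUOUS
        elif host_loci:
            origin = ORIGIN_HOST
        elif fungal_loci:
            origin = ORIGIN_FUNGAL
        else:
            origin = ORIGIN_UNASSIGNED
        per_read[seq] = ReadOrigin(origin, host_loci, fungal_loci)
        counts[origin] += count
    return OriginClassification(
        sample_id=library.sample_id,
        per_read=per_read,
        origin_counts=counts,
        total_reads=library.total_after_preprocess,
    )


# ---------------------------------------------------------------------------
# Size / 5' nucleotide profiling

@dataclass
class SizeNtProfile:
    """RPM matrix over read length (15-34) x 5' nucleotide (A/C/G/U)."""

    rpm: pd.DataFrame
    denominator: int
    subset: str

    @property
    def total_rpm(self) -> float:
        return float(self.rpm.to_numpy().sum())

    def modal_length(self) -> int:
        return int(self.rpm.sum(axis=1).idxmax())

    def five_prime_fraction(self, base: str = "U") -> float:
        total = self.total_rpm
        return float(self.rpm[base].sum() / total) if total else 0.0


def size_nt_profile(
    library: ReadLibrary,
    classification: OriginClassification,
    subset: str,
) -> SizeNtProfile:
    """Profile a library subset (``host``-mapped or ``fungal``-mapped reads).

    RPM is computed against the subset's own read total, so the matrix sums to
    1e6 whenever the subset is non-empty ("reads per million" of that subset).
    """
    if subset not in (ORIGIN_HOST, ORIGIN_FUNGAL):
        raise ValueError("subset must be 'host' or 'fungal'")
    lengths = range(MIN_READ_LEN, MAX_READ_LEN + 1)
    mat = pd.DataFrame(0.0, index=list(lengths), columns=["A", "C", "G", "U"])
    denom = 0
    counts = np.zeros((MAX_READ_LEN - MIN_READ_LEN + 1, 4))
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq, count in library.reads.items():
        if classification.per_read[seq].origin != subset:
            continue
        denom += count
        counts[len(seq) - MIN_READ_LEN, col[seq[0]]] += count
    if denom == 0:
        logger.warning("size_nt_profile(%s, %s): empty subset, all-zero profile", library.sample_id, subset)
        return SizeNtProfile(rpm=mat, denominator=0, subset=subset)
    mat.iloc[:, :] = counts * 1e6 / denom
    return SizeNtProfile(rpm=mat, denominator=denom, subset=subset)


# ---------------------------------------------------------------------------
# Feature-class assignment

_PRIORITY = {cls: i for i, cls in enumerate(FEATURE_CLASSES)}
INTERGENIC = "intergenic"


class FeatureIndex:
    """Interval lookup of typed features, one tree per contig."""

    def __init__(self, features: Sequence[FeatureInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self._trees.setdefault(f.contig, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, contig: str, start: int, end: int) -> list[FeatureInterval]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_feature(loci: Sequence[Locus], feature_index: FeatureIndex) -> str:
    """Highest-priority feature class overlapping any locus by >= 1 base.

    Priority: rRNA > tRNA > snRNA > snoRNA > repeat > mRNA > intergenic.
    """
    best = len(FEATURE_CLASSES)  # intergenic sentinel
    for locus in loci:
        for feat in feature_index.overlapping(locus.contig, locus.start, locus.end):
            best = min(best, _PRIORITY[feat.feature_class])
    return FEATURE_CLASSES[best] if best < len(FEATURE_CLASSES) else INTERGENIC


def feature_composition(
    library: ReadLibrary,
    classification: OriginClassification,
    feature_index: FeatureIndex,
) -> pd.Series:
    """Read-weighted feature-class fractions of the fungal-mapped reads."""
    counts = {cls: 0 for cls in FEATURE_CLASSES + (INTERGENIC,)}
    total = 0
    for seq, count in library.reads.items():
        ro = classification.per_read[seq]
        if ro.origin != ORIGIN_FUNGAL:
            continue
        counts[assign_feature(ro.fungal_loci, feature_index)] += count
        total += count
    frac = pd.Series(counts, dtype=float)
    return frac / total if total else frac


# ---------------------------------------------------------------------------
# Candidate selection

@dataclass(frozen=True)
class CandidateFlags:
    size_ok: bool
    rpm_ok_all_am: bool
    absent_in_mock: bool
    fungal_exclusive: bool

    @property
    def all_ok(self) -> bool:
        return self.size_ok and self.rpm_ok_all_am and self.absent_in_mock and self.fungal_exclusive


@dataclass
class CandidateSRNA:
    """A cross-kingdom sRNA candidate with per-sample RPM, loci and filter flags."""

    sequence: str
    length: int
    rpm_am: dict[str, float]
    rpm_mock: dict[str, float]
    mock_counts: dict[str, int]
    fungal_loci: tuple[Locus, ...]
    flags: CandidateFlags

    @property
    def is_candidate(self) -> bool:
        return self.flags.all_ok


class CandidateSelection:
    """Result of candidate selection; also evaluates filter flags for any sequence."""

    def __init__(
        self,
        am_libs: Sequence[ReadLibrary],
        mock_libs: Sequence[ReadLibrary],
        classifications: dict[str, OriginClassification],
        min_rpm: float,
        sizes: tuple[int, int],
        max_mock_count: int,
    ):
        if not am_libs:
            raise ValueError("candidate selection requires at least one AM library")
        self._am = list(am_libs)
        self._mock = list(mock_libs)
        self._cls = classifications
        self.min_rpm = min_rpm
        self.sizes = sizes
        self.max_mock_count = max_mock_count
        self.fungal_totals = {lib.sample_id: classifications[lib.sample_id].fungal_total for lib in am_libs}
        self.mock_fungal_totals = {
            lib.sample_id: classifications[lib.sample_id].fungal_total for lib in mock_libs
        }
        self.candidates: list[CandidateSRNA] = []
        self._select()

    def _rpm(self, count: int, fungal_total: int) -> float:
        return count * 1e6 / fungal_total if fungal_total else 0.0

    def evaluate(self, seq: str) -> CandidateSRNA:
        """Full flag evaluation for one sequence (used for reporting rejections)."""
        lo, hi = self.sizes
        size_ok = lo <= len(seq) <= hi
        origin = None
        fungal_loci: tuple[Locus, ...] = ()
        for lib in self._am:
            ro = self._cls[lib.sample_id].per_read.get(seq)
            if ro is not None:
                origin = ro.origin
                fungal_loci = ro.fungal_loci
                break
        fungal_exclusive = origin == ORIGIN_FUNGAL
        rpm_am = {
            lib.sample_id: self._rpm(lib.reads.get(seq, 0), self.fungal_totals[lib.sample_id])
            for lib in self._am
        }
        rpm_ok = all(v > self.min_rpm for v in rpm_am.values())
        mock_counts = {lib.sample_id: lib.reads.get(seq, 0) for lib in self._mock}
        absent_in_mock = all(c <= self.max_mock_count for c in mock_counts.values())
        rpm_mock = {
            lib.sample_id: self._rpm(lib.reads.get(seq, 0), self.mock_fungal_totals[lib.sample_id])
            for lib in self._mock
        }
        return CandidateSRNA(
            sequence=seq,
            length=len(seq),
            rpm_am=rpm_am,
            rpm_mock=rpm_mock,
            mock_counts=mock_counts,
            fungal_loci=fungal_loci,
            flags=CandidateFlags(size_ok, rpm_ok, absent_in_mock, fungal_exclusive),
        )

    def _select(self) -> None:
        lo, hi = self.sizes
        first = self._am[0]
        # a sequence must be present (with >min_rpm) in every AM library, so the
        # first AM library's reads are a sufficient universe to scan
        for seq in first.reads:
            if not lo <= len(seq) <= hi:
                continue
            if self._cls[first.sample_id].per_read[seq].origin != ORIGIN_FUNGAL:
                continue
            ok = True
            for lib in self._am:
                count = lib.reads.get(seq, 0)
                if self._rpm(count, self.fungal_totals[lib.sample_id]) <= self.min_rpm:
                    ok = False
                    break
            if not ok:
                continue
            if any(lib.reads.get(seq, 0) > self.max_mock_count for lib in self._mock):
                continue
            self.candidates.append(self.evaluate(seq))
        self.candidates.sort(key=lambda c: c.sequence)


def select_candidates(
    am_libraries: Sequence[ReadLibrary],
    mock_libraries: Sequence[ReadLibrary],
    classifications: dict[str, OriginClassification],
    min_rpm: float = 25.0,
    sizes: tuple[int, int] = (21, 24),
    max_mock_count: int = 0,
) -> CandidateSelection:
    """Select cross-kingdom sRNA candidates.

    A sequence is a candidate iff it is fungal-exclusive, its length lies in
    ``sizes`` (inclusive), its RPM (of the per-library fungal-mapped total) is
    strictly greater than ``min_rpm`` in every AM library, and its raw count is
    at most ``max_mock_count`` (default 0) in every mock library.  Sequences
    differing by a single nucleotide are deliberately kept as distinct
    candidates.
    """
    return CandidateSelection(am_libraries, mock_libraries, classifications, min_rpm, sizes, max_mock_count)
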