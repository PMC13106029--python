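"""On-disk formats and the in-memory sequence/annotation containers shared by every stage.

Conventions
-----------
* Internal coordinates are 0-based, half-open.  Everything written to GFF3 is
  1-based, inclusive (the GFF3 standard); :func:`to_gff_coords` /
  :func:`from_gff_coords` convert and are exact inverses of each other.
* The internal alphabet is DNA (``ACGTN``, uppercase).  RNA input (``U``) is
  folded to ``T`` on read; reports that show small RNAs print them back in the
  RNA alphabet via :func:`to_rna`.
* All writers are plain-text and bit-stable for a fixed input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

#: Closed set of annotation classes used for read assignment, in priority order.
FEATURE_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")

#: Repeat subtypes that the fungal annotation distinguishes.
REPEAT_SUBTYPES = ("transposon", "simple_inverted", "tandem")

VALID_CONDITIONS = ("mock", "AM")

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")
_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-alphabet sequence."""
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def to_dna(seq: str) -> str:
    """Uppercase and fold RNA ``U`` to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Render an internal DNA-alphabet sequence in the RNA alphabet."""
    return seq.upper().replace("T", "U")


def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF3 1-based inclusive."""
    return start + 1, end


def from_gff_coords(start1: int, end1: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> internal 0-based half-open."""
    return start1 - 1, end1


@dataclass(frozen=True)
class FastaRecord:
    """A single named sequence (genome contig, CDS, ...)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        seq = to_dna(self.sequence)
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"record {self.id!r}: invalid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureInterval:
    """A typed genomic interval (internal 0-based, half-open coordinates)."""

    contig: str
    start: int
    end: int
    strand: str
    feature_class: str
    subtype: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"feature {self.name or self.contig}: bad interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name or self.contig}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature class {self.feature_class!r} not in {FEATURE_CLASSES}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """Contig sequences plus typed feature intervals for one organism."""

    label: str  # "host" or "fungus"
    contigs: list[FastaRecord]
    features: list[FeatureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._seq = {c.id: c.sequence for c in self.contigs}
        if len(self._seq) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        for f in self.features:
            if f.contig not in self._seq:
                raise ValueError(f"feature on unknown contig {f.contig!r}")
            if f.end > len(self._seq[f.contig]):
                raise ValueError(f"feature {f.name or f.contig} extends past contig end")

    def sequence(self, contig: str) -> str:
        return self._seq[contig]

    def contig_length(self, contig: str) -> int:
        return len(self._seq[contig])

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass
class ReadLibrary:
    """One sample's collapsed small-RNA reads (unique sequence -> count)."""

    sample_id: str
    condition: str
    reads: dict[str, int]
    total_raw: int = 0

    def __post_init__(self) -> None:
        if self.condition not in VALID_CONDITIONS:
            raise ValueError(f"condition must be one of {VALID_CONDITIONS}, got {self.condition!r}")
        self.total_after_preprocess = sum(self.reads.values())
        if self.total_raw == 0:
            self.total_raw = self.total_after_preprocess
        if self.total_after_preprocess > self.total_raw:
            raise ValueError("collapsed read count exceeds raw total")

    @property
    def n_unique(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[FastaRecord]:
    """Read a FASTA file; folds case and RNA->DNA, preserves file order.

    Raises :class:`ParseError` naming the line number for malformed headers or
    empty sequences.
    """
    records: list[FastaRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def _flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}:{header_line}: record {header!r} has an empty sequence")
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise ParseError(f"{path}:{header_line}: duplicate record id {rid!r}")
        seen.add(rid)
        try:
            records.append(FastaRecord(id=rid, sequence=seq, description=desc))
        except ValueError as exc:
            raise ParseError(f"{path}:{header_line}: {exc}") from exc
        header, chunks = None, []

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(line_no)
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}:{line_no}: malformed FASTA header")
                header_line = line_no
            else:
                if header is None:
                    raise ParseError(f"{path}:{line_no}: sequence before any FASTA header")
                chunks.append(line)
        _flush(line_no if chunks or header else 0)
    return records


def write_fasta(records: Iterable[FastaRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ

def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a 4-line-record FASTQ file.

    Qualities are parsed (the record structure is validated) but not
    interpreted; no quality filtering is applied anywhere in the pipeline.
    """
    try:
        with open(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                yield to_dna(seq)
    except ValueError as exc:  # Biopython signals truncated/malformed records
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path, genome: AnnotatedGenome | None = None) -> list[FeatureInterval]:
    """Read GFF3 feature lines into internal intervals.

    Feature types outside :data:`FEATURE_CLASSES` are dropped (a summary count
    is logged).  Per-line problems (end < start, unknown contig) are collected
    and raised together as one :class:`ParseError`.
    """
    features: list[FeatureInterval] = []
    errors: list[str] = []
    dropped: Counter[str] = Counter()
    contig_len = None
    if genome is not None:
        contig_len = {c.id: len(c) for c in genome.contigs}

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                errors.append(f"line {line_no}: expected 9 tab-separated columns, got {len(cols)}")
                continue
            contig, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            if ftype not in FEATURE_CLASSES:
                dropped[ftype] += 1
                continue
            try:
                start, end = from_gff_coords(int(start1), int(end1))
            except ValueError:
                errors.append(f"line {line_no}: non-integer coordinates")
                continue
            if end <= start:
                errors.append(f"line {line_no}: end < start ({start1}..{end1})")
                continue
            if contig_len is not None:
                if contig not in contig_len:
                    errors.append(f"line {line_no}: unknown contig {contig!r}")
                    continue
                if end > contig_len[contig]:
                    errors.append(f"line {line_no}: interval extends past contig end")
                    continue
            attr = dict(
                part.split("=", 1) for part in attrs.split(";") if "=" in part
            )
            features.append(
                FeatureInterval(
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "+",
                    feature_class=ftype,
                    subtype=attr.get("subtype", ""),
                    name=attr.get("ID", ""),
                )
            )
    if dropped:
        logger.info("read_gff3(%s): dropped feature types outside the closed set: %s", path, dict(dropped))
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return features


def write_gff3(features: Iterable[FeatureInterval], path: str | Path, source: str = "ckrna") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            start1, end1 = to_gff_coords(f.start, f.end)
            attrs = []
            if f.name:
                attrs.append(f"ID={f.name}")
            if f.subtype:
                attrs.append(f"subtype={f.subtype}")
            fh.write(
                "\t".join(
                    [f.contig, source, f.feature_class, str(start1), str(end1), ".", f.strand, ".", ";".join(attrs) or "."]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet

def read_sample_sheet(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV sample sheet with columns sample_id / condition / path.

    Conditions are case-normalized to ``mock`` / ``AM``; duplicate sample ids
    and unknown conditions are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "path"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(required)}")
    norm = {"mock": "mock", "am": "AM"}
    entries: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        cond = norm.get(str(row.condition).strip().lower())
        if cond is None:
            raise ParseError(f"{path}: unknown condition {row.condition!r} for sample {row.sample_id!r}")
        if row.sample_id in seen:
            raise ParseError(f"{path}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        entries.append((str(row.sample_id), cond, str(row.path)))
    return entries


def write_sample_sheet(entries: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\tpath\n")
        for sample_id, condition, fq in entries:
            fh.write(f"{sample_id}\t{condition}\t{fq}\n")
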