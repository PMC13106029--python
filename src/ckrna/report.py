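"""End-to-end orchestration: one config in, a reproducible run directory out.

``run_pipeline`` wires the stages together: load references and libraries,
adapter-clip and collapse, classify read origin against both genomes, profile
sizes and 5' nucleotides, assign fungal feature classes, select cross-kingdom
candidates, predict their host targets and call cleavability.  Every table is
written as TSV, the run report as JSON with SHA-256 checksums of all
artifacts, so reruns of the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .pipeline import (
    FeatureIndex,
    assign_feature,
    build_index,
    classify_origin,
    feature_composition,
    preprocess_fastq,
    select_candidates,
    size_nt_profile,
)
from .seqio import read_fasta, read_gff3, read_sample_sheet, to_rna, AnnotatedGenome
from .targets import predict_targets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    host_fasta: str
    fungus_fasta: str
    host_gff3: str
    fungus_gff3: str
    cds_fasta: str
    sample_sheet: str
    adapter: str
    out_dir: str = "ckrna_out"
    min_rpm: float = 25.0
    size_min: int = 21
    size_max: int = 24
    score_cutoff: float = 4.5
    ratio_cutoff: float = 0.7
    max_mock_count: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        base = Path(path).parent
        for attr in ("host_fasta", "fungus_fasta", "host_gff3", "fungus_gff3", "cds_fasta", "sample_sheet"):
            p = Path(getattr(cfg, attr))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"config path {attr} does not resolve: {p}")
            setattr(cfg, attr, str(p))
        return cfg


@dataclass
class RunReport:
    config: dict
    version: str
    samples: list[dict] = field(default_factory=list)
    n_candidates: int = 0
    n_target_hits: int = 0
    artifacts: dict[str, str] = field(default_factory=dict)  # file -> sha256


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the full analysis; returns the report and writes all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)

    def _stage(name: str, sample: str | None = None):
        logger.info("stage=%s%s", name, f" sample={sample}" if sample else "")

    _stage("load_references")
    host = AnnotatedGenome("host", read_fasta(config.host_fasta))
    host.features = read_gff3(config.host_gff3, host)
    fungus = AnnotatedGenome("fungus", read_fasta(config.fungus_fasta))
    fungus.features = read_gff3(config.fungus_gff3, fungus)
    transcripts = read_fasta(config.cds_fasta)
    sheet = read_sample_sheet(config.sample_sheet)
    base = Path(config.sample_sheet).parent

    _stage("build_indexes")
    host_index = build_index(host)
    fungal_index = build_index(fungus)
    feat_index = FeatureIndex(fungus.features)

    libs, classifications = [], {}
    accounting_rows = []
    profile_frames = []
    comp_rows = []
    for sample_id, condition, fq in sheet:
        _stage("preprocess", sample_id)
        fq_path = Path(fq)
        if not fq_path.is_absolute():
            fq_path = base / fq_path
        try:
            lib, stats = preprocess_fastq(fq_path, config.adapter, sample_id, condition)
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess sample={sample_id}: {exc}") from exc
        _stage("classify", sample_id)
        cls = classify_origin(lib, host_index, fungal_index)
        libs.append(lib)
        classifications[sample_id] = cls
        row = {
            "sample_id": sample_id,
            "condition": condition,
            "raw_reads": stats.total_raw,
            "clipped_reads": lib.total_after_preprocess,
            **{f"{o}_reads": cls.origin_counts[o] for o in cls.origin_counts},
            "fungal_pct": 100.0 * cls.fungal_fraction,
        }
        assert sum(cls.origin_counts.values()) == lib.total_after_preprocess
        accounting_rows.append(row)
        report.samples.append(row)
        _stage("profile", sample_id)
        for subset in ("host", "fungal"):
            prof = size_nt_profile(lib, cls, subset)
            df = prof.rpm.reset_index(names="length")
            df.insert(0, "sample_id", sample_id)
            df.insert(1, "subset", subset)
            profile_frames.append(df)
        comp = feature_composition(lib, cls, feat_index)
        comp_rows.append(pd.Series({"sample_id": sample_id, **comp.to_dict()}))

    _stage("candidates")
    am = [l for l in libs if l.condition == "AM"]
    mock = [l for l in libs if l.condition == "mock"]
    if not am:
        raise RuntimeError("stage=candidates: no AM libraries in the sample sheet")
    selection = select_candidates(
        am, mock, classifications,
        min_rpm=config.min_rpm,
        sizes=(config.size_min, config.size_max),
        max_mock_count=config.max_mock_count,
    )
    cand_rows = []
    for i, c in enumerate(selection.candidates, 1):
        row = {
            "candidate_id": f"cksRNA{i:02d}",
            "sequence_rna": to_rna(c.sequence),
            "length": c.length,
            "n_loci": len(c.fungal_loci),
            "loci": ";".join(f"{l.contig}:{l.start + 1}-{l.end}({l.strand})" for l in c.fungal_loci),
            "feature_class": assign_feature(c.fungal_loci, feat_index),
        }
        for sid, rpm in {**c.rpm_am, **c.rpm_mock}.items():
            row[f"rpm_{sid}"] = rpm
        cand_rows.append(row)
    report.n_candidates = len(selection.candidates)

    _stage("targets")
    srna_map = {f"cksRNA{i:02d}": c.sequence for i, c in enumerate(selection.candidates, 1)}
    hits = predict_targets(
        srna_map, transcripts,
        score_cutoff=config.score_cutoff, ratio_cutoff=config.ratio_cutoff,
    )
    report.n_target_hits = len(hits)
    hit_rows = [
        {
            "srna_id": h.srna_id,
            "transcript_id": h.transcript_id,
            "site_start_1based": h.site_start + 1,
            "site": to_rna(h.site),
            "score": h.score,
            "energy_ratio": round(h.energy_ratio, 6),
            "cleavable": h.cleavable,
            "cleavage_pos_1based": (h.cleavage_pos + 1) if h.cleavage_pos is not None else "",
        }
        for h in hits
    ]

    _stage("write_artifacts")
    _write_tsv(pd.DataFrame(accounting_rows), out / "classification_summary.tsv")
    _write_tsv(pd.concat(profile_frames, ignore_index=True), out / "size_nt_profiles.tsv")
    _write_tsv(pd.DataFrame(comp_rows), out / "feature_composition.tsv")
    _write_tsv(pd.DataFrame(cand_rows), out / "candidates.tsv")
    _write_tsv(pd.DataFrame(hit_rows), out / "target_hits.tsv")
    for name in ("classification_summary", "size_nt_profiles", "feature_composition", "candidates", "target_hits"):
        report.artifacts[f"{name}.tsv"] = _sha256(out / f"{name}.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
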