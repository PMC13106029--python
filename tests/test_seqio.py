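import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ckrna.seqio import (
    AnnotatedGenome,
    FastaRecord,
    FeatureInterval,
    ParseError,
    ReadLibrary,
    from_gff_coords,
    read_fasta,
    read_fastq,
    read_gff3,
    read_sample_sheet,
    revcomp,
    to_gff_coords,
    to_rna,
    write_fasta,
    write_fastq,
    write_gff3,
    write_sample_sheet,
)


def test_fasta_folds_case_and_rna_alphabet(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nacgu\n")
    (rec,) = read_fasta(p)
    assert rec.id == "a" and rec.sequence == "ACGT"
    assert to_rna(rec.sequence) == "ACGU"


def test_fasta_preserves_record_order(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">a\nACGT\n>b\nGGGG\n")
    assert [r.id for r in read_fasta(p)] == ["a", "b"]


@pytest.mark.parametrize(
    "text,fragment",
    [(">a\n>b\nACGT\n", "empty sequence"), ("ACGT\n", "before any FASTA header"), (">a\nAC\n>a\nGG\n", "duplicate")],
)
def test_fasta_parse_errors_name_the_line(tmp_path, text, fragment):
    p = tmp_path / "bad.fasta"
    p.write_text(text)
    with pytest.raises(ParseError, match=fragment):
        read_fasta(p)


def test_fasta_round_trip_on_random_records(tmp_path):
    rng = np.random.default_rng(7)
    records = [
        FastaRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=rng.integers(20, 400))), "desc here")
        for i in range(100)
    ]
    p = tmp_path / "rt.fasta"
    write_fasta(records, p)
    back = read_fasta(p)
    assert [(r.id, r.sequence, r.description) for r in back] == [
        (r.id, r.sequence, r.description) for r in records
    ]


def test_fastq_reader_and_round_trip(tmp_path):
    p = tmp_path / "r.fastq"
    p.write_text("@r\nACGT\n+\nIIII\n")
    assert list(read_fastq(p)) == ["ACGT"]
    empty = tmp_path / "e.fastq"
    empty.write_text("")
    assert list(read_fastq(empty)) == []
    rng = np.random.default_rng(5)
    reads = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(500)]
    rt = tmp_path / "rt.fastq"
    write_fastq(reads, rt)
    assert list(read_fastq(rt)) == reads


def test_fastq_truncated_record_errors(tmp_path):
    p = tmp_path / "t.fastq"
    p.write_text("@r\nACGT\n+\n")
    with pytest.raises(ParseError):
        list(read_fastq(p))


def test_gff3_coordinate_convention(tmp_path):
    p = tmp_path / "f.gff3"
    p.write_text("chr1\t.\trRNA\t1\t100\t.\t+\t.\tID=x\n")
    (f,) = read_gff3(p)
    assert (f.start, f.end, f.feature_class, f.name) == (0, 100, "rRNA", "x")


def test_gff3_drops_types_outside_closed_set(tmp_path, caplog):
    p = tmp_path / "f.gff3"
    p.write_text("chr1\t.\texon\t1\t10\t.\t+\t.\t.\nchr1\t.\ttRNA\t5\t40\t.\t-\t.\tID=t1\n")
    feats = read_gff3(p)
    assert [f.feature_class for f in feats] == ["tRNA"]


def test_gff3_reports_bad_lines(tmp_path):
    genome = AnnotatedGenome("host", [FastaRecord("chr1", "ACGT" * 30)])
    p = tmp_path / "f.gff3"
    p.write_text("chr1\t.\trRNA\t50\t10\t.\t+\t.\t.\nchrX\t.\ttRNA\t1\t10\t.\t+\t.\t.\n")
    with pytest.raises(ParseError, match="end < start"):
        read_gff3(p, genome)
    p.write_text("chrX\t.\ttRNA\t1\t10\t.\t+\t.\t.\n")
    with pytest.raises(ParseError, match="unknown contig"):
        read_gff3(p, genome)


def test_gff3_round_trip(tmp_path, small_world):
    p = tmp_path / "fungus.gff3"
    write_gff3(small_world.fungus.features, p)
    back = read_gff3(p, small_world.fungus)
    assert back == small_world.fungus.features


@given(st.integers(min_value=0, max_value=10**6), st.integers(min_value=1, max_value=10**4))
def test_gff_coordinate_conversion_is_an_involution(start, length):
    end = start + length
    assert from_gff_coords(*to_gff_coords(start, end)) == (start, end)


def test_sample_sheet_normalizes_and_validates(tmp_path):
    p = tmp_path / "s.tsv"
    write_sample_sheet([("s1", "mock", "a.fastq"), ("s2", "AM", "b.fastq")], p)
    assert read_sample_sheet(p) == [("s1", "mock", "a.fastq"), ("s2", "AM", "b.fastq")]
    p.write_text("sample_id\tcondition\tpath\ns1\tam\tx.fastq\n")
    assert read_sample_sheet(p)[0][1] == "AM"
    p.write_text("sample_id\tcondition\tpath\ns1\tAM\tx\ns1\tmock\ty\n")
    with pytest.raises(ParseError, match="duplicate"):
        read_sample_sheet(p)
    p.write_text("sample_id\tcondition\tpath\ns1\tcontrol\tx\n")
    with pytest.raises(ParseError, match="unknown condition"):
        read_sample_sheet(p)


def test_read_library_invariants():
    lib = ReadLibrary("s", "AM", {"A" * 21: 3, "C" * 21: 2}, total_raw=10)
    assert lib.total_after_preprocess == 5 and lib.n_unique == 2
    with pytest.raises(ValueError):
        ReadLibrary("s", "treated", {"A" * 21: 1})
    with pytest.raises(ValueError):
        ReadLibrary("s", "AM", {"A" * 21: 5}, total_raw=2)


def test_feature_interval_validation():
    with pytest.raises(ValueError):
        FeatureInterval("c", 10, 5, "+", "rRNA")
    with pytest.raises(ValueError):
        FeatureInterval("c", 0, 5, "+", "exon")


def test_revcomp_involution_and_pairing():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("ACGGTTAC")) == "ACGGTTAC"
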