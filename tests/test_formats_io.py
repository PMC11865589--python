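"""Format readers/writers: coordinate conventions and round trips."""

import numpy as np
import pytest

from syn4d import formats_io as fio
from syn4d.synthetic_data import write_fixture
from tests.conftest import small_config


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

GFF3_TOY = """##gff-version 3
chr1\tsrc\texon\t100\t102\t.\t+\t.\tID=e1;Parent=t1;gene_id=g1
chr1\tsrc\tCDS\t100\t102\t.\t+\t.\tID=c1;Parent=t1;gene_id=g1
"""

GTF_MINUS = """chr1\tsrc\texon\t11\t22\t.\t-\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t31\t42\t.\t-\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t11\t22\t.\t-\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\tCDS\t31\t42\t.\t-\t.\tgene_id "g1"; transcript_id "t1";
"""

GTF_MINUS_BAD_CDS = GTF_MINUS.replace("\t22\t", "\t20\t")


def test_gff3_coordinates_become_zero_based_half_open(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(GFF3_TOY)
    t = fio.read_transcripts(str(p))["t1"]
    assert t.cds == [(99, 102)]
    assert t.strand == "+"


def test_minus_strand_exons_in_transcription_order(tmp_path):
    p = tmp_path / "toy.gtf"
    p.write_text(GTF_MINUS)
    t = fio.read_transcripts(str(p))["t1"]
    assert t.exons == [(30, 42), (10, 22)]  # descending genomic = transcription order
    assert t.cds_length == 24


def test_cds_not_divisible_by_three_is_skipped(tmp_path, caplog):
    p = tmp_path / "toy.gtf"
    p.write_text(GTF_MINUS_BAD_CDS)
    with caplog.at_level("WARNING"):
        out = fio.read_transcripts(str(p))
    assert out == {}
    assert "not divisible by 3" in caplog.text


def test_gtf_round_trip_is_identity(small_bundle, tmp_path):
    path = tmp_path / "out.gtf"
    fio.write_transcripts_gtf(small_bundle.transcripts, str(path))
    back = fio.read_transcripts(str(path))
    assert set(back) == set(small_bundle.transcripts)
    for tid, t in small_bundle.transcripts.items():
        b = back[tid]
        assert (b.chrom, b.strand, b.exons, b.cds, b.gene_id) == (
            t.chrom, t.strand, t.exons, t.cds, t.gene_id
        )


# ---------------------------------------------------------------------------
# score tracks
# ---------------------------------------------------------------------------

def test_bedgraph_expansion_and_missing(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t3\t2.5\n")
    track = fio.read_score_track(str(p))
    assert [track.get("chr1", i) for i in range(3)] == [2.5, 2.5, 2.5]
    assert np.isnan(track.get("chr1", 5))
    assert np.isnan(track.get("chr2", 0))


def test_overlapping_bedgraph_is_an_error(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t3\t1.0\nchr1\t2\t4\t2.0\n")
    with pytest.raises(ValueError, match="overlapping"):
        fio.read_score_track(str(p))


def test_fixedstep_wig_equals_equivalent_bedgraph(tmp_path):
    wig = tmp_path / "t.wig"
    wig.write_text("fixedStep chrom=chr1 start=11 step=1\n1.5\n2.5\n3.5\n")
    bg = tmp_path / "t.bedgraph"
    bg.write_text("chr1\t10\t11\t1.5\nchr1\t11\t12\t2.5\nchr1\t12\t13\t3.5\n")
    assert fio.read_score_track(str(wig)) == fio.read_score_track(str(bg))


def test_bedgraph_round_trip(small_bundle, tmp_path):
    p = tmp_path / "scores.bedgraph"
    fio.write_bedgraph(small_bundle.scores, str(p))
    back = fio.read_score_track(str(p))
    for chrom, pos, val in small_bundle.scores.items():
        assert back.get(chrom, pos) == pytest.approx(val, rel=1e-5)


# ---------------------------------------------------------------------------
# intervals, variants, fasta, alignment
# ---------------------------------------------------------------------------

def test_bed_is_read_as_is(tmp_path):
    p = tmp_path / "t.bed"
    p.write_text("chr1\t10\t20\tname1\n")
    track = fio.read_intervals(str(p))
    assert track.overlapping("chr1", 0, 100) == [(10, 20, "name1")]
    assert track.covers("chr1", 10) and not track.covers("chr1", 20)


def test_vcf_snv_position_conversion_and_indel_skip(tmp_path, caplog):
    p = tmp_path / "t.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t11\t.\tG\tA\t.\t.\tAF=0.01\n"
        "chr1\t20\t.\tGT\tG\t.\t.\tAF=0.01\n"
        "chr1\t30\t.\tC\tA,T\t.\t.\tAF=0.01\n"
    )
    df = fio.read_variants(str(p))
    assert len(df) == 1
    assert df.loc[0, "pos"] == 10
    assert (df.loc[0, "major"], df.loc[0, "minor"]) == ("G", "A")


def test_vcf_major_minor_swap_when_af_above_half(tmp_path):
    p = tmp_path / "t.vcf"
    p.write_text(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t5\t.\tT\tC\t.\t.\tAF=0.9\n"
    )
    df = fio.read_variants(str(p))
    assert (df.loc[0, "major"], df.loc[0, "minor"]) == ("C", "T")
    assert df.loc[0, "maf"] == pytest.approx(0.1)


def test_variant_tsv_round_trip(small_bundle, tmp_path):
    p = tmp_path / "v.tsv"
    fio.write_variants(small_bundle.variants, str(p))
    back = fio.read_variants(str(p))
    orig = small_bundle.variants[fio.VARIANT_COLUMNS]
    assert back.drop(columns="maf").equals(orig.drop(columns="maf"))
    assert np.allclose(back["maf"], orig["maf"], rtol=1e-9)


def test_fasta_round_trip(small_bundle, tmp_path):
    p = tmp_path / "g.fa"
    fio.write_fasta(small_bundle.genome, str(p))
    assert fio.read_fasta(str(p)) == small_bundle.genome


def test_alignment_tsv_round_trip(small_bundle, tmp_path):
    p = tmp_path / "aln.tsv"
    fio.write_alignment(small_bundle.alignment, str(p))
    assert fio.read_alignment(str(p)) == small_bundle.alignment


def test_maf_subset_projects_onto_reference_columns(tmp_path):
    maf = tmp_path / "t.maf"
    maf.write_text(
        "##maf version=1\n"
        "a score=0\n"
        "s ref.chr1 3 4 + 100 AC-GT\n"
        "s spA.chr9 0 5 + 100 ACTGT\n"
        "s spB.chr2 0 4 + 100 AC-GA\n"
        "\n"
    )
    aln = fio.read_alignment_maf(str(maf), "ref")
    assert aln.species == ["ref", "spA", "spB"]
    assert aln.column("chr1", 3) == "AAA"
    assert aln.column("chr1", 4) == "CCC"
    assert aln.column("chr1", 5) == "GGG"  # ref gap column dropped, coords advance
    assert aln.column("chr1", 6) == "TTA"


def test_readers_are_pure(small_bundle, tmp_path):
    out = tmp_path / "fix"
    write_fixture(small_config(), str(out), bundle=small_bundle)
    a1 = fio.read_alignment(str(out / "alignment.tsv"))
    a2 = fio.read_alignment(str(out / "alignment.tsv"))
    assert a1 == a2
    t1 = fio.read_transcripts(str(out / "annotation.gtf"))
    t2 = fio.read_transcripts(str(out / "annotation.gtf"))
    assert {k: (v.exons, v.cds) for k, v in t1.items()} == {
        k: (v.exons, v.cds) for k, v in t2.items()
    }
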