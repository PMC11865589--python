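"""Conservation classification, GC4, splice-position and window-GC summaries."""

import numpy as np
import pandas as pd
import pytest

from syn4d import conservation_summary as cs
from syn4d import site_catalog as sc
from syn4d.formats_io import TranscriptModel
from syn4d.synthetic_data import generate_bundle
from tests.conftest import small_config


def test_tau_comparison_is_inclusive():
    calls = cs.classify_conserved(pd.Series([2.27, 2.2699, np.nan]))
    assert calls.tolist() == [True, False, pd.NA]


def test_conserved_fraction_matches_generator_truth(small_bundle, small_frame):
    frac = cs.conserved_fraction(small_frame["score"], tau=small_bundle.tau)
    assert frac == pytest.approx(small_bundle.config.pi_conserved, abs=0.03)


def _tiny_frame():
    return pd.DataFrame(
        {
            "transcript_id": ["t1"] * 4,
            "ref_base": ["G", "C", "A", "T"],
            "count_A": [0, 0, 8, 1],
            "count_C": [1, 9, 0, 1],
            "count_G": [9, 0, 1, 0],
            "count_T": [0, 1, 1, 8],
            "n_aligned": [10, 10, 10, 10],
            "score": [5.0, np.nan, 1.0, 3.0],
        }
    )


def test_transcript_gc4_both_modes():
    df = _tiny_frame()
    assert cs.transcript_gc4(df, "human")["t1"] == pytest.approx(0.5)
    # mammal mode: sum G = 10, sum C = 11 over 40 aligned bases
    assert cs.transcript_gc4(df, "mammal")["t1"] == pytest.approx(21 / 40)
    with pytest.raises(ValueError):
        cs.transcript_gc4(df, "bogus")


def test_mean_score_by_base_class_arithmetic():
    df = pd.DataFrame(
        {
            "transcript_id": ["t1"] * 3,
            "ref_base": ["A", "T", "G"],
            "score": [1.0, 3.0, 5.0],
        }
    )
    out = cs.mean_score_by_base_class(df)
    assert out.loc["t1", "AT"] == pytest.approx(2.0)
    assert out.loc["t1", "GC"] == pytest.approx(5.0)


def test_at_gc_mean_scores_correlate_across_transcripts(small_frame):
    """Shared per-transcript conservation couples the AT and GC components."""
    out = cs.mean_score_by_base_class(small_frame).dropna()
    r = np.corrcoef(out["AT"], out["GC"])[0, 1]
    assert r > 0


def _exon_toy(strand="+"):
    exons = [(0, 30), (50, 80), (100, 130)]
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel("t1", "g1", "chr1", strand, exons=exons, cds=list(exons))


@pytest.mark.parametrize(
    "pos,expected_class,expected_dist",
    [
        (50, "5p+1", 0),
        (51, "5p+2", 1),
        (52, "5p+3", 2),
        (79, "3p-1", 0),
        (78, "3p-2", 1),
        (60, "internal", 10),
        (0, "internal", 0),     # first base of the first exon is not splice-adjacent
        (129, "internal", 0),   # last base of the last exon
    ],
)
def test_exon_position_classes_plus_strand(pos, expected_class, expected_dist):
    t = _exon_toy("+")
    cls, dist, _ = cs.exon_position_class(pos, t)
    assert (cls, dist) == (expected_class, expected_dist)


def test_exon_position_classes_mirror_on_minus_strand():
    """A minus-strand gene mirrors the plus-strand class assignment."""
    t = _exon_toy("-")
    # transcription order runs right to left: genomic 79 is the first base
    # of the middle exon in transcription order (it follows exon [100,130))
    assert cs.exon_position_class(79, t)[0] == "5p+1"
    assert cs.exon_position_class(50, t)[0] == "3p-1"
    assert cs.exon_position_class(51, t)[0] == "3p-2"


def test_single_exon_is_always_internal():
    t = TranscriptModel("t1", "g1", "chr1", "+", exons=[(0, 30)], cds=[(0, 30)])
    assert cs.exon_position_class(0, t)[0] == "internal"
    assert cs.exon_position_class(29, t)[0] == "internal"


def test_position_outside_exons_raises():
    with pytest.raises(ValueError):
        cs.exon_position_class(40, _exon_toy("+"))


def test_five_prime_label_wins_in_tiny_exon():
    t = TranscriptModel(
        "t1", "g1", "chr1", "+", exons=[(0, 10), (20, 22), (30, 40)],
        cds=[(0, 10), (20, 22), (30, 40)],
    )
    assert cs.exon_position_class(20, t)[0] == "5p+1"
    assert cs.exon_position_class(21, t)[0] == "5p+2"


def test_splice_table_proportions_and_totals(small_frame):
    table = cs.splice_base_table(small_frame)
    nonempty = table[table["n_sites"] > 0]
    sums = nonempty[["prop_A", "prop_T", "prop_C", "prop_G"]].sum(axis=1)
    assert np.allclose(sums, 1.0)
    # site totals partition the catalog
    human_rows = table[table["mode"] == "human"]
    assert human_rows["n_sites"].sum() == len(small_frame)


def test_score_bins_conserve_base_totals(small_frame):
    table = cs.score_binned_base_counts(small_frame)
    total = table[["A", "C", "G", "T"]].to_numpy().sum()
    expected = small_frame[["count_A", "count_C", "count_G", "count_T"]].to_numpy().sum()
    assert total == expected
    assert table["n_sites"].sum() == small_frame["score"].notna().sum()


def test_score_bin_single_site():
    df = pd.DataFrame(
        {
            "score": [0.5], "count_A": [0], "count_C": [0],
            "count_G": [10], "count_T": [0],
        }
    )
    table = cs.score_binned_base_counts(df)
    assert len(table) == 1
    assert (table.loc[0, "bin_left"], table.loc[0, "bin_right"]) == (0.0, 1.0)
    assert table.loc[0, "G"] == 10


def test_genome_window_gc_and_local_assignment():
    genome = {"chr1": "G" * 100 + "GCGCGCGCAT" * 10}
    wgc = cs.genome_window_gc(genome, window=100)
    assert wgc.loc[0, "gc"] == pytest.approx(1.0)
    assert wgc.loc[1, "gc"] == pytest.approx(0.8)
    t = TranscriptModel("t1", "g1", "chr1", "+", exons=[(50, 150)], cds=[(50, 150)])
    assert cs.assign_local_gc(t, wgc) == pytest.approx(0.9)  # equal overlap of both


def test_all_n_window_is_missing():
    wgc = cs.genome_window_gc({"chr1": "N" * 50}, window=50)
    assert np.isnan(wgc.loc[0, "gc"])


def test_exon_group_gc4_boundary_and_first_exon_elevation():
    """Units need strictly more than min_sites; a boosted first-exon GC
    equilibrium shows up as a higher first-exon group median."""
    bundle = generate_bundle(
        small_config(seed=23, first_exon_gc_boost=0.18, tree_depth=1.0, n_genes=30)
    )
    cat = sc.build_catalog(
        bundle.transcripts, bundle.genome, bundle.alignment, bundle.scores
    )
    df = cat.to_frame()
    groups = cs.exon_group_gc4(df, bundle.transcripts, min_sites=10)
    assert groups["first_exon"].median() > groups["internal_exon"].median()
    # boundary: exactly min_sites is excluded
    tiny = df.groupby("transcript_id").head(10)
    g10 = cs.exon_group_gc4(tiny, bundle.transcripts, min_sites=10)
    assert all(len(v) == 0 for v in g10.values())
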