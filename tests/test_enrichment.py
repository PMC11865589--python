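"""Observed/expected enrichment scores, percentile cut-offs and class tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syn4d import enrichment as en
from syn4d.formats_io import IntervalTrack, TranscriptModel


def test_obs_exp_examples():
    # every unit at the global rate scores 1
    assert en.obs_exp_score(2, 10, 20, 100) == pytest.approx(1.0)
    assert en.obs_exp_score(0, 10, 20, 100) == 0.0
    # a fully conserved unit against a 20.8% global rate
    assert en.obs_exp_score(19, 19, 208, 1000) == pytest.approx(1 / 0.208)
    assert math.isnan(en.obs_exp_score(0, 0, 20, 100))
    with pytest.raises(ValueError, match="no conserved events"):
        en.obs_exp_score(1, 2, 0, 100)


@settings(deadline=None)
@given(
    st.integers(1, 50), st.integers(50, 100),
    st.integers(1, 500), st.integers(500, 1000), st.integers(2, 9),
)
def test_obs_exp_scale_invariance(k, n, K, N, c):
    assert en.obs_exp_score(c * k, c * n, c * K, c * N) == pytest.approx(
        en.obs_exp_score(k, n, K, N)
    )


@pytest.mark.parametrize("exclude_cpg,exclude_splice", [
    (False, False), (True, False), (False, True), (True, True),
])
def test_unit_counts_sum_to_global_under_exclusions(small_frame, small_bundle,
                                                    exclude_cpg, exclude_splice):
    res = en.transcript_conservation_enrichment(
        small_frame, tau=small_bundle.tau,
        exclude_cpg=exclude_cpg, exclude_splice_adjacent=exclude_splice,
    )
    sub = small_frame[small_frame["score"].notna()]
    if exclude_cpg:
        sub = sub[~sub["cpg"]]
    if exclude_splice:
        sub = sub[sub["edge_dist"] >= en.SPLICE_RADIUS_BP]
    assert res["n"].sum() == len(sub)
    assert res["k"].sum() == (sub["score"] >= small_bundle.tau).sum()


def test_enriched_genes_rank_high(small_bundle, small_frame):
    res = en.transcript_conservation_enrichment(small_frame, tau=small_bundle.tau)
    truth = small_bundle.truth.genes.set_index("transcript_id")
    enriched = truth.index[truth["enriched"]]
    others = truth.index[~truth["enriched"]]
    enriched = [t for t in enriched if t in res.index]
    mean_enriched = res.loc[enriched, "score"].mean()
    mean_other = res.loc[[t for t in others if t in res.index], "score"].mean()
    assert mean_enriched > mean_other


def test_cpg_enrichment_minimum_site_boundary(small_frame, small_bundle):
    res = en.cpg_enrichment(small_frame, tau=small_bundle.tau, min_cpg_sites=5)
    assert (res["n"] >= 5).all()
    cpg_counts = small_frame[small_frame["cpg"]].groupby("transcript_id").size()
    assert set(res.index) == set(cpg_counts.index[cpg_counts >= 5])


def test_cpg_enrichment_example_rate():
    # one transcript with 8/9 conserved CpG 4d sites against global rate r
    df = pd.DataFrame(
        {
            "transcript_id": ["t1"] * 9 + ["t2"] * 91,
            "cpg": [True] * 100,
            "score": [5.0] * 8 + [0.0] + [5.0] * 12 + [0.0] * 79,
            "edge_dist": [10] * 100,
        }
    )
    res = en.cpg_enrichment(df, tau=2.27, min_cpg_sites=5)
    r_global = 20 / 100
    assert res.loc["t1", "score"] == pytest.approx((8 / 9) / r_global)


def test_empty_cpg_catalog_gives_empty_result():
    df = pd.DataFrame(
        {"transcript_id": ["t1"], "cpg": [False], "score": [1.0], "edge_dist": [5]}
    )
    assert len(en.cpg_enrichment(df)) == 0


def test_percentile_cutoffs_order_statistics():
    scores = pd.Series(np.arange(1.0, 101.0), index=[f"t{i}" for i in range(100)])
    cuts = en.percentile_cutoffs(scores, q=(0.95, 0.0))
    thr, members = cuts[0.95]
    assert thr == pytest.approx(95.05)
    assert members == {f"t{i}" for i in range(95, 100)}  # scores 96..100
    thr0, members0 = cuts[0.0]
    assert thr0 == pytest.approx(1.0)
    assert len(members0) == 99  # strict > excludes the minimum itself


def test_percentile_all_equal_gives_empty_membership():
    scores = pd.Series([2.0, 2.0, 2.0])
    thr, members = en.percentile_cutoffs(scores, q=(0.95,))[0.95]
    assert thr == 2.0 and members == set()


def _df_with_positions():
    return pd.DataFrame(
        {
            "transcript_id": ["t1"] * 10,
            "chrom": ["chr1"] * 10,
            "pos": np.arange(0, 100, 10),
            "score": [5.0] * 2 + [0.0] * 8,
            "cpg": [False] * 10,
            "edge_dist": [10] * 10,
        }
    )


def test_tf_overlap_enrichment_tiling_and_disjoint():
    df = _df_with_positions()
    track = IntervalTrack("tfbs")
    track.add("chr1", 0, 100, "TF_ALL")      # tiles everything -> score 1
    track.add("chr1", 0, 11, "TF_CONS")      # covers only the 2 conserved sites
    track.add("chr2", 0, 100, "TF_NONE")     # disjoint -> missing
    res = en.tf_overlap_enrichment(df, track, tau=2.27)
    assert "TF_NONE" not in res.index
    # pooled rate = (2 + 2) / (10 + 2); TF_ALL observed 2/10
    pooled = 4 / 12
    assert res.loc["TF_ALL", "score"] == pytest.approx((2 / 10) / pooled)
    assert res.loc["TF_CONS", "score"] == pytest.approx(1.0 / pooled)


def test_pcg_sites_per_conserved_ratio():
    df = _df_with_positions()
    t = TranscriptModel("t1", "g1", "chr1", "+", exons=[(0, 100)], cds=[(0, 100)])
    track = IntervalTrack("EZH2")
    track.add("chr1", 0, 10)
    track.add("chr1", 20, 30)
    track.add("chr1", 40, 50)
    track.add("chr1", 60, 70)
    out = en.pcg_sites_per_conserved(df, {"t1": t}, [track], tau=2.27)
    assert out["t1"] == pytest.approx(4 / 2)
    empty = en.pcg_sites_per_conserved(df, {"t1": t}, [IntervalTrack("RNF2")], tau=2.27)
    assert empty["t1"] == 0.0


def test_class_summary_shift_and_omitted_class():
    values = pd.Series(
        {f"g{i}": 1.0 for i in range(10)} | {f"h{i}": 3.0 for i in range(10)}
    )
    classes = pd.Series(
        {f"g{i}": "c1" for i in range(10)} | {f"h{i}": "c5" for i in range(10)}
    )
    table = en.class_summary(values, classes)
    assert set(table["class"]) == {"c1", "c5"}  # c2..c4 omitted (no genes)
    means = table.set_index("class")["mean"]
    assert means["c5"] > means["c1"]


def test_class_summary_requires_two_classes():
    values = pd.Series({"g1": 1.0, "g2": 2.0})
    classes = pd.Series({"g1": "c1", "g2": "c1"})
    with pytest.raises(ValueError):
        en.class_summary(values, classes)


def test_null_permutation_calibrates_99th_percentile():
    """Uniform-conservation null: ~1% of units pass the 99th percentile."""
    rng = np.random.default_rng(5)
    n_genes = 200
    sites_per_gene = rng.poisson(40, size=n_genes) + 5
    tids = np.repeat([f"t{i:03d}" for i in range(n_genes)], sites_per_gene)
    n_sites = len(tids)
    base = pd.DataFrame(
        {
            "transcript_id": tids,
            "cpg": False,
            "edge_dist": 10,
        }
    )
    labels = np.zeros(n_sites, dtype=bool)
    labels[: int(0.2 * n_sites)] = True
    fractions = []
    for _ in range(50):
        rng.shuffle(labels)
        df = base.assign(score=np.where(labels, 3.0, 0.0))
        res = en.transcript_conservation_enrichment(df, tau=2.27)
        _, members = en.percentile_cutoffs(res["score"], q=(0.99,))[0.99]
        fractions.append(len(members) / len(res))
    assert abs(np.mean(fractions) - 0.01) < 0.005
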