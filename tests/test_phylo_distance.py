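"""Pseudosequences, p-distances and neighbour joining."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syn4d import phylo_distance as phy
from syn4d import site_catalog as sc


def test_pseudosequence_concatenation_toy():
    def rec(pos, bases):
        counts = {b: bases.count(b) for b in "ACGT"}
        return sc.SiteRecord(
            chrom="chr1", pos=pos, transcript_id="t", gene_id="g", codon_index=0,
            strand="+", ref_base=bases[0], species_bases=bases, counts=counts,
            n_aligned=len(bases),
        )

    cat = sc.Catalog(["X", "Y"], [rec(10, "GA"), rec(5, "CT")])
    seqs = phy.build_pseudosequences(cat)
    # fixed genomic order: pos 5 before pos 10
    assert seqs == {"X": "CG", "Y": "TA"}


def test_pseudosequence_lengths_equal_complete_count(small_catalog):
    seqs = phy.build_pseudosequences(small_catalog)
    n_complete = len(sc.complete_sites(small_catalog))
    assert all(len(s) == n_complete for s in seqs.values())
    assert set(seqs) == set(small_catalog.species)


@pytest.mark.parametrize(
    "a,b,expected", [("ACGT", "ACGT", 0.0), ("ACGT", "ACGA", 0.25)]
)
def test_p_distance_examples(a, b, expected):
    D = phy.p_distance_matrix({"x": a, "y": b})
    assert D.loc["x", "y"] == pytest.approx(expected)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 10_000))
def test_p_distance_symmetric_with_zero_diagonal(seed):
    rng = np.random.default_rng(seed)
    seqs = {
        f"s{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(4)
    }
    D = phy.p_distance_matrix(seqs)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert ((D.to_numpy() >= 0) & (D.to_numpy() <= 1)).all()


def test_p_distance_rejects_unequal_lengths():
    with pytest.raises(ValueError):
        phy.p_distance_matrix({"x": "ACGT", "y": "ACG"})


def test_nj_three_taxon_closed_form():
    D = pd.DataFrame(
        [[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    tree = phy.neighbor_joining(D)
    lengths = {leaf.name: leaf.branch_length for leaf in tree.leaves()}
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)
    assert phy.mean_distance(D, "A") == pytest.approx(0.25)


def test_nj_recovers_additive_five_taxon_tree():
    # caterpillar tree ((A,B),C),(D,E) with known branch lengths
    newick_tree = phy.TreeNode(
        children=[
            phy.TreeNode(name="C", branch_length=0.30),
            phy.TreeNode(
                branch_length=0.10,
                children=[
                    phy.TreeNode(name="A", branch_length=0.05),
                    phy.TreeNode(name="B", branch_length=0.20),
                ],
            ),
            phy.TreeNode(
                branch_length=0.25,
                children=[
                    phy.TreeNode(name="D", branch_length=0.15),
                    phy.TreeNode(name="E", branch_length=0.40),
                ],
            ),
        ]
    )
    D = phy.path_length_matrix(newick_tree)
    recovered = phy.neighbor_joining(D)
    assert phy.splits(recovered) == phy.splits(newick_tree)
    D2 = phy.path_length_matrix(recovered)
    assert np.allclose(D2.loc[D.index, D.columns], D, atol=1e-9)


def test_nj_star_matrix_ties_break_deterministically():
    n = 5
    names = [f"s{i}" for i in range(n)]
    D = pd.DataFrame(0.4, index=names, columns=names)
    np.fill_diagonal(D.to_numpy(), 0.0)
    D.iloc[:, :] = np.where(np.eye(n, dtype=bool), 0.0, 0.4)
    t1 = phy.neighbor_joining(D)
    t2 = phy.neighbor_joining(D)
    assert t1.newick() == t2.newick()
    leaf_lengths = {l.name: l.branch_length for l in t1.leaves()}
    assert len({round(v, 12) for v in leaf_lengths.values()}) == 1


def test_nj_matches_scikit_bio_topology(small_catalog):
    """Independent oracle: scikit-bio's NJ on the bundle's distance matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    seqs = phy.build_pseudosequences(small_catalog)
    D = phy.p_distance_matrix(seqs)
    mine = phy.neighbor_joining(D)
    sk_tree = sk_nj(SkDM(D.to_numpy(), ids=list(D.index)))
    sk_splits = set()
    all_leaves = frozenset(D.index)
    for node in sk_tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_leaves) - 1:
            sk_splits.add(min(below, frozenset(all_leaves - below), key=sorted))
    assert phy.splits(mine) == sk_splits


def test_nj_rejects_bad_matrices():
    D = pd.DataFrame(
        [[0.0, 1.0, 2.0], [0.5, 0.0, 1.0], [2.0, 1.0, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    with pytest.raises(ValueError, match="symmetric"):
        phy.neighbor_joining(D)
    D2 = pd.DataFrame(
        [[0.0, -0.1], [-0.1, 0.0]], index=list("AB"), columns=list("AB")
    )
    with pytest.raises(ValueError):
        phy.neighbor_joining(D2)


def test_distance_increases_with_tree_path_length():
    """Divergence at complete sites tracks the generating tree's paths.

    A shallow tree keeps the p-distances away from saturation so the
    rank agreement with the true path lengths is informative.
    """
    from scipy import stats

    from syn4d.synthetic_data import generate_bundle
    from tests.conftest import small_config

    bundle = generate_bundle(small_config(seed=19, n_genes=10, tree_depth=0.5))
    cat = sc.build_catalog(
        bundle.transcripts, bundle.genome, bundle.alignment, bundle.scores
    )
    seqs = phy.build_pseudosequences(cat)
    D = phy.p_distance_matrix(seqs)
    true_paths = phy.path_length_matrix(bundle.tree)
    pairs_d, pairs_t = [], []
    names = list(D.index)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs_d.append(D.loc[a, b])
            pairs_t.append(true_paths.loc[a, b])
    rho = stats.spearmanr(pairs_d, pairs_t).statistic
    assert rho > 0.5


def test_mean_distance_two_species():
    D = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["a", "b"], columns=["a", "b"])
    assert phy.mean_distance(D, "a") == pytest.approx(0.1)
    assert phy.mean_distance(D, "b") == pytest.approx(0.1)


def test_newick_round_trip_byte_stable(small_bundle, tmp_path):
    p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
    phy.write_newick(small_bundle.tree, str(p1))
    back = phy.read_newick(str(p1))
    phy.write_newick(back, str(p2))
    assert p1.read_text() == p2.read_text()
    # topology and lengths preserved
    d1 = phy.path_length_matrix(small_bundle.tree)
    d2 = phy.path_length_matrix(back)
    assert np.allclose(d1, d2.loc[d1.index, d1.columns], atol=1e-12)
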