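"""Statistical layer: OLS with relative-importance decomposition,
correlations, and group comparisons.

The conservation model regresses per-site conservation scores (kept
only where the score is >= 0, so the model explains conservation, not
acceleration) on the site's sequence-context and regulatory-overlap
features.  "Relative importance" is the LMG / Shapley decomposition of
the model r-squared: each predictor's share is its average increment to
r-squared over predictor orderings (exact enumeration up to 16
predictors, seeded sampling of orderings beyond that), normalised to
sum to one.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import genetic_code as gc
from .conservation_summary import assign_local_gc, genome_window_gc
from .formats_io import IntervalTrack, TranscriptModel
from .site_catalog import Catalog, spliced_cds

log = logging.getLogger(__name__)


@dataclass
class LinearModelFit:
    response: str
    table: pd.DataFrame  # index: Intercept + predictors; estimate, se, t, p
    r_squared: float
    n: int


# ---------------------------------------------------------------------------
# OLS and correlations
# ---------------------------------------------------------------------------

def fit_ols(y: np.ndarray, X: pd.DataFrame, response: str = "y") -> LinearModelFit:
    """Gaussian OLS with classical standard errors and t tests.

    Raises on a rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > p + 1 observations")
    _check_rank(X)
    design = sm.add_constant(X.astype(float), prepend=True)
    res = sm.OLS(y, design).fit()
    names = ["Intercept"] + list(X.columns)
    table = pd.DataFrame(
        {
            "estimate": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "t": res.tvalues.to_numpy(),
            "p": res.pvalues.to_numpy(),
        },
        index=names,
    )
    return LinearModelFit(
        response=response, table=table, r_squared=float(res.rsquared), n=len(y)
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify offending columns by rank drop on removal
    bad = []
    for i, col in enumerate(X.columns):
        reduced = np.delete(arr, i + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(col)
    raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

def _subset_r2_cache(y: np.ndarray, X: np.ndarray) -> dict[int, float]:
    """r-squared for every predictor subset, keyed by bitmask.

    Uses the centered cross-product matrices, so each subset costs one
    small positive-definite solve.
    """
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Sxx = Xc.T @ Xc
    Sxy = Xc.T @ yc
    Syy = float(yc @ yc)
    p = X.shape[1]
    cache = {0: 0.0}
    for mask in range(1, 1 << p):
        idx = [i for i in range(p) if mask >> i & 1]
        A = Sxx[np.ix_(idx, idx)]
        b = Sxy[idx]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        cache[mask] = float(b @ beta / Syy) if Syy > 0 else 0.0
    return cache


def lmg_importance(
    y: np.ndarray,
    X: pd.DataFrame,
    mode: str = "exact",
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.Series:
    """LMG (Shapley) shares of r-squared per predictor, normalised to sum 1.

    mode="exact" averages a predictor's r-squared increment over all
    orderings via subset enumeration (p <= 16); mode="sampled" averages
    over ``n_perm`` seeded random orderings.
    """
    y = np.asarray(y, dtype=float)
    arr = X.to_numpy(dtype=float)
    p = arr.shape[1]
    names = list(X.columns)
    if p == 1:
        return pd.Series([1.0], index=names)

    if mode == "exact":
        if p > 16:
            raise ValueError("exact mode enumerates 2^p subsets; use sampled for p > 16")
        cache = _subset_r2_cache(y, arr)
        fact = [math.factorial(k) for k in range(p + 1)]
        shares = np.zeros(p)
        for mask in range(1 << p):
            k = bin(mask).count("1")
            w = fact[k] * fact[p - k - 1] / fact[p]
            r2_s = cache[mask]
            for j in range(p):
                if mask >> j & 1:
                    continue
                shares[j] += w * (cache[mask | (1 << j)] - r2_s)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        Xc = arr - arr.mean(axis=0)
        yc = y - y.mean()
        Sxx = Xc.T @ Xc
        Sxy = Xc.T @ yc
        Syy = float(yc @ yc)

        def r2(idx: list[int]) -> float:
            if not idx:
                return 0.0
            A, b = Sxx[np.ix_(idx, idx)], Sxy[idx]
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(A, b, rcond=None)[0]
            return float(b @ beta / Syy)

        shares = np.zeros(p)
        for _ in range(n_perm):
            order = rng.permutation(p)
            prev, chosen = 0.0, []
            for j in order:
                chosen.append(int(j))
                cur = r2(chosen)
                shares[j] += cur - prev
                prev = cur
        shares /= n_perm
    else:
        raise ValueError(f"unknown mode {mode!r}")

    total = shares.sum()
    if total <= 0:
        return pd.Series(np.full(p, 1.0 / p), index=names)
    return pd.Series(shares / total, index=names)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_compare(values: np.ndarray, groups: np.ndarray) -> dict:
    """ANOVA across groups with Tukey HSD post hoc; Welch t and the
    Wilcoxon rank-sum W (first-group rank sum, average ranks for ties)
    for the two-group case.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g] for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    if all(np.var(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        raise ValueError("zero variance everywhere: F undefined")
    k = len(labels)
    n_total = len(values)
    f_stat, f_p = stats.f_oneway(*arrays)
    out: dict = {
        "anova": {
            "F": float(f_stat),
            "df_between": k - 1,
            "df_within": n_total - k,
            "p": float(f_p),
        },
        "groups": {g: {"n": len(a), "mean": float(a.mean())} for g, a in zip(labels, arrays)},
    }
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tukey = pairwise_tukeyhsd(values, groups)
    out["tukey"] = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    if k == 2:
        a, b = arrays
        t_res = stats.ttest_ind(a, b, equal_var=False)
        ranks = stats.rankdata(values)
        W = float(ranks[groups == labels[0]].sum())
        u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
        out["welch"] = {"t": float(t_res.statistic), "df": float(t_res.df), "p": float(t_res.pvalue)}
        out["wilcoxon"] = {"W": W, "p": float(u_res.pvalue)}
    return out


# ---------------------------------------------------------------------------
# the conservation model feature assembly and fit
# ---------------------------------------------------------------------------

MODEL_FEATURES = [
    "gc_proportion",        # mammalian G+C fraction at the site
    "dist_exon_edge",       # bp to the nearest exon boundary
    "background_gc",        # 1-Mb window GC of the transcript locus
    "ccre",                 # candidate cis-regulatory element overlap
    "n_exons",              # exon count of the transcript
    "tfbs",                 # TF binding-site overlap
    "uorf",                 # upstream ORF overlap
    "cpg",                  # CpG context flag
    "syn_mu",               # per-gene synonymous mutation rate
    "n_aligned",            # aligned species count
    "ese_70bp",             # ESE hexamer within 70 bp of an exon end
    "rbp",                  # RNA-binding protein site overlap
    "lncrna",               # lncRNA overlap
    "mirna",                # miRNA target-site overlap
]

ESE_EDGE_WINDOW_BP = 70


def ese_site_flags(
    catalog: Catalog,
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
    hexamers: set[str],
    edge_window: int = ESE_EDGE_WINDOW_BP,
) -> pd.Series:
    """Flag catalog sites inside an ESE hexamer near an exon end.

    Hexamer occurrences are scanned on the spliced CDS; a site is
    flagged when it falls inside an occurrence and lies within
    ``edge_window`` bp of either end of its exon.
    """
    in_hex_by_tid: dict[str, np.ndarray] = {}
    flags = {}
    for i, r in enumerate(catalog):
        mask = in_hex_by_tid.get(r.transcript_id)
        if mask is None:
            seq = spliced_cds(transcripts[r.transcript_id], genome)
            mask = np.zeros(len(seq), dtype=bool)
            for start in range(len(seq) - 5):
                if seq[start: start + 6] in hexamers:
                    mask[start: start + 6] = True
            in_hex_by_tid[r.transcript_id] = mask
        spliced_pos = r.codon_index * 3 + 2
        flags[i] = bool(mask[spliced_pos]) and 0 <= r.edge_dist < edge_window
    return pd.Series(flags)


def assemble_site_features(
    catalog: Catalog,
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
    tracks: dict[str, IntervalTrack],
    syn_mu: pd.Series,
    ese_hexamers: set[str],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-site design matrix for the conservation model.

    ``tracks`` maps feature names (ccre, tfbs, uorf, rbp, lncrna,
    mirna) to interval tracks; ``syn_mu`` is the per-gene synonymous
    mutation rate.
    """
    df = catalog.to_frame()
    wgc = genome_window_gc(genome, window)
    local_gc = {
        tid: assign_local_gc(transcripts[tid], wgc) for tid in sorted(transcripts)
    }
    feat = pd.DataFrame(index=df.index)
    feat["score"] = df["score"]
    feat["gc_proportion"] = (df["count_G"] + df["count_C"]) / df["n_aligned"]
    feat["dist_exon_edge"] = df["edge_dist"].astype(float)
    feat["background_gc"] = df["transcript_id"].map(local_gc)
    feat["n_exons"] = df["transcript_id"].map(
        {tid: t.exon_count for tid, t in transcripts.items()}
    ).astype(float)
    feat["cpg"] = df["cpg"].astype(float)
    feat["syn_mu"] = df["gene_id"].map(syn_mu)
    feat["n_aligned"] = df["n_aligned"].astype(float)
    for name in ("ccre", "tfbs", "uorf", "rbp", "lncrna", "mirna"):
        track = tracks.get(name)
        if track is None:
            feat[name] = 0.0
            continue
        feat[name] = [
            float(track.covers(c, int(p))) for c, p in zip(df["chrom"], df["pos"])
        ]
    feat["ese_70bp"] = ese_site_flags(
        catalog, transcripts, genome, ese_hexamers
    ).astype(float).to_numpy()
    return feat


def conservation_model(
    features: pd.DataFrame,
    min_score: float = 0.0,
    importance_mode: str = "exact",
    n_perm: int = 500,
    seed: int | None = None,
) -> tuple[LinearModelFit, pd.Series]:
    """Fit the conservation OLS on sites with score >= min_score.

    Constant features are dropped with a warning; returns the fit and
    the LMG importance shares of the retained predictors.
    """
    sub = features[features["score"].notna() & (features["score"] >= min_score)]
    sub = sub.dropna()
    cols = [c for c in MODEL_FEATURES if c in sub.columns]
    kept = []
    for c in cols:
        if sub[c].nunique() <= 1:
            log.warning("conservation_model: dropping constant feature %s", c)
            continue
        kept.append(c)
    X = sub[kept]
    y = sub["score"].to_numpy()
    fit = fit_ols(y, X, response="score")
    shares = lmg_importance(y, X, mode=importance_mode, n_perm=n_perm, seed=seed)
    return fit, shares
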