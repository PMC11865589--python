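"""Observed/expected conservation-enrichment scoring.

The unit of enrichment is a transcript (4d sites or 4d CpG sites as
events) or a transcription factor (site-by-binding-interval overlap
pairs as events).  The score is the observed conserved-event rate in
the unit divided by the global conserved-event rate, so 1 means "as
expected", 0 means no conserved events, and a unit with no events has
no score.  Percentile cut-offs are linear-interpolation empirical
quantiles with strict (>) membership.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .conservation_summary import DEFAULT_TAU
from .formats_io import IntervalTrack, TranscriptModel

log = logging.getLogger(__name__)

SPLICE_RADIUS_BP = 3  # exclusion radius around exon edges


def obs_exp_score(k_unit: int, n_unit: int, K_global: int, N_global: int) -> float:
    """(k/n) / (K/N); NaN when the unit has no events; error when K == 0."""
    if K_global == 0:
        raise ValueError("no conserved events globally")
    if N_global <= 0:
        raise ValueError("global event total must be positive")
    if n_unit == 0:
        return math.nan
    return (k_unit / n_unit) / (K_global / N_global)


def _scores_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Attach obs/exp scores and percentile ranks to per-unit (k, n) counts."""
    K, N = int(counts["k"].sum()), int(counts["n"].sum())
    counts = counts.copy()
    counts["observed_rate"] = counts["k"] / counts["n"]
    counts["expected_rate"] = K / N if N else math.nan
    counts["score"] = [
        obs_exp_score(int(k), int(n), K, N) for k, n in zip(counts["k"], counts["n"])
    ]
    counts["percentile"] = counts["score"].rank(pct=True)
    return counts


def _conserved_mask(df: pd.DataFrame, tau: float) -> pd.Series:
    return df["score"].notna() & (df["score"] >= tau)


def transcript_conservation_enrichment(
    df: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    exclude_cpg: bool = False,
    exclude_splice_adjacent: bool = False,
    splice_radius: int = SPLICE_RADIUS_BP,
) -> pd.DataFrame:
    """Per-transcript enrichment of conserved 4d sites.

    Exclusion flags remove CpG-context sites and/or sites within
    ``splice_radius`` bp of an exon edge before counting; both the
    per-unit and the global counts are recomputed under the same
    exclusion.
    """
    sub = df[df["score"].notna()]
    if exclude_cpg:
        sub = sub[~sub["cpg"]]
    if exclude_splice_adjacent:
        sub = sub[sub["edge_dist"] >= splice_radius]
    counts = (
        sub.assign(conserved=_conserved_mask(sub, tau))
        .groupby("transcript_id")
        .agg(k=("conserved", "sum"), n=("conserved", "size"))
    )
    return _scores_from_counts(counts)


def cpg_enrichment(
    df: pd.DataFrame, tau: float = DEFAULT_TAU, min_cpg_sites: int = 5
) -> pd.DataFrame:
    """Per-transcript enrichment of conserved 4d sites in CpG context.

    Transcripts with fewer than ``min_cpg_sites`` CpG 4d sites are
    excluded from the ranking.
    """
    sub = df[df["score"].notna() & df["cpg"]]
    if len(sub) == 0:
        log.info("cpg_enrichment: no CpG-context 4d sites in catalog")
        return pd.DataFrame(
            columns=["k", "n", "observed_rate", "expected_rate", "score", "percentile"]
        )
    counts = (
        sub.assign(conserved=_conserved_mask(sub, tau))
        .groupby("transcript_id")
        .agg(k=("conserved", "sum"), n=("conserved", "size"))
    )
    counts = counts[counts["n"] >= min_cpg_sites]
    return _scores_from_counts(counts)


def percentile_cutoffs(
    scores: pd.Series, q: tuple[float, ...] = (0.95, 0.99)
) -> dict[float, tuple[float, set]]:
    """Empirical quantile thresholds with strict-greater membership sets."""
    vals = scores.dropna()
    if len(vals) < 2:
        raise ValueError("need at least two finite scores")
    out = {}
    for quant in q:
        thr = float(np.quantile(vals.to_numpy(), quant, method="linear"))
        members = set(vals.index[vals > thr])
        if not members and vals.nunique() == 1:
            log.warning("percentile_cutoffs: all scores equal, empty membership")
        out[quant] = (thr, members)
    return out


def tf_overlap_enrichment(
    df: pd.DataFrame,
    tf_intervals: IntervalTrack,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Per-TF enrichment of conserved 4d sites among binding-site overlaps.

    Events are (site, interval) overlap pairs; the global expectation
    pools all TFs.  A TF whose intervals overlap no catalog site gets
    no score.
    """
    sub = df[df["score"].notna()]
    conserved = _conserved_mask(sub, tau).to_numpy()
    tf_names = sorted(tf_intervals.labels())
    k = {tf: 0 for tf in tf_names}
    n = {tf: 0 for tf in tf_names}
    for (chrom, pos), cons in zip(
        zip(sub["chrom"].to_numpy(), sub["pos"].to_numpy()), conserved
    ):
        for _, _, label in tf_intervals.overlapping(chrom, int(pos), int(pos) + 1):
            if label is None:
                continue
            n[label] += 1
            if cons:
                k[label] += 1
    counts = pd.DataFrame(
        {"k": pd.Series(k), "n": pd.Series(n)}
    ).loc[lambda d: d["n"] > 0]
    if len(counts) == 0 or counts["k"].sum() == 0:
        raise ValueError("no conserved events globally")
    return _scores_from_counts(counts)


def pcg_sites_per_conserved(
    df: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    pcg_tracks: list[IntervalTrack],
    tau: float = DEFAULT_TAU,
) -> pd.Series:
    """PcG binding intervals per conserved 4d site, per gene.

    The overlap is measured on the gene's genomic span (transcript
    start to end), summed over the supplied PcG tracks; genes without a
    conserved 4d site have no ratio.
    """
    sub = df[df["score"].notna()]
    cons_per_tid = (
        sub.assign(conserved=_conserved_mask(sub, tau))
        .groupby("transcript_id")["conserved"].sum()
    )
    out = {}
    for tid, n_cons in cons_per_tid.items():
        if n_cons < 1:
            continue
        t = transcripts[tid]
        s, e = t.span
        n_pcg = sum(track.n_overlapping(t.chrom, s, e) for track in pcg_tracks)
        out[tid] = n_pcg / n_cons
    return pd.Series(out, dtype=float)


def class_summary(
    values: pd.Series, classes: pd.Series
) -> pd.DataFrame:
    """Descriptive per-class table (n, mean, median) for gene methylation classes.

    Genes missing from the class map are excluded; classes with no
    mapped genes are omitted.  Inference on the class differences is
    delegated to :func:`syn4d.model_stats.group_compare`.
    """
    joined = pd.DataFrame({"value": values}).join(
        classes.rename("class"), how="inner"
    ).dropna()
    if joined["class"].nunique() < 2:
        raise ValueError("need at least two represented classes")
    return (
        joined.groupby("class")["value"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
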