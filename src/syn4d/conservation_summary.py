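"""Descriptive conservation summaries over the shared-4d catalog.

Classification at the conservation threshold tau (inclusive, score >=
tau), per-transcript GC4 in human-reference and mammal-summed modes,
mean scores split by AT/GC reference base, exon-position classes around
splice junctions, splice-position base tables, score-binned base
counts, 1-Mb window GC context, and GC4 distributions for the
single-exon / first / last / internal exon groups.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .formats_io import TranscriptModel
from .site_catalog import Catalog

log = logging.getLogger(__name__)

DEFAULT_TAU = 2.27

EDGE_CLASSES = ["5p+1", "5p+2", "5p+3", "3p-1", "3p-2", "internal"]


def classify_conserved(scores: pd.Series, tau: float = DEFAULT_TAU) -> pd.Series:
    """Boolean conserved call per site: score >= tau (inclusive).

    Sites without a score are not classifiable; they come back as
    pandas NA and are excluded (with a logged count) from downstream
    fractions.
    """
    missing = int(scores.isna().sum())
    if missing:
        log.info("classify_conserved: %d sites without scores excluded", missing)
    out = pd.Series(pd.NA, index=scores.index, dtype="boolean")
    out[scores.notna()] = scores[scores.notna()] >= tau
    return out


def conserved_fraction(scores: pd.Series, tau: float = DEFAULT_TAU) -> float:
    calls = classify_conserved(scores, tau).dropna()
    if len(calls) == 0:
        return math.nan
    return float(calls.mean())


# ---------------------------------------------------------------------------
# GC4 and score summaries
# ---------------------------------------------------------------------------

def transcript_gc4(df: pd.DataFrame, mode: str = "human") -> pd.Series:
    """Per-transcript GC fraction at 4d sites.

    mode="human": fraction of sites whose reference base is G or C.
    mode="mammal": (sum G + sum C) / (sum aligned) over all per-species
    bases at the transcript's 4d sites.
    """
    if mode == "human":
        isgc = df["ref_base"].isin(["G", "C"]).astype(float)
        return isgc.groupby(df["transcript_id"]).mean()
    if mode == "mammal":
        grp = df.groupby("transcript_id")[["count_G", "count_C", "n_aligned"]].sum()
        return (grp["count_G"] + grp["count_C"]) / grp["n_aligned"]
    raise ValueError(f"unknown GC4 mode {mode!r}")


def mean_score_by_base_class(df: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript mean score over AT-reference and GC-reference 4d sites.

    A transcript with no site in one class gets NaN for that component.
    """
    sub = df[df["score"].notna()].copy()
    sub["base_class"] = np.where(sub["ref_base"].isin(["G", "C"]), "GC", "AT")
    table = sub.pivot_table(
        index="transcript_id", columns="base_class", values="score", aggfunc="mean"
    )
    return table.reindex(columns=["AT", "GC"])


def score_binned_base_counts(df: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Per-score-bin mammalian base counts (left-closed unit bins on integers)."""
    sub = df[df["score"].notna()]
    if len(sub) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "A", "C", "G", "T", "n_sites"])
    lo = math.floor(sub["score"].min() / bin_width) * bin_width
    hi = math.ceil(sub["score"].max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(
        np.floor((sub["score"].to_numpy() - lo) / bin_width).astype(int),
        0, len(edges) - 2,
    )
    out = []
    for b in range(len(edges) - 1):
        rows = sub.iloc[np.nonzero(idx == b)[0]]
        out.append(
            (
                edges[b], edges[b + 1],
                int(rows["count_A"].sum()), int(rows["count_C"].sum()),
                int(rows["count_G"].sum()), int(rows["count_T"].sum()),
                len(rows),
            )
        )
    return pd.DataFrame(out, columns=["bin_left", "bin_right", "A", "C", "G", "T", "n_sites"])


# ---------------------------------------------------------------------------
# exon positions and splice tables
# ---------------------------------------------------------------------------

def exon_position_class(
    pos: int, transcript: TranscriptModel
) -> tuple[str, int, int]:
    """Splice-adjacency class, distance to the nearest exon edge, exon index.

    Classes (transcription order): "5p+1/+2/+3" are the first three
    bases of a non-first exon (just downstream of a 3' splice site),
    "3p-1/-2" the last and penultimate base of a non-last exon (just
    upstream of a 5' splice site); anything else, and every position of
    a single-exon transcript, is "internal".  In a very short exon that
    could host both labels, the 5' label wins.  The distance is the
    minimum bp to either boundary of the containing exon (0 at an
    edge).
    """
    for idx, (s, e) in enumerate(transcript.exons):
        if s <= pos < e:
            break
    else:
        raise ValueError(
            f"position {pos} outside exons of {transcript.transcript_id}"
        )
    length = e - s
    off5 = pos - s if transcript.strand == "+" else e - 1 - pos
    off3 = length - 1 - off5
    dist = min(off5, off3)
    n = transcript.exon_count
    if n == 1:
        return "internal", dist, idx
    if idx > 0 and off5 <= 2:
        return f"5p+{off5 + 1}", dist, idx
    if idx < n - 1 and off3 <= 1:
        return ("3p-1" if off3 == 0 else "3p-2"), dist, idx
    return "internal", dist, idx


def annotate_exon_positions(
    catalog: Catalog, transcripts: dict[str, TranscriptModel]
) -> None:
    """Attach edge class and edge distance to every catalog record."""
    for r in catalog:
        cls, dist, _ = exon_position_class(r.pos, transcripts[r.transcript_id])
        r.edge_class = cls
        r.edge_dist = dist


def splice_base_table(df: pd.DataFrame, conserved_only: bool = False,
                      tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Base proportions per splice-position class.

    Two counting modes are reported per class: "mammal" sums the
    per-species base counts across all species; "human" tallies the
    reference base.  Non-empty rows have proportions summing to 1.
    """
    sub = df
    if conserved_only:
        sub = df[df["score"].notna() & (df["score"] >= tau)]
    rows = []
    for cls in EDGE_CLASSES:
        cls_rows = sub[sub["edge_class"] == cls]
        n = len(cls_rows)
        mam = np.array(
            [cls_rows[f"count_{b}"].sum() for b in "ATCG"], dtype=float
        )
        hum = np.array(
            [(cls_rows["ref_base"] == b).sum() for b in "ATCG"], dtype=float
        )
        for mode, counts in (("mammal", mam), ("human", hum)):
            total = counts.sum()
            props = counts / total if total > 0 else [math.nan] * 4
            rows.append((cls, mode, n, *props))
    return pd.DataFrame(
        rows, columns=["class", "mode", "n_sites", "prop_A", "prop_T", "prop_C", "prop_G"]
    )


# ---------------------------------------------------------------------------
# local GC context
# ---------------------------------------------------------------------------

def genome_window_gc(genome: dict[str, str], window: int = 1_000_000) -> pd.DataFrame:
    """GC fraction in fixed windows across the genome (N excluded; all-N = NaN)."""
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        for start in range(0, len(seq), window):
            chunk = seq[start: start + window]
            acgt = sum(chunk.count(b) for b in "ACGT")
            gc_n = chunk.count("G") + chunk.count("C")
            rows.append(
                (chrom, start, min(start + window, len(seq)),
                 gc_n / acgt if acgt else math.nan)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


def assign_local_gc(
    transcript: TranscriptModel, window_gc: pd.DataFrame
) -> float:
    """Overlap-length weighted mean window GC over the transcript span."""
    s, e = transcript.span
    rows = window_gc[
        (window_gc["chrom"] == transcript.chrom)
        & (window_gc["end"] > s)
        & (window_gc["start"] < e)
    ]
    weights, values = [], []
    for _, w in rows.iterrows():
        if math.isnan(w["gc"]):
            continue
        ov = min(e, w["end"]) - max(s, w["start"])
        weights.append(ov)
        values.append(w["gc"])
    if not weights:
        return math.nan
    return float(np.average(values, weights=weights))


# ---------------------------------------------------------------------------
# exon-group GC4
# ---------------------------------------------------------------------------

def exon_group_gc4(
    df: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
    min_sites: int = 10,
) -> dict[str, pd.Series]:
    """Mammal-mode GC4 per qualifying unit, grouped by exon position.

    Groups: "single_exon" (whole transcripts of single-exon genes),
    "first_exon" / "last_exon" / "internal_exon" (individual exons of
    multi-exon transcripts).  A unit qualifies only with strictly more
    than ``min_sites`` 4d sites.
    """
    exon_idx = np.empty(len(df), dtype=int)
    for i, (tid, pos) in enumerate(zip(df["transcript_id"], df["pos"])):
        _, _, idx = exon_position_class(int(pos), transcripts[tid])
        exon_idx[i] = idx
    work = df.assign(exon_idx=exon_idx)

    def gc4_mammal(rows: pd.DataFrame) -> float:
        return (rows["count_G"].sum() + rows["count_C"].sum()) / rows["n_aligned"].sum()

    groups: dict[str, dict[str, float]] = {
        "single_exon": {}, "first_exon": {}, "last_exon": {}, "internal_exon": {}
    }
    for tid, trows in work.groupby("transcript_id"):
        t = transcripts[tid]
        if t.single_exon:
            if len(trows) > min_sites:
                groups["single_exon"][tid] = gc4_mammal(trows)
            continue
        for idx, erows in trows.groupby("exon_idx"):
            if len(erows) <= min_sites:
                continue
            if idx == 0:
                key = "first_exon"
            elif idx == t.exon_count - 1:
                key = "last_exon"
            else:
                key = "internal_exon"
            groups[key][f"{tid}:exon{idx}"] = gc4_mammal(erows)
    return {k: pd.Series(v, dtype=float) for k, v in groups.items()}
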