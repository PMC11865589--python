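"""Population-variant overlay on the shared-4d catalog.

Couples a table of biallelic SNVs (major/minor allele + minor allele
frequency) to the catalog, then summarises variability by conservation:
the fraction of variable sites per score bin (optionally stratified by
the mammalian major base), a Pearson chi-square of the 12 variant types
(4 major x 3 minor alleles, forward-strand) among conserved variable
sites against type proportions from all variable sites, and a Welch
two-sample t comparison of MAF between conserved and non-conserved
sites.  Alleles are handled in reference-forward orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import genetic_code as gc
from .conservation_summary import DEFAULT_TAU

log = logging.getLogger(__name__)

VARIANT_TYPES = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]  # 12 ordered major->minor pairs


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    table: pd.DataFrame  # per category: observed, expected, residual
    p_value: float


def overlay(df: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Join the variant table onto the catalog frame.

    Output columns add: ``maf`` (0 when the site is monomorphic),
    ``major``, ``minor`` (forward strand; NA when monomorphic),
    ``variant_type`` (major->minor, only when variable) and
    ``ref_matches_major``.  Sites whose monomorphic allele disagrees
    with the reference base are counted and warned about.
    """
    out = df.copy()
    # forward-strand reference base at the site
    fwd_ref = [
        b if s == "+" else gc.complement_base(b)
        for b, s in zip(out["ref_base"], out["strand"])
    ]
    out["ref_base_fwd"] = fwd_ref
    var = variants.set_index(["chrom", "pos"])
    idx = pd.MultiIndex.from_arrays([out["chrom"], out["pos"]])
    joined = var.reindex(idx)
    out["maf"] = joined["maf"].fillna(0.0).to_numpy()
    out["major"] = joined["major"].to_numpy()
    out["minor"] = joined["minor"].to_numpy()
    monomorphic = out["maf"] == 0
    out.loc[monomorphic, ["major", "minor"]] = pd.NA
    out["variant_type"] = pd.NA
    variable = ~monomorphic
    out.loc[variable, "variant_type"] = (
        out.loc[variable, "major"] + ">" + out.loc[variable, "minor"]
    )
    out["ref_matches_major"] = True
    out.loc[variable, "ref_matches_major"] = (
        out.loc[variable, "major"] == out.loc[variable, "ref_base_fwd"]
    )
    mismatches = int((~out["ref_matches_major"]).sum())
    if mismatches:
        log.info("overlay: %d sites where reference != major allele", mismatches)
    bad = joined["ref"].notna().to_numpy() & monomorphic.to_numpy()
    if bad.any():
        ref_disagree = (
            joined["ref"].to_numpy()[bad] != out["ref_base_fwd"].to_numpy()[bad]
        ).sum()
        if ref_disagree:
            log.warning(
                "overlay: %d monomorphic variant records disagree with the reference base",
                int(ref_disagree),
            )
    return out


def variable_fraction_by_bin(
    ov: pd.DataFrame,
    maf_min: float = 0.0,
    bin_width: float = 1.0,
    stratify_by_major_base: bool = False,
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Fraction of variable sites (MAF strictly > maf_min) per score bin.

    Bins are the unit-width, integer-aligned convention of the score
    summaries.  When stratified, the mammalian major base defines the
    strata.  Each row reports the bin mean score for correlation
    against the variable fraction.
    """
    sub = ov[ov["score"].notna()].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "major_base", "n", "n_variable", "fraction", "mean_score"])
    lo = math.floor(sub["score"].min() / bin_width) * bin_width
    sub["bin_left"] = (np.floor(sub["score"] / bin_width) * bin_width).astype(float)
    sub["variable"] = sub["maf"] > maf_min
    keys = ["bin_left", "major_base"] if stratify_by_major_base else ["bin_left"]
    rows = []
    for key, grp in sub.groupby(keys):
        left = key[0] if isinstance(key, tuple) else key
        base = key[1] if stratify_by_major_base else "all"
        rows.append(
            (
                left, left + bin_width, base, len(grp),
                int(grp["variable"].sum()), float(grp["variable"].mean()),
                float(grp["score"].mean()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["bin_left", "bin_right", "major_base", "n", "n_variable", "fraction", "mean_score"],
    ).sort_values(["major_base", "bin_left"]).reset_index(drop=True)


def variant_type_chisq(
    ov: pd.DataFrame, tau: float = DEFAULT_TAU, subset_mask: pd.Series | None = None
) -> ChiSqResult:
    """Pearson chi-square of variant-type proportions in a subset.

    Observed counts are the 12 major->minor types among *variable*
    sites of the subset (default: conserved sites, score >= tau);
    expected counts scale the type proportions of all variable sites
    regardless of conservation.  Types absent globally are dropped with
    a reduced df.  Residuals are Pearson residuals (O - E)/sqrt(E).
    """
    variable = ov[ov["maf"] > 0]
    if subset_mask is None:
        subset_mask = ov["score"].notna() & (ov["score"] >= tau)
    subset = ov[subset_mask & (ov["maf"] > 0)]
    if len(subset) == 0:
        raise ValueError("subset has no variable sites")
    global_counts = variable["variant_type"].value_counts().reindex(VARIANT_TYPES, fill_value=0)
    dropped = [t for t in VARIANT_TYPES if global_counts[t] == 0]
    if dropped:
        log.info("variant_type_chisq: dropping empty global categories %s", dropped)
    kept = [t for t in VARIANT_TYPES if global_counts[t] > 0]
    obs = subset["variant_type"].value_counts().reindex(kept, fill_value=0).astype(float)
    props = global_counts[kept] / global_counts[kept].sum()
    exp = props * len(subset)
    resid = (obs - exp) / np.sqrt(exp)
    statistic = float((resid ** 2).sum())
    dof = len(kept) - 1
    p = float(stats.chi2.sf(statistic, dof)) if dof > 0 else math.nan
    table = pd.DataFrame(
        {"observed": obs, "expected": exp, "residual": resid}
    )
    table.index.name = "variant_type"
    return ChiSqResult(statistic=statistic, df=dof, table=table, p_value=p)


def maf_group_compare(ov: pd.DataFrame, tau: float = DEFAULT_TAU) -> dict:
    """Welch two-sample t of MAF at conserved vs non-conserved sites."""
    scored = ov[ov["score"].notna()]
    cons = scored.loc[scored["score"] >= tau, "maf"].to_numpy()
    noncons = scored.loc[scored["score"] < tau, "maf"].to_numpy()
    if len(cons) < 2 or len(noncons) < 2:
        raise ValueError("both groups need at least two sites")
    res = stats.ttest_ind(cons, noncons, equal_var=False)
    return {
        "mean_conserved": float(cons.mean()),
        "mean_nonconserved": float(noncons.mean()),
        "sd_conserved": float(cons.std(ddof=1)),
        "sd_nonconserved": float(noncons.std(ddof=1)),
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "n_conserved": int(len(cons)),
        "n_nonconserved": int(len(noncons)),
    }
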