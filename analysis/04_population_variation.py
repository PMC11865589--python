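"""Population variation at 4d sites.

Overlays the variant table on the catalog, summarises the variable
fraction per score bin, tests variant-type proportions among conserved
sites against the global expectation (Pearson chi-square with
residuals), and compares MAF between conserved and non-conserved sites
(Welch t).
"""

from scipy import stats

from _common import RESULTS, load_fixture, load_tau
from syn4d import formats_io as fio
from syn4d import popvar

*_, variants = load_fixture()
df = fio.read_tsv(str(RESULTS / "site_catalog.tsv"))
tau = load_tau()

ov = popvar.overlay(df, variants)
fio.write_tsv(
    ov[["chrom", "pos", "transcript_id", "score", "maf", "variant_type",
        "ref_matches_major"]],
    str(RESULTS / "variant_overlay.tsv"),
)

table = popvar.variable_fraction_by_bin(ov, maf_min=0.0, tau=tau)
fio.write_tsv(table, str(RESULTS / "variable_fraction_by_bin.tsv"))
big = table[table["n"] >= 30]
rho = stats.spearmanr(big["mean_score"], big["fraction"]).statistic
print(f"variable fraction vs score bin: Spearman rho = {rho:.2f}")

chisq = popvar.variant_type_chisq(ov, tau=tau)
fio.write_tsv(chisq.table.reset_index(), str(RESULTS / "variant_type_chisq.tsv"))
print(
    f"variant types at conserved sites: chi2 = {chisq.statistic:.1f}, "
    f"d.f. = {chisq.df}, P = {chisq.p_value:.3g}"
)

maf = popvar.maf_group_compare(ov, tau=tau)
print(
    f"MAF conserved vs non-conserved: {maf['mean_conserved']:.2e} vs "
    f"{maf['mean_nonconserved']:.2e} (Welch t = {maf['t']:.2f}, "
    f"d.f. = {maf['df']:.0f}, P = {maf['p']:.3g})"
)
print("wrote variant_overlay, variable_fraction_by_bin, variant_type_chisq")
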