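"""Linear model of 4d-site conservation with relative importance.

Assembles the per-site feature matrix (mammalian GC proportion,
distance to exon edge, background window GC, regulatory-overlap flags,
CpG context, per-gene synonymous mutation rate, aligned-species count,
ESE-within-70-bp flag), fits OLS on sites with non-negative scores and
decomposes the model r-squared into LMG relative-importance shares.
"""

from _common import FIXTURE, RESULTS, load_fixture, load_tau
from syn4d import conservation_summary as cs
from syn4d import formats_io as fio
from syn4d import model_stats as ms
from syn4d import site_catalog as sc

genome, transcripts, alignment, scores, _ = load_fixture()
catalog = sc.build_catalog(transcripts, genome, alignment, scores)
cs.annotate_exon_positions(catalog, transcripts)

tracks = {
    name: fio.read_intervals(str(FIXTURE / f"track_{name}.bed"), name=name)
    for name in ("tfbs", "ccre", "rbp", "uorf", "lncrna", "mirna")
}
syn_mu = fio.read_tsv(str(FIXTURE / "gene_mu.tsv")).set_index("gene_id")["syn_mu"]
with open(FIXTURE / "ese_hexamers.txt") as fh:
    hexamers = {line.strip() for line in fh if line.strip()}

feats = ms.assemble_site_features(
    catalog, transcripts, genome, tracks, syn_mu, hexamers, window=20_000
)
fit, shares = ms.conservation_model(feats, min_score=0.0, importance_mode="exact")

table = fit.table.copy()
table["relative_importance"] = shares.reindex(table.index)
fio.write_tsv(table.reset_index(names="variable"),
              str(RESULTS / "conservation_model.tsv"))

print(f"conservation model: n = {fit.n:,} sites with score >= 0, "
      f"r^2 = {fit.r_squared:.3f}")
print("relative importance (top 5):")
print(shares.sort_values(ascending=False).head(5).round(4).to_string())
print(f"wrote {RESULTS / 'conservation_model.tsv'}")
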