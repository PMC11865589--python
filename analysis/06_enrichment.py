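"""Conservation enrichment of transcripts, CpG sites, TFs and PcG binding.

Scores every transcript's observed/expected rate of conserved 4d
sites, flags the 95th/99th percentile sets, repeats the scoring on CpG
4d sites and on TF binding-site overlaps, relates PcG-binding density
to enrichment, and summarises enrichment by gene methylation class.
"""

import pandas as pd

from _common import FIXTURE, RESULTS, load_fixture, load_tau
from syn4d import enrichment as en
from syn4d import formats_io as fio
from syn4d import model_stats as ms

genome, transcripts, *_ = load_fixture()
df = fio.read_tsv(str(RESULTS / "site_catalog.tsv"))
tau = load_tau()

res = en.transcript_conservation_enrichment(df, tau=tau)
fio.write_tsv(res.reset_index(), str(RESULTS / "transcript_enrichment.tsv"))
cuts = en.percentile_cutoffs(res["score"], q=(0.95, 0.99))
thr95, top95 = cuts[0.95]
thr99, top99 = cuts[0.99]
print(f"transcript enrichment: {len(res)} units; "
      f"95th pct > {thr95:.2f} ({len(top95)} transcripts), "
      f"99th pct > {thr99:.2f} ({len(top99)})")

cpg = en.cpg_enrichment(df, tau=tau, min_cpg_sites=5)
fio.write_tsv(cpg.reset_index(), str(RESULTS / "cpg_enrichment.tsv"))
print(f"CpG enrichment: {len(cpg)} transcripts with >= 5 CpG 4d sites")

tfbs = fio.read_intervals(str(FIXTURE / "track_tfbs.bed"), name="tfbs")
tf = en.tf_overlap_enrichment(df, tfbs, tau=tau)
fio.write_tsv(tf.reset_index(names="tf"), str(RESULTS / "tf_enrichment.tsv"))
print("top TFs by enrichment:")
print(tf["score"].sort_values(ascending=False).head(3).to_string())

pcg_tracks = [
    fio.read_intervals(str(p), name=p.stem.split("_", 1)[1])
    for p in sorted(FIXTURE.glob("pcg_*.bed"))
]
ratio = en.pcg_sites_per_conserved(df, transcripts, pcg_tracks, tau=tau)
joined = pd.DataFrame({"pcg_per_conserved": ratio}).join(res["score"]).dropna()
r, p = ms.pearson_r(joined["pcg_per_conserved"], joined["score"])
print(f"PcG sites per conserved 4d site vs enrichment: r = {r:.2f} (P = {p:.3g})")

meth = fio.read_tsv(str(FIXTURE / "methylation_classes.tsv"))
gene_of = {tid: t.gene_id for tid, t in transcripts.items()}
scores_by_gene = res["score"].rename(index=gene_of)
classes = meth.set_index("gene_id")["methylation_class"]
table = en.class_summary(scores_by_gene, classes)
fio.write_tsv(table, str(RESULTS / "methylation_class_summary.tsv"))
groups = ms.group_compare(
    scores_by_gene[classes.index.intersection(scores_by_gene.index)].to_numpy(),
    classes[classes.index.intersection(scores_by_gene.index)].to_numpy(),
)
print(f"enrichment by methylation class: ANOVA F = {groups['anova']['F']:.1f}, "
      f"P = {groups['anova']['p']:.3g}")
print(table.to_string(index=False))
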