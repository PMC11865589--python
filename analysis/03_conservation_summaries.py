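"""Descriptive conservation summaries over the catalog.

Classifies sites at the calibrated threshold, then writes per-transcript
GC4 and mean-score summaries, the splice-position base table, the
score-binned base counts and the exon-group GC4 distributions.
"""

import pandas as pd

from _common import RESULTS, load_fixture, load_tau
from syn4d import conservation_summary as cs
from syn4d import formats_io as fio

genome, transcripts, *_ = load_fixture()
df = fio.read_tsv(str(RESULTS / "site_catalog.tsv"))
tau = load_tau()

frac = cs.conserved_fraction(df["score"], tau=tau)
print(f"conserved 4d sites at tau={tau:.3f}: {frac:.1%}")

# per-transcript summary table
summary = pd.DataFrame(
    {
        "gc4_human": cs.transcript_gc4(df, "human"),
        "gc4_mammal": cs.transcript_gc4(df, "mammal"),
    }
).join(cs.mean_score_by_base_class(df))
summary["n_4d"] = df.groupby("transcript_id").size()
wgc = cs.genome_window_gc(genome, window=20_000)
summary["local_gc"] = {
    tid: cs.assign_local_gc(transcripts[tid], wgc) for tid in summary.index
}
fio.write_tsv(summary.reset_index(), str(RESULTS / "transcript_summary.tsv"))

r_atgc = summary[["AT", "GC"]].dropna().corr().iloc[0, 1]
print(f"per-transcript AT-vs-GC mean-score correlation: r = {r_atgc:.2f}")

splice = cs.splice_base_table(df, conserved_only=True, tau=tau)
fio.write_tsv(splice, str(RESULTS / "splice_base_table.tsv"))
bins = cs.score_binned_base_counts(df)
fio.write_tsv(bins, str(RESULTS / "score_bin_base_counts.tsv"))

groups = cs.exon_group_gc4(df, transcripts, min_sites=10)
rows = [
    {"group": k, "n_units": len(v), "median_gc4": v.median()}
    for k, v in groups.items()
]
fio.write_tsv(pd.DataFrame(rows), str(RESULTS / "exon_group_gc4.tsv"))
for row in rows:
    print(f"  {row['group']:<14} n={row['n_units']:<4} median GC4 = {row['median_gc4']:.3f}")
print("wrote transcript_summary, splice_base_table, score_bin_base_counts, exon_group_gc4")
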