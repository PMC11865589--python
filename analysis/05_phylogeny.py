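"""Species divergence at complete 4d sites.

Builds per-species pseudosequences from the complete-site subset,
computes the p-distance matrix and the neighbour-joining tree, and
correlates per-species GC content at these sites with effective
population size and mean genetic distance.
"""

import pandas as pd

from _common import FIXTURE, RESULTS, load_fixture, load_tau
from syn4d import formats_io as fio
from syn4d import model_stats as ms
from syn4d import phylo_distance as phy
from syn4d import site_catalog as sc

genome, transcripts, alignment, scores, _ = load_fixture()
catalog = sc.build_catalog(transcripts, genome, alignment, scores)
tau = load_tau()

complete = sc.Catalog(catalog.species, sc.complete_sites(catalog))
seqs = phy.build_pseudosequences(complete)
fio.write_fasta(seqs, str(RESULTS / "pseudosequences.fa"))
print(f"pseudosequences: {len(seqs)} species x {len(next(iter(seqs.values()))):,} sites")

D = phy.p_distance_matrix(seqs)
phy.write_distance_matrix(D, str(RESULTS / "p_distance_matrix.tsv"))
tree = phy.neighbor_joining(D)
phy.write_newick(tree, str(RESULTS / "nj_tree.nwk"))
print(f"NJ tree written: {RESULTS / 'nj_tree.nwk'}")

meta = fio.read_tsv(str(FIXTURE / "species_meta.tsv")).set_index("species")
# per-species GC content at the *conserved* complete sites, where the
# Ne association is expected to act
conserved_complete = sc.Catalog(
    catalog.species,
    [r for r in complete if r.score >= tau],
)
cons_seqs = phy.build_pseudosequences(conserved_complete)
per_species = pd.DataFrame(
    {
        "mean_distance": {sp: phy.mean_distance(D, sp) for sp in D.index},
        "gc4_conserved": {
            sp: sum(b in "GC" for b in seq) / len(seq)
            for sp, seq in cons_seqs.items()
        },
    }
).join(meta)
fio.write_tsv(per_species.reset_index(names="species"),
              str(RESULTS / "species_divergence.tsv"))

import numpy as np

r_ne, p_ne = ms.pearson_r(per_species["gc4_conserved"], np.log(per_species["ne"]))
r_d, p_d = ms.pearson_r(per_species["gc4_conserved"], per_species["mean_distance"])
print(f"GC4 at conserved complete sites vs log Ne       : r = {r_ne:.2f} (P = {p_ne:.3g})")
print(f"GC4 at conserved complete sites vs mean distance: r = {r_d:.2f} (P = {p_d:.3g})")
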