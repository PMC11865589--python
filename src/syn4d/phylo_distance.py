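"""Distance-based phylogenetics from complete-site pseudosequences.

Every species' bases at the catalog's complete sites (no missing data
in any species) are concatenated, in a fixed genomic order, into one
pseudosequence per species.  Pairwise dissimilarity is the p-distance
(raw mismatch proportion over comparable positions).  The tree is built
with the classical neighbour-joining algorithm (Saitou-Nei Q criterion
with Studier-Keppler distance updates); negative estimated branch
lengths are clamped to zero with the deficit transferred to the sister
branch, and ties in the Q matrix break deterministically on the
smallest (i, j) pair in the current node order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .site_catalog import Catalog, complete_sites


# ---------------------------------------------------------------------------
# tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an (un)rooted tree; branch_length is the edge to the parent."""

    name: str = ""
    branch_length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def _min_leaf(self) -> str:
        return min(self.leaf_names())

    def canonicalise(self) -> None:
        """Sort children everywhere by their smallest descendant leaf label."""
        for c in self.children:
            c.canonicalise()
        self.children.sort(key=lambda c: c._min_leaf())

    def newick(self) -> str:
        self.canonicalise()
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.branch_length:.10g}"
        inner = ",".join(c._newick_inner() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.branch_length:.10g}"


def path_length_matrix(tree: TreeNode) -> pd.DataFrame:
    """Leaf-to-leaf path lengths (sum of branch lengths along the path)."""
    leaves = sorted(tree.leaf_names())
    dist = pd.DataFrame(0.0, index=leaves, columns=leaves)

    def collect(node: TreeNode) -> dict[str, float]:
        """Distances from each descendant leaf up to this node."""
        if node.is_leaf:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child in node.children:
            d = {k: v + child.branch_length for k, v in collect(child).items()}
            below.append(d)
        for i in range(len(below)):
            for j in range(i + 1, len(below)):
                for a, da in below[i].items():
                    for b, db in below[j].items():
                        dist.loc[a, b] = dist.loc[b, a] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    collect(tree)
    return dist


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set (topology fingerprint)."""
    all_leaves = frozenset(tree.leaf_names())
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_leaves) - 1:
            side = min(below, frozenset(all_leaves - below), key=sorted)
            out.add(side)
        return below

    walk(tree)
    return out


# ---------------------------------------------------------------------------
# pseudosequences and p-distances
# ---------------------------------------------------------------------------

def build_pseudosequences(catalog: Catalog) -> dict[str, str]:
    """Concatenated per-species bases over the catalog's complete sites.

    Sites are ordered by (chrom, pos); every species must be aligned at
    every included site (run the complete-site subset first).
    """
    records = complete_sites(catalog)
    if any(r.n_aligned != len(catalog.species) for r in records):
        raise ValueError("pseudosequences require complete sites only")
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    seqs = {sp: [] for sp in catalog.species}
    for r in records:
        if "-" in r.species_bases:
            raise ValueError(f"missing base at {r.chrom}:{r.pos}")
        for sp, b in zip(catalog.species, r.species_bases):
            seqs[sp].append(b)
    return {sp: "".join(bases) for sp, bases in seqs.items()}


def p_distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """Pairwise raw mismatch proportions over positions where both are ACGT."""
    names = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1 or lengths == {0}:
        raise ValueError("sequences must have equal non-zero length")
    acgt = np.frombuffer(b"ACGT", dtype="S1")
    arrs = {n: np.frombuffer(seqs[n].encode(), dtype="S1") for n in names}
    valid = {n: np.isin(arrs[n], acgt) for n in names}
    D = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            both = valid[a] & valid[b]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise ValueError(f"no comparable positions between {a} and {b}")
            d = float((arrs[a][both] != arrs[b][both]).mean())
            D.loc[a, b] = D.loc[b, a] = d
    return D


def mean_distance(D: pd.DataFrame, species: str) -> float:
    """Arithmetic mean distance from one species to all others."""
    if len(D) < 2:
        raise ValueError("need at least two species")
    row = D.loc[species].drop(species)
    return float(row.mean())


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Classical NJ on a symmetric distance matrix; returns an unrooted tree
    represented with a trifurcating root node.
    """
    if len(D) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    mat = D.to_numpy(dtype=float)
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if (mat < 0).any():
        raise ValueError("distance matrix must be non-negative")

    nodes: list[TreeNode] = [TreeNode(name=n) for n in D.index]
    d = mat.copy()

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        # Q criterion; first strict minimum in (i, j) order = deterministic tie-break
        best, best_q = None, math.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        dij = d[i, j]
        li = dij / 2 + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        # clamp negative branch estimates, transferring the deficit to the sister
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        parent = TreeNode(children=[child_i, child_j])
        # Studier-Keppler update of distances to the new node
        keep = [k for k in range(n) if k not in (i, j)]
        new_d = np.empty((len(keep) + 1, len(keep) + 1))
        for a, k in enumerate(keep):
            for b, l in enumerate(keep):
                new_d[a, b] = d[k, l]
            du = (d[i, k] + d[j, k] - dij) / 2
            new_d[a, -1] = new_d[-1, a] = max(du, 0.0)
        new_d[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        d = new_d

    a, b = nodes
    final = d[0, 1]
    if not a.is_leaf:
        root, other = a, b
    else:
        root, other = b, a
    other.branch_length = final
    root.children.append(other)
    root.branch_length = 0.0
    root.canonicalise()
    return root


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: str) -> None:
    """Write the canonical newick form (children ordered by smallest leaf)."""
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def read_newick(path: str) -> TreeNode:
    """Read a newick tree (via Biopython) into the package's tree structure."""
    from Bio import Phylo

    clade = Phylo.read(path, "newick").root

    def convert(cl) -> TreeNode:
        node = TreeNode(
            name=cl.name or "",
            branch_length=float(cl.branch_length or 0.0),
            children=[convert(c) for c in cl.clades],
        )
        return node

    tree = convert(clade)
    tree.canonicalise()
    return tree


def write_distance_matrix(D: pd.DataFrame, path: str) -> None:
    D.to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
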