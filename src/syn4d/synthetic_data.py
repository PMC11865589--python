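"""Synthetic input bundles with known ground truth.

The generator emulates the statistical structure of the study inputs at
desk scale: a pure-birth species tree; protein-coding gene models with
introns, strand mixing and a designated single-exon subset; codon
sequences evolved along the tree under a conserved/neutral rate mixture
at four-fold degenerate third positions with class-specific GC-biased
stationary frequencies (and an elevated GC equilibrium in first exons);
a per-base score track derived from each site's substitution deficit
with a threshold calibrated to a target false-discovery rate among
positive scores; a population variant table whose variability is
damped at conserved sites and whose minor alleles carry a GC->AT
excess; regulatory interval tracks and methylation classes coupled to
a designated enriched-gene set; and per-species metadata (Ne, young-TE
fraction, genome size) coupled to per-species GC content at conserved
sites.

Every statistical coupling is a config field that can be switched to
its null value, and the full bundle is deterministic under
(config, seed): one RNG stream, fixed call order.

Substitution events are the realised Poisson events of the
stationary-frequency replacement process (a proposal from the
stationary distribution counts as an event whether or not it changes
the base), so a neutral site's event count has mean exactly equal to
the tree length and the score's normal-deviate scaling is exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .formats_io import (
    AlignmentColumns,
    IntervalTrack,
    ScoreTrack,
    TranscriptModel,
    write_alignment,
    write_bedgraph,
    write_fasta,
    write_intervals,
    write_transcripts_gtf,
    write_tsv,
    write_variants,
)
from .phylo_distance import TreeNode
from .site_catalog import cds_coordinates

BASE_IDX = {b: i for i, b in enumerate("ACGT")}
IDX_BASE = "ACGT"

PCG_NAMES = ("EZH2", "SUZ12", "RNF2")
METHYLATION_CLASSES = ("c1", "c2", "c3", "c4", "c5")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator parameters; the defaults are the study conditions of the
    default small bundle (12 species, 60 genes, ~8,000 shared 4d sites)."""

    seed: int = 17

    # species tree
    n_species: int = 12
    birth_rate: float = 1.0
    tree_depth: float = 4.0          # mean root-to-tip neutral events per site

    # gene models
    n_genes: int = 60
    single_exon_fraction: float = 0.1
    mean_exons: float = 5.0
    codons_min: int = 200
    codons_max: int = 500
    min_exon_len: int = 60           # nt
    intron_len_min: int = 60
    intron_len_max: int = 200
    spacer_len_min: int = 100
    spacer_len_max: int = 300
    noncoding_gc: float = 0.4

    # site classes and rates
    pi_conserved: float = 0.2        # overall conserved fraction of 4d sites
    rate_ratio: float = 0.1          # conserved rate / neutral rate
    aa_rate: float = 0.02            # proposal rate at amino-acid-constrained positions
    gene_mu_logsd: float = 0.1       # per-gene mutation-rate multiplier (lognormal)

    # GC equilibria at 4d sites
    gc_conserved: float = 0.8
    gc_neutral: float = 0.5
    first_exon_gc_boost: float = 0.1

    # scores
    score_noise_sd: float = 0.5
    fdr_target: float = 0.05

    # alignment gaps
    mask_rate: float = 0.02          # per species-codon unalignment probability

    # population variants
    variant_rate: float = 0.3
    conserved_variant_multiplier: float = 0.4   # lambda_v < 1 damps conserved variability
    maf_beta_a: float = 0.3
    maf_beta_b: float = 8.0
    gc_to_at_excess: float = 0.7     # P(minor in {A,T}) at conserved G/C sites
    ref_flip_fraction: float = 0.02  # fraction of variable sites with reference != major

    # enrichment structure
    n_enriched_genes: int = 6
    enrichment_multiplier: float = 3.0

    # regulatory tracks
    n_tf: int = 8
    tf_intervals: int = 40
    tf_interval_len: int = 30
    tf_enriched_pref: float = 0.8    # first TF's preference for enriched genes
    pcg_intervals: int = 60          # per PcG track
    pcg_interval_len: int = 40
    pcg_enriched_pref: float = 0.8
    c5_pref: float = 0.8             # P(c5 | PcG-covered gene)
    n_ccre: int = 150
    ccre_len: int = 150
    n_rbp: int = 200
    rbp_len: int = 25
    n_uorf: int = 80
    uorf_len: int = 30
    n_lncrna: int = 30
    lncrna_len: int = 400
    n_mirna: int = 100
    mirna_len: int = 8
    n_ese_hexamers: int = 40

    # species metadata
    ne_logmean: float = 10.4
    ne_gc_coupling: float = -0.5     # effect (log-units) per SD of species GC4
    ne_log_noise: float = 0.5
    yte_mean: float = 0.15
    yte_ne_coupling: float = -0.03   # per SD of log Ne
    yte_noise: float = 0.03
    gsize_logmean: float = 21.0
    gsize_logsd: float = 0.3


@dataclass
class SimTruth:
    """Hidden per-site and per-gene labels behind a generated bundle."""

    sites: pd.DataFrame     # chrom,pos,gene_id,transcript_id,conserved,subs,score,variable,ref_flip
    genes: pd.DataFrame     # gene_id,transcript_id,enriched,mu,pi_conserved,strand,n_exons
    species: pd.DataFrame   # species,gc4_conserved,log_ne
    tau: float
    n_ref_flips: int
    tree_newick: str


@dataclass
class SimBundle:
    config: SimConfig
    species: list[str]
    tree: TreeNode
    genome: dict[str, str]
    transcripts: dict[str, TranscriptModel]
    alignment: AlignmentColumns
    scores: ScoreTrack
    tau: float
    variants: pd.DataFrame
    tracks: dict[str, IntervalTrack]
    pcg_tracks: list[IntervalTrack]
    ese_hexamers: set[str]
    methylation: pd.Series        # gene_id -> class
    species_meta: pd.DataFrame
    syn_mu: pd.Series             # gene_id -> per-gene rate multiplier
    truth: SimTruth


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, birth_rate: float, depth: float, rng: np.random.Generator
) -> TreeNode:
    """Pure-birth (Yule) tree, rescaled so every root-to-tip path = ``depth``."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    root = TreeNode(name="")
    first = (TreeNode(), TreeNode())
    root.children = list(first)
    start_time: dict[int, float] = {id(n): 0.0 for n in first}
    active = list(first)
    t = 0.0
    leaf_counter = 0

    def next_name() -> str:
        nonlocal leaf_counter
        name = "ref" if leaf_counter == 0 else f"sp{leaf_counter:02d}"
        leaf_counter += 1
        return name

    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.branch_length = t - start_time[id(node)]
        left, right = TreeNode(), TreeNode()
        node.children = [left, right]
        start_time[id(left)] = start_time[id(right)] = t
        active.extend([left, right])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    for node in active:
        node.branch_length = t_end - start_time[id(node)]
        node.name = next_name()

    scale = depth / t_end if t_end > 0 else 0.0

    def rescale(node: TreeNode) -> None:
        node.branch_length *= scale
        for c in node.children:
            rescale(c)

    rescale(root)
    root.branch_length = 0.0
    return root


def tree_length(tree: TreeNode) -> float:
    total = 0.0
    stack = [tree]
    while stack:
        node = stack.pop()
        total += node.branch_length
        stack.extend(node.children)
    return total


# ---------------------------------------------------------------------------
# gene models and root sequences
# ---------------------------------------------------------------------------

_PREFIXES: dict[str, list[tuple[str, list[str]]]] = {}
for _codon, _aa in gc.CODON_TABLE.items():
    if _aa == gc.STOP:
        continue
    _fams = _PREFIXES.setdefault(_aa, [])
    for _pref, _thirds in _fams:
        if _pref == _codon[:2]:
            _thirds.append(_codon[2])
            break
    else:
        _fams.append((_codon[:2], [_codon[2]]))

_AMINO_ACIDS = sorted(_PREFIXES)
_STOP_CHOICES = ["TAA", "TGA", "TAG"]


def _third_base_probs(allowed: list[str], gc_frac: float) -> np.ndarray:
    w = np.array(
        [gc_frac / 2 if b in "GC" else (1 - gc_frac) / 2 for b in allowed]
    )
    return w / w.sum()


def _random_seq(n: int, gc_frac: float, rng: np.random.Generator) -> str:
    p = [(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2]
    return "".join(IDX_BASE[i] for i in rng.choice(4, size=n, p=p))


@dataclass
class _GeneLayout:
    gene_id: str
    transcript_id: str
    strand: str
    root_seq: np.ndarray          # coding strand, uint8 base codes, incl. stop codon
    rates: np.ndarray             # per-position proposal rates (x gene mu)
    kind: np.ndarray              # 0 frozen, 1 aa-constrained, 2 four-fold
    eq_gc: np.ndarray             # stationary GC at kind==2 positions
    conserved: np.ndarray         # bool, meaningful at kind==2 positions
    exon_lengths: list[int]
    mu: float
    pi: float


def _plan_gene(
    gene_id: str,
    transcript_id: str,
    cfg: SimConfig,
    single_exon: bool,
    pi_gene: float,
    mu: float,
    rng: np.random.Generator,
) -> _GeneLayout:
    n_codons = int(rng.integers(cfg.codons_min, cfg.codons_max + 1))
    cds_len = 3 * (n_codons + 1)  # + stop codon
    if single_exon:
        n_exons = 1
    else:
        n_exons = 2 + int(rng.poisson(max(cfg.mean_exons - 2.0, 0.0)))
        n_exons = min(n_exons, max(2, cds_len // cfg.min_exon_len))
    # cut the CDS into exon pieces, each at least min_exon_len
    free = cds_len - n_exons * cfg.min_exon_len
    cuts = np.sort(rng.integers(0, free + 1, size=n_exons - 1)) if n_exons > 1 else np.array([], int)
    pieces = np.diff(np.concatenate([[0], cuts, [free]]))
    exon_lengths = [int(cfg.min_exon_len + p) for p in pieces]

    # exon index of each coding position
    exon_of = np.zeros(cds_len, dtype=int)
    off = 0
    for i, length in enumerate(exon_lengths):
        exon_of[off: off + length] = i
        off += length

    seq = np.zeros(cds_len, dtype=np.uint8)
    rates = np.full(cds_len, cfg.aa_rate, dtype=float)
    kind = np.ones(cds_len, dtype=np.uint8)
    eq_gc = np.full(cds_len, cfg.gc_neutral, dtype=float)
    conserved = np.zeros(cds_len, dtype=bool)

    for k in range(n_codons):
        aa = _AMINO_ACIDS[int(rng.integers(len(_AMINO_ACIDS)))]
        fams = _PREFIXES[aa]
        weights = np.array([len(t) for _, t in fams], dtype=float)
        fam = fams[int(rng.choice(len(fams), p=weights / weights.sum()))]
        prefix, thirds = fam
        pos3 = 3 * k + 2
        boost = cfg.first_exon_gc_boost if exon_of[pos3] == 0 else 0.0
        if len(thirds) == 4:
            is_cons = bool(rng.random() < pi_gene)
            class_gc = cfg.gc_conserved if is_cons else cfg.gc_neutral
            site_gc = min(max(class_gc + boost, 0.02), 0.98)
            third = rng.choice(thirds, p=_third_base_probs(thirds, site_gc))
            kind[pos3] = 2
            rates[pos3] = cfg.rate_ratio if is_cons else 1.0
            eq_gc[pos3] = site_gc
            conserved[pos3] = is_cons
        else:
            site_gc = min(max(cfg.gc_neutral + boost, 0.02), 0.98)
            third = rng.choice(thirds, p=_third_base_probs(thirds, site_gc))
        codon = prefix + third
        for j, b in enumerate(codon):
            seq[3 * k + j] = BASE_IDX[b]

    stop = _STOP_CHOICES[int(rng.choice(3, p=[0.4, 0.4, 0.2]))]
    for j, b in enumerate(stop):
        seq[3 * n_codons + j] = BASE_IDX[b]
    rates[3 * n_codons:] = 0.0
    kind[3 * n_codons:] = 0

    rates *= mu
    strand = "+" if rng.random() < 0.5 else "-"
    return _GeneLayout(
        gene_id=gene_id, transcript_id=transcript_id, strand=strand,
        root_seq=seq, rates=rates, kind=kind, eq_gc=eq_gc,
        conserved=conserved, exon_lengths=exon_lengths, mu=mu, pi=pi_gene,
    )


def _assemble_genome(
    layouts: list[_GeneLayout], cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[str], dict[str, TranscriptModel]]:
    """Place gene segments (exons + introns) on one chromosome with spacers."""
    chrom = "chr1"
    parts: list[str] = []
    offset = 0
    transcripts: dict[str, TranscriptModel] = {}
    for lay in layouts:
        spacer = _random_seq(
            int(rng.integers(cfg.spacer_len_min, cfg.spacer_len_max + 1)),
            cfg.noncoding_gc, rng,
        )
        parts.append(spacer)
        offset += len(spacer)
        coding = "".join(IDX_BASE[b] for b in lay.root_seq)
        tx_parts: list[str] = []
        tx_exons: list[tuple[int, int]] = []  # transcription-space intervals
        pos = 0
        cursor = 0
        for i, length in enumerate(lay.exon_lengths):
            tx_exons.append((pos, pos + length))
            tx_parts.append(coding[cursor: cursor + length])
            cursor += length
            pos += length
            if i < len(lay.exon_lengths) - 1:
                intron = _random_seq(
                    int(rng.integers(cfg.intron_len_min, cfg.intron_len_max + 1)),
                    cfg.noncoding_gc, rng,
                )
                tx_parts.append(intron)
                pos += len(intron)
        tx_segment = "".join(tx_parts)
        L = len(tx_segment)
        if lay.strand == "+":
            fwd_segment = tx_segment
            g_exons = [(offset + a, offset + b) for a, b in tx_exons]
        else:
            fwd_segment = gc.reverse_complement(tx_segment)
            g_exons = [(offset + L - b, offset + L - a) for a, b in tx_exons]
        parts.append(fwd_segment)
        transcripts[lay.transcript_id] = TranscriptModel(
            transcript_id=lay.transcript_id,
            gene_id=lay.gene_id,
            chrom=chrom,
            strand=lay.strand,
            exons=g_exons,       # transcription order already
            cds=list(g_exons),
        )
        offset += L
    tail = _random_seq(
        int(rng.integers(cfg.spacer_len_min, cfg.spacer_len_max + 1)),
        cfg.noncoding_gc, rng,
    )
    parts.append(tail)
    return ["".join(parts)], transcripts


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

_AA_CODE = np.full(64, -1, dtype=np.int8)
for _codon, _aa in gc.CODON_TABLE.items():
    _idx = 16 * BASE_IDX[_codon[0]] + 4 * BASE_IDX[_codon[1]] + BASE_IDX[_codon[2]]
    _AA_CODE[_idx] = -1 if _aa == gc.STOP else ord(_aa)


def _evolve_gene(
    tree: TreeNode,
    lay: _GeneLayout,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Evolve one gene along the tree; returns leaf sequences and per-site
    event counts summed over all branches."""
    L = len(lay.root_seq)
    subs = np.zeros(L, dtype=np.int64)
    leaves: dict[str, np.ndarray] = {}
    # per 4d site cumulative stationary distribution
    cum_pi = np.empty((L, 4))
    g = lay.eq_gc
    cum_pi[:, 0] = (1 - g) / 2
    cum_pi[:, 1] = cum_pi[:, 0] + g / 2
    cum_pi[:, 2] = cum_pi[:, 1] + g / 2
    cum_pi[:, 3] = 1.0

    def mutate(seq: np.ndarray, blen: float) -> np.ndarray:
        out = seq.copy()
        counts = rng.poisson(lay.rates * blen)
        for pos in np.nonzero(counts)[0]:
            for _ in range(counts[pos]):
                if lay.kind[pos] == 2:
                    u = rng.random()
                    new = int(np.searchsorted(cum_pi[pos], u, side="right"))
                    subs[pos] += 1
                    out[pos] = new
                else:
                    cur = out[pos]
                    new = int((cur + 1 + rng.integers(3)) % 4)
                    k = pos - pos % 3
                    codon = out[k: k + 3].copy()
                    old_idx = 16 * codon[0] + 4 * codon[1] + codon[2]
                    codon[pos - k] = new
                    new_idx = 16 * codon[0] + 4 * codon[1] + codon[2]
                    subs[pos] += 1
                    if _AA_CODE[new_idx] != -1 and _AA_CODE[new_idx] == _AA_CODE[old_idx]:
                        out[pos] = new
        return out

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = mutate(seq, child.branch_length)
            if child.is_leaf:
                leaves[child.name] = child_seq
            else:
                walk(child, child_seq)

    walk(tree, lay.root_seq)
    return leaves, subs


# ---------------------------------------------------------------------------
# score calibration
# ---------------------------------------------------------------------------

def calibrate_tau(
    scores: np.ndarray, conserved: np.ndarray, fdr_target: float
) -> float:
    """Smallest positive threshold whose empirical FDR (neutral fraction
    among sites scoring at or above it) is within the target."""
    order = np.argsort(-scores)
    s_sorted = scores[order]
    neutral = ~conserved[order]
    frac_neutral = np.cumsum(neutral) / np.arange(1, len(scores) + 1)
    ok = (frac_neutral <= fdr_target) & (s_sorted > 0)
    if not ok.any():
        return float(s_sorted[0]) + 1e-9
    return float(s_sorted[np.nonzero(ok)[0].max()])


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(config: SimConfig | None = None, seed: int | None = None) -> SimBundle:
    """Generate the full deterministic input bundle with ground truth."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)

    tree = simulate_species_tree(cfg.n_species, cfg.birth_rate, cfg.tree_depth, rng)
    T = tree_length(tree)
    species = tree.leaf_names()
    species = ["ref"] + sorted(s for s in species if s != "ref")

    # gene plans
    n_single = int(round(cfg.single_exon_fraction * cfg.n_genes))
    single_ids = set(rng.choice(cfg.n_genes, size=n_single, replace=False).tolist())
    n_enriched = min(cfg.n_enriched_genes, cfg.n_genes)
    enriched_ids = set(
        rng.choice(cfg.n_genes, size=n_enriched, replace=False).tolist()
    )
    f_enr = n_enriched / cfg.n_genes
    norm = 1.0 + f_enr * (cfg.enrichment_multiplier - 1.0)
    layouts: list[_GeneLayout] = []
    for g_i in range(cfg.n_genes):
        mult = cfg.enrichment_multiplier if g_i in enriched_ids else 1.0
        pi_gene = min(cfg.pi_conserved * mult / norm, 0.95)
        mu = float(np.exp(rng.normal(0.0, cfg.gene_mu_logsd)))
        layouts.append(
            _plan_gene(
                f"g{g_i + 1:03d}", f"t{g_i + 1:03d}", cfg,
                g_i in single_ids, pi_gene, mu, rng,
            )
        )
    chroms, transcripts = _assemble_genome(layouts, cfg, rng)
    genome = {"chr1": chroms[0]}

    # evolution
    leaf_seqs: dict[str, dict[str, np.ndarray]] = {}  # gene -> species -> seq
    subs_counts: dict[str, np.ndarray] = {}
    for lay in layouts:
        leaves, subs = _evolve_gene(tree, lay, rng)
        leaf_seqs[lay.gene_id] = leaves
        subs_counts[lay.gene_id] = subs

    # patch the reference genome with the ref leaf's bases
    chrom_seq = list(genome["chr1"])
    coords_by_gene: dict[str, list[int]] = {}
    for lay in layouts:
        t = transcripts[lay.transcript_id]
        coords = cds_coordinates(t)
        coords_by_gene[lay.gene_id] = coords
        ref_seq = leaf_seqs[lay.gene_id]["ref"]
        for i, pos in enumerate(coords):
            b = IDX_BASE[ref_seq[i]]
            chrom_seq[pos] = b if t.strand == "+" else gc.complement_base(b)
    genome["chr1"] = "".join(chrom_seq)

    # alignment columns (reference-forward orientation) with unalignment masks
    aln = AlignmentColumns(species)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for lay in layouts:
        n_codons_total = len(lay.root_seq) // 3
        masks[lay.gene_id] = {
            sp: (
                np.zeros(n_codons_total, dtype=bool) if sp == "ref"
                else rng.random(n_codons_total) < cfg.mask_rate
            )
            for sp in species
        }
    for lay in layouts:
        t = transcripts[lay.transcript_id]
        coords = coords_by_gene[lay.gene_id]
        gene_leaves = leaf_seqs[lay.gene_id]
        gene_masks = masks[lay.gene_id]
        for i, pos in enumerate(coords):
            col = []
            for sp in species:
                if gene_masks[sp][i // 3]:
                    col.append("-")
                else:
                    b = IDX_BASE[gene_leaves[sp][i]]
                    col.append(b if t.strand == "+" else gc.complement_base(b))
            aln.set_column(t.chrom, pos, "".join(col))

    # scores at third codon positions, then FDR-calibrated tau on 4d truth
    scores = ScoreTrack()
    score_sd = math.sqrt(T) if T > 0 else 1.0
    site_rows = []
    for lay in layouts:
        t = transcripts[lay.transcript_id]
        coords = coords_by_gene[lay.gene_id]
        subs = subs_counts[lay.gene_id]
        n_codons = len(lay.root_seq) // 3 - 1  # exclude stop
        for k in range(n_codons):
            i = 3 * k + 2
            s = (T - subs[i]) / score_sd + rng.normal(0.0, cfg.score_noise_sd)
            scores.set(t.chrom, coords[i], s)
            if lay.kind[i] == 2:
                site_rows.append(
                    (
                        t.chrom, coords[i], lay.gene_id, lay.transcript_id,
                        bool(lay.conserved[i]), int(subs[i]), float(s),
                    )
                )
    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "gene_id", "transcript_id", "conserved", "subs", "score"],
    )
    tau = calibrate_tau(
        sites["score"].to_numpy(), sites["conserved"].to_numpy(), cfg.fdr_target
    )

    # population variants over the true 4d sites
    variants, variable_flags, flip_flags = _simulate_variants(
        sites, layouts, transcripts, coords_by_gene, leaf_seqs, cfg, rng
    )
    sites["variable"] = variable_flags
    sites["ref_flip"] = flip_flags

    # regulatory tracks, methylation classes, ESE hexamers
    genome_len = len(genome["chr1"])
    enriched_gene_names = {f"g{i + 1:03d}" for i in sorted(enriched_ids)}
    tracks, pcg_tracks = _simulate_tracks(
        transcripts, enriched_gene_names, genome_len, cfg, rng
    )
    ese_hexamers = _simulate_hexamers(cfg, rng)
    methylation = _assign_methylation(transcripts, pcg_tracks, cfg, rng)

    # species metadata coupled to per-species conserved-site GC content
    species_meta, species_truth = _simulate_species_meta(
        layouts, leaf_seqs, species, cfg, rng
    )

    genes = pd.DataFrame(
        {
            "gene_id": [lay.gene_id for lay in layouts],
            "transcript_id": [lay.transcript_id for lay in layouts],
            "enriched": [lay.gene_id in enriched_gene_names for lay in layouts],
            "mu": [lay.mu for lay in layouts],
            "pi_conserved": [lay.pi for lay in layouts],
            "strand": [lay.strand for lay in layouts],
            "n_exons": [len(lay.exon_lengths) for lay in layouts],
        }
    )
    truth = SimTruth(
        sites=sites,
        genes=genes,
        species=species_truth,
        tau=tau,
        n_ref_flips=int(sum(flip_flags)),
        tree_newick=tree.newick(),
    )
    syn_mu = genes.set_index("gene_id")["mu"]
    return SimBundle(
        config=cfg, species=species, tree=tree, genome=genome,
        transcripts=transcripts, alignment=aln, scores=scores, tau=tau,
        variants=variants, tracks=tracks, pcg_tracks=pcg_tracks,
        ese_hexamers=ese_hexamers, methylation=methylation,
        species_meta=species_meta, syn_mu=syn_mu, truth=truth,
    )


def _simulate_variants(sites, layouts, transcripts, coords_by_gene, leaf_seqs, cfg, rng):
    lay_by_gene = {lay.gene_id: lay for lay in layouts}
    rows, variable_flags, flip_flags = [], [], []
    for chrom, pos, gene_id, tid, conserved in zip(
        sites["chrom"], sites["pos"], sites["gene_id"],
        sites["transcript_id"], sites["conserved"],
    ):
        strand = transcripts[tid].strand
        coords = coords_by_gene[gene_id]
        i = coords.index(pos)  # coding index of the site
        ref_coding = IDX_BASE[leaf_seqs[gene_id]["ref"][i]]
        p_var = cfg.variant_rate * (
            cfg.conserved_variant_multiplier if conserved else 1.0
        )
        if rng.random() >= p_var:
            variable_flags.append(False)
            flip_flags.append(False)
            continue
        maf = 0.5 * float(rng.beta(cfg.maf_beta_a, cfg.maf_beta_b))
        maf = max(maf, 1e-5)
        major = ref_coding
        others = [b for b in "ACGT" if b != major]
        if conserved and major in "GC" and rng.random() < cfg.gc_to_at_excess:
            minor = "AT"[int(rng.integers(2))]
        else:
            minor = others[int(rng.integers(3))]
        flip = rng.random() < cfg.ref_flip_fraction
        if flip:
            major, minor = minor, major
        if strand == "-":
            major = gc.complement_base(major)
            minor = gc.complement_base(minor)
        ref_fwd = ref_coding if strand == "+" else gc.complement_base(ref_coding)
        rows.append((chrom, int(pos), ref_fwd, major, minor, maf))
        variable_flags.append(True)
        flip_flags.append(flip)
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "major", "minor", "maf"]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return variants, variable_flags, flip_flags


def _place_on_gene(t: TranscriptModel, length: int, rng) -> tuple[int, int]:
    s, e = t.span
    if e - s <= length:
        return s, e
    start = int(rng.integers(s, e - length))
    return start, start + length


def _simulate_tracks(transcripts, enriched_genes, genome_len, cfg, rng):
    tids = sorted(transcripts)
    enriched_tids = [
        tid for tid in tids if transcripts[tid].gene_id in enriched_genes
    ]
    tracks: dict[str, IntervalTrack] = {}

    tfbs = IntervalTrack("tfbs")
    for tf_i in range(cfg.n_tf):
        tf_name = f"TF{tf_i + 1:02d}"
        for _ in range(cfg.tf_intervals):
            if tf_i == 0 and enriched_tids and rng.random() < cfg.tf_enriched_pref:
                t = transcripts[enriched_tids[int(rng.integers(len(enriched_tids)))]]
                s, e = _place_on_gene(t, cfg.tf_interval_len, rng)
            else:
                s = int(rng.integers(0, max(genome_len - cfg.tf_interval_len, 1)))
                e = s + cfg.tf_interval_len
            tfbs.add("chr1", s, e, tf_name)
    tracks["tfbs"] = tfbs

    for name, count, length in (
        ("ccre", cfg.n_ccre, cfg.ccre_len),
        ("rbp", cfg.n_rbp, cfg.rbp_len),
        ("uorf", cfg.n_uorf, cfg.uorf_len),
        ("lncrna", cfg.n_lncrna, cfg.lncrna_len),
        ("mirna", cfg.n_mirna, cfg.mirna_len),
    ):
        track = IntervalTrack(name)
        for _ in range(count):
            s = int(rng.integers(0, max(genome_len - length, 1)))
            track.add("chr1", s, s + length)
        tracks[name] = track

    pcg_tracks = []
    for pcg_name in PCG_NAMES:
        track = IntervalTrack(pcg_name)
        for _ in range(cfg.pcg_intervals):
            if enriched_tids and rng.random() < cfg.pcg_enriched_pref:
                t = transcripts[enriched_tids[int(rng.integers(len(enriched_tids)))]]
            else:
                t = transcripts[tids[int(rng.integers(len(tids)))]]
            s, e = _place_on_gene(t, cfg.pcg_interval_len, rng)
            track.add("chr1", s, e, pcg_name)
        pcg_tracks.append(track)
    return tracks, pcg_tracks


def _simulate_hexamers(cfg, rng) -> set[str]:
    out: set[str] = set()
    while len(out) < cfg.n_ese_hexamers:
        out.add("".join(IDX_BASE[i] for i in rng.integers(0, 4, size=6)))
    return out


def _assign_methylation(transcripts, pcg_tracks, cfg, rng) -> pd.Series:
    classes = {}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        s, e = t.span
        covered = any(track.n_overlapping(t.chrom, s, e) > 0 for track in pcg_tracks)
        if covered and rng.random() < cfg.c5_pref:
            cls = "c5"
        elif not covered and rng.random() < 0.05:
            cls = "c5"
        else:
            cls = METHYLATION_CLASSES[int(rng.integers(4))]
        classes[t.gene_id] = cls
    return pd.Series(classes, name="methylation_class")


def _simulate_species_meta(layouts, leaf_seqs, species, cfg, rng):
    gc_frac = {}
    for sp in species:
        gc_count = total = 0
        for lay in layouts:
            pos_mask = (lay.kind == 2) & lay.conserved
            seq = leaf_seqs[lay.gene_id][sp][pos_mask]
            gc_count += int(np.isin(seq, [1, 2]).sum())  # C or G codes
            total += len(seq)
        gc_frac[sp] = gc_count / total if total else math.nan
    gc_arr = np.array([gc_frac[sp] for sp in species])
    z = (gc_arr - gc_arr.mean()) / (gc_arr.std() if gc_arr.std() > 0 else 1.0)
    log_ne = (
        cfg.ne_logmean + cfg.ne_gc_coupling * z
        + rng.normal(0.0, cfg.ne_log_noise, size=len(species))
    )
    zn = (log_ne - log_ne.mean()) / (log_ne.std() if log_ne.std() > 0 else 1.0)
    yte = np.clip(
        cfg.yte_mean + cfg.yte_ne_coupling * zn
        + rng.normal(0.0, cfg.yte_noise, size=len(species)),
        0.005, 0.6,
    )
    gsize = np.exp(rng.normal(cfg.gsize_logmean, cfg.gsize_logsd, size=len(species)))
    meta = pd.DataFrame(
        {
            "species": species,
            "ne": np.exp(log_ne),
            "yte_fraction": yte,
            "genome_size": gsize,
        }
    )
    truth = pd.DataFrame(
        {"species": species, "gc4_conserved": gc_arr, "log_ne": log_ne}
    )
    return meta, truth


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    config: SimConfig | None = None,
    out_dir: str = "fixture",
    seed: int | None = None,
    force: bool = False,
    bundle: SimBundle | None = None,
) -> SimBundle:
    """Write the full input bundle plus truth files to ``out_dir``.

    Refuses to write into an existing non-empty directory unless
    ``force`` is set.  Identical (config, seed) pairs produce
    byte-identical bundles.
    """
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    os.makedirs(out_dir, exist_ok=True)
    if bundle is None:
        bundle = generate_bundle(config, seed=seed)
    j = lambda name: os.path.join(out_dir, name)

    write_fasta(bundle.genome, j("genome.fa"))
    write_transcripts_gtf(bundle.transcripts, j("annotation.gtf"))
    write_alignment(bundle.alignment, j("alignment.tsv"))
    write_bedgraph(bundle.scores, j("scores.bedgraph"))
    write_variants(bundle.variants, j("variants.tsv"))
    for name, track in sorted(bundle.tracks.items()):
        write_intervals(track, j(f"track_{name}.bed"))
    for track in bundle.pcg_tracks:
        write_intervals(track, j(f"pcg_{track.name}.bed"))
    with open(j("ese_hexamers.txt"), "w") as fh:
        fh.write("\n".join(sorted(bundle.ese_hexamers)) + "\n")
    bundle.methylation.rename_axis("gene_id").reset_index().to_csv(
        j("methylation_classes.tsv"), sep="\t", index=False
    )
    write_tsv(bundle.species_meta, j("species_meta.tsv"))
    bundle.syn_mu.rename("syn_mu").rename_axis("gene_id").reset_index().to_csv(
        j("gene_mu.tsv"), sep="\t", index=False
    )
    write_tsv(bundle.truth.sites, j("site_truth.tsv"))
    write_tsv(bundle.truth.genes, j("gene_truth.tsv"))
    write_tsv(bundle.truth.species, j("species_truth.tsv"))
    with open(j("tree.nwk"), "w") as fh:
        fh.write(bundle.truth.tree_newick + "\n")
    manifest = {
        "seed": bundle.config.seed,
        "tau": bundle.tau,
        "n_species": len(bundle.species),
        "config": dataclasses.asdict(bundle.config),
    }
    with open(j("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return bundle
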