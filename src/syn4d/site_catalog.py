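"""Catalog of shared four-fold degenerate (4d) sites.

The catalog is built in three steps: enumerate the reference CDS codons
of each transcript (strand-aware, junction-spanning codons keep the
genomic coordinate of each base), attach the per-species codons from
the reference-anchored alignment columns, and apply the shared-4d
filter: a third-codon-position site is retained when the reference
codon is four-fold degenerate, at least ``min_aligned_frac`` of the
species are aligned over the whole codon, and at least ``min_4d_frac``
of the aligned species codons are themselves four-fold degenerate at
position 3.  Both threshold comparisons are inclusive (>=): at the
240-species scale with 85% aligned (204 species) the 95% rule then
requires a 4d codon in at least ceil(0.95 * 204) = 194 species.

All per-species bases stored on a SiteRecord are in coding-strand
orientation (the reference codon reading frame).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .formats_io import GAP, AlignmentColumns, ScoreTrack, TranscriptModel

log = logging.getLogger(__name__)

DEFAULT_MIN_ALIGNED_FRAC = 0.85
DEFAULT_MIN_4D_FRAC = 0.95

BASE_ORDER = "ACGT"  # fixed tie-break order for the major base


class InternalStopError(ValueError):
    """A transcript CDS translates with an internal stop codon."""


@dataclass
class CodonColumn:
    """One reference codon and (optionally) the aligned species codons."""

    transcript_id: str
    codon_index: int
    chrom: str
    strand: str
    coords: tuple[int, int, int]  # genomic coordinate of each codon base, translation order
    ref_codon: str                # coding-strand bases
    species_codons: list[str | None] | None = None


@dataclass
class SiteRecord:
    """One shared 4d site (third codon position) with its summaries."""

    chrom: str
    pos: int                      # genomic coordinate of the third codon base
    transcript_id: str
    gene_id: str
    codon_index: int
    strand: str
    ref_base: str                 # coding strand
    species_bases: str            # coding strand, one slot per species, '-' = unaligned
    counts: dict[str, int]
    n_aligned: int
    score: float = math.nan
    cpg: bool = False
    edge_class: str = "internal"
    edge_dist: int = -1
    degeneracy: str = "4d"

    @property
    def fixed_for(self) -> str | None:
        """The single base all counted species share, if any."""
        nonzero = [b for b in BASE_ORDER if self.counts[b] > 0]
        return nonzero[0] if len(nonzero) == 1 else None


class Catalog:
    """The shared-4d site catalog: an ordered list of SiteRecords."""

    def __init__(self, species: list[str], records: list[SiteRecord]) -> None:
        self.species = list(species)
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            base, tie = major_base(r)
            rows.append(
                (
                    r.chrom, r.pos, r.transcript_id, r.gene_id, r.codon_index,
                    r.strand, r.ref_base, r.species_bases,
                    r.counts["A"], r.counts["C"], r.counts["G"], r.counts["T"],
                    r.n_aligned, r.score, r.cpg, r.edge_class, r.edge_dist,
                    base, tie, r.fixed_for is not None and r.n_aligned == len(self.species),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chrom", "pos", "transcript_id", "gene_id", "codon_index",
                "strand", "ref_base", "species_bases",
                "count_A", "count_C", "count_G", "count_T",
                "n_aligned", "score", "cpg", "edge_class", "edge_dist",
                "major_base", "major_tie", "fixed",
            ],
        )


# ---------------------------------------------------------------------------
# codon enumeration and species attachment
# ---------------------------------------------------------------------------

def spliced_cds(transcript: TranscriptModel, genome: dict[str, str]) -> str:
    """Coding-strand CDS sequence spliced over the transcript's CDS intervals."""
    chrom_seq = genome[transcript.chrom]
    parts = []
    for s, e in transcript.cds:
        seg = chrom_seq[s:e]
        if transcript.strand == "-":
            seg = gc.reverse_complement(seg)
        parts.append(seg)
    return "".join(parts)


def cds_coordinates(transcript: TranscriptModel) -> list[int]:
    """Genomic coordinate of every CDS base, in translation order."""
    coords: list[int] = []
    for s, e in transcript.cds:
        rng = range(e - 1, s - 1, -1) if transcript.strand == "-" else range(s, e)
        coords.extend(rng)
    return coords


def enumerate_cds_codons(
    transcript: TranscriptModel, genome: dict[str, str]
) -> list[CodonColumn]:
    """Reference codons of a transcript CDS, in translation order.

    A trailing stop codon is trimmed; an internal stop raises
    :class:`InternalStopError` so the caller can exclude the transcript.
    """
    seq = spliced_cds(transcript, genome)
    coords = cds_coordinates(transcript)
    if len(seq) % 3 != 0:
        raise ValueError(f"{transcript.transcript_id}: CDS length not divisible by 3")
    codons = [seq[i: i + 3] for i in range(0, len(seq), 3)]
    if codons and gc.is_stop(codons[-1]):
        codons = codons[:-1]
    for i, codon in enumerate(codons):
        if gc.is_stop(codon):
            raise InternalStopError(
                f"{transcript.transcript_id}: internal stop at codon {i}"
            )
    return [
        CodonColumn(
            transcript_id=transcript.transcript_id,
            codon_index=i,
            chrom=transcript.chrom,
            strand=transcript.strand,
            coords=(coords[3 * i], coords[3 * i + 1], coords[3 * i + 2]),
            ref_codon=codon,
        )
        for i, codon in enumerate(codons)
    ]


def attach_species(
    columns: list[CodonColumn], alignment: AlignmentColumns
) -> list[CodonColumn]:
    """Fill per-species codons from alignment columns (coding-strand bases).

    A species' codon is unaligned (None) when any of its three bases is
    missing, gapped or ambiguous.
    """
    n = alignment.n_species
    for col in columns:
        per_species: list[str | None] = []
        cols3 = [alignment.column(col.chrom, p) for p in col.coords]
        for s in range(n):
            bases = []
            ok = True
            for c in cols3:
                b = c[s] if c is not None else GAP
                if b not in "ACGT":
                    ok = False
                    break
                if col.strand == "-":
                    b = gc.complement_base(b)
                bases.append(b)
            per_species.append("".join(bases) if ok else None)
        col.species_codons = per_species
    return columns


# ---------------------------------------------------------------------------
# the shared-4d filter
# ---------------------------------------------------------------------------

def column_passes_filter(
    col: CodonColumn,
    total_species: int,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    min_4d_frac: float = DEFAULT_MIN_4D_FRAC,
) -> bool:
    """Inclusive-threshold shared-4d test for one codon column."""
    if not gc.is_fourfold(col.ref_codon):
        return False
    aligned = [c for c in col.species_codons if c is not None]
    if not aligned or len(aligned) / total_species < min_aligned_frac:
        return False
    n_4d = sum(gc.is_fourfold(c) for c in aligned)
    return n_4d / len(aligned) >= min_4d_frac


def shared_4d_filter(
    columns: list[CodonColumn],
    species: list[str],
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    min_4d_frac: float = DEFAULT_MIN_4D_FRAC,
    gene_ids: dict[str, str] | None = None,
) -> Catalog:
    """Apply the shared-4d filter and materialise SiteRecords.

    Base counts are taken over *all* aligned species at the third codon
    position (coding strand).
    """
    total = len(species)
    records: list[SiteRecord] = []
    for col in columns:
        if col.species_codons is None:
            raise ValueError("attach_species must run before shared_4d_filter")
        if not column_passes_filter(col, total, min_aligned_frac, min_4d_frac):
            continue
        third = [c[2] if c is not None else GAP for c in col.species_codons]
        counts = {b: 0 for b in BASE_ORDER}
        for b in third:
            if b in counts:
                counts[b] += 1
        n_aligned = sum(counts.values())
        records.append(
            SiteRecord(
                chrom=col.chrom,
                pos=col.coords[2],
                transcript_id=col.transcript_id,
                gene_id=(gene_ids or {}).get(col.transcript_id, col.transcript_id),
                codon_index=col.codon_index,
                strand=col.strand,
                ref_base=col.ref_codon[2],
                species_bases="".join(third),
                counts=counts,
                n_aligned=n_aligned,
            )
        )
    return Catalog(species, records)


def major_base(record: SiteRecord) -> tuple[str, bool]:
    """Most common base across the counted species; ties broken A<C<G<T."""
    if record.n_aligned < 1:
        raise ValueError("major_base requires at least one aligned species")
    best = max(BASE_ORDER, key=lambda b: record.counts[b])
    tie = sum(record.counts[b] == record.counts[best] for b in BASE_ORDER) > 1
    return best, tie


def fixed_sites(catalog: Catalog, total_species: int | None = None) -> list[SiteRecord]:
    """Sites fixed for one base across *all* species (no missing data)."""
    total = total_species if total_species is not None else len(catalog.species)
    return [
        r for r in catalog
        if r.n_aligned == total and r.fixed_for is not None
    ]


def complete_sites(catalog: Catalog, total_species: int | None = None) -> list[SiteRecord]:
    """Sites aligned in every species."""
    total = total_species if total_species is not None else len(catalog.species)
    return [r for r in catalog if r.n_aligned == total]


# ---------------------------------------------------------------------------
# catalog construction driver
# ---------------------------------------------------------------------------

def build_catalog(
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
    alignment: AlignmentColumns,
    score_track: ScoreTrack | None = None,
    min_aligned_frac: float = DEFAULT_MIN_ALIGNED_FRAC,
    min_4d_frac: float = DEFAULT_MIN_4D_FRAC,
) -> Catalog:
    """Enumerate, attach, filter and annotate the full shared-4d catalog.

    Scores are attached from the track when given; CpG context is
    evaluated on the spliced (mRNA) CDS of each transcript, so a codon
    split across exons uses its transcript-sequence neighbours.
    """
    all_columns: list[CodonColumn] = []
    gene_ids = {}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        gene_ids[tid] = t.gene_id
        try:
            cols = enumerate_cds_codons(t, genome)
        except InternalStopError as exc:
            log.warning("excluding transcript: %s", exc)
            continue
        all_columns.extend(cols)
    attach_species(all_columns, alignment)
    catalog = shared_4d_filter(
        all_columns, alignment.species, min_aligned_frac, min_4d_frac, gene_ids
    )
    annotate_cpg(catalog, transcripts, genome)
    if score_track is not None:
        annotate_scores(catalog, score_track)
    return catalog


def annotate_scores(catalog: Catalog, track: ScoreTrack) -> int:
    """Attach per-site conservation scores; returns the count of missing scores."""
    missing = 0
    for r in catalog:
        r.score = track.get(r.chrom, r.pos)
        if math.isnan(r.score):
            missing += 1
    if missing:
        log.info("annotate_scores: %d catalog sites without a score", missing)
    return missing


def annotate_cpg(
    catalog: Catalog,
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
) -> None:
    """Flag catalog sites in CpG context on the spliced CDS of their transcript."""
    flags_by_tid: dict[str, np.ndarray] = {}
    for r in catalog:
        flags = flags_by_tid.get(r.transcript_id)
        if flags is None:
            seq = spliced_cds(transcripts[r.transcript_id], genome)
            flags = gc.cpg_flags(seq)
            flags_by_tid[r.transcript_id] = flags
        r.cpg = bool(flags[r.codon_index * 3 + 2])
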