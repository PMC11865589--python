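"""Readers and writers for the external formats the pipeline consumes.

One coordinate convention holds everywhere inside the package: 0-based,
half-open intervals on the forward strand of the reference.  Conversions
from the 1-based inclusive conventions of GTF/GFF3, WIG and VCF happen
here and only here.

The multi-species alignment is consumed as reference-anchored columns:
for each reference position, one base per species (or a gap marker).
The native dialect is a per-site TSV (columns: chrom, pos, then one
column per species, "-" = unaligned); a minimal MAF-subset reader that
projects alignment blocks onto reference columns is also provided.
"""

from __future__ import annotations

import logging
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

GAP = "-"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """One representative transcript of a protein-coding gene.

    ``exons`` and ``cds`` are lists of 0-based half-open (start, end)
    intervals on the forward strand, ordered 5'->3' in *transcription*
    order (descending genomic coordinate for minus-strand transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        ivs = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )


class ScoreTrack:
    """Per-base conservation scores; uncovered positions are NaN ("missing")."""

    def __init__(self) -> None:
        self._data: dict[str, dict[int, float]] = {}

    def set(self, chrom: str, pos: int, score: float) -> None:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score at {chrom}:{pos}")
        self._data.setdefault(chrom, {})[pos] = score

    def get(self, chrom: str, pos: int) -> float:
        """Score at a position; NaN when the track has no value there."""
        return self._data.get(chrom, {}).get(pos, float("nan"))

    def get_many(self, chrom: str, positions) -> np.ndarray:
        d = self._data.get(chrom, {})
        return np.array([d.get(int(p), np.nan) for p in positions], dtype=float)

    def n_positions(self) -> int:
        return sum(len(d) for d in self._data.values())

    def items(self):
        for chrom in sorted(self._data):
            for pos in sorted(self._data[chrom]):
                yield chrom, pos, self._data[chrom][pos]

    def __eq__(self, other) -> bool:
        return isinstance(other, ScoreTrack) and self._data == other._data


class IntervalTrack:
    """A named set of genomic intervals with an optional label each."""

    def __init__(self, name: str = "") -> None:
        self.name = name
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, label: str | None = None) -> None:
        if start >= end:
            raise ValueError(f"{self.name}: interval start {start} >= end {end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str | None]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def covers(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))

    def n_overlapping(self, chrom: str, start: int, end: int) -> int:
        return len(self.overlapping(chrom, start, end))

    def labels(self) -> set[str]:
        return {
            iv.data for tree in self._trees.values() for iv in tree if iv.data is not None
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (chrom, iv.begin, iv.end, iv.data if iv.data is not None else ".")
            for chrom, tree in sorted(self._trees.items())
            for iv in sorted(tree)
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalTrack) and self.to_frame().equals(other.to_frame())


class AlignmentColumns:
    """Reference-anchored alignment columns: one base per species per position."""

    def __init__(self, species: list[str]) -> None:
        self.species = list(species)
        self._cols: dict[str, dict[int, str]] = {}

    @property
    def n_species(self) -> int:
        return len(self.species)

    def set_column(self, chrom: str, pos: int, bases: str) -> None:
        if len(bases) != self.n_species:
            raise ValueError(
                f"column at {chrom}:{pos} has {len(bases)} slots, expected {self.n_species}"
            )
        self._cols.setdefault(chrom, {})[pos] = bases

    def column(self, chrom: str, pos: int) -> str | None:
        """Per-species bases (reference-forward orientation) or None if absent."""
        return self._cols.get(chrom, {}).get(pos)

    def positions(self, chrom: str) -> list[int]:
        return sorted(self._cols.get(chrom, {}))

    def chroms(self) -> list[str]:
        return sorted(self._cols)

    def __len__(self) -> int:
        return sum(len(c) for c in self._cols.values())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AlignmentColumns)
            and self.species == other.species
            and self._cols == other._cols
        )


# ---------------------------------------------------------------------------
# annotation (GTF / GFF3)
# ---------------------------------------------------------------------------

def _parse_gtf_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def _parse_gff3_attrs(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            key, val = part.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_transcripts(path: str) -> dict[str, TranscriptModel]:
    """Read exon/CDS features from a GTF or GFF3 file into transcript models.

    File coordinates (1-based inclusive) become internal 0-based
    half-open; minus-strand exon lists are ordered in transcription
    order.  Transcripts whose CDS length is not divisible by 3 are
    skipped with a logged warning.
    """
    gff3 = False
    feats: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##gff-version"):
                gff3 = True
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attr = fields
            if ftype not in ("exon", "CDS"):
                continue
            attrs = _parse_gff3_attrs(attr) if (gff3 or "=" in attr.split(";")[0]) else _parse_gtf_attrs(attr)
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: no transcript id")
            gid = attrs.get("gene_id", attrs.get("gene", tid))
            rec = feats.setdefault(
                tid, {"gene_id": gid, "chrom": chrom, "strand": strand, "exon": [], "CDS": []}
            )
            rec[ftype].append((int(start) - 1, int(end)))

    out: dict[str, TranscriptModel] = {}
    for tid, rec in feats.items():
        rev = rec["strand"] == "-"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=sorted(rec["exon"], reverse=rev),
            cds=sorted(rec["CDS"], reverse=rev),
        )
        if t.cds and t.cds_length % 3 != 0:
            log.warning(
                "skipping transcript %s: CDS length %d not divisible by 3",
                tid, t.cds_length,
            )
            continue
        out[tid] = t
    return out


def write_transcripts_gtf(transcripts: dict[str, TranscriptModel], path: str) -> None:
    """Write transcript models as a GTF (exon + CDS features)."""
    with open(path, "w") as fh:
        for tid in sorted(transcripts):
            t = transcripts[tid]
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for ftype, ivs in (("exon", t.exons), ("CDS", t.cds)):
                for s, e in sorted(ivs):
                    fh.write(
                        f"{t.chrom}\tsyn4d\t{ftype}\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# score tracks (bedGraph / fixed-step WIG)
# ---------------------------------------------------------------------------

def read_score_track(path: str) -> ScoreTrack:
    """Load a bedGraph or fixed-step wiggle file as per-base scores."""
    track = ScoreTrack()
    with open(path) as fh:
        first = fh.read(4096)
    is_wig = "fixedStep" in first.split("\n")[0] or first.startswith("track type=wiggle")
    if is_wig:
        _read_fixedstep(path, track)
    else:
        _read_bedgraph(path, track)
    return track


def _read_bedgraph(path: str, track: ScoreTrack) -> None:
    seen: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            try:
                chrom, start, end, value = line.split()[:4]
                start, end, value = int(start), int(end), float(value)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            positions = seen.setdefault(chrom, set())
            for pos in range(start, end):
                if pos in positions:
                    raise ValueError(
                        f"{path}:{lineno}: overlapping bedGraph interval at {chrom}:{pos}"
                    )
                positions.add(pos)
                track.set(chrom, pos, value)


def _read_fixedstep(path: str, track: ScoreTrack) -> None:
    chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                params = dict(p.split("=") for p in line.split()[1:])
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # WIG is 1-based
                step = int(params.get("step", 1))
                continue
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: value before fixedStep header")
            track.set(chrom, pos, float(line))
            pos += step


def write_bedgraph(track: ScoreTrack, path: str) -> None:
    """Write a score track as bedGraph, merging runs of equal adjacent scores."""
    with open(path, "w") as fh:
        run: list = []  # chrom, start, end, value
        for chrom, pos, val in track.items():
            if run and run[0] == chrom and run[2] == pos and run[3] == val:
                run[2] = pos + 1
            else:
                if run:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")
                run = [chrom, pos, pos + 1, val]
        if run:
            fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]:.6g}\n")


# ---------------------------------------------------------------------------
# intervals (BED)
# ---------------------------------------------------------------------------

def read_intervals(path: str, name: str = "") -> IntervalTrack:
    """Read a BED file (already 0-based half-open) into an interval track."""
    track = IntervalTrack(name=name or path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 and fields[3] != "." else None
            track.add(chrom, start, end, label)
    return track


def write_intervals(track: IntervalTrack, path: str) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# variants (VCF SNV subset / 6-column TSV)
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["chrom", "pos", "ref", "major", "minor", "maf"]


def read_variants(path: str) -> pd.DataFrame:
    """Load biallelic SNVs with major/minor allele and MAF.

    Accepts a VCF subset (positions converted from 1-based; multiallelic
    and indel records skipped with a logged count) or the authoritative
    6-column TSV (chrom, pos, ref, major, minor, maf).
    """
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: variant TSV missing columns {sorted(missing)}")
    _validate_variants(df, path)
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def _read_vcf(path: str) -> pd.DataFrame:
    rows = []
    skipped = 0
    with (io.TextIOWrapper(__import__("gzip").open(path)) if path.endswith(".gz") else open(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            chrom, pos, _, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1 or alt == ".":
                skipped += 1
                continue
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in fields[7].split(";")
            )
            af = float(info.get("AF", "nan"))
            if not np.isfinite(af):
                raise ValueError(f"{path}:{lineno}: SNV without AF info")
            if af <= 0.5:
                major, minor, maf = ref, alt, af
            else:
                major, minor, maf = alt, ref, 1.0 - af
            rows.append((chrom, pos - 1, ref, major, minor, maf))
    if skipped:
        log.info("read_variants: skipped %d multiallelic/indel records", skipped)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    _validate_variants(df, path)
    return df


def _validate_variants(df: pd.DataFrame, path: str) -> None:
    if len(df) == 0:
        return
    if ((df["maf"] < 0) | (df["maf"] > 0.5)).any():
        raise ValueError(f"{path}: MAF outside [0, 0.5]")
    if (df["major"] == df["minor"]).any():
        raise ValueError(f"{path}: major allele equals minor allele")


def write_variants(df: pd.DataFrame, path: str) -> None:
    df[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / alignment / generic TSV
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file as {name: sequence}; headers tokenised at whitespace."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(seqs: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_alignment(path: str) -> AlignmentColumns:
    """Read the per-site alignment TSV (chrom, pos, one base column per species)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["chrom", "pos"]:
        raise ValueError(f"{path}: alignment TSV must start with chrom, pos columns")
    species = list(df.columns[2:])
    aln = AlignmentColumns(species)
    cols = df[species].to_numpy()
    for (chrom, pos), bases in zip(
        zip(df["chrom"].to_numpy(), df["pos"].astype(int).to_numpy()), cols
    ):
        aln.set_column(chrom, int(pos), "".join(bases))
    return aln


def write_alignment(aln: AlignmentColumns, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(aln.species) + "\n")
        for chrom in aln.chroms():
            for pos in aln.positions(chrom):
                fh.write(f"{chrom}\t{pos}\t" + "\t".join(aln.column(chrom, pos)) + "\n")


def read_alignment_maf(path: str, ref_species: str) -> AlignmentColumns:
    """Project the blocks of a MAF subset onto reference-anchored columns.

    Sequence names must be ``species.chrom``; only forward-strand
    reference rows are supported.  Columns where the reference row is a
    gap are dropped (they have no reference coordinate).
    """
    from Bio import AlignIO

    species_order: list[str] = []
    blocks = list(AlignIO.parse(path, "maf"))
    for block in blocks:
        for rec in block:
            sp = rec.id.split(".")[0]
            if sp not in species_order:
                species_order.append(sp)
    if ref_species not in species_order:
        raise ValueError(f"{path}: reference species {ref_species} absent")
    species_order = [ref_species] + [s for s in species_order if s != ref_species]
    aln = AlignmentColumns(species_order)
    for block in blocks:
        ref_rec = next((r for r in block if r.id.split(".")[0] == ref_species), None)
        if ref_rec is None:
            continue
        chrom = ref_rec.id.split(".", 1)[1]
        start = ref_rec.annotations["start"]
        if ref_rec.annotations.get("strand", 1) != 1:
            raise ValueError(f"{path}: minus-strand reference rows unsupported")
        rows = {r.id.split(".")[0]: str(r.seq).upper() for r in block}
        pos = start
        for i, ref_base in enumerate(str(ref_rec.seq).upper()):
            if ref_base == "-":
                continue
            bases = "".join(
                (rows.get(sp, GAP * len(ref_rec.seq))[i] if sp in rows else GAP)
                for sp in species_order
            )
            bases = "".join(b if b in "ACGT" else GAP for b in bases)
            aln.set_column(chrom, pos, bases)
            pos += 1
    return aln


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
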