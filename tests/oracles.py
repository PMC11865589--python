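"""Independent brute-force oracles shared by unit and acceptance tests.

Everything here re-derives results from first principles (per-site
enumeration, Biopython translation) without calling the package's
filtering code paths, so it can stand as a cross-check against them.
"""

from Bio.Seq import Seq

from syn4d.formats_io import AlignmentColumns, TranscriptModel
from syn4d.genetic_code import complement_base


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_fourfold(codon: str) -> bool:
    aa = _translate(codon)
    if aa == "*":
        return False
    return all(_translate(codon[:2] + b) == aa for b in "ACGT")


def brute_force_sites(
    transcripts: dict[str, TranscriptModel],
    genome: dict[str, str],
    alignment: AlignmentColumns,
    min_aligned_frac: float = 0.85,
    min_4d_frac: float = 0.95,
) -> dict[tuple, dict]:
    """Re-derive the shared-4d site set per site, by direct enumeration.

    Returns {(chrom, pos): {ref_base, counts, n_aligned}} for every
    retained third-codon-position site.
    """
    n_species = alignment.n_species
    out: dict[tuple, dict] = {}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        coords = []
        for s, e in t.cds:
            rng = range(e - 1, s - 1, -1) if t.strand == "-" else range(s, e)
            coords.extend(rng)
        seq = []
        for pos in coords:
            b = genome[t.chrom][pos]
            seq.append(b if t.strand == "+" else complement_base(b))
        seq = "".join(seq)
        n_codons = len(seq) // 3
        for k in range(n_codons):
            codon = seq[3 * k: 3 * k + 3]
            if _translate(codon) == "*":
                continue  # trailing stop
            if not _is_fourfold(codon):
                continue
            # per-species codons from the alignment
            sp_codons = []
            for s_i in range(n_species):
                bases = []
                for j in range(3):
                    col = alignment.column(t.chrom, coords[3 * k + j])
                    b = col[s_i] if col is not None else "-"
                    if b not in "ACGT":
                        bases = None
                        break
                    bases.append(b if t.strand == "+" else complement_base(b))
                sp_codons.append("".join(bases) if bases else None)
            aligned = [c for c in sp_codons if c is not None]
            if not aligned or len(aligned) / n_species < min_aligned_frac:
                continue
            n4d = sum(_is_fourfold(c) for c in aligned)
            if n4d / len(aligned) < min_4d_frac:
                continue
            counts = {b: sum(c[2] == b for c in aligned) for b in "ACGT"}
            out[(t.chrom, coords[3 * k + 2])] = {
                "ref_base": codon[2],
                "counts": counts,
                "n_aligned": len(aligned),
            }
    return out
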