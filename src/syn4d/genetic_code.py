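"""Standard genetic code, codon-position degeneracy and CpG context.

Every downstream stage of the pipeline queries this module: codon
translation under the standard nuclear code, per-position degeneracy
(how many of the four bases at a codon position encode the same amino
acid, the incumbent included), strand complementation, and CpG
dinucleotide flags on a coding-strand sequence.

Degeneracy labels follow the usual molecular-evolution convention:
1 synonymous base -> "0d" (non-degenerate), 2 -> "2d", 3 -> "3d",
4 -> "4d" (four-fold degenerate).  Positions inside stop codons have no
defined degeneracy and are reported with the distinct label "stop".
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

STOP = "*"

# NCBI standard-code layout: amino acids for codons enumerated with the
# first base cycling slowest over T, C, A, G.
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_NCBI_ORDER = "TCAG"

CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA_STRING[i * 16 + j * 4 + k]
    for i, b1 in enumerate(_NCBI_ORDER)
    for j, b2 in enumerate(_NCBI_ORDER)
    for k, b3 in enumerate(_NCBI_ORDER)
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == STOP)

DEGENERACY_LABELS = {1: "0d", 2: "2d", 3: "3d", 4: "4d"}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AmbiguousCodonError(ValueError):
    """Raised when a codon contains a non-ACGT character."""


class StopCodonError(ValueError):
    """Raised when a degeneracy count is requested for a stop codon."""


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise AmbiguousCodonError(f"ambiguous codon: {codon!r}")


def translate(codon: str) -> str:
    """Translate a 3-mer to its one-letter amino acid symbol ('*' = stop)."""
    _check_codon(codon)
    return CODON_TABLE[codon]


def is_stop(codon: str) -> bool:
    _check_codon(codon)
    return codon in STOP_CODONS


def site_degeneracy(codon: str, pos: int) -> int:
    """Number of bases at 1-based position ``pos`` preserving the amino acid.

    The observed base is counted, so the result is in 1..4 and 4 means
    fully (four-fold) degenerate.  Stop codons have no defined degeneracy
    and raise :class:`StopCodonError`; use :func:`degeneracy_label` when a
    "stop" label is acceptable.
    """
    _check_codon(codon)
    if pos not in (1, 2, 3):
        raise ValueError(f"codon position must be 1..3, got {pos}")
    if codon in STOP_CODONS:
        raise StopCodonError(f"degeneracy undefined for stop codon {codon}")
    aa = CODON_TABLE[codon]
    i = pos - 1
    return sum(
        CODON_TABLE[codon[:i] + b + codon[i + 1:]] == aa for b in BASES
    )


def degeneracy_label(codon: str, pos: int) -> str:
    """Degeneracy class label ("0d"/"2d"/"3d"/"4d"), or "stop"."""
    _check_codon(codon)
    if codon in STOP_CODONS:
        return "stop"
    return DEGENERACY_LABELS[site_degeneracy(codon, pos)]


def is_fourfold(codon: str) -> bool:
    """True iff the codon's third position is four-fold degenerate."""
    return codon not in STOP_CODONS and site_degeneracy(codon, 3) == 4


def reverse_complement(seq: str) -> str:
    """Reverse-complement of a nucleotide string (N maps to N)."""
    if any(c not in "ACGTNacgtn" for c in seq):
        bad = next(c for c in seq if c not in "ACGTNacgtn")
        raise ValueError(f"cannot complement character {bad!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    if base not in "ACGTNacgtn":
        raise ValueError(f"cannot complement character {base!r}")
    return base.translate(_COMPLEMENT)


def cpg_flags(seq: str) -> np.ndarray:
    """Per-position CpG-context flags for a coding-strand sequence.

    Position ``i`` is flagged iff it is a C immediately followed by a G,
    or a G immediately preceded by a C.  Terminal positions use only the
    neighbour that exists.
    """
    n = len(seq)
    flags = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            flags[i] = True
            flags[i + 1] = True
    return flags
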