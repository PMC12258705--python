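"""Genetic-code constants shared across the package.

The codon table is taken from Biopython's standard (NCBI table 1) code; the
NNK degenerate-codon machinery on top of it is specific to the five-codon
saturation libraries this package analyses.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

#: The 20 standard amino acids in the canonical (alphabetical) order used for
#: every residue-by-position matrix and for one-hot feature columns.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

AA_SET = frozenset(AA_ALPHABET)

#: Genotype labels: wild type, ClpS knockout, LFTR (aat) knockout.
GENOTYPES = ("WT", "CLPS_KO", "LFTR_KO")

_STANDARD_TABLE = unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {'TAA', 'TAG', 'TGA'}

#: codon -> amino acid for the 61 sense codons; stops are absent on purpose.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)

#: All 32 NNK codons: N = A/C/G/T at positions 1-2, K = G/T at position 3.
NNK_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "GT")

#: The single stop codon reachable through NNK degeneracy.
NNK_STOP_CODONS = tuple(c for c in NNK_CODONS if c in STOP_CODONS)  # ('TAG',)

#: Amino acids encodable by an NNK codon (all 20).
NNK_AMINO_ACIDS = frozenset(
    CODON_TO_AA[c] for c in NNK_CODONS if c not in STOP_CODONS
)

#: amino acid -> tuple of NNK codons encoding it (used by the simulator to
#: pick a representative DNA sequence for a motif).
AA_TO_NNK_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in NNK_CODONS:
    if _codon in STOP_CODONS:
        continue
    _aa = CODON_TO_AA[_codon]
    AA_TO_NNK_CODONS.setdefault(_aa, ())
    AA_TO_NNK_CODONS[_aa] = AA_TO_NNK_CODONS[_aa] + (_codon,)


def nnk_motif_space_size(motif_length: int = 5) -> int:
    """Number of distinct amino-acid motifs reachable by ``motif_length``
    NNK codons, counted (not materialised) as ``20 ** motif_length``.

    The count of encodable residues is derived from the codon table rather
    than hard-coded.
    """
    return len(NNK_AMINO_ACIDS) ** motif_length


def validate_motif(motif: str, length: int = 5) -> str:
    """Return ``motif`` if it is a standard-residue string of the given
    length; raise ``ValueError`` otherwise."""
    if len(motif) != length:
        raise ValueError(f"motif {motif!r} must have length {length}")
    bad = set(motif) - AA_SET
    if bad:
        raise ValueError(f"motif {motif!r} contains non-standard residues {sorted(bad)}")
    return motif
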