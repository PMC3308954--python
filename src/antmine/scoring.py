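"""Substitution-matrix and codon-translation primitives shared by all stages.

The scoring scheme throughout the package is BLOSUM62 with affine gaps.  A gap
of length L costs ``gap_open + L * gap_extend`` (the NCBI convention, so the
default "11/1" means a 1-residue gap costs 12).  Translated stop codons are
kept in frame as ``*`` and score a large negative constant against everything,
which makes local alignments terminate at stops without splitting frames.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

#: residue ordering used for all numeric matrices; X = unknown, * = stop
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: score assigned to any pair involving a stop codon
STOP_SCORE = -1000

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@lru_cache(maxsize=None)
def load_matrix(name: str = "BLOSUM62"):
    """Return a Bio.Align substitution matrix with stop rows forced to STOP_SCORE."""
    mat = substitution_matrices.load(name).copy()
    for aa in mat.alphabet:
        mat[aa, "*"] = STOP_SCORE
        mat["*", aa] = STOP_SCORE
    return mat


@lru_cache(maxsize=None)
def matrix_array(name: str = "BLOSUM62") -> np.ndarray:
    """The same matrix as an int64 array indexed by AA_INDEX on both axes."""
    mat = load_matrix(name)
    arr = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int64)
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            arr[AA_INDEX[a], AA_INDEX[b]] = int(mat[a, b])
    return arr


def pair_score(a: str, b: str, matrix=None) -> int:
    matrix = matrix if matrix is not None else load_matrix()
    if a not in matrix.alphabet:
        raise KeyError(f"residue {a!r} absent from substitution matrix")
    if b not in matrix.alphabet:
        raise KeyError(f"residue {b!r} absent from substitution matrix")
    return int(matrix[a, b])


def check_residues(seq: str, matrix=None) -> None:
    """Hard error naming the first residue not covered by the matrix."""
    matrix = matrix if matrix is not None else load_matrix()
    alphabet = set(matrix.alphabet)
    for ch in seq:
        if ch not in alphabet:
            raise KeyError(f"residue {ch!r} absent from substitution matrix")


@lru_cache(maxsize=None)
def _codon_map(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    cmap = dict(table.forward_table)
    for codon in table.stop_codons:
        cmap[codon] = "*"
    return cmap


def translate_dna(seq: str, table_id: int = 1) -> str:
    """Translate a DNA string codon-by-codon.

    Trailing bases that do not fill a codon are dropped.  Any codon containing
    a base other than A/C/G/T (i.e. N after input normalization) translates to
    X, even where the ambiguity would not change the residue.
    """
    cmap = _codon_map(table_id)
    out = []
    for k in range(0, len(seq) - 2, 3):
        codon = seq[k : k + 3]
        out.append(cmap.get(codon, "X"))
    return "".join(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def make_aligner(
    mode: str,
    gap_open: int = 11,
    gap_extend: int = 1,
    matrix=None,
) -> PairwiseAligner:
    """A PairwiseAligner configured for the package's affine-gap convention."""
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix if matrix is not None else load_matrix()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner
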