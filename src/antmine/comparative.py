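"""Multiple alignment, identity, conserved-position mapping and sequence logos.

The progressive aligner follows the classic recipe: k-mer composition
distances feed a UPGMA guide tree, and profiles are merged bottom-up by
global profile-profile alignment under BLOSUM62.  It is judged on alignment
quality (sum-of-pairs score near the small-instance optimum, conserved
columns staying conserved), not on bit-identity with any particular MSA tool.

Logo information content per column is I = log2(20) - H, with H the Shannon
entropy of the residue frequencies in that column; gaps are excluded from the
denominator, matching standard logo practice, and no small-sample correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from . import scoring
from .seqio import ProteinRecord, RunConfig

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
MAX_BITS = math.log2(20)

#: score for a residue paired with a gap in sum-of-pairs / profile scoring
GAP_RES_SCORE = -4


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, k: int) -> str:
        return self.rows[k].replace("-", "")

    def to_records(self) -> list[ProteinRecord]:
        # aligned FASTA: gap symbol kept, so validate lazily via plain records
        return [ProteinRecord(i, r.replace("-", "X")) for i, r in zip(self.ids, self.rows)]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


@dataclass
class LogoMatrix:
    """Per-column residue frequencies, information (bits) and letter heights."""

    frequencies: pd.DataFrame  # columns = STANDARD_AA residues, one row per column
    information: np.ndarray
    heights: pd.DataFrame
    all_gap_columns: list[int] = field(default_factory=list)

    def write(self, path) -> None:
        out = self.heights.copy()
        out.insert(0, "information", self.information)
        out.to_csv(path, sep="\t", index_label="column")


def sum_of_pairs(rows: list[str], matrix=None, gap_res: int = GAP_RES_SCORE) -> int:
    """Sum-of-pairs alignment score: BLOSUM62 per residue pair, gap-residue
    pairs cost ``gap_res``, gap-gap pairs are free."""
    matrix = matrix if matrix is not None else scoring.load_matrix()
    total = 0
    n = len(rows)
    for c in range(len(rows[0])):
        col = [rows[k][c] for k in range(n)]
        for a in range(n):
            for b in range(a + 1, n):
                x, y = col[a], col[b]
                if x == "-" and y == "-":
                    continue
                if x == "-" or y == "-":
                    total += gap_res
                else:
                    total += int(matrix[x, y])
    return total


def _kmer_vector(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _cosine_distance(a: dict[str, int], b: dict[str, int]) -> float:
    keys = set(a) | set(b)
    dot = sum(a.get(x, 0) * b.get(x, 0) for x in keys)
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def _profile_align(rows_a: list[str], rows_b: list[str], matrix, gap_open: int, gap_extend: int):
    """Global profile-profile alignment; returns merged gapped rows (A then B).

    Column-column score is the mean pairwise substitution score across the two
    profiles; a new gap column scores each profile residue against a gap
    (GAP_RES_SCORE), i.e. gaps are linear per column, which keeps the
    traceback exactly reproducible.
    """
    na, nb = len(rows_a[0]), len(rows_b[0])
    aa_list = list(scoring.AA_ALPHABET) + ["-"]
    idx = {c: k for k, c in enumerate(aa_list)}
    mat = np.zeros((len(aa_list), len(aa_list)))
    for x in scoring.AA_ALPHABET:
        for y in scoring.AA_ALPHABET:
            mat[idx[x], idx[y]] = matrix[x, y]
    for x in scoring.AA_ALPHABET:
        mat[idx[x], idx["-"]] = GAP_RES_SCORE
        mat[idx["-"], idx[x]] = GAP_RES_SCORE
    mat[idx["-"], idx["-"]] = 0.0

    def profile(rows):
        p = np.zeros((len(rows[0]), len(aa_list)))
        for row in rows:
            for i, c in enumerate(row):
                p[i, idx[c]] += 1
        return p / len(rows)

    prof_a, prof_b = profile(rows_a), profile(rows_b)
    colscore = prof_a @ mat @ prof_b.T  # (na, nb)
    gap_vec = mat[:, idx["-"]]
    ga = prof_a @ gap_vec  # cost of aligning an A column to a new gap
    gb = prof_b @ gap_vec

    H = np.zeros((na + 1, nb + 1))
    H[1:, 0] = np.cumsum(ga)
    H[0, 1:] = np.cumsum(gb)
    for i in range(1, na + 1):
        Hi, Hi1 = H[i], H[i - 1]
        cs = colscore[i - 1]
        gai = ga[i - 1]
        for j in range(1, nb + 1):
            Hi[j] = max(Hi1[j - 1] + cs[j - 1], Hi1[j] + gai, Hi[j - 1] + gb[j - 1])
    # traceback; prefer diagonal, then consume-A, then consume-B
    i, j = na, nb
    path = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + colscore[i - 1, j - 1]:
            path.append("D")
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + ga[i - 1]:
            path.append("A")
            i -= 1
        else:
            path.append("B")
            j -= 1
    path.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for step in path:
        if step in ("D", "A"):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ia])
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
        if step in ("D", "B"):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[ib])
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append("-")
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def progressive_align(
    records: list[ProteinRecord],
    config: RunConfig | None = None,
    k: int = 3,
) -> MultipleAlignment:
    """Progressive multiple alignment (k-mer distance, UPGMA tree, profile merge).

    Deterministic for a fixed input order; a single record passes through
    unaligned.
    """
    config = config or RunConfig()
    if not records:
        raise ValueError("progressive_align requires at least one record")
    if len(records) == 1:
        return MultipleAlignment([records[0].id], [records[0].seq])
    matrix = scoring.load_matrix(config.matrix_name)
    k_eff = max(1, min(k, min(len(r.seq) for r in records)))
    vectors = [_kmer_vector(r.seq, k_eff) for r in records]
    n = len(records)
    condensed = []
    for a in range(n):
        for b in range(a + 1, n):
            condensed.append(_cosine_distance(vectors[a], vectors[b]))
    tree = linkage(np.array(condensed), method="average")
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].seq]) for i in range(n)
    }
    for step, (a, b, _, _) in enumerate(tree):
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        merged = _profile_align(rows_a, rows_b, matrix, config.gap_open, config.gap_extend)
        clusters[n + step] = (idx_a + idx_b, merged)
    order, rows = clusters.popitem()[1]
    by_input = sorted(zip(order, rows))
    return MultipleAlignment(
        [records[i].id for i, _ in by_input], [r for _, r in by_input]
    )


def percent_identity(a: str, b: str, mode: str = "global", config: RunConfig | None = None) -> float:
    """100 x identities / alignment columns under an optimal pairwise alignment."""
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or RunConfig()
    aligner = scoring.make_aligner(
        mode, config.gap_open, config.gap_extend, scoring.load_matrix(config.matrix_name)
    )
    alignments = aligner.align(a, b)
    if mode == "local" and alignments.score <= 0:
        return 0.0
    aln = alignments[0]
    sa, sb = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return 100.0 * ident / len(sa) if sa else 0.0


def logo(aln: MultipleAlignment) -> LogoMatrix:
    """Residue frequencies, information content and letter heights per column."""
    if len(aln.rows) < 2:
        raise ValueError("logo requires an alignment of >= 2 rows")
    ncol = aln.n_columns
    freq = np.zeros((ncol, len(STANDARD_AA)))
    aa_idx = {c: i for i, c in enumerate(STANDARD_AA)}
    all_gap = []
    for c in range(ncol):
        col = [row[c] for row in aln.rows]
        counts = np.zeros(len(STANDARD_AA))
        for ch in col:
            if ch in aa_idx:
                counts[aa_idx[ch]] += 1
        total = counts.sum()
        if total == 0:
            all_gap.append(c)
        else:
            freq[c] = counts / total
    info = np.zeros(ncol)
    for c in range(ncol):
        p = freq[c][freq[c] > 0]
        if len(p):
            entropy = -(p * np.log2(p)).sum()
            info[c] = MAX_BITS - entropy
    heights = freq * info[:, None]
    fdf = pd.DataFrame(freq, columns=list(STANDARD_AA))
    hdf = pd.DataFrame(heights, columns=list(STANDARD_AA))
    return LogoMatrix(frequencies=fdf, information=info, heights=hdf, all_gap_columns=all_gap)


def map_position(aln: MultipleAlignment, source_id: str, position: int) -> dict:
    """Map a residue position of one record through its alignment column.

    Returns {"column": c, "positions": {record id: index or "gap"}}.
    """
    try:
        src_row = aln.rows[aln.ids.index(source_id)]
    except ValueError:
        raise KeyError(f"record {source_id!r} not in alignment") from None
    if position < 0 or position >= len(src_row.replace("-", "")):
        raise IndexError(f"position {position} outside record {source_id!r}")
    count = -1
    column = -1
    for c, ch in enumerate(src_row):
        if ch != "-":
            count += 1
            if count == position:
                column = c
                break
    positions: dict[str, object] = {}
    for rid, row in zip(aln.ids, aln.rows):
        if row[column] == "-":
            positions[rid] = "gap"
        else:
            positions[rid] = sum(ch != "-" for ch in row[:column])
    return {"column": column, "positions": positions}
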