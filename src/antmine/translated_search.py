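"""Six-frame translated homology search: the tBLASTn analogue.

Contigs are translated in all six frames (stops kept in frame as ``*``) and
query proteins are aligned to each frame peptide by exact Smith-Waterman with
affine gaps under BLOSUM62.  Because ``*`` scores a large negative constant
against every residue, local alignments terminate at stop codons without the
frames being split, which keeps the peptide-to-DNA coordinate map intact.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from . import scoring
from .seqio import Contig, ProteinRecord, RunConfig

logger = logging.getLogger(__name__)

FRAMES = (1, 2, 3, -1, -2, -3)

#: cap on co-optimal alignments examined for the deterministic tie-break
_TIEBREAK_CAP = 64


@dataclass(frozen=True)
class FramePeptide:
    """One reading frame of a contig, with its peptide-to-DNA coordinate map."""

    contig_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    peptide: str
    contig_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def offset(self) -> int:
        return abs(self.frame) - 1

    def codon_interval(self, k: int) -> tuple[int, int]:
        """Forward-strand half-open DNA interval of peptide position ``k``."""
        f = self.offset
        if self.frame > 0:
            return (f + 3 * k, f + 3 * k + 3)
        return (self.contig_length - (f + 3 * k + 3), self.contig_length - (f + 3 * k))

    def dna_interval(self, pep_start: int, pep_end: int) -> tuple[int, int]:
        """Forward-strand DNA interval covered by peptide slice [start, end)."""
        f = self.offset
        if self.frame > 0:
            return (f + 3 * pep_start, f + 3 * pep_end)
        return (
            self.contig_length - (f + 3 * pep_end),
            self.contig_length - (f + 3 * pep_start),
        )


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    aligned_query: str
    aligned_subject: str

    @property
    def percent_identity(self) -> float:
        cols = len(self.aligned_query)
        ident = sum(a == b and a != "-" for a, b in zip(self.aligned_query, self.aligned_subject))
        return 100.0 * ident / cols if cols else 0.0

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


@dataclass(frozen=True)
class LocalHit:
    """A scored local alignment between a query protein and a translated frame."""

    contig_id: str
    frame: int
    strand: str
    query_id: str
    score: int
    query_start: int
    query_end: int
    subject_start: int  # forward-strand DNA, half-open
    subject_end: int
    pep_start: int  # residue coordinates in the frame peptide
    pep_end: int
    aligned_query: str
    aligned_subject: str
    percent_identity: float


def six_frame_translate(contig: Contig, table_id: int = 1) -> list[FramePeptide]:
    """Translate a contig in all six frames.

    Frames -1..-3 are forward translations of the reverse complement;
    N-containing codons give X and stops are emitted as ``*``.
    """
    n = len(contig.seq)
    if n < 3:
        logger.warning("contig %s shorter than one codon; empty frames", contig.id)
        return [FramePeptide(contig.id, f, "", n) for f in FRAMES]
    rc = scoring.reverse_complement(contig.seq)
    frames = []
    for frame in FRAMES:
        src = contig.seq if frame > 0 else rc
        off = abs(frame) - 1
        frames.append(
            FramePeptide(contig.id, frame, scoring.translate_dna(src[off:], table_id), n)
        )
    return frames


def local_align(
    query: str,
    subject: str,
    matrix=None,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment | None:
    """Best Smith-Waterman local alignment, or None when the optimum is empty.

    Ties are broken deterministically: lowest subject start, then lowest query
    start, then shortest alignment.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    matrix = matrix if matrix is not None else scoring.load_matrix()
    scoring.check_residues(query, matrix)
    scoring.check_residues(subject, matrix)
    aligner = scoring.make_aligner("local", gap_open, gap_extend, matrix)
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    best = None
    best_key = None
    for aln in itertools.islice(alignments, _TIEBREAK_CAP):
        blocks_q, blocks_s = aln.aligned
        key = (int(blocks_s[0][0]), int(blocks_q[0][0]), len(aln[0]))
        if best_key is None or key < best_key:
            best_key = key
            best = aln
    blocks_q, blocks_s = best.aligned
    return LocalAlignment(
        score=int(alignments.score),
        query_start=int(blocks_q[0][0]),
        query_end=int(blocks_q[-1][1]),
        subject_start=int(blocks_s[0][0]),
        subject_end=int(blocks_s[-1][1]),
        aligned_query=str(best[0]),
        aligned_subject=str(best[1]),
    )


def _frame_hits(
    query: ProteinRecord,
    frame: FramePeptide,
    config: RunConfig,
    matrix,
    max_hits_per_frame: int,
) -> list[LocalHit]:
    """Repeatedly take the best local alignment in one frame, masking each hit.

    Masking aligned subject residues with ``*`` (score -1000) lets weaker,
    non-overlapping alignments surface on later iterations, mimicking multiple
    BLAST HSPs per frame.
    """
    hits: list[LocalHit] = []
    working = frame.peptide
    min_score = max(config.min_hit_score, 1)
    for _ in range(max_hits_per_frame):
        if not working:
            break
        aln = local_align(query.seq, working, matrix, config.gap_open, config.gap_extend)
        if aln is None or aln.score < min_score:
            break
        dstart, dend = frame.dna_interval(aln.subject_start, aln.subject_end)
        hits.append(
            LocalHit(
                contig_id=frame.contig_id,
                frame=frame.frame,
                strand=frame.strand,
                query_id=query.id,
                score=aln.score,
                query_start=aln.query_start,
                query_end=aln.query_end,
                subject_start=dstart,
                subject_end=dend,
                pep_start=aln.subject_start,
                pep_end=aln.subject_end,
                aligned_query=aln.aligned_query,
                aligned_subject=aln.aligned_subject,
                percent_identity=aln.percent_identity,
            )
        )
        working = (
            working[: aln.subject_start]
            + "*" * (aln.subject_end - aln.subject_start)
            + working[aln.subject_end :]
        )
    return hits


def _overlap(a: LocalHit, b: LocalHit) -> float:
    """Overlap of the two DNA intervals as a fraction of the shorter one."""
    inter = min(a.subject_end, b.subject_end) - max(a.subject_start, b.subject_start)
    if inter <= 0:
        return 0.0
    shorter = min(a.subject_end - a.subject_start, b.subject_end - b.subject_start)
    return inter / shorter


def merge_hits(hits: list[LocalHit], min_overlap: float = 0.5) -> list[LocalHit]:
    """Collapse same-(query, contig, strand) hits overlapping >= 50% of the shorter.

    The higher-scoring hit is kept; a deterministic sort replaces the manual
    curation step of refining redundant automated hits.
    """
    by_group: dict[tuple, list[LocalHit]] = {}
    for h in hits:
        by_group.setdefault((h.query_id, h.contig_id, h.strand), []).append(h)
    kept: list[LocalHit] = []
    for group in by_group.values():
        group.sort(key=lambda h: (-h.score, h.subject_start, h.query_start))
        chosen: list[LocalHit] = []
        for h in group:
            if all(_overlap(h, c) < min_overlap for c in chosen):
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (-h.score, h.contig_id, h.query_id, h.subject_start))
    return kept


def search_contigs(
    queries: list[ProteinRecord],
    contigs: list[Contig],
    config: RunConfig | None = None,
    max_hits_per_frame: int = 5,
) -> list[LocalHit]:
    """Search every query against every contig in six frames.

    Returns merged hits sorted by descending score; an empty list is a valid
    outcome.
    """
    config = config or RunConfig()
    matrix = scoring.load_matrix(config.matrix_name)
    hits: list[LocalHit] = []
    for contig in contigs:
        frames = six_frame_translate(contig)
        for query in queries:
            for frame in frames:
                if frame.peptide:
                    hits.extend(_frame_hits(query, frame, config, matrix, max_hits_per_frame))
    return merge_hits(hits)


HIT_COLUMNS = [
    "query_id",
    "contig_id",
    "strand",
    "frame",
    "score",
    "percent_identity",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "pep_start",
    "pep_end",
    "aligned_query",
    "aligned_subject",
]


def write_hits(hits: list[LocalHit], path) -> None:
    rows = [{c: getattr(h, c) for c in HIT_COLUMNS} for h in hits]
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df["percent_identity"] = df["percent_identity"].round(2)
    df.to_csv(path, sep="\t", index=False)


def read_hits(path) -> list[LocalHit]:
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "contig_id": str})
    return [
        LocalHit(
            contig_id=row.contig_id,
            frame=int(row.frame),
            strand=row.strand,
            query_id=row.query_id,
            score=int(row.score),
            query_start=int(row.query_start),
            query_end=int(row.query_end),
            subject_start=int(row.subject_start),
            subject_end=int(row.subject_end),
            pep_start=int(row.pep_start),
            pep_end=int(row.pep_end),
            aligned_query=row.aligned_query,
            aligned_subject=row.aligned_subject,
            percent_identity=float(row.percent_identity),
        )
        for row in df.itertuples(index=False)
    ]
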