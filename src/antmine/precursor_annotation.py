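"""Segment precursors into signal / pro / mature regions by homology transfer.

Prepropeptides are organized as signal peptide, pro-region(s) and one or more
mature peptide domains.  The segmentation method is the one used for
annotating mined precursors: boundaries of an already-annotated reference are
mapped through a global alignment onto the new sequence.  Motif evidence
(dibasic prohormone-convertase sites KR/RR/KK and the glycine amidation
signal G[RK][RK]) can refine transferred mature-peptide boundaries within a
small slack, and every such override is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import scoring
from .seqio import ProteinRecord, RunConfig

logger = logging.getLogger(__name__)

SEGMENT_ROLES = ("signal", "pro", "mature", "neurophysin", "copeptin")

#: residues with Kyte-Doolittle hydropathy > 1.5, for the signal sanity check
_KD_HYDROPHOBIC = set("AILMFV") | {"C"}


@dataclass(frozen=True)
class Segment:
    role: str
    start: int  # half-open residue interval
    end: int
    confidence: str = "aligned"  # aligned | gap-adjusted | motif-adjusted


@dataclass(frozen=True)
class ReferenceAnnotation:
    """An annotated precursor used as the source of segment boundaries."""

    record: ProteinRecord
    segments: tuple[Segment, ...]

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s.start)
        if segs and segs[0].role == "signal" and segs[0].start != 0:
            raise ValueError("signal segment must start at position 0")
        prev_end = 0
        for seg in segs:
            if seg.role not in SEGMENT_ROLES:
                raise ValueError(f"unknown segment role {seg.role!r}")
            if seg.start < prev_end:
                raise ValueError("segments overlap")
            if seg.end > len(self.record.seq):
                raise ValueError("segment outside sequence")
            prev_end = seg.end

    @classmethod
    def from_rows(cls, record: ProteinRecord, rows) -> "ReferenceAnnotation":
        return cls(record, tuple(Segment(role, s, e) for role, s, e in rows))

    @property
    def signal_end(self) -> int | None:
        for seg in self.segments:
            if seg.role == "signal":
                return seg.end
        return None

    def mature_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "mature"]


@dataclass(frozen=True)
class MaturePeptide:
    sequence: str
    start: int
    end: int
    amidated: bool
    flank_n: str | None  # cleavage motif preceding the peptide, if any
    flank_c: str | None


@dataclass
class PrecursorAnnotation:
    """Transferred segmentation of a target precursor."""

    record: ProteinRecord
    segments: list[Segment]
    mature_peptides: list[MaturePeptide] = field(default_factory=list)
    percent_identity: float = 0.0

    def segment(self, role: str) -> Segment | None:
        for seg in self.segments:
            if seg.role == role:
                return seg
        return None


class NonHomologousError(ValueError):
    """Raised when target/reference identity is below the transfer floor."""


def _global_alignment(target: str, ref: str, config: RunConfig):
    aligner = scoring.make_aligner(
        "global", config.gap_open, config.gap_extend, scoring.load_matrix(config.matrix_name)
    )
    aln = aligner.align(target, ref)[0]
    return str(aln[0]), str(aln[1])


def _boundary_positions(ref_aln: str, tgt_aln: str) -> list[tuple[int, bool]]:
    """For each reference boundary 0..len(ref), the target position and gap flag."""
    n_ref = sum(c != "-" for c in ref_aln)
    out = [(0, False)] * (n_ref + 1)
    ref_count = 0
    tgt_count = 0
    out[0] = (0, False)
    for r, t in zip(ref_aln, tgt_aln):
        gap = t == "-"
        if t != "-":
            tgt_count += 1
        if r != "-":
            ref_count += 1
            out[ref_count] = (tgt_count, gap)
    return out


def percent_identity_of(aln_a: str, aln_b: str) -> float:
    cols = len(aln_a)
    ident = sum(a == b and a != "-" for a, b in zip(aln_a, aln_b))
    return 100.0 * ident / cols if cols else 0.0


def transfer_segments(
    target: ProteinRecord,
    ref: ReferenceAnnotation,
    config: RunConfig | None = None,
) -> PrecursorAnnotation:
    """Transfer reference segment boundaries to a target through global alignment.

    Refuses (NonHomologousError) when the alignment identity falls below the
    configured floor, signalling that the pair is not a credible homolog pair.
    """
    config = config or RunConfig()
    tgt_aln, ref_aln = _global_alignment(target.seq, ref.record.seq, config)
    identity = percent_identity_of(tgt_aln, ref_aln)
    if identity < config.identity_floor:
        raise NonHomologousError(
            f"{target.id} vs {ref.record.id}: identity {identity:.1f}% below floor "
            f"{config.identity_floor:.1f}%"
        )
    bounds = _boundary_positions(ref_aln, tgt_aln)
    n_tgt = len(target.seq)
    segments = []
    for seg in sorted(ref.segments, key=lambda s: s.start):
        t_start, gap_s = bounds[seg.start]
        t_end, gap_e = bounds[seg.end]
        t_start = min(t_start, n_tgt)
        t_end = min(t_end, n_tgt)
        if t_end > t_start:
            conf = "gap-adjusted" if (gap_s or gap_e) else "aligned"
            segments.append(Segment(seg.role, t_start, t_end, conf))
    ann = PrecursorAnnotation(record=target, segments=segments, percent_identity=identity)
    sig = ann.segment("signal")
    if sig is not None:
        core = sum(target.seq[sig.start : sig.end].count(a) for a in _KD_HYDROPHOBIC)
        if core < 6:
            logger.warning(
                "%s: transferred signal peptide has a weak hydrophobic core (%d residues)",
                target.id,
                core,
            )
    ann.mature_peptides = split_multipeptide_precursor(ann, ref)
    return ann


def find_cleavage_and_amidation(
    precursor: str,
    cleavage_motifs=("KR", "RR", "KK"),
    amidation_motifs=("GRK", "GKR", "GRR", "GKK"),
) -> list[tuple[int, str]]:
    """All dibasic-cleavage and G[RK][RK] amidation motif occurrences.

    Positions are the motif start indices; occurrences may overlap.  An
    amidation motif at position p marks residue p-1 as the amide-donating
    C-terminus of the preceding peptide.
    """
    sites = []
    for motif in tuple(cleavage_motifs) + tuple(amidation_motifs):
        start = 0
        while True:
            pos = precursor.find(motif, start)
            if pos < 0:
                break
            sites.append((pos, motif))
            start = pos + 1
    sites.sort()
    return sites


def _nearest_motif(sites, pos: int, slack: int, kinds) -> tuple[int, str] | None:
    best = None
    for p, motif in sites:
        if motif in kinds and abs(p - pos) <= slack:
            if best is None or abs(p - pos) < abs(best[0] - pos):
                best = (p, motif)
    return best


def split_multipeptide_precursor(
    ann: PrecursorAnnotation,
    ref: ReferenceAnnotation,
    config: RunConfig | None = None,
    slack: int = 3,
) -> list[MaturePeptide]:
    """One mature peptide per transferred mature segment.

    Boundaries are trimmed at flanking dibasic/amidation motifs found within
    ``slack`` residues of the transferred boundary; motif evidence overrides
    the transfer and every move is logged with before/after positions.
    """
    config = config or RunConfig()
    seq = ann.record.seq
    sites = find_cleavage_and_amidation(seq, config.cleavage_motifs, config.amidation_motifs)
    peptides: list[MaturePeptide] = []
    for seg in ann.segments:
        if seg.role != "mature":
            continue
        start, end = seg.start, seg.end
        flank_n = flank_c = None
        # N-boundary: a cleavage motif ending at the boundary
        cand = _nearest_motif(
            [(p + len(m), m) for p, m in sites], start, slack, set(config.cleavage_motifs)
        )
        if cand is not None:
            new_start, flank_n = cand
            if new_start != start:
                logger.info(
                    "%s: mature start moved %d -> %d by %s motif",
                    ann.record.id,
                    start,
                    new_start,
                    flank_n,
                )
            start = new_start
        amidated = False
        # C-boundary: amidation motif (peptide ends before the Gly) or dibasic
        cand = _nearest_motif(sites, end, slack, set(config.amidation_motifs))
        if cand is not None:
            new_end, flank_c = cand
            amidated = True
            if new_end != end:
                logger.info(
                    "%s: mature end moved %d -> %d by %s amidation motif",
                    ann.record.id,
                    end,
                    new_end,
                    flank_c,
                )
            end = new_end
        else:
            cand = _nearest_motif(sites, end, slack, set(config.cleavage_motifs))
            if cand is not None:
                new_end, flank_c = cand
                if new_end != end:
                    logger.info(
                        "%s: mature end moved %d -> %d by %s motif",
                        ann.record.id,
                        end,
                        new_end,
                        flank_c,
                    )
                end = new_end
        if end <= start:
            continue
        if not amidated and end < len(seq) and seq[end] == "G":
            # a lone glycine after the C-terminus still donates an amide when
            # followed by a basic residue
            if end + 1 < len(seq) and seq[end + 1] in "RK":
                amidated = True
        peptides.append(
            MaturePeptide(
                sequence=seq[start:end],
                start=start,
                end=end,
                amidated=amidated,
                flank_n=flank_n,
                flank_c=flank_c,
            )
        )
    return peptides
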