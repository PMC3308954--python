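"""Synthetic genomes with planted peptide-precursor genes of known structure.

Every pipeline stage can be exercised against ground truth without any
downloads: a precursor is built to an architectural spec (signal peptide with
a hydrophobic core, anionic pro-domain ending in a dibasic KR site, cationic
Cys-rich mature domain, optional glycine amidation signal, optional Cys-rich
neurophysin-like carrier domain), reverse-translated with uniformly drawn
codons, interrupted by canonical GT-AG introns at chosen phases, and embedded
in random background DNA of tunable GC content.

Three architectures are provided:

* ``defensin``    - signal + pro(KR) + one cationic mature domain with the
                    six-cysteine network (lengths default to 19/35/43, i.e. a
                    97-residue precursor with a 43-residue mature peptide);
* ``inotocin``    - signal + Cys1/Cys6 nonapeptide + GRK amidation signal +
                    a 12-cysteine neurophysin-like domain (150 residues);
* ``multipeptide``- signal + pro(KR) + several short amidated peptides
                    separated by dibasic sites, allatostatin-style.

The generator is deterministic: identical spec and seed give byte-identical
sequences and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import scoring
from .precursor_annotation import ReferenceAnnotation, Segment
from .seqio import Contig, ProteinRecord

_HYDROPHOBIC_CORE = "ALIVF"  # Kyte-Doolittle > 1.5
_NEUTRAL = "GSTANQ"
_MATURE_POOL = "GSTANQWYVFILM"  # neutral plus hydrophobics, no charge/Cys/basic
_STANDARD = "ACDEFGHIKLMNPQRSTVWY"

#: default inter-cysteine spacing of the mature defensin domain (CSab ranges)
DEFAULT_CYS_SPACING = (10, 4, 9, 6, 1)


@dataclass
class SyntheticGeneSpec:
    """Architecture and embedding parameters of one planted gene."""

    architecture: str = "defensin"  # defensin | inotocin | multipeptide
    signal_length: int = 19
    pro_length: int = 35  # includes the trailing KR cleavage site
    pro_charge: int = -4
    mature_lengths: tuple[int, ...] = (43,)
    mature_charge: int = 6
    cys_spacing: tuple[int, ...] = DEFAULT_CYS_SPACING
    neurophysin_length: int = 119
    amidation: bool = False
    intron_count: int = 1
    intron_lengths: tuple[int, ...] = ()
    intron_phases: tuple[int, ...] = ()
    #: no exon shorter than this many codons; spliceosomal exon recognition
    #: makes very short exons vanishingly rare in real genes
    min_exon_codons: int = 10
    flank_length: int = 800
    background_gc: float = 0.42
    divergence: float = 0.0
    strand: str = "+"

    def __post_init__(self):
        if self.architecture not in ("defensin", "inotocin", "multipeptide"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if min(
            (self.signal_length, self.pro_length, *self.mature_lengths), default=1
        ) < 1:
            raise ValueError("all segment lengths must be >= 1")


def preset(architecture: str, **overrides) -> SyntheticGeneSpec:
    """Canonical spec for each architecture.

    defensin: 19-residue signal, 35-residue pro-domain at net charge -4, one
    43-residue mature domain at +6 with the six-cysteine network (a 97-residue
    precursor).  inotocin: signal + Cys1/Cys6 nonapeptide + GRK + 12-Cys
    neurophysin (150 residues).  multipeptide: seven short amidated peptides
    from one precursor, allatostatin-style.
    """
    base = {
        "defensin": {},
        "inotocin": {"mature_lengths": (9,), "neurophysin_length": 119, "amidation": True},
        "multipeptide": {
            "mature_lengths": (8, 8, 8, 7, 30, 9, 28),
            "pro_length": 20,
            "pro_charge": 0,
            "amidation": True,
        },
    }[architecture]
    base = dict(base)
    base.update(overrides)
    return SyntheticGeneSpec(architecture=architecture, **base)


@dataclass
class GroundTruth:
    """Everything the pipeline should recover about one planted gene."""

    contig_id: str
    strand: str
    gene_start: int  # forward-strand coords of the coding region (excl. stop)
    gene_end: int
    exons: list[tuple[int, int]]  # transcription order, forward coords
    introns: list[tuple[int, int]]
    precursor: str
    segments: list[tuple[str, int, int]]  # (role, start, end) in residues
    mature_peptides: list[str]
    amidation_flags: list[bool]

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    def check_consistency(self, contig: Contig) -> bool:
        """Splice the recorded exons out of the contig and re-translate."""
        parts = [contig.seq[s:e] for s, e in sorted(self.exons)]
        cds = "".join(parts)
        if self.strand == "-":
            cds = scoring.reverse_complement(cds)
        return scoring.translate_dna(cds) == self.precursor


def _place_charges(
    rng, length: int, n_pos: int, n_neg: int, fixed: dict[int, str]
) -> list[str]:
    """Residue list with charges placed on free positions, no adjacent basics."""
    res = [fixed.get(i) for i in range(length)]
    free = [i for i in range(length) if res[i] is None]
    if n_pos + n_neg > len(free):
        raise ValueError("charge target exceeds available positions")

    def ok_basic(i):
        for j in (i - 1, i + 1):
            if 0 <= j < length and res[j] in ("K", "R"):
                return False
        return True

    order = list(rng.permutation(free))
    placed_pos = 0
    for i in order:
        if placed_pos == n_pos:
            break
        if res[i] is None and ok_basic(i):
            res[i] = str(rng.choice(list("KR")))
            placed_pos += 1
    if placed_pos < n_pos:
        raise ValueError("charge target exceeds available positions")
    free = [i for i in range(length) if res[i] is None]
    for i in list(rng.permutation(free))[:n_neg]:
        res[i] = str(rng.choice(list("DE")))
    for i in range(length):
        if res[i] is None:
            res[i] = str(rng.choice(list(_MATURE_POOL)))
    return res


def _signal(rng, length: int) -> str:
    if length < 8:
        raise ValueError("signal peptide must be >= 8 residues")
    core = "".join(rng.choice(list(_HYDROPHOBIC_CORE), size=length - 4))
    return "M" + str(rng.choice(list("KN"))) + core + str(rng.choice(list("ST"))) + "A"


def _pro(rng, length: int, charge: int) -> str:
    if length < 3:
        raise ValueError("pro-domain must be >= 3 residues (incl. KR site)")
    body_len = length - 2  # trailing KR
    n_neg = 2 - charge  # KR contributes +2
    if n_neg < 0 or n_neg > body_len:
        raise ValueError("pro charge target unsatisfiable at this length")
    body = _place_charges(rng, body_len, 0, n_neg, {})
    return "".join(body) + "KR"


def _mature_defensin(rng, length: int, charge: int, spacing: tuple[int, ...]) -> str:
    n_cys = len(spacing) + 1
    span = n_cys + sum(spacing)
    if span + 2 > length:
        raise ValueError("cysteine template longer than the mature domain")
    first = 2  # leave uncharged head room before the first Cys
    fixed = {}
    pos = first
    fixed[pos] = "C"
    for gap in spacing:
        pos += gap + 1
        fixed[pos] = "C"
    n_pos = charge + 2
    n_neg = 2
    if n_pos < 0:
        n_pos, n_neg = 0, -charge
    res = _place_charges(rng, length, n_pos, n_neg, fixed)
    return "".join(res)


def _neurophysin(rng, length: int, n_cys: int = 12) -> str:
    if length < 2 * n_cys:
        raise ValueError("neurophysin domain too short for its cysteines")
    positions = sorted(rng.choice(np.arange(1, length - 1), size=n_cys, replace=False))
    # enforce >= 1 residue between cysteines for a well-defined spacing vector
    fixed = {}
    last = -2
    for p in positions:
        p = int(max(p, last + 2))
        if p >= length - 1:
            break
        fixed[p] = "C"
        last = p
    while len(fixed) < n_cys:  # top up deterministically if collisions ate some
        for i in range(1, length - 1):
            if i not in fixed and (i - 1) not in fixed and (i + 1) not in fixed:
                fixed[i] = "C"
                if len(fixed) == n_cys:
                    break
    res = _place_charges(rng, length, 1, 2, fixed)
    return "".join(res)


def make_precursor(
    spec: SyntheticGeneSpec, seed: int
) -> tuple[ProteinRecord, ReferenceAnnotation]:
    """Construct a precursor protein satisfying the spec exactly.

    Raises ValueError for unsatisfiable specs (e.g. a charge target larger
    than the segment).
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    parts: list[str] = []
    pos = 0

    def push(role: str, seq: str):
        nonlocal pos
        segments.append(Segment(role, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)

    push("signal", _signal(rng, spec.signal_length))
    if spec.architecture == "defensin":
        push("pro", _pro(rng, spec.pro_length, spec.pro_charge))
        push(
            "mature",
            _mature_defensin(rng, spec.mature_lengths[0], spec.mature_charge, spec.cys_spacing),
        )
        if spec.amidation:
            push("pro", "GKR")
    elif spec.architecture == "inotocin":
        nona = _place_charges(
            rng, spec.mature_lengths[0], 1, 0, {0: "C", 5: "C"} if spec.mature_lengths[0] >= 6 else {0: "C"}
        )
        push("mature", "".join(nona))
        push("pro", "GRK")  # canonical amidation signal
        push("neurophysin", _neurophysin(rng, spec.neurophysin_length))
    else:  # multipeptide
        push("pro", _pro(rng, spec.pro_length, spec.pro_charge))
        for k, plen in enumerate(spec.mature_lengths):
            pep = _place_charges(rng, plen, 1, 0, {})
            push("mature", "".join(pep))
            push("pro", "GKR" if spec.amidation else "KR")
    seq = "".join(parts)
    rid = f"synthetic_{spec.architecture}"
    record = ProteinRecord(rid, seq)
    ann = ReferenceAnnotation(record, tuple(segments))
    return record, ann


def _reverse_translate(rng, protein: str) -> str:
    cmap = scoring._codon_map()
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(cmap.items()):
        by_aa.setdefault(aa, []).append(codon)
    return "".join(str(rng.choice(by_aa[aa])) for aa in protein)


def _random_dna(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_intron(rng, length: int, gc: float) -> str:
    if length < 4:
        raise ValueError("intron must be >= 4 bases")
    return "GT" + _random_dna(rng, length - 4, gc) + "AG"


def plant_gene(
    precursor: ProteinRecord,
    spec: SyntheticGeneSpec,
    seed: int,
    contig_id: str = "synth_contig",
    annotation: ReferenceAnnotation | None = None,
) -> tuple[Contig, GroundTruth]:
    """Embed a precursor gene (with introns) in background DNA.

    The coding sequence is reverse-translated with uniform codon choice,
    split by GT-AG introns at the requested phases, terminated by a stop
    codon, and placed between background flanks; the returned GroundTruth
    passes the splice-and-translate consistency check by construction.
    """
    rng = np.random.default_rng(seed)
    cds = _reverse_translate(rng, precursor.seq)
    stop = str(rng.choice(["TAA", "TAG", "TGA"]))

    n_codons = len(precursor.seq)
    count = spec.intron_count
    lengths = list(spec.intron_lengths) or [int(rng.integers(80, 400)) for _ in range(count)]
    phases = list(spec.intron_phases) or [int(rng.integers(0, 3)) for _ in range(count)]
    if len(lengths) != count or len(phases) != count:
        raise ValueError("intron lengths/phases must match intron count")
    codon_sites: list[int] = []
    if count > 0:
        lo, hi = spec.min_exon_codons, n_codons - spec.min_exon_codons
        if hi - lo < count * spec.min_exon_codons:
            raise ValueError("gene too short for the requested intron count")
        for _ in range(200):
            sites = sorted(int(x) for x in rng.choice(np.arange(lo, hi), size=count, replace=False))
            if all(b - a >= spec.min_exon_codons for a, b in zip(sites, sites[1:])):
                codon_sites = sites
                break
        else:
            raise ValueError("could not place introns with the required exon spacing")
    cut_points = sorted(3 * c + p for c, p in zip(codon_sites, phases))

    flank5 = _random_dna(rng, spec.flank_length, spec.background_gc)
    flank3 = _random_dna(rng, spec.flank_length, spec.background_gc)
    gene_start = len(flank5)

    pieces = []
    exons = []
    introns = []
    prev = 0
    offset = gene_start
    for cut, length in zip(cut_points, lengths):
        exon_seq = cds[prev:cut]
        pieces.append(exon_seq)
        exons.append((offset, offset + len(exon_seq)))
        offset += len(exon_seq)
        intron_seq = _random_intron(rng, length, spec.background_gc)
        pieces.append(intron_seq)
        introns.append((offset, offset + len(intron_seq)))
        offset += len(intron_seq)
        prev = cut
    pieces.append(cds[prev:])
    exons.append((offset, offset + len(cds) - prev))
    offset += len(cds) - prev
    gene_end = offset

    forward = flank5 + "".join(pieces) + stop + flank3
    if spec.strand == "-":
        n = len(forward)
        seq = scoring.reverse_complement(forward)
        exons = [(n - e, n - s) for s, e in exons]
        introns = [(n - e, n - s) for s, e in introns]
        gene_start, gene_end = n - gene_end, n - gene_start
    else:
        seq = forward

    segments = (
        [(s.role, s.start, s.end) for s in annotation.segments] if annotation else []
    )
    mature = (
        [precursor.seq[s.start : s.end] for s in annotation.mature_segments()]
        if annotation
        else []
    )
    amid = []
    for s in annotation.mature_segments() if annotation else []:
        nxt = precursor.seq[s.end : s.end + 1]
        amid.append(nxt == "G")
    truth = GroundTruth(
        contig_id=contig_id,
        strand=spec.strand,
        gene_start=gene_start,
        gene_end=gene_end,
        exons=exons,
        introns=introns,
        precursor=precursor.seq,
        segments=segments,
        mature_peptides=mature,
        amidation_flags=amid,
    )
    contig = Contig(id=contig_id, seq=seq)
    if not truth.check_consistency(contig):
        raise AssertionError("planted gene failed the splice-and-translate check")
    return contig, truth


def diverge_query(
    protein: str, divergence: float, seed: int, preserve: tuple[int, ...] = ()
) -> str:
    """Substitute exactly round(divergence * length) positions.

    BLOSUM62-positive substitutions are preferred with probability 0.7;
    positions in ``preserve`` are never touched.  No indels are introduced, so
    gap-free global identity equals 100 * (1 - divergence) up to rounding.
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_sub = round(divergence * len(protein))
    candidates = [i for i in range(len(protein)) if i not in set(preserve)]
    if n_sub > len(candidates):
        raise ValueError("preserve set leaves too few substitutable positions")
    chosen = sorted(rng.choice(np.array(candidates), size=n_sub, replace=False)) if n_sub else []
    matrix = scoring.load_matrix()
    out = list(protein)
    for i in chosen:
        orig = protein[i]
        positive = [a for a in _STANDARD if a != orig and matrix[orig, a] > 0]
        others = [a for a in _STANDARD if a != orig and a not in positive]
        pool = positive if (positive and rng.random() < 0.7) else others
        out[i] = str(rng.choice(pool))
    return "".join(out)


def make_family(
    record: ProteinRecord, n: int, divergence: float, seed: int, preserve_cys: bool = True
) -> list[ProteinRecord]:
    """A family of homologs of one precursor, optionally with fixed cysteines."""
    preserve = tuple(i for i, c in enumerate(record.seq) if c == "C") if preserve_cys else ()
    members = [record]
    for k in range(1, n):
        seq = diverge_query(record.seq, divergence, seed + k, preserve)
        members.append(ProteinRecord(f"{record.id}_h{k}", seq))
    return members


def make_genome(
    n_genes: int, spec: SyntheticGeneSpec, seed: int, prefix: str = "synth"
) -> tuple[list[Contig], list[GroundTruth], ProteinRecord, ReferenceAnnotation]:
    """One contig per planted gene, one shared precursor.

    All genes encode the same precursor (drawn once from the spec) but differ
    in codon choice, intron placement and background, which is the layout of
    a per-gene recovery experiment: the returned precursor is the exact query
    at divergence 0, or the substrate for diverge_query.
    """
    precursor, ann = make_precursor(spec, seed)
    contigs, truths = [], []
    for g in range(n_genes):
        contig, truth = plant_gene(
            precursor, spec, seed + 1000 * (g + 1), contig_id=f"{prefix}_{g:04d}", annotation=ann
        )
        contigs.append(contig)
        truths.append(truth)
    return contigs, truths, precursor, ann


def write_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_json() for t in truths], fh, indent=2)
        fh.write("\n")
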