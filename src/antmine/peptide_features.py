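"""Characterization statistics for peptide segments.

Net charge is the formal count (+1 per Arg/Lys, -1 per Asp/Glu); histidine
and the termini are ignored.  This integer scheme is the one that reproduces
the published charge bookkeeping for insect defensins (mature domains around
+3..+6 balanced by anionic pro-domains around -3..-4) and is documented
prominently because pH-dependent schemes give different numbers.

The CSab (cysteine-stabilized alpha-beta) classification is operational: a
segment is flagged when it has exactly six cysteines whose spacings fall in
configurable ranges fitted to insect defensin mature domains; the disulfide
pairing is then reported by homology convention (1-4, 2-5, 3-6), never
computed from structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

POSITIVE = set("RK")
NEGATIVE = set("DE")
HYDROPHOBIC = set("AVFILMWYC")

#: allowed gaps between consecutive Cys: C-x(4-16)-C-x(2-5)-C-x(8-12)-C-x(4-8)-C-x(1)-C
CSAB_SPACING_RANGES = ((4, 16), (2, 5), (8, 12), (4, 8), (1, 1))

CSAB_PAIRING = ((1, 4), (2, 5), (3, 6))


@dataclass
class PeptideFeatures:
    """Charge, cysteine-network and composition profile of one peptide segment."""

    peptide_id: str
    role: str
    length: int
    net_charge: int
    positive: int
    negative: int
    cys_count: int
    cys_spacing: tuple[int, ...]
    csab: bool
    pro_count: int
    pro_fraction: float
    hydrophobic_fraction: float
    amidated: bool = False
    pairing: tuple[tuple[int, int], ...] = ()
    conserved_positions: dict[int, str] = field(default_factory=dict)


def net_charge(seq: str) -> int:
    """Formal net charge: (+1 per R/K) + (-1 per D/E); His and termini ignored.

    Additive over concatenation by construction.
    """
    return sum(c in POSITIVE for c in seq) - sum(c in NEGATIVE for c in seq)


def cys_network(
    seq: str, spacing_ranges=CSAB_SPACING_RANGES
) -> tuple[int, tuple[int, ...], bool]:
    """Cysteine count, inter-Cys spacing vector, and the CSab flag.

    The flag is true iff there are exactly six cysteines and every spacing
    (residues strictly between consecutive Cys) lies within its configured
    range.
    """
    positions = [i for i, c in enumerate(seq) if c == "C"]
    spacing = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    flag = len(positions) == 6 and all(
        lo <= gap <= hi for gap, (lo, hi) in zip(spacing, spacing_ranges)
    )
    return len(positions), spacing, flag


def composition(seq: str) -> tuple[int, float, float, int, int]:
    """(Pro count, Pro fraction, hydrophobic fraction, positive count, negative count)."""
    n = len(seq)
    pro = seq.count("P")
    hydro = sum(c in HYDROPHOBIC for c in seq)
    pos = sum(c in POSITIVE for c in seq)
    neg = sum(c in NEGATIVE for c in seq)
    return pro, pro / n if n else 0.0, hydro / n if n else 0.0, pos, neg


def charge_complementarity(pro_seq: str, mature_seq: str) -> tuple[int, int, float | None]:
    """Pro-domain vs mature charge and the neutralization ratio -pro/mature.

    The anionic pro-domain offsets the cationic mature peptide during
    biosynthesis; the ratio is None when the mature charge is zero.
    """
    if not pro_seq or not mature_seq:
        raise ValueError("charge_complementarity requires non-empty segments")
    pc = net_charge(pro_seq)
    mc = net_charge(mature_seq)
    ratio = (-pc / mc) if mc != 0 else None
    return pc, mc, ratio


def profile_segment(
    peptide_id: str,
    role: str,
    seq: str,
    amidated: bool = False,
    spacing_ranges=CSAB_SPACING_RANGES,
) -> PeptideFeatures:
    """Full feature profile of one peptide segment."""
    count, spacing, flag = cys_network(seq, spacing_ranges)
    pro, pro_frac, hydro_frac, pos, neg = composition(seq)
    return PeptideFeatures(
        peptide_id=peptide_id,
        role=role,
        length=len(seq),
        net_charge=pos - neg,
        positive=pos,
        negative=neg,
        cys_count=count,
        cys_spacing=spacing,
        csab=flag,
        pro_count=pro,
        pro_fraction=pro_frac,
        hydrophobic_fraction=hydro_frac,
        amidated=amidated,
        pairing=CSAB_PAIRING if flag else (),
    )
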