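"""Gene-structure prediction by spliced alignment of a protein to genomic DNA.

This is the homology-based gene modelling stage: given a query precursor
protein and a genomic window around a translated-search hit, a dynamic
program aligns query residues to codons while allowing GT-AG introns between
codons (phase 0) and inside codons after one or two bases (phases 1 and 2).
The objective is

    sum of BLOSUM62(query residue, translated codon)
    - affine protein gap costs (open + L * extend)
    - a flat intron-open penalty per intron (no length cost within bounds)

maximized locally in both query and DNA (a zero floor, so the intronless
optimum coincides with Smith-Waterman on the translated frame).  Split codons
across phase-1/2 introns are scored exactly: donor-side partial bases are
tracked by grouping donor candidates on their base content, so the translated
split codon is known when the acceptor is reached.

Scores are integers throughout, which lets the traceback re-derive each DP
decision by exact equality instead of storing backpointers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d

from . import scoring
from .seqio import Contig, ProteinRecord, RunConfig
from .translated_search import LocalHit

logger = logging.getLogger(__name__)

NEG = -(2**30)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_X = scoring.AA_INDEX["X"]


@dataclass(frozen=True)
class Intron:
    """A spliced-out interval with its boundary dinucleotides."""

    start: int  # coordinates in the model's coordinate frame (forward strand)
    end: int
    donor: str
    acceptor: str
    phase: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """Exon/intron structure with its spliced coding translation.

    ``exons`` and ``introns`` are forward-strand half-open intervals listed in
    transcription direction (coordinates decrease along the list on the minus
    strand).  ``translation`` is the protein encoded by the concatenated exons
    read in transcription direction.
    """

    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    introns: list[Intron]
    translation: str
    score: int
    query_id: str
    query_start: int
    query_end: int

    @property
    def complete(self) -> bool:
        return "*" not in self.translation

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class OrfCandidate:
    """A single-exon ORF extension of a hit: interval plus its translation."""

    contig_id: str
    strand: str
    start: int  # forward-strand half-open, stop codon included when found
    end: int
    protein: str
    partial: bool
    query_id: str


def lagged_window_max(values: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """out[t] = max(values[d] for d in [t-hi, t-lo]), NEG where the window is empty.

    Used for intron donor lookups: an acceptor at t may pair with any donor a
    bounded distance behind it.
    """
    n = len(values)
    out = np.full(n, NEG, dtype=values.dtype)
    if lo > hi or lo >= n:
        return out
    width = hi - lo + 1
    # trailing[t] = max(values[t-width+1 : t+1]); origin shifts the centred window
    trailing = maximum_filter1d(
        values, size=width, mode="constant", cval=NEG, origin=(width - 1) // 2
    )
    out[lo:] = trailing[: n - lo]
    return out


def _base_indices(region: str) -> np.ndarray:
    arr = np.full(len(region), 4, dtype=np.int64)  # 4 = N/other
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(region.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _codon_lut() -> np.ndarray:
    lut = np.empty(64, dtype=np.int64)
    bases = "ACGT"
    for i1 in range(4):
        for i2 in range(4):
            for i3 in range(4):
                aa = scoring.translate_dna(bases[i1] + bases[i2] + bases[i3])
                lut[i1 * 16 + i2 * 4 + i3] = scoring.AA_INDEX[aa]
    return lut


_LUT = _codon_lut()


class _SplicedDP:
    """Forward DP matrices plus enough context for equality-based traceback."""

    def __init__(self, query: str, region: str, config: RunConfig):
        self.q = query
        self.s = region
        self.cfg = config
        self.m = len(query)
        self.n = len(region)
        self.go = config.gap_open
        self.ge = config.gap_extend
        self.ip = config.intron_open_penalty
        self.minL = config.min_intron
        self.maxL = config.max_intron
        self.mat = scoring.matrix_array(config.matrix_name)
        self.qidx = np.array([scoring.AA_INDEX[a] for a in query], dtype=np.int64)
        self._precompute()
        self._forward()

    # -- setup -------------------------------------------------------------
    def _precompute(self):
        n = self.n
        b = _base_indices(self.s)
        self.b = b
        # aa index of codon ending at j (j >= 3)
        aa = np.full(n + 1, _X, dtype=np.int64)
        if n >= 3:
            b1, b2, b3 = b[:-2], b[1:-1], b[2:]
            valid = (b1 < 4) & (b2 < 4) & (b3 < 4)
            codes = np.where(valid, b1 * 16 + b2 * 4 + b3, 0)
            aa[3:] = np.where(valid, _LUT[codes], _X)
        self.codon_aa = aa

        sb = np.frombuffer(self.s.encode(), dtype=np.uint8)
        donor = np.zeros(n + 1, dtype=bool)  # donor[d]: s[d:d+2] == GT
        acc = np.zeros(n + 1, dtype=bool)  # acc[a]: s[a-2:a] == AG
        if n >= 2:
            dd = (sb[:-1] == ord(self.cfg.intron_donor[0])) & (
                sb[1:] == ord(self.cfg.intron_donor[1])
            )
            donor[: n - 1] = dd
            aa_ = (sb[:-1] == ord(self.cfg.intron_acceptor[0])) & (
                sb[1:] == ord(self.cfg.intron_acceptor[1])
            )
            acc[2:] = aa_
        self.donor = donor
        self.acc = acc

        # phase-1 donor groups: boundary c, partial base s[c], donor at c+1
        self.ph1_masks = []
        self.ph1_T = []  # aa of split codon (g, s[a], s[a+1]) indexed by acceptor a
        d1 = np.zeros(n + 1, dtype=bool)
        d1[: n - 1] = donor[1:n]
        for g in range(5):  # 0..3 = ACGT, 4 = N group
            mask = np.zeros(n + 1, dtype=bool)
            mask[:n] = d1[:n] & ((b == g) if g < 4 else (b >= 4))
            self.ph1_masks.append(mask)
            T = np.full(n + 1, _X, dtype=np.int64)
            if g < 4 and n >= 2:
                b2, b3 = b[:-1], b[1:]
                valid = (b2 < 4) & (b3 < 4)
                codes = np.where(valid, g * 16 + b2 * 4 + b3, 0)
                T[: n - 1] = np.where(valid, _LUT[codes], _X)
            self.ph1_T.append(T)

        # phase-2 donor groups: boundary c, partial bases s[c]s[c+1], donor at c+2
        self.ph2_masks = []
        self.ph2_T = []
        d2 = np.zeros(n + 1, dtype=bool)
        d2[: n - 2] = donor[2:n]
        groups = [(g1, g2) for g1 in range(4) for g2 in range(4)] + [None]
        self.ph2_groups = groups
        for grp in groups:
            mask = np.zeros(n + 1, dtype=bool)
            if n >= 2:
                if grp is None:
                    gm = (b[:-1] >= 4) | (b[1:] >= 4)
                else:
                    gm = (b[:-1] == grp[0]) & (b[1:] == grp[1])
                mask[: n - 1] = d2[: n - 1] & gm
            self.ph2_masks.append(mask)
            T = np.full(n + 1, _X, dtype=np.int64)
            if grp is not None:
                valid = b < 4
                codes = np.where(valid, grp[0] * 16 + grp[1] * 4 + b, 0)
                T[:n] = np.where(valid, _LUT[codes], _X)
            self.ph2_T.append(T)

    # -- forward pass ------------------------------------------------------
    def _forward(self):
        m, n = self.m, self.n
        self.Hfin = np.zeros((m + 1, n + 1), dtype=np.int64)
        self.Hrow1 = np.zeros((m + 1, n + 1), dtype=np.int64)
        self.Dq = np.full((m + 1, n + 1), NEG, dtype=np.int64)
        go, ge, ip = self.go, self.ge, self.ip
        best = (0, 0, 0)  # score, i, j

        for i in range(1, m + 1):
            hprev = self.Hfin[i - 1]
            mrow = self.mat[self.qidx[i - 1]]
            # codon match
            cm = np.full(n + 1, NEG, dtype=np.int64)
            if n >= 3:
                cm[3:] = hprev[:-3] + mrow[self.codon_aa[3:]]
            # phase-1/2 intron closures (consume residue i-1 across the intron)
            ph = np.full(n + 1, NEG, dtype=np.int64)
            for g in range(5):
                V = np.where(self.ph1_masks[g], hprev, NEG)
                W = lagged_window_max(V, self.minL + 1, self.maxL + 1)
                # boundary j = a + 2 for acceptor a
                cand = np.full(n + 1, NEG, dtype=np.int64)
                ok = self.acc & (W > NEG // 2)
                a_idx = np.nonzero(ok[: n - 1])[0]
                if len(a_idx):
                    vals = W[a_idx] + mrow[self.ph1_T[g][a_idx]] - ip
                    cand[a_idx + 2] = vals
                np.maximum(ph, cand, out=ph)
            for gi in range(len(self.ph2_groups)):
                V = np.where(self.ph2_masks[gi], hprev, NEG)
                W = lagged_window_max(V, self.minL + 2, self.maxL + 2)
                cand = np.full(n + 1, NEG, dtype=np.int64)
                ok = self.acc & (W > NEG // 2)
                a_idx = np.nonzero(ok[:n])[0]
                if len(a_idx):
                    vals = W[a_idx] + mrow[self.ph2_T[gi][a_idx]] - ip
                    cand[a_idx + 1] = vals
                np.maximum(ph, cand, out=ph)
            # query-deletion gap (consumes query only)
            dq = np.maximum(hprev - (go + ge), self.Dq[i - 1] - ge)
            self.Dq[i] = dq
            hb = np.maximum.reduce([np.zeros(n + 1, dtype=np.int64), cm, ph, dq])
            # codon insertions (gap in query, consumes DNA in whole codons)
            hrow1 = hb.copy()
            for r in range(3):
                idx = np.arange(r, n + 1, 3)
                if len(idx) < 2:
                    continue
                vals = hb[idx] + ge * np.arange(len(idx), dtype=np.int64)
                run = np.maximum.accumulate(vals)
                dd = np.full(len(idx), NEG, dtype=np.int64)
                dd[1:] = run[:-1] - go - ge * np.arange(1, len(idx), dtype=np.int64)
                hrow1[idx] = np.maximum(hrow1[idx], dd)
            self.Hrow1[i] = hrow1
            # phase-0 introns (between codons, same row)
            V0 = np.where(self.donor, hrow1, NEG)
            W0 = lagged_window_max(V0, self.minL, self.maxL)
            p0 = np.where(self.acc, W0 - ip, NEG)
            hfin = np.maximum(hrow1, p0)
            self.Hfin[i] = hfin
            jbest = int(np.argmax(hfin))
            if hfin[jbest] > best[0]:
                best = (int(hfin[jbest]), i, jbest)
        self.best = best

    # -- traceback ---------------------------------------------------------
    def traceback(self):
        """Return (ops, i0, j0): ops in 3'->5' order, each a tuple.

        op kinds: ("codon", j-3, j), ("ins", j-3k, j) for unmatched codons,
        ("del", count) for unmatched query residues, and
        ("intron", start, end, phase, pieces) where pieces are the split-codon
        exon fragments flanking the intron.
        """
        score, i, j = self.best
        if score <= 0:
            return None
        ops = []
        s, q = self.s, self.q
        go, ge, ip = self.go, self.ge, self.ip
        state = "H"
        while True:
            if state == "H":
                v = int(self.Hfin[i][j])
                if v == int(self.Hrow1[i][j]):
                    state = "R"
                    continue
                # phase-0 intron ending at j
                d = self._find_donor0(i, j, v)
                ops.append(("intron", d, j, 0, None))
                j = d
                state = "R"
                continue
            v = int(self.Hrow1[i][j])
            if v == 0:
                return ops, i, j
            mrow = self.mat[self.qidx[i - 1]] if i >= 1 else None
            if i >= 1 and j >= 3 and v == int(self.Hfin[i - 1][j - 3] + mrow[self.codon_aa[j]]):
                ops.append(("codon", j - 3, j))
                i, j, state = i - 1, j - 3, "H"
                continue
            hit = self._try_dd(i, j, v)
            if hit is not None:
                k = hit
                ops.append(("ins", j - 3 * k, j))
                j -= 3 * k
                continue
            if v == int(self.Dq[i][j]):
                cnt = 0
                while int(self.Dq[i][j]) == int(self.Dq[i - 1][j]) - ge:
                    cnt += 1
                    i -= 1
                # opening step
                assert int(self.Dq[i][j]) == int(self.Hfin[i - 1][j]) - (go + ge)
                cnt += 1
                i -= 1
                ops.append(("del", cnt))
                state = "H"
                continue
            hit = self._try_split_intron(i, j, v)
            if hit is not None:
                (c, start, end, phase) = hit
                ops.append(("intron", start, end, phase, c))
                i, j, state = i - 1, c, "H"
                continue
            raise AssertionError(f"traceback failed at i={i} j={j} v={v}")

    def _find_donor0(self, i: int, j: int, v: int) -> int:
        lo = max(0, j - self.maxL)
        hi = j - self.minL
        row = self.Hrow1[i]
        for d in range(lo, hi + 1):
            if self.donor[d] and int(row[d]) - self.ip == v:
                return d
        raise AssertionError("phase-0 donor not found")

    def _try_dd(self, i: int, j: int, v: int) -> int | None:
        row = self.Hrow1[i]
        k = 1
        while j - 3 * k >= 0:
            if v == int(row[j - 3 * k]) - self.go - self.ge * k:
                return k
            if int(row[j - 3 * k]) - self.go - self.ge * k > v:
                # larger values upstream can only come from Dd itself; keep looking
                pass
            k += 1
        return None

    def _try_split_intron(self, i: int, j: int, v: int):
        if i < 1:
            return None
        mrow = self.mat[self.qidx[i - 1]]
        s = self.s
        # phase 1: boundary j = a+2, acceptor at a, codon = s[c] + s[a] + s[a+1]
        a = j - 2
        if a >= 2 and self.acc[a]:
            lo = max(0, a - 1 - self.maxL)
            hi = a - 1 - self.minL
            for c in range(lo, hi + 1):
                if c + 2 < self.n and self.donor[c + 1]:
                    aa = scoring.translate_dna(s[c] + s[a] + s[a + 1]) or "X"
                    sc = int(self.Hfin[i - 1][c]) + int(mrow[scoring.AA_INDEX[aa]]) - self.ip
                    if sc == v:
                        return (c, c + 1, a, 1)
        # phase 2: boundary j = a+1, codon = s[c] + s[c+1] + s[a]
        a = j - 1
        if a >= 2 and self.acc[a]:
            lo = max(0, a - 2 - self.maxL)
            hi = a - 2 - self.minL
            for c in range(lo, hi + 1):
                if c + 3 < self.n and self.donor[c + 2]:
                    aa = scoring.translate_dna(s[c] + s[c + 1] + s[a]) or "X"
                    sc = int(self.Hfin[i - 1][c]) + int(mrow[scoring.AA_INDEX[aa]]) - self.ip
                    if sc == v:
                        return (c, c + 2, a, 2)
        return None


def _assemble(ops, j0, j_end):
    """Turn reversed traceback ops into exon/intron intervals (region coords)."""
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int, int]] = []
    cur_start = j0
    for op in reversed(ops):
        if op[0] == "intron":
            _, start, end, phase, _ = op
            exons.append((cur_start, start))
            introns.append((start, end, phase))
            cur_start = end
    exons.append((cur_start, j_end))
    exons = [(s, e) for s, e in exons if e > s]
    return exons, introns


def spliced_align(
    query: str,
    region: str,
    config: RunConfig | None = None,
    offset: int = 0,
    contig_id: str = "",
    strand: str = "+",
    query_id: str = "",
) -> GeneModel | None:
    """Maximum-scoring spliced gene model of ``query`` in ``region``.

    ``region`` is the forward-strand DNA of the window starting at ``offset``
    on the contig; for minus-strand models the DP runs on the reverse
    complement and intervals are mapped back to forward coordinates.  Returns
    None when no positive-scoring model exists ("no prediction").
    """
    config = config or RunConfig()
    if len(region) < 3 or not query:
        raise ValueError("spliced_align requires region >= 3 bases and a non-empty query")
    oriented = region if strand == "+" else scoring.reverse_complement(region)
    dp = _SplicedDP(query, oriented, config)
    tb = dp.traceback()
    if tb is None:
        return None
    ops, i0, j0 = tb
    score, i_end, j_end = dp.best
    exons_o, introns_o = _assemble(ops, j0, j_end)
    n = len(oriented)

    def fwd(iv: tuple[int, int]) -> tuple[int, int]:
        if strand == "+":
            return (offset + iv[0], offset + iv[1])
        return (offset + n - iv[1], offset + n - iv[0])

    exons = [fwd(iv) for iv in exons_o]
    introns = [
        Intron(
            start=fwd((s_, e_))[0],
            end=fwd((s_, e_))[1],
            donor=oriented[s_ : s_ + 2],
            acceptor=oriented[e_ - 2 : e_],
            phase=ph,
        )
        for (s_, e_, ph) in introns_o
    ]
    cds = "".join(oriented[s_:e_] for s_, e_ in sorted((iv for iv in exons_o)))
    translation = scoring.translate_dna(cds)
    return GeneModel(
        contig_id=contig_id,
        strand=strand,
        exons=exons,
        introns=introns,
        translation=translation,
        score=score,
        query_id=query_id,
        query_start=i0,
        query_end=i_end,
    )


def identify_orf(hit: LocalHit, contig: Contig) -> OrfCandidate:
    """Extend a hit to an open reading frame in its own frame.

    5' extension walks upstream codon-by-codon to the nearest in-frame ATG,
    stopping (and flagging the candidate partial) at the first in-frame stop
    or the contig edge; 3' extension runs to the first in-frame stop, which is
    included in the interval.
    """
    oriented = contig.seq if hit.strand == "+" else scoring.reverse_complement(contig.seq)
    off = abs(hit.frame) - 1
    n = len(oriented)
    p0 = off + 3 * hit.pep_start
    start = p0
    partial = True
    p = p0
    while p >= 0:
        codon = oriented[p : p + 3]
        aa = scoring.translate_dna(codon)
        if aa == "*":
            break
        if codon == "ATG":
            start = p
            partial = False
            break
        p -= 3
    end = off + 3 * hit.pep_end
    p = end
    found_stop = False
    while p + 3 <= n:
        if scoring.translate_dna(oriented[p : p + 3]) == "*":
            end = p + 3
            found_stop = True
            break
        p += 3
    if not found_stop:
        end = off + 3 * ((n - off) // 3)
        partial = True
    coding_end = end - 3 if found_stop else end
    protein = scoring.translate_dna(oriented[start:coding_end])
    if hit.strand == "+":
        fstart, fend = start, end
    else:
        fstart, fend = n - end, n - start
    return OrfCandidate(
        contig_id=hit.contig_id,
        strand=hit.strand,
        start=fstart,
        end=fend,
        protein=protein,
        partial=partial,
        query_id=hit.query_id,
    )


def model_to_precursor(model: GeneModel | None) -> ProteinRecord:
    """Spliced translation of a model as a ProteinRecord named contig_query."""
    if model is None or not model.exons:
        raise ValueError("cannot derive a precursor from an empty model")
    name = f"{model.contig_id}_{model.query_id}"
    return ProteinRecord(
        id=name,
        seq=model.translation,
        description="partial" if not model.complete else "",
        partial=not model.complete,
    )
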