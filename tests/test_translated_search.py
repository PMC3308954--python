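"""Six-frame translation and exact local search, checked against hand oracles."""

import numpy as np
import pytest

from conftest import random_protein
from oracles import enumerate_local_score, sw_local_score

from antmine import scoring
from antmine.seqio import Contig, RunConfig
from antmine.synthetic_data import SyntheticGeneSpec, make_precursor, plant_gene
from antmine.translated_search import (
    local_align,
    search_contigs,
    six_frame_translate,
)


class TestSixFrameTranslate:
    @pytest.mark.parametrize(
        "seq,frame,expected",
        [
            ("ATGAAA", 1, "MK"),
            ("TTTCAT", -1, "MK"),  # reverse complement of ATGAAA
            ("ATGNAA", 1, "MX"),
            ("ATGTAAAAA", 1, "M*K"),
        ],
    )
    def test_frame_translations(self, seq, frame, expected):
        frames = {f.frame: f for f in six_frame_translate(Contig("c", seq))}
        assert frames[frame].peptide == expected

    def test_short_contig_gives_empty_frames(self):
        frames = six_frame_translate(Contig("c", "AC"))
        assert all(f.peptide == "" for f in frames)

    def test_frame_lengths(self, rng):
        from conftest import random_dna

        seq = random_dna(rng, 101)
        for f in six_frame_translate(Contig("c", seq)):
            assert len(f.peptide) == (101 - f.offset) // 3

    def test_coordinate_map_codon_width_and_monotonicity(self, rng):
        from conftest import random_dna

        contig = Contig("c", random_dna(rng, 60))
        for f in six_frame_translate(contig):
            intervals = [f.codon_interval(k) for k in range(len(f.peptide))]
            assert all(e - s == 3 for s, e in intervals)
            starts = [s for s, _ in intervals]
            assert starts == sorted(starts) if f.frame > 0 else starts == sorted(
                starts, reverse=True
            )
            # translating the mapped codon reproduces the peptide residue
            for k, (s, e) in enumerate(intervals):
                codon = contig.seq[s:e]
                if f.frame < 0:
                    codon = scoring.reverse_complement(codon)
                assert scoring.translate_dna(codon) == f.peptide[k]


class TestLocalAlign:
    def test_mk_self_alignment_scores_ten(self):
        aln = local_align("MK", "MK")
        assert aln.score == 10
        assert (aln.aligned_query, aln.aligned_subject) == ("MK", "MK")

    def test_all_negative_pairs_give_empty_optimum(self):
        assert local_align("AAAA", "PPPP") is None

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(KeyError, match="J"):
            local_align("MJ", "MK")

    def test_matches_handwritten_dp_on_random_pairs(self, blosum62, rng):
        for _ in range(300):
            q = random_protein(rng, int(rng.integers(1, 9)))
            s = random_protein(rng, int(rng.integers(1, 9)))
            expected = sw_local_score(q, s, blosum62, 11, 1)
            aln = local_align(q, s)
            got = aln.score if aln else 0
            assert got == expected, (q, s)

    def test_dp_oracle_agrees_with_exhaustive_enumeration(self, blosum62, rng):
        # validates the oracle itself on tiny instances
        for _ in range(40):
            q = random_protein(rng, int(rng.integers(1, 5)))
            s = random_protein(rng, int(rng.integers(1, 5)))
            assert sw_local_score(q, s, blosum62, 11, 1) == enumerate_local_score(
                q, s, blosum62, 11, 1
            )


def planted_contig(rng, seed=3):
    spec = SyntheticGeneSpec(intron_count=0)
    precursor, ann = make_precursor(spec, seed)
    contig, truth = plant_gene(precursor, spec, seed + 1, annotation=ann)
    return precursor, contig, truth


class TestSearchContigs:
    def test_planted_query_found_at_full_identity(self, rng, config):
        precursor, contig, truth = planted_contig(rng)
        hits = search_contigs([precursor], [contig], config)
        top = hits[0]
        assert top.percent_identity == 100.0
        assert (top.query_start, top.query_end) == (0, len(precursor.seq))
        assert (top.subject_start, top.subject_end) == (truth.gene_start, truth.gene_end)

    def test_strand_symmetry(self, rng, config):
        precursor, contig, _ = planted_contig(rng)
        rc = Contig(contig.id, scoring.reverse_complement(contig.seq))
        fwd = search_contigs([precursor], [contig], config)
        rev = search_contigs([precursor], [rc], config)
        assert sorted(h.score for h in fwd) == sorted(h.score for h in rev)
        n = len(contig.seq)
        fwd_ivals = sorted((h.subject_start, h.subject_end) for h in fwd)
        rev_ivals = sorted((n - h.subject_end, n - h.subject_start) for h in rev)
        assert fwd_ivals == rev_ivals
        assert {h.strand for h in fwd} == {"-" if s == "+" else "+" for s in (h.strand for h in rev)}

    def test_min_score_monotonicity(self, rng, config):
        precursor, contig, _ = planted_contig(rng)
        low = search_contigs([precursor], [contig], RunConfig(min_hit_score=30))
        high = search_contigs([precursor], [contig], RunConfig(min_hit_score=200))
        keys = lambda hits: {(h.query_id, h.contig_id, h.strand, h.subject_start) for h in hits}
        assert keys(high) <= keys(low)

    def test_self_hit_scores_self_alignment(self, config, blosum62):
        precursor, contig, _ = planted_contig(np.random.default_rng(0), seed=8)
        hits = search_contigs([precursor], [contig], config)
        self_score = sum(int(blosum62[a, a]) for a in precursor.seq)
        assert hits[0].score == self_score

    def test_empty_result_when_min_score_exceeds_self_score(self, config):
        precursor, contig, _ = planted_contig(np.random.default_rng(5), seed=12)
        cfg = RunConfig(min_hit_score=10**6)
        assert search_contigs([precursor], [contig], cfg) == []


class TestMergeHits:
    def test_overlapping_hits_collapse_to_higher_score(self, rng, config):
        precursor, contig, _ = planted_contig(rng)
        hits = search_contigs([precursor], [contig], config)
        # merged output never contains two same-strand hits overlapping >= 50%
        for a in hits:
            for b in hits:
                if a is b or (a.query_id, a.contig_id, a.strand) != (
                    b.query_id,
                    b.contig_id,
                    b.strand,
                ):
                    continue
                inter = min(a.subject_end, b.subject_end) - max(a.subject_start, b.subject_start)
                shorter = min(
                    a.subject_end - a.subject_start, b.subject_end - b.subject_start
                )
                assert inter < 0.5 * shorter

    def test_hits_sorted_by_descending_score(self, rng, config):
        precursor, contig, _ = planted_contig(rng)
        hits = search_contigs([precursor], [contig], config)
        assert [h.score for h in hits] == sorted((h.score for h in hits), reverse=True)
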