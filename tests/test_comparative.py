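"""Progressive alignment, identity, logos and position mapping."""

import numpy as np
import pytest

from conftest import random_protein
from oracles import msa3_optimal_sp, nw_global_score

from antmine.comparative import (
    GAP_RES_SCORE,
    MAX_BITS,
    MultipleAlignment,
    logo,
    map_position,
    percent_identity,
    progressive_align,
    sum_of_pairs,
)
from antmine.seqio import ProteinRecord
from antmine.synthetic_data import make_family, make_precursor, preset


class TestProgressiveAlign:
    def test_identical_pair_aligns_gap_free(self):
        recs = [ProteinRecord("a", "MKWVC"), ProteinRecord("b", "MKWVC")]
        aln = progressive_align(recs)
        assert aln.rows == ["MKWVC", "MKWVC"]
        assert percent_identity(*[r.seq for r in recs]) == 100.0

    def test_single_record_passthrough(self):
        aln = progressive_align([ProteinRecord("a", "MKWVC")])
        assert aln.rows == ["MKWVC"]

    def test_degapping_roundtrip(self, rng):
        recs = [ProteinRecord(f"r{i}", random_protein(rng, int(rng.integers(10, 30)))) for i in range(6)]
        aln = progressive_align(recs)
        by_id = {r.id: r.seq for r in recs}
        for rid, row in zip(aln.ids, aln.rows):
            assert row.replace("-", "") == by_id[rid]

    def test_near_optimal_on_small_triples(self, blosum62, rng):
        # related triples: diverged copies of one short peptide
        from antmine.synthetic_data import diverge_query

        for seed in range(5):
            base = random_protein(np.random.default_rng(seed), 6)
            trip = [
                base,
                diverge_query(base, 0.34, seed + 10),
                diverge_query(base, 0.34, seed + 20),
            ]
            recs = [ProteinRecord(f"s{i}", s) for i, s in enumerate(trip)]
            aln = progressive_align(recs)
            got = sum_of_pairs(aln.rows)
            opt = msa3_optimal_sp(*trip, blosum62, GAP_RES_SCORE)
            assert got >= opt - max(1, 0.05 * abs(opt)), (trip, got, opt)

    def test_planted_family_keeps_cys_columns_conserved(self):
        record, ann = make_precursor(preset("defensin"), seed=81)
        seg = ann.mature_segments()[0]
        mature = ProteinRecord("mat", record.seq[seg.start : seg.end])
        family = make_family(mature, 10, divergence=0.25, seed=5)
        aln = progressive_align(family)
        conserved_c = 0
        for c in range(aln.n_columns):
            col = {row[c] for row in aln.rows}
            if col == {"C"}:
                conserved_c += 1
        assert conserved_c >= 6


class TestPercentIdentity:
    def test_identical_strings(self):
        assert percent_identity("MKWVC", "MKWVC") == 100.0

    def test_half_identity_global(self):
        assert percent_identity("AAAA", "AATT") == 50.0

    def test_global_score_matches_handwritten_dp(self, blosum62, rng):
        from antmine import scoring

        aligner = scoring.make_aligner("global", 11, 1)
        for _ in range(150):
            a = random_protein(rng, int(rng.integers(1, 7)))
            b = random_protein(rng, int(rng.integers(1, 7)))
            assert int(aligner.score(a, b)) == nw_global_score(a, b, blosum62, 11, 1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            percent_identity("", "MK")


class TestLogo:
    def test_fully_conserved_column(self):
        aln = MultipleAlignment(["a", "b", "c"], ["C", "C", "C"])
        lm = logo(aln)
        assert lm.information[0] == pytest.approx(MAX_BITS)
        assert lm.heights.loc[0, "C"] == pytest.approx(MAX_BITS)

    def test_uniform_column_zero_bits(self):
        rows = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        aln = MultipleAlignment([f"r{i}" for i in range(20)], rows)
        lm = logo(aln)
        assert lm.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_state_column(self):
        aln = MultipleAlignment(["a", "b"], ["C", "W"])
        lm = logo(aln)
        assert lm.information[0] == pytest.approx(MAX_BITS - 1.0)

    def test_all_gap_column_flagged_zero(self):
        aln = MultipleAlignment(["a", "b"], ["C-", "C-"])
        lm = logo(aln)
        assert lm.all_gap_columns == [1]
        assert lm.information[1] == 0.0

    def test_bounds_hold_for_every_column(self, rng):
        recs = [ProteinRecord(f"r{i}", random_protein(rng, 15)) for i in range(4)]
        aln = progressive_align(recs)
        lm = logo(aln)
        assert np.all(lm.information >= 0) and np.all(lm.information <= MAX_BITS + 1e-12)

    def test_doubling_alignment_preserves_information(self, rng):
        recs = [ProteinRecord(f"r{i}", random_protein(rng, 12)) for i in range(3)]
        aln = progressive_align(recs)
        doubled = MultipleAlignment(
            aln.ids + [i + "b" for i in aln.ids], aln.rows + aln.rows
        )
        assert np.allclose(logo(doubled).information, logo(aln).information)

    def test_adding_consensus_row_never_decreases_information(self, rng):
        # duplicating an arbitrary row CAN raise column entropy (a minority
        # residue gains weight); adding the per-column consensus cannot
        recs = [ProteinRecord(f"r{i}", random_protein(rng, 15)) for i in range(5)]
        aln = progressive_align(recs)
        lm = logo(aln)
        consensus = "".join(
            max(
                sorted({row[c] for row in aln.rows if row[c] != "-"}) or "-",
                key=lambda ch: sum(row[c] == ch for row in aln.rows),
            )
            for c in range(aln.n_columns)
        )
        bigger = MultipleAlignment(aln.ids + ["cons"], aln.rows + [consensus])
        lm2 = logo(bigger)
        assert np.all(lm2.information >= lm.information - 1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            logo(MultipleAlignment(["a"], ["MK"]))


class TestMapPosition:
    def test_identity_alignment_maps_identically(self):
        aln = MultipleAlignment(["a", "b"], ["MKWVC", "MKWVC"])
        out = map_position(aln, "a", 3)
        assert out["positions"] == {"a": 3, "b": 3}

    def test_gap_shift(self):
        aln = MultipleAlignment(["a", "b"], ["MK--WVC", "MKAAWVC"])
        out = map_position(aln, "a", 2)  # W of record a
        assert out["column"] == 4
        assert out["positions"]["b"] == 4

    def test_position_opposite_gap_reports_gap(self):
        aln = MultipleAlignment(["a", "b"], ["MKAAW", "MK--W"])
        out = map_position(aln, "a", 2)
        assert out["positions"]["b"] == "gap"

    def test_mapping_is_self_inverse(self, rng):
        recs = [ProteinRecord(f"r{i}", random_protein(rng, 20)) for i in range(4)]
        aln = progressive_align(recs)
        for pos in (0, 5, 10):
            out = map_position(aln, aln.ids[0], pos)
            for rid, mapped in out["positions"].items():
                if mapped == "gap":
                    continue
                back = map_position(aln, rid, mapped)
                assert back["column"] == out["column"]
                assert back["positions"][aln.ids[0]] == pos

    def test_conserved_cys_maps_to_cys_in_family(self):
        record, ann = make_precursor(preset("defensin"), seed=82)
        seg = ann.mature_segments()[0]
        mature = record.seq[seg.start : seg.end]
        family = make_family(ProteinRecord("m0", mature), 8, 0.2, seed=6)
        aln = progressive_align(family)
        first_cys = mature.index("C")
        out = map_position(aln, "m0", first_cys)
        for rid, mapped in out["positions"].items():
            seq = next(r.seq for r in family if r.id == rid)
            assert mapped != "gap" and seq[mapped] == "C"

    def test_out_of_range_is_an_error(self):
        aln = MultipleAlignment(["a", "b"], ["MK", "MK"])
        with pytest.raises(IndexError):
            map_position(aln, "a", 5)
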