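"""ORF delineation and spliced protein-to-genome alignment on planted genes."""

import numpy as np
import pytest

from antmine import scoring
from antmine.gene_model import (
    identify_orf,
    lagged_window_max,
    model_to_precursor,
    spliced_align,
)
from antmine.seqio import Contig, RunConfig
from antmine.synthetic_data import SyntheticGeneSpec, make_precursor, plant_gene
from antmine.translated_search import LocalHit, local_align, search_contigs, six_frame_translate


def make_hit(contig, frame, pep_start, pep_end, query_id="q"):
    fp = {f.frame: f for f in six_frame_translate(contig)}[frame]
    ds, de = fp.dna_interval(pep_start, pep_end)
    return LocalHit(
        contig_id=contig.id,
        frame=frame,
        strand=fp.strand,
        query_id=query_id,
        score=50,
        query_start=0,
        query_end=pep_end - pep_start,
        subject_start=ds,
        subject_end=de,
        pep_start=pep_start,
        pep_end=pep_end,
        aligned_query="",
        aligned_subject="",
        percent_identity=100.0,
    )


class TestIdentifyOrf:
    def test_extends_to_atg_and_stop(self):
        contig = Contig("c", "CCATGAAATAACC")
        # hit over the AAA codon, frame +3 (offset 2)
        orf = identify_orf(make_hit(contig, 3, 1, 2), contig)
        assert (orf.start, orf.end) == (2, 11)
        assert orf.protein == "MK"
        assert not orf.partial

    def test_stop_before_atg_flags_partial(self):
        contig = Contig("c", "CCTAAAAATAACC")
        orf = identify_orf(make_hit(contig, 3, 1, 2), contig)
        assert orf.partial
        assert orf.start == 5  # hit start kept as interval start

    def test_contig_edge_without_stop_flags_partial(self):
        contig = Contig("c", "ATGAAAGGG")
        orf = identify_orf(make_hit(contig, 1, 1, 2), contig)
        assert orf.partial

    def test_planted_intronless_gene_recovers_precursor(self, config):
        spec = SyntheticGeneSpec(intron_count=0)
        precursor, ann = make_precursor(spec, 21)
        contig, truth = plant_gene(precursor, spec, 22, annotation=ann)
        hits = search_contigs([precursor], [contig], config)
        orf = identify_orf(hits[0], contig)
        assert orf.protein == precursor.seq
        assert not orf.partial


def reverse_translate_simple(protein):
    cmap = scoring._codon_map()
    by_aa = {}
    for codon, aa in sorted(cmap.items()):
        by_aa.setdefault(aa, codon)
    return "".join(by_aa[a] for a in protein)


class TestSplicedAlign:
    def test_intronless_score_equals_local_alignment(self, rng, config):
        from conftest import random_dna, random_protein

        prot = "M" + random_protein(rng, 40)
        dna = reverse_translate_simple(prot)
        region = random_dna(rng, 150) + dna + "TAA" + random_dna(rng, 150)
        model = spliced_align(prot, region, config, query_id="q", contig_id="c")
        assert model.introns == []
        frame_pep = scoring.translate_dna(region[len(region) % 3 :])
        best_sw = max(
            (local_align(prot, scoring.translate_dna(region[off:])).score for off in range(3)),
        )
        assert model.score == best_sw
        assert model.translation == prot

    @pytest.mark.parametrize("phase", [0, 1, 2])
    def test_planted_two_exon_gene_recovered_exactly(self, phase, config):
        spec = SyntheticGeneSpec(intron_count=1, intron_lengths=(250,), intron_phases=(phase,))
        precursor, ann = make_precursor(spec, 31 + phase)
        contig, truth = plant_gene(precursor, spec, 32 + phase, annotation=ann)
        model = spliced_align(
            precursor.seq, contig.seq, config, contig_id=contig.id, query_id="q"
        )
        assert sorted(model.exons) == sorted(truth.exons)
        assert [i.phase for i in model.introns] == [phase]
        assert model.introns[0].length == 250
        assert (model.introns[0].donor, model.introns[0].acceptor) == ("GT", "AG")
        assert model.translation == precursor.seq

    def test_splice_consistency_invariant(self, config):
        # stored translation always equals translating the concatenated exons
        for seed in range(6):
            spec = SyntheticGeneSpec(intron_count=2)
            precursor, ann = make_precursor(spec, 100 + seed)
            contig, truth = plant_gene(precursor, spec, 200 + seed, annotation=ann)
            model = spliced_align(
                precursor.seq, contig.seq, config, contig_id=contig.id, query_id="q"
            )
            cds = "".join(contig.seq[s:e] for s, e in sorted(model.exons))
            if model.strand == "-":
                cds = scoring.reverse_complement(cds)
            assert scoring.translate_dna(cds) == model.translation

    def test_score_dominance_over_single_exon(self, config):
        spec = SyntheticGeneSpec(intron_count=1)
        precursor, ann = make_precursor(spec, 55)
        contig, _ = plant_gene(precursor, spec, 56, annotation=ann)
        model = spliced_align(
            precursor.seq, contig.seq, config, contig_id=contig.id, query_id="q"
        )
        best_single = max(
            (
                a.score
                for off in range(3)
                for a in [local_align(precursor.seq, scoring.translate_dna(contig.seq[off:]))]
                if a is not None
            ),
            default=0,
        )
        assert model.score >= best_single
        assert len(model.introns) >= 1

    def test_intron_lengths_within_configured_bounds(self, config):
        spec = SyntheticGeneSpec(intron_count=2)
        precursor, ann = make_precursor(spec, 77)
        contig, _ = plant_gene(precursor, spec, 78, annotation=ann)
        model = spliced_align(precursor.seq, contig.seq, config)
        for intron in model.introns:
            assert config.min_intron <= intron.length <= config.max_intron

    def test_long_intron_recovered_exactly(self):
        # insect defensin genes carry kilobase-scale introns (e.g. 4702 bp in
        # the leaf-cutter ant); make sure long introns are handled exactly
        cfg = RunConfig(min_intron=40, max_intron=10000)
        spec = SyntheticGeneSpec(intron_count=1, intron_lengths=(4702,), intron_phases=(1,))
        precursor, ann = make_precursor(spec, 41)
        contig, truth = plant_gene(precursor, spec, 42, annotation=ann)
        model = spliced_align(precursor.seq, contig.seq, cfg, contig_id=contig.id, query_id="q")
        assert [i.length for i in model.introns] == [4702]
        assert sorted(model.exons) == sorted(truth.exons)
        assert model.translation == precursor.seq

    def test_no_positive_model_returns_none(self, config):
        assert spliced_align("WWWWW", "A" * 300, config) is None

    def test_region_with_n_bases_translates_to_x(self, config):
        prot = "MKKLLV"
        dna = reverse_translate_simple(prot)
        region = ("N" * 30) + dna + ("N" * 30)
        model = spliced_align(prot, region, config)
        assert model is not None and model.translation == prot


class TestModelToPrecursor:
    def test_two_exon_model_yields_planted_precursor(self, config):
        spec = SyntheticGeneSpec(intron_count=1)
        precursor, ann = make_precursor(spec, 91)
        contig, truth = plant_gene(precursor, spec, 92, annotation=ann)
        model = spliced_align(
            precursor.seq, contig.seq, config, contig_id=contig.id, query_id=precursor.id
        )
        rec = model_to_precursor(model)
        assert rec.seq == precursor.seq
        assert rec.id == f"{contig.id}_{precursor.id}"
        assert not rec.partial

    def test_empty_model_is_an_error(self):
        with pytest.raises(ValueError):
            model_to_precursor(None)


class TestLaggedWindowMax:
    def test_against_bruteforce(self):
        rng = np.random.default_rng(0)
        from antmine.gene_model import NEG

        for _ in range(100):
            n = int(rng.integers(1, 50))
            v = rng.integers(-40, 40, size=n).astype(np.int64)
            lo = int(rng.integers(0, 10))
            hi = lo + int(rng.integers(0, 18))
            got = lagged_window_max(v, lo, hi)
            for t in range(n):
                window = [v[d] for d in range(max(0, t - hi), t - lo + 1) if 0 <= d < n]
                assert got[t] == (max(window) if window else NEG)
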