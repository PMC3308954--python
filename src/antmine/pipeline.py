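"""End-to-end orchestration: search -> gene model -> segmentation -> features.

A run takes genomic contigs and query precursor proteins (optionally with
reference segment annotations), finds translated-search hits, predicts
spliced gene models in windows around the best hits, derives precursor
proteins, transfers segment annotations, profiles every segment, and writes
one set of outputs per run plus a JSON report and manifest.

Manual curation steps of the original workflow are replaced by deterministic
rules (overlap merging, motif-boundary overrides, partial flags), each of
which is logged, so identical inputs and seed reproduce identical outputs.
The reciprocal-confirmation pass re-searches every predicted precursor
against the genome and flags (never drops) predictions that fail to re-locate
their own locus as the top hit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import peptide_features
from .gene_model import GeneModel, identify_orf, model_to_precursor, spliced_align
from .precursor_annotation import (
    NonHomologousError,
    PrecursorAnnotation,
    ReferenceAnnotation,
    transfer_segments,
)
from .seqio import (
    Contig,
    ProteinRecord,
    RunConfig,
    read_fasta,
    write_fasta,
    write_feature_table,
    write_gff3,
    write_manifest,
)
from .translated_search import LocalHit, search_contigs, write_hits

logger = logging.getLogger(__name__)

OUTCOMES = ("full precursor", "partial", "mature-only", "none")

#: fraction of the query that must be covered for a "full precursor" call
FULL_COVERAGE = 0.9


@dataclass
class Discovery:
    """One predicted locus and everything derived from it."""

    query_id: str
    contig_id: str
    strand: str
    outcome: str
    model: GeneModel | None = None
    precursor: ProteinRecord | None = None
    annotation: PrecursorAnnotation | None = None
    coverage: float = 0.0
    orf_partial: bool = False
    reciprocal_ok: bool | None = None


@dataclass
class RunReport:
    discoveries: list[Discovery] = field(default_factory=list)
    n_hits: int = 0
    n_models: int = 0
    outputs: dict[str, str] = field(default_factory=dict)

    def best_by_contig(self) -> dict[str, Discovery]:
        """Highest-scoring discovery per contig (weak spurious loci lose)."""
        best: dict[str, Discovery] = {}
        for d in self.discoveries:
            score = d.model.score if d.model else -1
            cur = best.get(d.contig_id)
            cur_score = cur.model.score if cur and cur.model else -1
            if cur is None or score > cur_score:
                best[d.contig_id] = d
        return best

    def outcome_counts(self) -> dict[str, int]:
        counts = {o: 0 for o in OUTCOMES}
        for d in self.discoveries:
            counts[d.outcome] += 1
        return counts

    def to_json(self) -> dict:
        return {
            "n_hits": self.n_hits,
            "n_models": self.n_models,
            "outcomes": self.outcome_counts(),
            "discoveries": [
                {
                    "query_id": d.query_id,
                    "contig_id": d.contig_id,
                    "strand": d.strand,
                    "outcome": d.outcome,
                    "coverage": round(d.coverage, 4),
                    "score": d.model.score if d.model else None,
                    "n_introns": len(d.model.introns) if d.model else None,
                    "reciprocal_ok": d.reciprocal_ok,
                }
                for d in self.discoveries
            ],
            "outputs": self.outputs,
        }


def _window(hit: LocalHit, contig: Contig, pad: int) -> tuple[int, int]:
    lo = max(0, hit.subject_start - pad)
    hi = min(len(contig.seq), hit.subject_end + pad)
    return lo, hi


def _classify(
    model: GeneModel | None,
    query: ProteinRecord,
    orf_partial: bool,
    reference: ReferenceAnnotation | None,
) -> tuple[str, float]:
    if model is None:
        return "none", 0.0
    coverage = (model.query_end - model.query_start) / len(query.seq)
    # the single-exon ORF flag only speaks for intronless candidates; a spliced
    # model vouches for itself through completeness and coverage
    orf_ok = not orf_partial or len(model.introns) > 0
    if model.complete and coverage >= FULL_COVERAGE and orf_ok and model.translation[:1] == "M":
        return "full precursor", coverage
    if reference is not None:
        for seg in reference.mature_segments():
            if model.query_start <= seg.start and model.query_end >= seg.end:
                return "mature-only", coverage
    return "partial", coverage


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) > 0


def run_pipeline(
    genome,
    queries,
    references: dict[str, ReferenceAnnotation] | None = None,
    config: RunConfig | None = None,
    outdir=None,
) -> RunReport:
    """Run the full mining workflow.

    ``genome`` and ``queries`` may be paths to FASTA files or in-memory
    record lists; ``references`` maps query ids to their segment annotations.
    When ``outdir`` is given, all stage outputs, the report and the manifest
    are written there.
    """
    config = config or RunConfig()
    references = references or {}
    t0 = time.time()
    genome_path = None
    queries_path = None
    if isinstance(genome, (str, Path)):
        genome_path = str(genome)
        contigs = read_fasta(genome, "dna")
    else:
        contigs = list(genome)
    if isinstance(queries, (str, Path)):
        queries_path = str(queries)
        query_records = read_fasta(queries, "protein")
    else:
        query_records = list(queries)
    by_contig = {c.id: c for c in contigs}
    by_query = {q.id: q for q in query_records}

    hits = search_contigs(query_records, contigs, config)
    logger.info("search: %d merged hits", len(hits))

    report = RunReport(n_hits=len(hits))
    claimed: dict[tuple[str, str, str], list[tuple[int, int]]] = {}
    models: list[GeneModel] = []
    for hit in hits:  # already sorted by descending score
        key = (hit.query_id, hit.contig_id, hit.strand)
        span = (hit.subject_start, hit.subject_end)
        if any(_overlaps(span, s) for s in claimed.get(key, [])):
            continue  # sibling exon hit of an already-modelled locus
        contig = by_contig[hit.contig_id]
        query = by_query[hit.query_id]
        lo, hi = _window(hit, contig, config.max_intron)
        model = spliced_align(
            query.seq,
            contig.seq[lo:hi],
            config,
            offset=lo,
            contig_id=contig.id,
            strand=hit.strand,
            query_id=query.id,
        )
        orf = identify_orf(hit, contig)
        if model is not None:
            claimed.setdefault(key, []).append(model.span)
            models.append(model)
        outcome, coverage = _classify(model, query, orf.partial, references.get(hit.query_id))
        disc = Discovery(
            query_id=hit.query_id,
            contig_id=hit.contig_id,
            strand=hit.strand,
            outcome=outcome,
            model=model,
            coverage=coverage,
            orf_partial=orf.partial,
        )
        if model is not None:
            disc.precursor = model_to_precursor(model)
            ref = references.get(hit.query_id)
            if ref is not None:
                try:
                    disc.annotation = transfer_segments(disc.precursor, ref, config)
                except NonHomologousError as exc:
                    logger.warning("segmentation refused: %s", exc)
        report.discoveries.append(disc)
    report.n_models = len(models)

    # reciprocal confirmation: each precursor must re-locate its own locus
    for disc in report.discoveries:
        if disc.precursor is None or disc.model is None:
            continue
        rehits = search_contigs([disc.precursor], contigs, config, max_hits_per_frame=1)
        if not rehits:
            disc.reciprocal_ok = False
            continue
        # co-optimal top hits (e.g. paralogous loci with identical score) count
        top_score = rehits[0].score
        disc.reciprocal_ok = any(
            h.score == top_score
            and h.contig_id == disc.contig_id
            and _overlaps((h.subject_start, h.subject_end), disc.model.span)
            for h in rehits
        )
        if not disc.reciprocal_ok:
            # expected under paralogy: identical loci share the top score
            logger.info(
                "reciprocal check failed for %s on %s", disc.query_id, disc.contig_id
            )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_hits(hits, outdir / "hits.tsv")
        write_gff3(models, outdir / "models.gff3", {c.id: len(c.seq) for c in contigs})
        precursors = [d.precursor for d in report.discoveries if d.precursor is not None]
        if precursors:
            write_fasta(precursors, outdir / "precursors.faa")
        seg_rows = []
        feat_rows = []
        for disc in report.discoveries:
            if disc.annotation is None:
                continue
            ann = disc.annotation
            for seg in ann.segments:
                seg_rows.append(
                    {
                        "id": ann.record.id,
                        "role": seg.role,
                        "start": seg.start,
                        "end": seg.end,
                        "confidence": seg.confidence,
                        "sequence": ann.record.seq[seg.start : seg.end],
                    }
                )
                feat_rows.append(
                    peptide_features.profile_segment(
                        ann.record.id, seg.role, ann.record.seq[seg.start : seg.end]
                    )
                )
            for k, pep in enumerate(ann.mature_peptides):
                feat_rows.append(
                    peptide_features.profile_segment(
                        f"{ann.record.id}|mature{k}", "mature-peptide", pep.sequence, pep.amidated
                    )
                )
        import pandas as pd

        pd.DataFrame(
            seg_rows, columns=["id", "role", "start", "end", "confidence", "sequence"]
        ).to_csv(outdir / "segments.tsv", sep="\t", index=False)
        write_feature_table(feat_rows, outdir / "features.tsv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report.to_json(), fh, indent=2)
            fh.write("\n")
        write_manifest(
            outdir / "manifest.json",
            {
                "genome": genome_path or f"<{len(contigs)} in-memory contigs>",
                "queries": queries_path or f"<{len(query_records)} in-memory queries>",
            },
            config,
            {"elapsed_seconds": round(time.time() - t0, 3)},
        )
        report.outputs = {
            name: str(outdir / name)
            for name in [
                "hits.tsv",
                "models.gff3",
                "precursors.faa",
                "segments.tsv",
                "features.tsv",
                "report.json",
                "manifest.json",
            ]
        }
    return report
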