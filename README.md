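# antmine

Genome-mining of defense peptides and neuropeptides in insect genome contigs.

Small secreted peptides — antimicrobial defensins, proline-rich abaecins,
venom pilosulins, and neuropeptide hormones such as inotocins (the insect
oxytocin/vasopressin relatives), allatostatins and tachykinins — are hard to
characterize by peptidomics because the source material (ant venom glands,
neural tissue) is minute. Their genes, however, are recoverable directly from
whole-genome shotgun (WGS) contigs by homology. `antmine` re-creates that
classic mining workflow as a tested, reproducible library and command-line
tool for bioinformaticians who have a bag of contigs, a handful of known
precursor proteins from related species, and want annotated peptides out.

## The method

Given DNA contigs and query precursor proteins, the pipeline runs:

1. **Translated search** (the tBLASTn step). Each contig is translated in all
   six frames, with stop codons kept in frame as `*`, and each query is
   aligned to each frame peptide by *exact* Smith–Waterman with BLOSUM62 and
   affine gaps (a gap of length L costs 11 + L). Stops score −1000 so local
   alignments terminate at them. Overlapping hits on one strand are merged by
   a deterministic 50 %-overlap rule.
2. **Gene modelling** (the GeneWise-style step). In a window around each hit,
   a dynamic program aligns query residues to codons while allowing canonical
   GT–AG introns between codons and inside codons (phases 0/1/2); split
   codons across an intron are scored exactly. The objective is
   `Σ BLOSUM62(residue, codon) − gaps − 20 per intron`, maximized locally, so
   an intronless gene scores exactly its Smith–Waterman optimum. The result
   is an exon/intron structure plus the spliced precursor translation.
3. **Precursor segmentation.** Signal peptide, pro-domain(s) and mature
   peptide(s) are transferred from an annotated reference through a global
   alignment; dibasic cleavage sites (KR/RR/KK) and the glycine amidation
   signal (G[RK][RK]) refine mature boundaries within ±3 residues, logged.
4. **Peptide characterization.** Formal net charge (+1 per R/K, −1 per D/E;
   His and termini ignored), positive/negative residue counts, Pro content,
   hydrophobic fraction, cysteine count and spacing, and the CSαβ defensin
   flag (six cysteines with defensin-like spacing, disulfide pairing reported
   by the C1–C4, C2–C5, C3–C6 homology convention).
5. **Comparative analysis.** Progressive multiple alignment (3-mer distances,
   UPGMA guide tree, profile–profile merge), percent identity, conserved-
   position mapping through alignment columns, and sequence-logo information
   content `I_c = log2(20) − H_c` per column.

A synthetic-genome generator plants precursor genes of known architecture
(defensin-like, inotocin-like, or multi-peptide allatostatin-like) with
chosen introns, background GC and query divergence, so every stage can be
validated against ground truth without any downloads.

## Worked example

```bash
# simulate a genome with 3 planted defensin-like genes (one intron each)
antmine simulate --architecture defensin --n-genes 3 --introns 1 --seed 5 \
    --out genome.fna --truth truth.json --queries-out query.faa \
    --ref-ann-out query_segments.tsv

# run the full pipeline (segmentation needs the query's annotation)
antmine run --genome genome.fna --queries query.faa \
    --ref-ann query_segments.tsv --outdir out/
```

which prints the outcome tally:

```json
{
  "full precursor": 3,
  "partial": 0,
  "mature-only": 0,
  "none": 0
}
```

All three planted genes come back as complete precursors. `out/` then holds
`hits.tsv` (translated-search hits), `models.gff3` (exon/intron structures;
intron lengths are recoverable from the gaps between CDS rows),
`precursors.faa`, `segments.tsv`, `features.tsv` and `report.json`. For a
defensin-like precursor the feature table row of the mature domain reads,
e.g., length 43, net charge +6, 8 positive and 2 negative residues, 6
cysteines, `csab True` — the charge/cysteine signature of an insect defensin,
balanced by a pro-domain row at net charge −4.

The same stages are available as library calls (`antmine.search_contigs`,
`antmine.spliced_align`, `antmine.transfer_segments`,
`antmine.profile_segment`, `antmine.progressive_align`, ...) and as
separate CLI subcommands (`search`, `annotate`, `segment`, `features`,
`align`, `simulate`) for stage-by-stage runs.

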