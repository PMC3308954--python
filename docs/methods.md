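# Methods

This note records the models, parameter choices and numerical conventions
behind `antmine`, and what the synthetic benchmarks do and do not establish.

## Scoring model

All protein scoring uses BLOSUM62. Affine gaps follow the NCBI convention: a
gap of length L costs `gap_open + L * gap_extend`, default 11/1, so a single
gapped residue costs 12. Stop codons translate to `*` and score −1000 against
every residue (including `*`), which makes local alignments terminate at
stops without frames being split — the peptide-to-DNA coordinate map of each
frame stays total. Codons containing N translate to X even when the ambiguity
would not change the residue; X scores as in BLOSUM62.

Pairwise local (Smith–Waterman) and global (Needleman–Wunsch) alignments are
computed by Biopython's `PairwiseAligner` configured to this convention; the
test suite checks it for exact score agreement against an independently
written plain-Python dynamic program, and that oracle in turn against
exhaustive alignment-path enumeration on tiny instances. Local co-optimal
alignments are tie-broken deterministically (lowest subject start, then
lowest query start, then shortest alignment), examining at most 64
co-optimal alignments — enough for every case the suite generates.

## Translated search

Six frames per contig (three forward, three on the reverse complement).
Within one frame, multiple hits are extracted by iteratively taking the best
local alignment and masking its subject span with `*`; the default
`min_hit_score` is 40 matrix units (roughly a 9–10 residue identical match),
exposed in `RunConfig` because no universal cutoff exists — raise it for
short or low-complexity queries. Hits of the same query/contig/strand whose
DNA intervals overlap by at least 50 % of the shorter are collapsed keeping
the higher score; this deterministic rule replaces the manual curation a
human would do on redundant automated hits.

## Spliced gene models

The spliced aligner is a dynamic program over (query residue, DNA position)
with codon-match states, affine protein gaps, and intron states at all three
codon phases. Introns are canonical GT–AG only, with a flat open penalty
(default 20 matrix units) and zero length cost inside configurable bounds
(default 40–20 000 bp). Split codons across phase-1/2 introns are scored
exactly: donor candidates are grouped by their partial-codon bases, a sliding
window maximum (bounded by the intron length limits) is kept per group, and
the full codon is scored when the acceptor is reached. Scores are integers
throughout, so the traceback re-derives every decision by exact equality
instead of storing backpointers.

Design choices worth knowing:

* The DP is local in both query and DNA (zero floor), so an intronless gene
  scores exactly its translated Smith–Waterman optimum and weak flanking
  homology is not forced into the model.
* Two introns with no codon between them are not representable; under a flat
  intron penalty such a parse is never better than a single intron, so this
  costs nothing in practice.
* A flat penalty of 20 means a terminal exon contributing fewer than 20
  matrix points (roughly 4 residues) cannot pay for its intron and will be
  dropped in favour of a slightly shorter single-exon parse. This is a real
  property of the objective, not a bug; the synthetic generator therefore
  never creates exons shorter than 10 codons (see below), and real
  spliceosomal exons are effectively never that short either.
* Ties are resolved toward fewer introns and leftmost boundaries.
* The DP window around a hit is the hit padded by `max_intron` on both
  sides, capped at the contig.

ORF delineation around a hit extends 5′ codon-by-codon to the nearest
in-frame ATG (stopping, and flagging the candidate partial, at an in-frame
stop or the contig edge) and 3′ to the first in-frame stop. The nearest-ATG
rule is deliberate: a longest-ORF rule would routinely prepend background
residues whenever random upstream sequence happens to contain an in-frame
ATG before a stop.

## Precursor segmentation

Boundaries are transferred from an annotated homolog through a global
alignment — the homology-transfer method itself, not a signal-peptide
predictor. A transfer is refused below 20 % alignment identity (configurable)
as non-homology. A boundary landing opposite a target gap moves to the next
real target position and is flagged `gap-adjusted`. A hydrophobic-core sanity
check on the transferred signal peptide (at least 6 residues with
Kyte–Doolittle hydropathy > 1.5) is logged as a warning, never enforced.
Mature-peptide boundaries are refined by motif evidence within ±3 residues:
dibasic prohormone-convertase sites (KR, RR, KK) at the N-boundary and
amidation signals (G followed by two basic residues) or dibasic sites at the
C-boundary; every motif-driven move is logged with before/after positions.
When motif and transfer disagree by more than the slack, the transferred
boundary wins and both are visible in the log. A peptide is flagged amidated
when a glycine (donating the C-terminal amide) immediately follows it.

## Peptide features

Net charge is the formal integer count (+1 per Arg/Lys, −1 per Asp/Glu) with
histidine and the termini ignored. This scheme is stated prominently because
pH-dependent (pKa-based) schemes give different values; the formal scheme is
the one under which an insect defensin mature domain comes out at +3…+6 with
an anionic pro-domain near −4. The hydrophobic residue class is AVFILMWYC —
a repo-defined choice, as the class is not standardized. The CSαβ flag is an
operational classification: exactly six cysteines with spacings in
C-x(4–16)-C-x(2–5)-C-x(8–12)-C-x(4–8)-C-x(1)-C; the ranges are repo-defined
(fitted to insect defensin mature domains) and configurable. Disulfide
pairing is reported by the family convention (C1–C4, C2–C5, C3–C6), never
computed from structure.

## Comparative analysis

The progressive aligner uses 3-mer count vectors and cosine distance, a
UPGMA guide tree (scipy average linkage), and global profile–profile merges
with mean-pairwise column scores; gap columns score −4 per residue-gap pair
(linear per column), which keeps the merge traceback exactly reproducible.
No attempt is made to replicate any particular MSA tool's output bit-for-bit;
alignment quality is judged by sum-of-pairs proximity to a small-instance
exhaustive optimum (within 5 % on seeded triples in the suite) and by
conserved columns staying conserved. Logo information is
`I_c = log2(20) − H_c` with frequencies normalized over observed residues
(gaps excluded from the denominator, standard logo practice) and no
small-sample correction; all-gap columns report 0 bits and are flagged.

## Synthetic data generator

The generator emulates the three precursor architectures the mining workflow
targets, at the sizes typical of the real peptides:

* **defensin**: 19-residue signal peptide (hydrophobic core), 35-residue
  pro-domain built to net charge −4 and ending in a KR cleavage site, and a
  43-residue mature domain built to net charge +6 (8 positive, 2 negative
  residues) with six cysteines at CSαβ-compatible spacing — a 97/43
  precursor/mature layout.
* **inotocin**: signal + nonapeptide with cysteines at positions 1 and 6 +
  the canonical GRK amidation/cleavage signal + a 119-residue
  neurophysin-like carrier domain with 12 cysteines (150 residues total).
* **multipeptide**: seven short amidated peptides (8, 8, 8, 7, 30, 9, 28
  residues) released from one precursor by dibasic sites,
  allatostatin-style.

Genes are reverse-translated with uniform codon choice (no codon-usage
model), interrupted by GT–AG introns of 80–400 bp by default (any length can
be requested) at random phases, terminated by a random stop codon, and
embedded in i.i.d. background DNA of tunable GC (default 0.42) with 800 bp
flanks. Intron sites keep every exon at least 10 codons long — real
spliceosomal exon recognition imposes minimum exon sizes, and (see above) a
sub-20-point terminal exon is unpayable under the flat intron penalty, so
shorter exons would benchmark an input class that neither the method nor
real genes produce. Query divergence substitutes an exact count of
positions, preferring BLOSUM62-positive replacements with probability 0.7,
and introduces no indels; the family generator can hold cysteine positions
fixed.

What the generator does **not** emulate: codon-usage bias, repeats and
low-complexity tracts, sequencing error, paralogous subfamilies,
non-canonical splice sites, and UTR/promoter context. Passing the planted-
gene benchmarks therefore demonstrates correctness of the algorithms under
clean homology, not discovery performance on real WGS data — on real data
the binding constraints are query relatedness and contig fragmentation,
which the divergence and truncation tests probe only in idealized form.

## Benchmarks and problem sizes

The acceptance suite and `scripts/acceptance.py` use: 100 planted defensin
genes (34/33/33 with 0/1/2 introns) at full query identity for exact
exon-boundary and precursor recovery; 51 single-intron genes searched with a
30 %-diverged query for mature-domain residue accuracy; 10 000 random pairs
of length ≤ 8 for exact-score agreement with the independent Smith–Waterman
(plus 500 tiny pairs against full enumeration of co-optimal global
alignments for percent identity); and a 10-member defensin family at 25 %
divergence for the conserved-cysteine logo check. These sizes make the whole
suite a few minutes of desk-scale compute while keeping the binomial margins
meaningful.

Two further checks reproduce published per-species values (mature/pro-domain
charges, lengths and cysteine counts of the ant defensins, and the 4702-bp
leaf-cutter-ant defensin intron). They require the published supplementary
precursor sequences and one GenBank WGS contig, which are not redistributed
with this repository: place `published_defensin_precursors.faa` (ids `AcDEF`, `CfDEF1`,
`CfDEF2`, `HsDEF1`, optionally `HsDEF1a`, `HsDEF2`),
`published_defensin_segments.tsv` (columns `id role start end`, 0-based half-open) and
`ADTU01021145.1.fna` under `tests/data/published/` to enable them; until
then those two tests fail with instructions. The same machinery is exercised
synthetically, including exact recovery of a planted 4702-bp intron.

## Reciprocal confirmation

Every predicted precursor is re-searched against the genome and must
re-locate its own locus among the top-scoring hits; failures are flagged in
the report, never dropped. In genomes containing several identical planted
paralogs the top score legitimately ties across loci, and for multi-exon
genes a protein re-search scores each exon separately, so this flag is
informative on single-locus runs and conservative elsewhere.

## Degenerate inputs and edge behaviour

Contigs shorter than one codon translate to six empty frames with a warning.
Queries containing residues absent from the matrix are a hard error naming
the residue. A search window with no positive-scoring spliced model returns
"no prediction" rather than a forced model. Empty model lists serialize to a
header-only GFF3; feature tables serialize empty as header-only TSV. All
internal coordinates are 0-based half-open on the forward strand; conversion
to 1-based inclusive happens only in the GFF3 writer.
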