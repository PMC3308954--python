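"""Readers and writers for the formats the pipeline touches, plus run config.

Internal coordinates are 0-based half-open on the forward strand everywhere in
the package; conversion to 1-based inclusive happens only when GFF3 is written.
Lowercase letters and IUPAC ambiguity codes are normalized once, on load.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

#: residues/bases the loader maps to N in DNA mode (IUPAC ambiguity codes)
DNA_AMBIGUOUS = set("RYSWKMBDHVU")


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over {A,C,G,T,N}; the search substrate."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"contig {self.id}: illegal bases {sorted(bad)}")

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20 standard residues plus X and *)."""

    id: str
    seq: str
    description: str = ""
    partial: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.seq:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.seq) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id}: illegal residues {sorted(bad)}")

    def __len__(self):
        return len(self.seq)


@dataclass
class RunConfig:
    """Tunable parameters of a mining run.

    Alignment defaults follow protein BLAST (BLOSUM62, gap open 11, extend 1);
    the intron model is canonical GT-AG with a flat open penalty and length
    bounds, and the cleavage/amidation motif set covers the dibasic sites
    recognized by prohormone convertases plus the glycine amidation signals.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_hit_score: int = 40
    intron_donor: str = "GT"
    intron_acceptor: str = "AG"
    min_intron: int = 40
    max_intron: int = 20000
    intron_open_penalty: int = 20
    cleavage_motifs: tuple[str, ...] = ("KR", "RR", "KK")
    amidation_motifs: tuple[str, ...] = ("GRK", "GKR", "GRR", "GKK")
    identity_floor: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if min(self.gap_open, self.gap_extend, self.intron_open_penalty) < 0:
            raise ValueError("penalties must be >= 0")
        if not self.min_intron < self.max_intron:
            raise ValueError("min intron must be < max intron")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("cleavage_motifs", "amidation_motifs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = self.to_dict()
        for key in ("cleavage_motifs", "amidation_motifs"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _normalize_dna(raw: str, rec_id: str) -> str:
    seq = raw.upper()
    mapped = 0
    out = []
    for ch in seq:
        if ch in DNA_ALPHABET:
            out.append(ch)
        elif ch in DNA_AMBIGUOUS:
            out.append("N")
            mapped += 1
        else:
            raise ValueError(f"record {rec_id}: illegal DNA character {ch!r}")
    if mapped:
        logger.warning("record %s: mapped %d ambiguity code(s) to N", rec_id, mapped)
    return "".join(out)


def read_fasta(path, alphabet: str) -> list:
    """Read a FASTA file as Contig (alphabet='dna') or ProteinRecord ('protein').

    Record order is preserved.  Duplicate ids, empty files and (in protein
    mode) residues outside the 20+X+* alphabet are hard errors; in DNA mode
    IUPAC ambiguity codes are mapped to N with a logged warning.
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        raw = str(rec.seq)
        if alphabet == "dna":
            records.append(Contig(id=rec.id, seq=_normalize_dna(raw, rec.id), description=desc))
        else:
            records.append(ProteinRecord(id=rec.id, seq=raw.upper(), description=desc))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def write_gff3(models: Sequence, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Serialize GeneModel objects as GFF3 gene/mRNA/CDS rows.

    Internal half-open 0-based intervals become 1-based inclusive here and
    nowhere else.  Intron lengths are recoverable from the gaps between CDS
    rows of one mRNA.
    """
    lines = ["##gff-version 3"]
    for k, model in enumerate(models):
        exons = sorted(model.exons)
        start, end = exons[0][0], exons[-1][1]
        if start < 0 or (
            contig_lengths is not None and end > contig_lengths.get(model.contig_id, end)
        ):
            raise ValueError(
                f"model {model.query_id} on {model.contig_id}: coordinates outside contig"
            )
        gid = f"gene{k:05d}"
        attrs = f"ID={gid};Name={model.query_id}"
        strand = model.strand
        lines.append(
            "\t".join(
                [model.contig_id, "antmine", "gene", str(start + 1), str(end), ".", strand, ".", attrs]
            )
        )
        mid = f"{gid}.t1"
        lines.append(
            "\t".join(
                [
                    model.contig_id,
                    "antmine",
                    "mRNA",
                    str(start + 1),
                    str(end),
                    f"{model.score:g}",
                    strand,
                    ".",
                    f"ID={mid};Parent={gid}",
                ]
            )
        )
        for es, ee in exons:
            lines.append(
                "\t".join(
                    [
                        model.contig_id,
                        "antmine",
                        "CDS",
                        str(es + 1),
                        str(ee),
                        ".",
                        strand,
                        ".",
                        f"Parent={mid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


FEATURE_COLUMNS = [
    "id",
    "role",
    "length",
    "net_charge",
    "positive",
    "negative",
    "cys_count",
    "pro_count",
    "pro_fraction",
    "hydrophobic_fraction",
    "csab",
    "amidated",
]


def write_feature_table(rows: Iterable, path) -> None:
    """Write PeptideFeatures rows as a TSV with a stable column order."""
    data = []
    for r in rows:
        data.append(
            {
                "id": r.peptide_id,
                "role": r.role,
                "length": r.length,
                "net_charge": r.net_charge,
                "positive": r.positive,
                "negative": r.negative,
                "cys_count": r.cys_count,
                "pro_count": r.pro_count,
                "pro_fraction": round(r.pro_fraction, 6),
                "hydrophobic_fraction": round(r.hydrophobic_fraction, 6),
                "csab": bool(r.csab),
                "amidated": bool(r.amidated),
            }
        )
    df = pd.DataFrame(data, columns=FEATURE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "role": str})


def read_reference_annotations(path) -> dict[str, list[tuple[str, int, int]]]:
    """Sidecar TSV of reference segments: record id, role, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=["id", "role", "start", "end"], header=0)
    out: dict[str, list[tuple[str, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.id), []).append((str(row.role), int(row.start), int(row.end)))
    return out


def write_reference_annotations(segments: dict[str, list[tuple[str, int, int]]], path) -> None:
    rows = [
        {"id": rid, "role": role, "start": s, "end": e}
        for rid, segs in segments.items()
        for role, s, e in segs
    ]
    pd.DataFrame(rows, columns=["id", "role", "start", "end"]).to_csv(path, sep="\t", index=False)


def write_manifest(path, inputs: dict, config: RunConfig, extra: dict | None = None) -> None:
    """JSON run manifest: inputs, configuration, seed and free-form run facts."""
    manifest = {"inputs": inputs, "config": config.to_dict(), "seed": config.seed}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
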