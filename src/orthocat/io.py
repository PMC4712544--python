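"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython SeqIO; annotation tables as TSV via pandas; catalog
annotation as GFF3 (1-based inclusive coordinates); per-base coverage as
bedGraph; read alignments as SAM via pysam (see :mod:`orthocat.boundary`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CatalogEntry,
    OrthologTable,
    ReferenceTranscript,
    TranscriptContig,
    sanitize_sequence,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_contigs",
    "read_fasta",
    "read_reference",
    "read_ortholog_table",
    "write_contigs",
    "write_catalog",
    "read_bedgraph",
    "to_gff3_coords",
    "from_gff3_coords",
]


def to_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def from_gff3_coords(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open (inverse of to_gff3_coords)."""
    return start - 1, end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain id -> sequence dict; duplicate IDs are an error."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate ID {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_contigs(path: str | Path) -> list[TranscriptContig]:
    """Read assembled transcript contigs from FASTA.

    Lowercase is normalized to uppercase; symbols outside {A,C,G,T,N} are
    collapsed to N (counted, warned). Assembly-graph provenance is parsed
    from Trinity-style headers (``>TRINITY_DN5_c0_g1_i1`` -> graph id
    ``TRINITY_DN5_c0_g1``). Duplicate IDs or an empty file are hard errors.
    """
    contigs: list[TranscriptContig] = []
    seen: set[str] = set()
    replaced_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate contig ID {rec.id!r}")
        seen.add(rec.id)
        seq, replaced = sanitize_sequence(str(rec.seq))
        replaced_total += replaced
        graph_id = rec.id.rsplit("_i", 1)[0] if "_i" in rec.id else None
        contigs.append(TranscriptContig(id=rec.id, sequence=seq, graph_id=graph_id))
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    if replaced_total:
        log.warning("%s: %d non-ACGTN symbols collapsed to N", path, replaced_total)
    return contigs


REFERENCE_COLUMNS = ["accession", "gene_symbol", "cds_start", "cds_end", "selenoprotein", "species"]


def read_reference(mrna_fasta: str | Path, annot_table: str | Path) -> list[ReferenceTranscript]:
    """Load the reference transcriptome: mRNA FASTA plus annotation TSV.

    TSV columns: accession, gene_symbol, cds_start, cds_end (0-based
    half-open on the mRNA), selenoprotein (0/1), species. Rows violating the
    CDS invariants are skipped with a logged count; an accession missing
    from the FASTA is a hard error.
    """
    seqs = read_fasta(mrna_fasta)
    table = pd.read_csv(annot_table, sep="\t", dtype={"accession": str, "gene_symbol": str})
    refs: list[ReferenceTranscript] = []
    skipped = 0
    for row in table.itertuples(index=False):
        if row.accession not in seqs:
            raise ValueError(f"{annot_table}: accession {row.accession!r} not in {mrna_fasta}")
        try:
            refs.append(
                ReferenceTranscript(
                    accession=row.accession,
                    gene_symbol=row.gene_symbol,
                    mrna=seqs[row.accession],
                    cds_start=int(row.cds_start),
                    cds_end=int(row.cds_end),
                    selenoprotein=bool(row.selenoprotein),
                    species=str(getattr(row, "species", "reference")),
                )
            )
        except ValueError as exc:
            skipped += 1
            log.warning("skipping reference row: %s", exc)
    if skipped:
        log.warning("%s: skipped %d invalid reference rows", annot_table, skipped)
    return refs


def read_ortholog_table(table_path: str | Path, cds_fasta: str | Path) -> OrthologTable:
    """Load the multi-species ortholog table (gene_symbol, species, accession)
    with its companion CDS FASTA."""
    seqs = read_fasta(cds_fasta)
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    out = OrthologTable()
    for row in table.itertuples(index=False):
        if row.accession not in seqs:
            raise ValueError(f"{table_path}: accession {row.accession!r} not in {cds_fasta}")
        out.add(row.gene_symbol, row.species, row.accession, seqs[row.accession])
    out.validate()
    return out


def write_contigs(contigs, path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """bedGraph -> {chrom: [(start, end, value), ...]} (0-based half-open)."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            out.setdefault(chrom, []).append((int(start), int(end), float(value)))
    return out


@dataclass
class CatalogFiles:
    transcripts_fasta: Path
    cds_fasta: Path
    gff3: Path
    summary_tsv: Path


def write_catalog(entries: list[CatalogEntry], out_dir: str | Path) -> CatalogFiles:
    """Emit the final catalog: transcript FASTA, CDS FASTA, GFF3, TSV summary.

    GFF3 carries CDS, clip, N-gap and vector-flag features per transcript,
    1-based inclusive. An empty entry set yields valid empty files plus a
    warning.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = CatalogFiles(
        transcripts_fasta=out / "transcripts.fa",
        cds_fasta=out / "cds.fa",
        gff3=out / "catalog.gff3",
        summary_tsv=out / "catalog.tsv",
    )
    if not entries:
        log.warning("writing empty catalog to %s", out)

    entries = sorted(entries, key=lambda e: e.entry_id)
    SeqIO.write(
        [SeqRecord(Seq(e.sequence), id=e.entry_id,
                   description=f"gene={e.gene_symbol} ortholog={e.reference_accession}")
         for e in entries],
        str(files.transcripts_fasta), "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(e.cds_sequence), id=e.entry_id, description=f"gene={e.gene_symbol}")
         for e in entries if e.cds_end > e.cds_start],
        str(files.cds_fasta), "fasta",
    )

    with open(files.gff3, "w") as gff:
        gff.write("##gff-version 3\n")
        for e in entries:
            gff.write(f"##sequence-region {e.entry_id} 1 {len(e.sequence)}\n")
            s1, e1 = to_gff3_coords(0, len(e.sequence))
            attrs = f"ID={e.entry_id};gene={e.gene_symbol};ortholog={e.reference_accession}"
            gff.write(_gff_line(e.entry_id, "mRNA", s1, e1, ".", attrs))
            if e.cds_end > e.cds_start:
                s1, e1 = to_gff3_coords(e.cds_start, e.cds_end)
                gff.write(_gff_line(
                    e.entry_id, "CDS", s1, e1, ".",
                    f"ID={e.entry_id}.cds;Parent={e.entry_id};status={e.cds_status.value};"
                    f"source_route={e.cds_source.value}",
                ))
            pos = 0
            if e.scaffold_plan is not None:
                for part in e.scaffold_plan.parts:
                    if part.kind == "gap":
                        s1, e1 = to_gff3_coords(pos, pos + part.length)
                        gff.write(_gff_line(
                            e.entry_id, "gap", s1, e1, ".",
                            f"Parent={e.entry_id};template_span={part.template_start}-{part.template_end}",
                        ))
                    pos += part.length
            for clip in e.clip_records:
                gff.write(_gff_line(
                    e.entry_id, "clip", 0, 0, ".",
                    f"Parent={e.entry_id};end={clip.end};removed_length={clip.removed_length};"
                    f"reason={clip.reason}",
                ).replace("\t0\t0\t", "\t.\t.\t"))
            for flag in e.vector_flags:
                s1, e1 = to_gff3_coords(flag.start, flag.end)
                gff.write(_gff_line(
                    e.entry_id, "vector_match", s1, e1, str(flag.score),
                    f"Parent={e.entry_id};category={flag.category};topology={flag.topology};"
                    f"vector={flag.vector_id}",
                ))

    rows = []
    for e in entries:
        rows.append({
            "entry_id": e.entry_id,
            "gene_symbol": e.gene_symbol,
            "reference_accession": e.reference_accession,
            "length": len(e.sequence),
            "cds_start": e.cds_start,
            "cds_end": e.cds_end,
            "cds_status": e.cds_status.value,
            "cds_source": e.cds_source.value,
            "completeness_fraction": round(e.completeness_fraction, 4),
            "assignment_class": e.assignment.klass.value if e.assignment else ".",
            "scaffolded": int(e.scaffold_plan is not None),
            "n_clips": len(e.clip_records),
            "clipped_bases": sum(c.removed_length for c in e.clip_records),
            "clip_detail": ";".join(
                f"{c.end}:{c.removed_length}:{c.reason}" for c in e.clip_records) or ".",
            "vector_flags": len(e.vector_flags),
        })
    pd.DataFrame(
        rows,
        columns=[
            "entry_id", "gene_symbol", "reference_accession", "length", "cds_start",
            "cds_end", "cds_status", "cds_source", "completeness_fraction",
            "assignment_class", "scaffolded", "n_clips", "clipped_bases",
            "clip_detail", "vector_flags",
        ],
    ).to_csv(files.summary_tsv, sep="\t", index=False)
    return files


def _gff_line(seqid: str, feature: str, start: int, end: int, score: str, attrs: str) -> str:
    return f"{seqid}\torthocat\t{feature}\t{start}\t{end}\t{score}\t+\t.\t{attrs}\n"
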