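"""Descriptive assembly and catalog statistics."""

from __future__ import annotations

import json
import statistics
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .model import CatalogEntry

__all__ = ["n50", "CatalogSummary", "summarize"]


def n50(lengths: list[int]) -> int:
    """Largest length L such that sequences of length >= L hold at least
    half of the total bases. Always an element of the input."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    raise AssertionError("unreachable")


@dataclass
class CatalogSummary:
    contig_count: int
    transcript_count: int
    gene_count: int
    n50: int
    n50_ungapped: int  # N runs excluded from scaffold lengths
    length_min: int
    length_median: float
    length_max: int
    cds_status_counts: dict[str, int] = field(default_factory=dict)
    cds_source_counts: dict[str, int] = field(default_factory=dict)
    scaffolded_gene_count: int = 0
    median_fold_increase: float = 0.0
    clipped_transcript_count: int = 0
    total_clipped_bases: int = 0
    vector_flagged_count: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    def log_block(self) -> str:
        lines = [
            f"contigs in          : {self.contig_count}",
            f"catalog transcripts : {self.transcript_count}",
            f"genes               : {self.gene_count}",
            f"N50 / N50 ungapped  : {self.n50} / {self.n50_ungapped}",
            f"length min/med/max  : {self.length_min}/{self.length_median}/{self.length_max}",
            f"CDS status          : " + ", ".join(
                f"{k}={v}" for k, v in sorted(self.cds_status_counts.items())),
            f"scaffolded genes    : {self.scaffolded_gene_count}"
            + (f" (median fold increase {self.median_fold_increase:.2f})"
               if self.scaffolded_gene_count else ""),
            f"clipped transcripts : {self.clipped_transcript_count} "
            f"({self.total_clipped_bases} bases removed)",
            f"vector-flagged      : {self.vector_flagged_count}",
        ]
        return "\n".join(lines)


def summarize(
    entries: list[CatalogEntry],
    contig_count: int,
    core_lengths: dict[str, int] | None = None,
) -> CatalogSummary:
    """Aggregate the catalog into a summary.

    ``core_lengths`` maps scaffolded entry ids to the length of the core
    contig before extension; per scaffolded gene the fold information
    increase is final length / core length and the median is reported.
    """
    if not entries:
        return CatalogSummary(
            contig_count=contig_count, transcript_count=0, gene_count=0,
            n50=0, n50_ungapped=0, length_min=0, length_median=0.0, length_max=0,
        )
    lengths = [len(e.sequence) for e in entries]
    ungapped = [len(e.sequence) - e.sequence.count("N") for e in entries]
    status_counts: dict[str, int] = {}
    source_counts: dict[str, int] = {}
    for e in entries:
        status_counts[e.cds_status.value] = status_counts.get(e.cds_status.value, 0) + 1
        source_counts[e.cds_source.value] = source_counts.get(e.cds_source.value, 0) + 1
    folds = []
    scaffolded_genes = set()
    for e in entries:
        if e.scaffold_plan is not None:
            scaffolded_genes.add(e.gene_symbol)
            if core_lengths and e.entry_id in core_lengths and core_lengths[e.entry_id] > 0:
                folds.append(len(e.sequence) / core_lengths[e.entry_id])
    clipped = [e for e in entries if e.clip_records]
    return CatalogSummary(
        contig_count=contig_count,
        transcript_count=len(entries),
        gene_count=len({e.gene_symbol for e in entries}),
        n50=n50(lengths),
        n50_ungapped=n50(ungapped),
        length_min=min(lengths),
        length_median=float(statistics.median(lengths)),
        length_max=max(lengths),
        cds_status_counts=status_counts,
        cds_source_counts=source_counts,
        scaffolded_gene_count=len(scaffolded_genes),
        median_fold_increase=float(statistics.median(folds)) if folds else 0.0,
        clipped_transcript_count=len(clipped),
        total_clipped_bases=sum(c.removed_length for e in clipped for c in e.clip_records),
        vector_flagged_count=sum(1 for e in entries if e.vector_flags),
    )
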