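"""Gene-symbol assignment by reciprocal best nucleotide hits.

The search runs at the nucleotide level against reference CDSs — the most
sensitive way to separate paralogs whose proteins are identical (the
calmodulin genes CALM1/2/3 encode one protein but differ in synonymous
sites). Best bidirectional hits (BBH) pair each contig with the reference
CDS for which each is the other's top hit; leftover contigs with a single
best hit (SBH) to a still-unassigned reference are rescued afterwards.
Assigned contigs are then oriented to their ortholog, and residual hits to
other genes expose fusion ("misassembled") contigs, which are copied per
gene for independent downstream processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .align import DEFAULT_SCHEME, AlignmentHit, KmerIndex, ScoringScheme, local_hits
from .model import Assignment, AssignmentClass, ReferenceTranscript, TranscriptContig

log = logging.getLogger(__name__)

__all__ = [
    "HitMatrix",
    "GeneRegion",
    "compute_hit_matrix",
    "best_per_query",
    "assign_bbh",
    "assign_sbh",
    "orient",
    "detect_multi_gene",
    "split_multi_gene",
]


class HitMatrix:
    """Best hit per (contig, reference) pair, in both search directions.

    ``forward`` holds contig-vs-CDS hits (query = contig), ``reverse``
    CDS-vs-full-contig hits (query = CDS). At most one hit is stored per
    ordered pair and direction.
    """

    def __init__(self) -> None:
        self.forward: dict[tuple[str, str], AlignmentHit] = {}
        self.reverse: dict[tuple[str, str], AlignmentHit] = {}

    def contig_hits(self, contig_id: str) -> list[tuple[str, AlignmentHit]]:
        return [(acc, h) for (cid, acc), h in self.forward.items() if cid == contig_id]

    def reference_hits(self, accession: str) -> list[tuple[str, AlignmentHit]]:
        return [(cid, h) for (cid, acc), h in self.reverse.items() if acc == accession]


def compute_hit_matrix(
    contigs: list[TranscriptContig],
    references: list[ReferenceTranscript],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_score: int = 40,
) -> HitMatrix:
    """All-against-all best local hits, contig->CDS and CDS->contig.

    Contigs are searched against reference CDS sequences only (not full
    mRNAs); the reverse direction searches each CDS against the full contig.
    ``min_score`` suppresses spurious short hits.
    """
    matrix = HitMatrix()
    cds_index = {r.accession: KmerIndex(r.cds, scheme.word_size) for r in references}
    contig_index = {c.id: KmerIndex(c.sequence, scheme.word_size) for c in contigs}
    for contig in contigs:
        for ref in references:
            fwd = local_hits(
                contig.sequence, ref.cds, scheme, query_id=contig.id,
                subject_id=ref.accession, min_score=min_score,
                subject_index=cds_index[ref.accession],
            )
            if fwd:
                matrix.forward[(contig.id, ref.accession)] = fwd[0]
            rev = local_hits(
                ref.cds, contig.sequence, scheme, query_id=ref.accession,
                subject_id=contig.id, min_score=min_score,
                subject_index=contig_index[contig.id],
            )
            if rev:
                matrix.reverse[(contig.id, ref.accession)] = rev[0]
    return matrix


def best_per_query(hits: list[tuple[str, AlignmentHit]]) -> tuple[str, AlignmentHit] | None:
    """Top subject by score; ties broken by longer aligned length, then
    lexicographic subject id."""
    if not hits:
        return None
    return min(hits, key=lambda t: (-t[1].score, -t[1].aligned_length, t[0]))


def assign_bbh(
    contigs: list[TranscriptContig],
    references: list[ReferenceTranscript],
    matrix: HitMatrix,
) -> list[Assignment]:
    """Best-bidirectional-hit assignment.

    (contig, reference) is assigned iff the reference is the contig's top
    forward hit and the contig is the reference's top reverse hit.
    Reciprocity makes the result a partial bijection by construction.
    """
    by_acc = {r.accession: r for r in references}
    best_fwd = {
        c.id: best_per_query(matrix.contig_hits(c.id)) for c in contigs
    }
    best_rev = {
        r.accession: best_per_query(matrix.reference_hits(r.accession)) for r in references
    }
    assignments: list[Assignment] = []
    for contig in sorted(contigs, key=lambda c: c.id):
        fwd = best_fwd[contig.id]
        if fwd is None:
            continue
        acc, hit = fwd
        rev = best_rev[acc]
        if rev is None or rev[0] != contig.id:
            continue
        assignments.append(
            Assignment(
                contig_id=contig.id,
                reference_accession=acc,
                gene_symbol=by_acc[acc].gene_symbol,
                klass=AssignmentClass.BBH,
                score=hit.score,
                strand=hit.strand,
            )
        )
    return assignments


def assign_sbh(
    contigs: list[TranscriptContig],
    references: list[ReferenceTranscript],
    matrix: HitMatrix,
    assigned: list[Assignment],
    ambiguity_margin: float = 0.98,
) -> list[Assignment]:
    """Single-best-hit rescue for contigs and references left over after BBH.

    A leftover contig is assigned iff its best remaining hit targets an
    unassigned reference and no second remaining hit scores within
    ``ambiguity_margin`` of the top. When two contigs claim one reference
    the higher score wins (tie: lexicographic contig id).
    """
    used_contigs = {a.contig_id for a in assigned}
    used_refs = {a.reference_accession for a in assigned}
    by_acc = {r.accession: r for r in references}
    candidates: list[tuple[float, str, str, AlignmentHit]] = []
    for contig in sorted(contigs, key=lambda c: c.id):
        if contig.id in used_contigs:
            continue
        remaining = [(acc, h) for acc, h in matrix.contig_hits(contig.id) if acc not in used_refs]
        if not remaining:
            continue
        remaining.sort(key=lambda t: (-t[1].score, -t[1].aligned_length, t[0]))
        acc, top = remaining[0]
        if len(remaining) > 1 and remaining[1][1].score >= ambiguity_margin * top.score:
            log.debug("SBH: %s ambiguous between %s and %s", contig.id, acc, remaining[1][0])
            continue
        candidates.append((top.score, contig.id, acc, top))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    assignments: list[Assignment] = []
    taken_refs: set[str] = set()
    taken_contigs: set[str] = set()
    for score, cid, acc, hit in candidates:
        if acc in taken_refs or cid in taken_contigs:
            continue
        taken_refs.add(acc)
        taken_contigs.add(cid)
        assignments.append(
            Assignment(
                contig_id=cid, reference_accession=acc,
                gene_symbol=by_acc[acc].gene_symbol,
                klass=AssignmentClass.SBH, score=score, strand=hit.strand,
            )
        )
    return assignments


def orient(
    contig: TranscriptContig, assignment: Assignment
) -> tuple[TranscriptContig, Assignment]:
    """Orient a contig according to its assigned ortholog.

    A minus-strand assignment reverse-complements the sequence; the
    returned assignment is on the plus strand of the oriented contig.
    Recorded intervals [s,e) on a length-L contig remap to [L-e, L-s).
    """
    if assignment.strand == "+":
        return replace(contig, oriented=True), assignment
    return contig.reverse_complemented(), replace(assignment, strand="+")


@dataclass
class GeneRegion:
    contig_id: str
    start: int
    end: int
    gene_symbol: str
    accession: str
    score: int


def detect_multi_gene(
    contig: TranscriptContig,
    assignment: Assignment,
    references: list[ReferenceTranscript],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    overlap_fraction: float = 0.2,
    min_length: int = 100,
    min_score: int = 60,
    reference_indexes: dict[str, KmerIndex] | None = None,
) -> list[GeneRegion]:
    """Find additional genes on an assigned (oriented) contig.

    Hits to other genes whose contig interval overlaps the primary
    orthologous region by less than ``overlap_fraction`` of the hit span
    and that pass length/score floors become extra regions; regions are
    merged per gene and the list is ordered by start (the primary region
    included).
    """
    by_acc = {r.accession: r for r in references}
    primary_ref = by_acc[assignment.reference_accession]
    regions: dict[str, GeneRegion] = {}

    def top_hit(ref: ReferenceTranscript) -> list[AlignmentHit]:
        index = reference_indexes.get(ref.accession) if reference_indexes else None
        return local_hits(
            contig.sequence, ref.cds, scheme, query_id=contig.id,
            subject_id=ref.accession, min_score=min_score, subject_index=index,
        )

    primary_hits = top_hit(primary_ref)
    if not primary_hits:
        return []
    p = primary_hits[0]
    regions[primary_ref.gene_symbol] = GeneRegion(
        contig.id, p.q_start, p.q_end, primary_ref.gene_symbol,
        primary_ref.accession, p.score,
    )
    primary_iv = (p.q_start, p.q_end)
    for ref in sorted(references, key=lambda r: r.accession):
        if ref.gene_symbol == primary_ref.gene_symbol:
            continue
        for hit in top_hit(ref):
            span = hit.q_span
            if span < min_length:
                continue
            ov = max(0, min(hit.q_end, primary_iv[1]) - max(hit.q_start, primary_iv[0]))
            if ov >= overlap_fraction * span:
                continue
            prev = regions.get(ref.gene_symbol)
            if prev is None:
                regions[ref.gene_symbol] = GeneRegion(
                    contig.id, hit.q_start, hit.q_end, ref.gene_symbol,
                    ref.accession, hit.score,
                )
            else:  # merge per gene; the best-scoring isoform names the region
                regions[ref.gene_symbol] = GeneRegion(
                    contig.id, min(prev.start, hit.q_start), max(prev.end, hit.q_end),
                    ref.gene_symbol,
                    ref.accession if hit.score > prev.score else prev.accession,
                    max(hit.score, prev.score),
                )
            break  # best hit per reference is enough
    return sorted(regions.values(), key=lambda r: (r.start, r.gene_symbol))


def split_multi_gene(
    contig: TranscriptContig, regions: list[GeneRegion]
) -> list[tuple[TranscriptContig, GeneRegion]]:
    """Copy a multi-gene contig once per gene.

    Each copy carries the full original sequence — the physical cut is
    deferred to boundary clipping — plus its own gene region. IDs are
    suffixed deterministically (``~1``, ``~2``, ... in region order). A
    single region returns the contig unchanged.
    """
    if len(regions) < 2:
        return [(contig, regions[0])] if regions else []
    out = []
    for k, region in enumerate(regions, start=1):
        out.append((replace(contig, id=f"{contig.id}~{k}"), region))
    return out
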