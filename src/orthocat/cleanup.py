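"""Optional redundancy reduction and vector-contamination screening.

Redundancy reduction mirrors cluster-and-keep-longest behaviour: contigs
fully embedded in (or locally diverged copies of) a longer contig join its
cluster and only the longest representative survives. It is off by default
in the pipeline — collapsing near-identical paralogs is riskier than
carrying redundancy, and downstream one-to-one assignment removes
redundancy anyway.

Vector screening annotates — never deletes — matches to a vector database,
classified by score and topology (terminal vs internal) following the NCBI
VecScreen category bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import DEFAULT_SCHEME, KmerIndex, ScoringScheme, local_hits
from .model import TranscriptContig

log = logging.getLogger(__name__)

__all__ = ["ContigCluster", "VectorFlag", "cluster_redundant", "vecscreen", "VECSCREEN_BANDS"]


@dataclass
class ContigCluster:
    representative: str
    members: list[str] = field(default_factory=list)


@dataclass
class VectorFlag:
    transcript_id: str
    start: int
    end: int
    score: int
    category: str  # strong | moderate | weak
    topology: str  # terminal | internal
    vector_id: str = ""


def cluster_redundant(
    contigs: list[TranscriptContig],
    identity_threshold: float = 0.95,
    containment_fraction: float = 0.9,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[ContigCluster]:
    """Greedy longest-first clustering of redundant contigs.

    Contigs are visited longest first (ties: lexicographic id, so the
    representative invariant holds by construction). Each contig joins the
    first existing representative it matches at >= ``identity_threshold``
    over >= ``containment_fraction`` of its own length, else founds a new
    cluster. The output clusters partition the input.
    """
    if not (0 < identity_threshold <= 1 and 0 < containment_fraction <= 1):
        raise ValueError("thresholds must lie in (0,1]")
    order = sorted(contigs, key=lambda c: (-len(c), c.id))
    clusters: list[ContigCluster] = []
    reps: list[tuple[TranscriptContig, KmerIndex]] = []
    for contig in order:
        placed = False
        for k, (rep, index) in enumerate(reps):
            hits = local_hits(
                contig.sequence, rep.sequence, scheme,
                query_id=contig.id, subject_id=rep.id, subject_index=index,
            )
            if not hits:
                continue
            top = hits[0]
            if top.identity >= identity_threshold and top.q_span >= containment_fraction * len(contig):
                clusters[k].members.append(contig.id)
                placed = True
                break
        if not placed:
            clusters.append(ContigCluster(representative=contig.id, members=[contig.id]))
            reps.append((contig, KmerIndex(contig.sequence, scheme.word_size)))
    return clusters


# NCBI VecScreen category score bands, keyed by topology. A match whose
# alignment starts within the terminal margin of either transcript end is
# "terminal"; internal matches need higher scores for the same category.
VECSCREEN_BANDS = {
    "terminal": {"strong": 24, "moderate": 19, "weak": 16},
    "internal": {"strong": 30, "moderate": 25, "weak": 23},
}


def vecscreen(
    transcripts: dict[str, str],
    vector_db: dict[str, str],
    terminal_margin: int = 25,
    bands: dict[str, dict[str, int]] | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[VectorFlag]:
    """Screen final transcripts for vector contamination.

    Returns annotation flags sorted by transcript then position; nothing is
    masked or removed. An empty vector DB yields an empty result with a
    warning.
    """
    if not vector_db:
        log.warning("vecscreen: empty vector database, nothing screened")
        return []
    bands = bands or VECSCREEN_BANDS
    min_report = min(min(b.values()) for b in bands.values())
    flags: list[VectorFlag] = []
    indexes = {vid: KmerIndex(vseq, scheme.word_size) for vid, vseq in vector_db.items()}
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        for vid in sorted(vector_db):
            for hit in local_hits(
                seq, vector_db[vid], scheme, query_id=tid, subject_id=vid,
                min_score=min_report, subject_index=indexes[vid],
            ):
                topology = (
                    "terminal"
                    if hit.q_start < terminal_margin or hit.q_end > len(seq) - terminal_margin
                    else "internal"
                )
                category = None
                for cat in ("strong", "moderate", "weak"):
                    if hit.score >= bands[topology][cat]:
                        category = cat
                        break
                if category is None:
                    continue
                flags.append(
                    VectorFlag(
                        transcript_id=tid, start=hit.q_start, end=hit.q_end,
                        score=hit.score, category=category, topology=topology,
                        vector_id=vid,
                    )
                )
    flags.sort(key=lambda f: (f.transcript_id, f.start, -f.score))
    return flags
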