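"""Ortholog-guided scaffolding of fragmented transcript contigs.

Contigs without an assigned gene symbol but with hits to an already
identified ortholog are fit-aligned to that ortholog's mRNA, a minimal
spanning set is chosen greedily (largest coverage gain first), and the
core contig is extended by the winners. Gaps between non-overlapping
placements become N runs sized exactly by the uncovered ortholog span, so
the scaffold keeps the ortholog's coordinate frame; overlapping placements
are joined at the midpoint of their template overlap, each side
contributing its aligned half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import DEFAULT_SCHEME, FitResult, ScoringScheme, fit_align
from .model import TranscriptContig, reverse_complement

log = logging.getLogger(__name__)

__all__ = [
    "FragmentPlacement",
    "ScaffoldPart",
    "ScaffoldPlan",
    "collect_candidates",
    "greedy_min_cover",
    "build_scaffold",
]


@dataclass
class FragmentPlacement:
    contig_id: str
    fit: FitResult
    sequence: str  # oriented fragment sequence
    orientation: str = "+"

    @property
    def template_start(self) -> int:
        return self.fit.template_start

    @property
    def template_end(self) -> int:
        return self.fit.template_end

    @property
    def template_interval(self) -> tuple[int, int]:
        return (self.fit.template_start, self.fit.template_end)


@dataclass
class ScaffoldPart:
    kind: str  # 'fragment' | 'gap'
    length: int
    template_start: int
    template_end: int
    contig_id: str | None = None
    frag_start: int | None = None  # fragment slice actually used
    frag_end: int | None = None


@dataclass
class ScaffoldPlan:
    gene_symbol: str
    core_contig_id: str
    parts: list[ScaffoldPart] = field(default_factory=list)

    @property
    def gap_lengths(self) -> list[int]:
        return [p.length for p in self.parts if p.kind == "gap"]

    def template_coverage(self, template_length: int) -> float:
        covered = sum(p.template_end - p.template_start for p in self.parts if p.kind == "fragment")
        return covered / template_length if template_length else 0.0


def collect_candidates(
    ortholog_mrna: str,
    fragments: list[tuple[TranscriptContig, str]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_fit_fraction: float = 0.4,
) -> list[FragmentPlacement]:
    """Fit unassigned candidate fragments onto the orthologous mRNA.

    ``fragments`` pairs each candidate contig with the strand of its hit to
    the gene's reference CDS; minus-strand fragments are reverse
    complemented before fitting. Unalignable fragments are dropped.
    """
    placements: list[FragmentPlacement] = []
    for contig, strand in fragments:
        seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        fit = fit_align(seq, ortholog_mrna, scheme, min_score_fraction=min_fit_fraction)
        if not fit.aligned:
            log.debug("scaffold candidate %s unalignable to ortholog", contig.id)
            continue
        placements.append(FragmentPlacement(contig.id, fit, seq, orientation=strand))
    placements.sort(key=lambda p: (p.template_start, -(p.template_end - p.template_start), p.contig_id))
    return placements


def greedy_min_cover(
    core_interval: tuple[int, int],
    candidates: list[FragmentPlacement],
    template_length: int,
) -> list[FragmentPlacement]:
    """Minimum fragment set spanning most of the ortholog (greedy sweep).

    The reachable coverage is the union of the core interval and all
    candidate intervals. The classical interval-cover greedy attains it
    with provably minimum cardinality: repeatedly take the leftmost
    position still uncovered and, among the candidates covering it, select
    the one reaching furthest right (ties: earlier template start, then
    longer placement, then lexicographic contig id). Stops when nothing
    uncovered remains reachable; the selection is deterministic.
    """
    covered = np.zeros(template_length, dtype=bool)
    covered[core_interval[0] : core_interval[1]] = True
    reachable = covered.copy()
    for cand in candidates:
        reachable[cand.template_start : cand.template_end] = True
    selected: list[FragmentPlacement] = []
    remaining = list(candidates)
    while True:
        uncovered = np.nonzero(reachable & ~covered)[0]
        if len(uncovered) == 0:
            break
        p = int(uncovered[0])
        eligible = [c for c in remaining if c.template_start <= p < c.template_end]
        best = min(
            eligible,
            key=lambda c: (
                -c.template_end,
                c.template_start,
                -(c.template_end - c.template_start),
                c.contig_id,
            ),
        )
        covered[best.template_start : best.template_end] = True
        selected.append(best)
        remaining.remove(best)
    selected.sort(key=lambda p: (p.template_start, p.contig_id))
    return selected


def build_scaffold(
    core: FragmentPlacement,
    selected: list[FragmentPlacement],
    ortholog_mrna: str,
    gene_symbol: str,
) -> tuple[str, ScaffoldPlan]:
    """Assemble the scaffold sequence and its provenance plan.

    Parts are laid out in template order. Consecutive placements that
    overlap on the template are cut at the overlap midpoint; disjoint
    placements are separated by an N run exactly as long as the intervening
    template span. The outermost parts keep their unaligned overhangs
    (5' and 3' UTR sequence the ortholog frame does not cover). Every
    scaffold base maps to exactly one fragment slice or one gap record.
    """
    parts_in = sorted(
        [core] + selected,
        key=lambda p: (p.template_start, 0 if p is core else 1, p.contig_id),
    )
    plan = ScaffoldPlan(gene_symbol=gene_symbol, core_contig_id=core.contig_id)
    pieces: list[str] = []

    # cut positions per part, in fragment coordinates
    cuts: list[list[int]] = []
    for k, part in enumerate(parts_in):
        cuts.append([0 if k == 0 else part.fit.frag_start,
                     len(part.sequence) if k == len(parts_in) - 1 else part.fit.frag_end])

    drop = [False] * len(parts_in)
    for k in range(len(parts_in) - 1):
        a, b = parts_in[k], parts_in[k + 1]
        if a.template_end > b.template_start:  # overlap: cut both at template midpoint
            mid = (b.template_start + a.template_end) // 2
            cuts[k][1] = min(cuts[k][1], a.fit.frag_index_at_template(mid))
            cuts[k + 1][0] = max(cuts[k + 1][0], b.fit.frag_index_at_template(mid))
    gaps: list[tuple[int, int, int]] = []  # (after part index, gap length, template start)

    for k in range(len(parts_in) - 1):
        a, b = parts_in[k], parts_in[k + 1]
        if a.template_end <= b.template_start:
            gap = b.template_start - a.template_end
            if gap > 0:
                gaps.append((k, gap, a.template_end))

    gap_by_part = {k: (g, ts) for k, g, ts in gaps}
    for k, part in enumerate(parts_in):
        lo, hi = cuts[k]
        if lo >= hi:
            log.warning("scaffold part %s fully consumed by junction cuts; dropped", part.contig_id)
            drop[k] = True
        else:
            pieces.append(part.sequence[lo:hi])
            plan.parts.append(
                ScaffoldPart(
                    kind="fragment",
                    length=hi - lo,
                    template_start=part.template_start,
                    template_end=part.template_end,
                    contig_id=part.contig_id,
                    frag_start=lo,
                    frag_end=hi,
                )
            )
        if k in gap_by_part and not drop[k]:
            gap, ts = gap_by_part[k]
            pieces.append("N" * gap)
            plan.parts.append(
                ScaffoldPart(kind="gap", length=gap, template_start=ts, template_end=ts + gap)
            )
    sequence = "".join(pieces)
    coverage = plan.template_coverage(len(ortholog_mrna))
    if coverage < 0.5:
        log.warning(
            "scaffold for %s covers only %.0f%% of the ortholog", gene_symbol, 100 * coverage
        )
    return sequence, plan
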