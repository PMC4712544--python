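"""Pairwise nucleotide alignment services used by every pipeline stage.

Three entry points:

``local_hits``
    Local (Smith-Waterman) hits on both strands. Small problems run the
    exact DP over the full matrix; larger ones use seed-and-extend — shared
    11-mers group into diagonal bands, and the exact DP runs on each seeded
    subregion. This is the package's BLASTN surrogate; an external aligner
    can be plugged in through the same :class:`AlignmentHit` contract.

``fit_align``
    Free-end-gap ("fitting") alignment of a fragment onto a template,
    returning the covered template interval and a per-base correspondence.
    Used for ortholog-guided scaffolding and CDS window transfer.

``terminus_align``
    Local alignment of the final <=50 nt of an orthologous mRNA against a
    transcript, for 3'-end evidence scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import reverse_complement

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "FitResult",
    "encode",
    "local_hits",
    "smith_waterman",
    "fit_align",
    "terminus_align",
    "KmerIndex",
]

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _ch in enumerate("ACGT"):
    _ENC[ord(_ch)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A,C,G,T,N -> 0..4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Megablast-like nucleotide scoring.

    A gap of length k costs ``gap_open + k * gap_extend``. Word size 11 is
    the seeding granularity; orthologous coding sequences within ~15%
    divergence share abundant 11-mers.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 11

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    identity: float
    aligned_length: int

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start


@dataclass
class FitResult:
    """Fitting alignment of a fragment onto a template."""

    score: int
    frag_start: int
    frag_end: int
    template_start: int
    template_end: int
    identity: float
    aligned_length: int
    mapping: np.ndarray = field(repr=False)  # fragment index -> template index or -1
    aligned: bool = True

    def template_position(self, frag_index: int) -> int:
        return int(self.mapping[frag_index])

    def frag_index_at_template(self, t: int) -> int:
        """Smallest aligned fragment index whose template position is >= t.

        Returns len(fragment) if every aligned base maps before ``t``.
        Used to cut overlapping scaffold fragments at a template midpoint.
        """
        idx = np.nonzero(self.mapping >= 0)[0]
        pos = self.mapping[idx]
        k = int(np.searchsorted(pos, t, side="left"))
        if k == len(idx):
            return len(self.mapping)
        return int(idx[k])


def smith_waterman(query: str, subject: str, scheme: ScoringScheme = DEFAULT_SCHEME):
    """Exact local alignment of two plus-strand sequences.

    Returns (score, q_interval, s_interval, matches, columns); score 0 means
    no positive-scoring local alignment exists.
    """
    a = encode(query)
    b = encode(subject)
    best, bi, bj, H, E, F, ptr = _kernels.local_dp(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    if best <= 0:
        return 0, (0, 0), (0, 0), 0, 0
    qs, ss, matches, cols = _kernels.traceback(
        a, b, H, E, F, ptr, bi, bj, scheme.gap_open, scheme.gap_extend
    )
    return int(best), (int(qs), int(bi)), (int(ss), int(bj)), int(matches), int(cols)


class KmerIndex:
    """Exact k-mer position index of a subject sequence (seeding helper)."""

    def __init__(self, sequence: str, word_size: int = DEFAULT_SCHEME.word_size):
        self.sequence = sequence
        self.word_size = word_size
        index: dict[str, list[int]] = {}
        k = word_size
        for i in range(len(sequence) - k + 1):
            w = sequence[i : i + k]
            if "N" in w:
                continue
            index.setdefault(w, []).append(i)
        self._index = index

    def seeds(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, subject_pos) pairs of shared words."""
        k = self.word_size
        out: list[tuple[int, int]] = []
        idx = self._index
        for i in range(len(query) - k + 1):
            hits = idx.get(query[i : i + k])
            if hits:
                for j in hits:
                    out.append((i, j))
        return out


def _seed_regions(
    seeds: list[tuple[int, int]],
    qlen: int,
    slen: int,
    word_size: int,
    band: int = 48,
    margin: int = 64,
    max_regions: int = 50,
) -> list[tuple[int, int, int, int]]:
    """Group seeds into diagonal bands and return padded (q0,q1,s0,s1) boxes."""
    if not seeds:
        return []
    seeds = sorted(seeds, key=lambda t: (t[0] - t[1], t[0]))
    groups: list[list[tuple[int, int]]] = []
    cur = [seeds[0]]
    for qp, sp in seeds[1:]:
        if (qp - sp) - (cur[-1][0] - cur[-1][1]) <= band:
            cur.append((qp, sp))
        else:
            groups.append(cur)
            cur = [(qp, sp)]
    groups.append(cur)

    boxes = []
    for g in groups:
        q0 = max(0, min(q for q, _ in g) - margin)
        q1 = min(qlen, max(q for q, _ in g) + word_size + margin)
        s0 = max(0, min(s for _, s in g) - margin)
        s1 = min(slen, max(s for _, s in g) + word_size + margin)
        boxes.append([q0, q1, s0, s1, len(g)])
    # merge overlapping boxes so one homologous region yields one DP
    boxes.sort(key=lambda b: (b[0], b[2]))
    merged: list[list[int]] = []
    for b in boxes:
        for m in merged:
            if b[0] < m[1] and b[1] > m[0] and b[2] < m[3] and b[3] > m[2]:
                m[0] = min(m[0], b[0])
                m[1] = max(m[1], b[1])
                m[2] = min(m[2], b[2])
                m[3] = max(m[3], b[3])
                m[4] += b[4]
                break
        else:
            merged.append(b)
    merged.sort(key=lambda b: -b[4])
    return [(b[0], b[1], b[2], b[3]) for b in merged[:max_regions]]


def _strand_hits(
    q: str,
    subject: str,
    strand: str,
    orig_qlen: int,
    query_id: str,
    subject_id: str,
    scheme: ScoringScheme,
    max_dp_cells: int,
    index: KmerIndex | None,
) -> list[AlignmentHit]:
    hits: list[AlignmentHit] = []

    def make_hit(score, qiv, siv, matches, cols, qoff=0, soff=0):
        qs, qe = qiv[0] + qoff, qiv[1] + qoff
        if strand == "-":  # map back to original query coordinates
            qs, qe = orig_qlen - qe, orig_qlen - qs
        return AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            q_start=qs,
            q_end=qe,
            s_start=siv[0] + soff,
            s_end=siv[1] + soff,
            strand=strand,
            score=score,
            identity=matches / cols if cols else 0.0,
            aligned_length=cols,
        )

    if len(q) * len(subject) <= max_dp_cells:
        score, qiv, siv, matches, cols = smith_waterman(q, subject, scheme)
        if score > 0:
            hits.append(make_hit(score, qiv, siv, matches, cols))
        return hits

    if index is None or index.word_size != scheme.word_size:
        index = KmerIndex(subject, scheme.word_size)
    seeds = index.seeds(q)
    for q0, q1, s0, s1 in _seed_regions(seeds, len(q), len(subject), scheme.word_size):
        score, qiv, siv, matches, cols = smith_waterman(q[q0:q1], subject[s0:s1], scheme)
        if score > 0:
            hits.append(make_hit(score, qiv, siv, matches, cols, qoff=q0, soff=s0))
    return hits


def local_hits(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "query",
    subject_id: str = "subject",
    min_score: int = 0,
    max_dp_cells: int = 512 * 512,
    subject_index: KmerIndex | None = None,
) -> list[AlignmentHit]:
    """Local alignment hits of ``query`` against ``subject`` on both strands.

    Instances with at most ``max_dp_cells`` matrix cells run the exact DP,
    so on small inputs the top hit equals the full Smith-Waterman optimum;
    larger inputs are seeded. Hits are sorted by score (then aligned length,
    query start, strand) descending; overlapping lower-scoring hits are
    retained — multi-gene detection needs them.
    """
    if not query or not subject:
        raise ValueError("local_hits requires non-empty sequences")
    hits: list[AlignmentHit] = []
    for strand in "+-":
        q = query if strand == "+" else reverse_complement(query)
        hits.extend(
            _strand_hits(
                q, subject, strand, len(query), query_id, subject_id, scheme,
                max_dp_cells, subject_index,
            )
        )
    hits = [h for h in hits if h.score >= min_score and h.score > 0]
    hits.sort(key=lambda h: (-h.score, -h.aligned_length, h.q_start, h.strand))
    # drop near-duplicate hits produced by overlapping seed boxes
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for k in kept:
            if k.strand == h.strand and _overlap(h.q_interval, k.q_interval) > 0.8 * h.q_span \
                    and _overlap(h.s_interval, k.s_interval) > 0.8 * (h.s_end - h.s_start):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def fit_align(
    fragment: str,
    template: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_score_fraction: float = 0.3,
) -> FitResult:
    """Fit ``fragment`` onto ``template`` with free end gaps on both sides.

    The covered template interval and a per-base fragment->template mapping
    are returned. A result scoring below ``min_score_fraction`` of the
    maximum attainable (fragment length x match score) is flagged
    unalignable. Prepending K template bases shifts the covered interval by
    exactly K (position-shift equivariance).
    """
    if not fragment or not template:
        raise ValueError("fit_align requires non-empty sequences")
    a = encode(fragment)
    b = encode(template)
    best, bi, bj, H, E, F, ptr = _kernels.overlap_dp(
        a, b, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    fs, ts, matches, cols, mapping = _kernels.overlap_traceback(
        a, b, H, E, F, ptr, bi, bj, scheme.gap_open, scheme.gap_extend
    )
    aligned_idx = np.nonzero(mapping >= 0)[0]
    floor = min_score_fraction * len(fragment) * scheme.match
    if best < floor or len(aligned_idx) == 0:
        return FitResult(
            score=int(best), frag_start=0, frag_end=0, template_start=0,
            template_end=0, identity=0.0, aligned_length=0,
            mapping=np.full(len(fragment), -1, dtype=np.int64), aligned=False,
        )
    t0 = int(mapping[aligned_idx[0]])
    t1 = int(mapping[aligned_idx[-1]]) + 1
    return FitResult(
        score=int(best),
        frag_start=int(aligned_idx[0]),
        frag_end=int(aligned_idx[-1]) + 1,
        template_start=t0,
        template_end=t1,
        identity=matches / cols if cols else 0.0,
        aligned_length=int(cols),
        mapping=mapping,
    )


def terminus_align(
    seq: str,
    ortholog_tail: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[int, float]:
    """Locate the orthologous mRNA 3' terminus on ``seq``.

    ``ortholog_tail`` should be the final <=50 nt of the orthologous mRNA
    (a shorter ortholog contributes whatever it has). Returns the position
    on ``seq`` where the terminus ends (0-based, exclusive) and the score
    normalized by the maximum attainable (tail length x match).
    """
    if not ortholog_tail:
        return 0, 0.0
    score, _qiv, siv, _m, _c = smith_waterman(ortholog_tail, seq, scheme)
    if score <= 0:
        return 0, 0.0
    return siv[1], score / (len(ortholog_tail) * scheme.match)
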