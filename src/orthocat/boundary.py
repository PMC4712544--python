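"""mRNA boundary refinement.

Assemblers rarely recover precise 3' ends: cleavage is cell-biologically
imprecise, alternative poly(A) sites exist, and trailing (genomic or
read-through) sequence survives assembly. Four per-position evidence
features are computed over each oriented transcript — poly(A) signal
motifs, drops in read coverage, reads with protruding poly(A) tails, and a
local alignment of the orthologous mRNA terminus — mapped through fuzzy
membership ramps, combined as a weighted score, and the transcript is
clipped at the best-scoring position past the CDS when the score clears a
threshold. Contigs carrying several genes are cut within intercoding
regions, at the supported position if one exists, else at the center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import DEFAULT_SCHEME, ScoringScheme, terminus_align

log = logging.getLogger(__name__)

__all__ = [
    "FeatureTrack",
    "ClipDecision",
    "POLYA_MOTIFS",
    "DEFAULT_WEIGHTS",
    "scan_polya_signals",
    "coverage_drop_track",
    "polya_read_track",
    "terminus_track",
    "fuzzy_combine",
    "clip_3prime",
    "clip_5prime",
    "split_intercoding",
    "coverage_from_bedgraph",
    "tail_supports_from_sam",
]

# canonical poly(A) signal and its common single-base variants; weights are
# relative motif strengths
POLYA_MOTIFS: dict[str, float] = {
    "AATAAA": 1.0,
    "ATTAAA": 0.8,
    "TATAAA": 0.5,
    "AGTAAA": 0.5,
    "AATACA": 0.5,
    "CATAAA": 0.5,
    "AATATA": 0.5,
    "GATAAA": 0.5,
    "AATGAA": 0.5,
    "AATAGA": 0.5,
    "ACTAAA": 0.5,
    "AAGAAA": 0.5,
}

DEFAULT_WEIGHTS = {"signal": 0.3, "drop": 0.2, "reads": 0.3, "terminus": 0.2}


@dataclass
class FeatureTrack:
    """Per-position evidence arrays over one transcript, all in [0,1]."""

    signal: np.ndarray
    drop: np.ndarray
    reads: np.ndarray
    terminus: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.signal)
        for name in ("drop", "reads", "terminus"):
            if len(getattr(self, name)) != n:
                raise ValueError("feature tracks must share the transcript length")


@dataclass
class ClipDecision:
    end: str  # '5p' | '3p'
    position: int  # 3p keeps [0,pos); 5p keeps [pos,len)
    score: float
    reason: str
    features: dict[str, float] | None = None


def scan_polya_signals(
    seq: str,
    motifs: dict[str, float] | None = None,
    downstream_min: int = 10,
    downstream_max: int = 30,
) -> np.ndarray:
    """Score potential 3' ends by poly(A) signal occurrence.

    Cleavage happens 10-30 nt downstream of the signal hexamer, so each
    motif occurrence deposits its weight on the positions
    ``[motif_end + downstream_min, motif_end + downstream_max)``; the
    strongest motif wins per position.
    """
    motifs = motifs or POLYA_MOTIFS
    track = np.zeros(len(seq))
    for motif, weight in motifs.items():
        start = seq.find(motif)
        while start != -1:
            lo = start + len(motif) + downstream_min
            hi = min(len(seq), start + len(motif) + downstream_max)
            if lo < len(seq):
                np.maximum(track[lo:hi], weight, out=track[lo:hi])
            start = seq.find(motif, start + 1)
    return track


def coverage_drop_track(
    coverage: np.ndarray, window: int = 25, eps: float = 1e-6, min_left: float = 1.0
) -> np.ndarray:
    """Score informative drops in read coverage.

    score(i) = clamp(1 - mean(cov[i:i+w]) / max(mean(cov[i-w:i]), eps), 0, 1),
    with windows clipped at the transcript edges. A drop needs coverage to
    drop from: positions whose upstream window averages below ``min_left``
    reads score zero (otherwise every position of an uncovered tail would
    look like a perfect drop).
    """
    cov = np.asarray(coverage, dtype=float)
    n = len(cov)
    if n == 0 or not np.any(cov > 0):
        if n:
            log.warning("coverage_drop_track: all-zero coverage")
        return np.zeros(n)
    cum = np.concatenate([[0.0], np.cumsum(cov)])

    def mean(a: int, b: int) -> float:
        a = max(0, a)
        b = min(n, b)
        if b <= a:
            return 0.0
        return (cum[b] - cum[a]) / (b - a)

    track = np.zeros(n)
    for i in range(n):
        left = mean(i - window, i)
        if left < min_left:
            continue
        right = mean(i, i + window)
        track[i] = min(max(1.0 - right / max(left, eps), 0.0), 1.0)
    return track


def tail_supports_from_sam(sam_path, transcript_id: str, a_min: int = 5, purity: float = 0.9):
    """Count poly(A)-tailed read ends per position from a SAM/BAM file.

    A read supports the position of its last aligned base if its 3'
    soft-clipped tail has >= ``a_min`` bases of >= ``purity`` adenine.
    """
    import pysam

    counts: dict[int, int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.reference_name != transcript_id:
                continue
            cigar = read.cigartuples
            if not cigar or cigar[-1][0] != 4:  # BAM_CSOFT_CLIP
                continue
            clip_len = cigar[-1][1]
            if clip_len < a_min:
                continue
            tail = read.query_sequence[-clip_len:]
            if tail.count("A") / len(tail) < purity:
                continue
            pos = read.reference_end - 1  # last aligned base
            counts[pos] = counts.get(pos, 0) + 1
    return counts


def polya_read_track(length: int, supports: dict[int, int]) -> np.ndarray:
    """Normalize per-position tailed-read support counts to [0,1]."""
    track = np.zeros(length)
    if not supports:
        log.warning("polya_read_track: no supporting reads")
        return track
    peak = max(supports.values())
    for pos, count in supports.items():
        if 0 <= pos < length:
            track[pos] = count / peak
    return track


def terminus_track(
    seq: str,
    ortholog_mrna: str,
    tail_length: int = 50,
    half_width: int = 10,
    min_score: float = 0.4,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Place the ortholog-terminus alignment score as a triangular peak.

    The final <=50 nt of the orthologous mRNA is locally aligned to the
    transcript; the normalized score lands where the terminus ends and
    decays linearly to zero over +-``half_width`` nt. Scores below
    ``min_score`` are indistinguishable from chance alignments of random
    50-mers and yield an all-zero track.
    """
    track = np.zeros(len(seq))
    tail = ortholog_mrna[-tail_length:]
    end_pos, score = terminus_align(seq, tail, scheme)
    if score < min_score:
        return track
    peak = end_pos - 1  # index of the last aligned base
    for offset in range(-half_width, half_width + 1):
        i = peak + offset
        if 0 <= i < len(seq):
            track[i] = max(track[i], score * (1 - abs(offset) / half_width))
    return track


def _ramp(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def fuzzy_combine(
    tracks: FeatureTrack,
    weights: dict[str, float] | None = None,
    lo: float = 0.1,
    hi: float = 0.9,
    available: dict[str, bool] | None = None,
) -> np.ndarray:
    """Weighted fuzzy combination of the four evidence features.

    Each track passes through a piecewise-linear membership ramp (0 below
    ``lo``, 1 above ``hi``) and the memberships are summed with the given
    weights. When an evidence source is declared unavailable (``available``
    maps feature name to False) its weight is redistributed over the
    remaining features, so the combined score stays in [0,1]. The result is
    monotone in every feature.
    """
    weights = dict(weights or DEFAULT_WEIGHTS)
    if available:
        for name, ok in available.items():
            if not ok:
                weights.pop(name, None)
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no available features to combine")
    combined = np.zeros(len(tracks.signal))
    for name, weight in weights.items():
        combined += (weight / total) * _ramp(getattr(tracks, name), lo, hi)
    return combined


def clip_3prime(
    sequence_length: int,
    cds_end: int,
    combined: np.ndarray,
    threshold: float = 0.5,
) -> ClipDecision | None:
    """Clip the 3' end at the most reliable supported position.

    Only positions at or beyond the CDS stop are considered (a clip never
    removes CDS bases of the entry's own gene). The clip keeps the
    supported end inclusive: position ``i`` scoring best yields a cut at
    ``i + 1``. Below ``threshold``, no clip.
    """
    if len(combined) != sequence_length:
        raise ValueError("combined score length must equal the sequence length")
    region = combined[cds_end:]
    if len(region) == 0:
        return None
    best_offset = int(np.argmax(region))
    best_score = float(region[best_offset])
    if best_score < threshold:
        return None
    pos = cds_end + best_offset + 1
    if pos >= sequence_length:
        return None  # supported end is the current end: nothing to remove
    return ClipDecision(end="3p", position=pos, score=best_score, reason="polyA_end")


def clip_5prime(
    cds_start: int,
    promoter_end: int | None,
    guard: int = 0,
) -> ClipDecision | None:
    """Clip the 5' end at the downstream edge of a predicted promoter,
    never into the CDS."""
    if promoter_end is None:
        return None
    pos = min(promoter_end, max(cds_start - guard, 0))
    if pos <= 0:
        return None
    return ClipDecision(end="5p", position=pos, score=1.0, reason="promoter")


def split_intercoding(
    cds_intervals: list[tuple[int, int]],
    combined: np.ndarray,
    threshold: float = 0.5,
) -> list[tuple[int, float, str]]:
    """Cut positions between consecutive CDS regions of a fusion transcript.

    Within each intercoding interval the best combined-score position is
    used when it clears ``threshold``; otherwise the interval midpoint.
    Returns one (position, score, reason) per junction, in order; reasons
    are ``intercoding_split`` (evidence) or ``intercoding_center``.
    """
    ivs = sorted(cds_intervals)
    cuts: list[tuple[int, float, str]] = []
    for (a_start, a_end), (b_start, b_end) in zip(ivs, ivs[1:]):
        if a_end > b_start:
            raise ValueError(f"CDS intervals overlap: [{a_start},{a_end}) and [{b_start},{b_end})")
        region = combined[a_end:b_start]
        if len(region) > 0:
            best_offset = int(np.argmax(region))
            best_score = float(region[best_offset])
        else:
            best_offset, best_score = 0, 0.0
        if best_score >= threshold:
            cuts.append((a_end + best_offset, best_score, "intercoding_split"))
        else:
            cuts.append(((a_end + b_start) // 2, best_score, "intercoding_center"))
    return cuts


def coverage_from_bedgraph(
    intervals: list[tuple[int, int, float]], length: int
) -> np.ndarray:
    """Expand bedGraph intervals to a per-base coverage array."""
    cov = np.zeros(length)
    for start, end, value in intervals:
        cov[max(0, start) : min(length, end)] = value
    return cov
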