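"""CDS identification on (scaffolded) transcripts.

The primary route transfers orthologous CDS windows: the CDS of the
assigned reference — and, when an ortholog table provides them, the most
similar isoform of each additional species — is fit-aligned to the
transcript, and the covered interval is examined for a valid reading frame
(no premature stop; for selenoproteins in-frame UGA is read through as
selenocysteine and only non-UGA stops disqualify). Among valid frames the
one most complete relative to its ortholog wins. If no window yields a
valid frame, a gene-predictor adapter is consulted and the prediction most
similar to the ortholog CDS is annotated; as a last resort the longest ORF
is assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol

from .align import DEFAULT_SCHEME, ScoringScheme, fit_align, local_hits
from .model import (
    CdsSource,
    CdsStatus,
    OrthologTable,
    ReferenceTranscript,
    STOP_CODONS,
)

log = logging.getLogger(__name__)

__all__ = [
    "OrthologWindow",
    "CdsCall",
    "PredictedGene",
    "GenePredictor",
    "NaivePredictor",
    "build_windows",
    "validate_frames",
    "choose_call",
    "predictor_fallback",
    "longest_orf",
    "classify_completeness",
    "identify_cds",
]


@dataclass
class OrthologWindow:
    species: str
    accession: str
    start: int  # transcript interval hypothesized to contain the CDS
    end: int
    score: int
    cds_length: int  # length of the source ortholog CDS


@dataclass
class CdsCall:
    start: int
    end: int
    frame: int
    source: CdsSource
    has_start: bool
    has_stop: bool
    completeness_fraction: float
    supporting_species: list[str] = field(default_factory=list)
    spans_gap: bool = False  # an N codon was treated as coding

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PredictedGene:
    """Output contract of a gene-predictor adapter."""

    start: int
    end: int
    score: float
    promoter_end: int | None = None  # downstream edge of a predicted promoter


class GenePredictor(Protocol):
    def __call__(self, sequence: str) -> list[PredictedGene]: ...


def _is_stop(codon: str, seleno: bool) -> bool:
    if "N" in codon:  # codons spanning scaffold N gaps are treated as coding
        return False
    if seleno:
        return codon in ("TAA", "TAG")
    return codon in STOP_CODONS


def build_windows(
    transcript: str,
    reference: ReferenceTranscript,
    ortholog_table: OrthologTable | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_fit_fraction: float = 0.3,
) -> list[OrthologWindow]:
    """Transfer candidate CDS windows from orthologous CDSs.

    The assigned reference contributes first; each extra species in the
    ortholog table contributes its most similar isoform (by alignment score
    against the reference CDS). Windows are sorted by transfer score.
    An empty result triggers the predictor fallback.
    """
    sources: list[tuple[str, str, str]] = [(reference.species, reference.accession, reference.cds)]
    if ortholog_table is not None:
        for species, accessions in sorted(ortholog_table.species_for(reference.gene_symbol).items()):
            if species == reference.species:
                continue
            best_acc, best_score = None, -1
            for acc in accessions:
                seq = ortholog_table.sequence(acc)
                hits = local_hits(seq, reference.cds, scheme, query_id=acc,
                                  subject_id=reference.accession)
                score = hits[0].score if hits else 0
                if score > best_score:
                    best_acc, best_score = acc, score
            if best_acc is not None:
                sources.append((species, best_acc, ortholog_table.sequence(best_acc)))
    windows: list[OrthologWindow] = []
    for species, acc, cds_seq in sources:
        fit = fit_align(cds_seq, transcript, scheme, min_score_fraction=min_fit_fraction)
        if not fit.aligned:
            continue
        windows.append(
            OrthologWindow(
                species=species, accession=acc,
                start=fit.template_start, end=fit.template_end,
                score=fit.score, cds_length=len(cds_seq),
            )
        )
    windows.sort(key=lambda w: (-w.score, w.species))
    return windows


def validate_frames(
    transcript: str,
    window: OrthologWindow,
    selenoprotein: bool = False,
    end_slack: int = 6,
    start_search: int = 90,
) -> list[CdsCall]:
    """Scan the three reading frames over an ortholog window.

    A frame is valid iff it contains no premature stop (stops closer than
    ``end_slack`` to the window end count as the genuine terminator; UGA is
    tolerated for selenoproteins; codons containing N never count as
    stops). The start is extended upstream in-frame to the nearest ATG
    within ``start_search`` nt, and the end runs to the first stop at or
    beyond the window end when one exists within the transcript.
    """
    n = len(transcript)
    calls: list[CdsCall] = []
    for phase in range(3):
        s0 = window.start + phase
        if s0 + 3 > n:
            continue
        premature_limit = window.end - 3 - end_slack
        pos = s0
        stop_at: int | None = None
        premature = False
        spans_gap = False
        while pos + 3 <= n:
            codon = transcript[pos : pos + 3]
            if "N" in codon and pos < window.end:
                spans_gap = True
            if _is_stop(codon, selenoprotein):
                if pos < premature_limit:
                    premature = True
                else:
                    stop_at = pos
                break
            pos += 3
        if premature:
            continue
        end = stop_at + 3 if stop_at is not None else s0 + ((n - s0) // 3) * 3
        has_stop = stop_at is not None
        # start codon: at s0 or nearest in-frame ATG upstream
        start = s0
        has_start = transcript[s0 : s0 + 3] == "ATG"
        if not has_start:
            u = s0 - 3
            while u >= 0 and s0 - u <= start_search:
                codon = transcript[u : u + 3]
                if codon == "ATG":
                    start = u
                    has_start = True
                    break
                if _is_stop(codon, selenoprotein):
                    break
                u -= 3
        calls.append(
            CdsCall(
                start=start, end=end, frame=phase,
                source=CdsSource.ORTHOLOG_WINDOW,
                has_start=has_start, has_stop=has_stop,
                completeness_fraction=(end - start) / window.cds_length,
                supporting_species=[window.species],
                spans_gap=spans_gap,
            )
        )
    return calls


def choose_call(calls: list[CdsCall]) -> CdsCall:
    """Pick the call most complete with respect to its ortholog.

    Ties break on the number of present termini (start + stop), then on
    call length, then on the lowest frame index.
    """
    if not calls:
        raise ValueError("choose_call requires at least one call")
    return min(
        calls,
        key=lambda c: (
            -c.completeness_fraction,
            -(int(c.has_start) + int(c.has_stop)),
            -c.length,
            c.frame,
        ),
    )


class NaivePredictor:
    """Built-in gene predictor: maximal ORFs scored by length with a small
    Kozak-context bonus. Predicts no promoters, so promoter-based 5'
    clipping is a no-op under this adapter.
    """

    def __init__(self, min_orf_length: int = 150):
        self.min_orf_length = min_orf_length

    def __call__(self, sequence: str) -> list[PredictedGene]:
        preds = []
        for start, end in _orf_scan(sequence):
            if end - start < self.min_orf_length:
                continue
            score = float(end - start)
            if start >= 3 and sequence[start - 3] in "AG" and sequence[start + 3 : start + 4] == "G":
                score += 50.0  # Kozak-like context
            preds.append(PredictedGene(start=start, end=end, score=score))
        preds.sort(key=lambda p: (-p.score, p.start))
        return preds


def _orf_scan(sequence: str) -> list[tuple[int, int]]:
    """All maximal ATG->stop ORFs (stop included) on the given strand."""
    n = len(sequence)
    orfs: list[tuple[int, int]] = []
    for phase in range(3):
        start: int | None = None
        for pos in range(phase, n - 2, 3):
            codon = sequence[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS and "N" not in codon:
                orfs.append((start, pos + 3))
                start = None
    return orfs


def predictor_fallback(
    transcript: str,
    reference: ReferenceTranscript,
    predictor: GenePredictor | None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> CdsCall | None:
    """Annotate the predicted CDS most similar to the assigned ortholog.

    Similarity is the local alignment score between the predicted region
    and the ortholog CDS. Returns None when the adapter is unavailable or
    yields nothing (the longest-ORF last resort then applies).
    """
    if predictor is None:
        return None
    predictions = predictor(transcript)
    if not predictions:
        return None
    best = None
    best_score = -1
    for pred in predictions:
        region = transcript[pred.start : pred.end]
        if not region:
            continue
        hits = local_hits(region, reference.cds, scheme)
        score = hits[0].score if hits else 0
        if score > best_score:
            best, best_score = pred, score
    if best is None:
        return None
    has_stop = transcript[best.end - 3 : best.end] in STOP_CODONS
    return CdsCall(
        start=best.start, end=best.end, frame=best.start % 3,
        source=CdsSource.PREDICTOR,
        has_start=transcript[best.start : best.start + 3] == "ATG",
        has_stop=has_stop,
        completeness_fraction=(best.end - best.start) / len(reference.cds),
    )


def longest_orf(transcript: str, ortholog_cds_length: int | None = None) -> CdsCall:
    """Last-resort call: the longest start->stop ORF on the given strand,
    or, failing that, the longest stop-free stretch in any frame."""
    orfs = _orf_scan(transcript)
    if orfs:
        start, end = max(orfs, key=lambda iv: (iv[1] - iv[0], -iv[0]))
        return CdsCall(
            start=start, end=end, frame=start % 3,
            source=CdsSource.LONGEST_ORF, has_start=True, has_stop=True,
            completeness_fraction=(end - start) / ortholog_cds_length if ortholog_cds_length else 0.0,
        )
    # no complete ORF: longest stop-free codon stretch
    best = (0, 0)
    n = len(transcript)
    for phase in range(3):
        run_start = phase
        for pos in range(phase, n - 2 + 1, 3):
            codon = transcript[pos : pos + 3]
            if len(codon) < 3:
                break
            if codon in STOP_CODONS:
                if pos - run_start > best[1] - best[0]:
                    best = (run_start, pos)
                run_start = pos + 3
        end = phase + ((n - phase) // 3) * 3
        if end - run_start > best[1] - best[0]:
            best = (run_start, end)
    return CdsCall(
        start=best[0], end=best[1], frame=best[0] % 3,
        source=CdsSource.LONGEST_ORF, has_start=False, has_stop=False,
        completeness_fraction=(best[1] - best[0]) / ortholog_cds_length if ortholog_cds_length else 0.0,
    )


def classify_completeness(call: CdsCall) -> CdsStatus:
    """ORF-status classes: full length requires both start and stop codons."""
    if call.has_start and call.has_stop:
        return CdsStatus.FULL_LENGTH
    if call.has_stop:
        return CdsStatus.PARTIAL_5P
    if call.has_start:
        return CdsStatus.PARTIAL_3P
    return CdsStatus.INTERNAL


def identify_cds(
    transcript: str,
    reference: ReferenceTranscript,
    ortholog_table: OrthologTable | None = None,
    predictor: GenePredictor | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    end_slack: int = 6,
    start_search: int = 90,
) -> CdsCall:
    """Full CDS identification with strict fallback order:
    ortholog windows, then predictor, then longest ORF."""
    windows = build_windows(transcript, reference, ortholog_table, scheme)
    calls: list[CdsCall] = []
    for window in windows:
        calls.extend(
            validate_frames(transcript, window, reference.selenoprotein, end_slack, start_search)
        )
    if calls:
        return choose_call(calls)
    call = predictor_fallback(transcript, reference, predictor, scheme)
    if call is not None:
        return call
    return longest_orf(transcript, len(reference.cds))
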