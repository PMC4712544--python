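"""CDS identification: window transfer, frame validation, fallbacks."""

import pytest

from orthocat import cds
from orthocat.model import (
    CdsSource,
    CdsStatus,
    OrthologTable,
    ReferenceTranscript,
    STOP_CODONS,
    translate,
)

from conftest import mutate, random_dna


def _cds_seq(rng, n_codons, seleno=False):
    codons = []
    while len(codons) < n_codons - 2:
        c = random_dna(rng, 3)
        if c not in STOP_CODONS and c != "ATG":
            codons.append(c)
    if seleno:
        codons[len(codons) // 2] = "TGA"
    return "ATG" + "".join(codons) + "TAA"


def _reference(rng, n_codons=120, seleno=False):
    cds_seq = _cds_seq(rng, n_codons, seleno)
    utr5, utr3 = random_dna(rng, 80), random_dna(rng, 120)
    return ReferenceTranscript(
        accession="ref1", gene_symbol="G1", mrna=utr5 + cds_seq + utr3,
        cds_start=80, cds_end=80 + len(cds_seq), selenoprotein=seleno,
    )


class TestBuildWindows:
    def test_planted_cds_window_recovered(self, rng):
        ref = _reference(rng)
        transcript = random_dna(rng, 100) + ref.cds + random_dna(rng, 50)
        windows = cds.build_windows(transcript, ref)
        assert (windows[0].start, windows[0].end) == (100, 100 + len(ref.cds))

    def test_most_similar_isoform_chosen_per_species(self, rng):
        ref = _reference(rng)
        table = OrthologTable()
        similar = mutate(rng, ref.cds, 0.05)
        distant = mutate(rng, ref.cds, 0.35)
        table.add("G1", "spB", "iso_similar", similar)
        table.add("G1", "spB", "iso_distant", distant)
        transcript = random_dna(rng, 60) + ref.cds + random_dna(rng, 60)
        windows = cds.build_windows(transcript, ref, table)
        spB = [w for w in windows if w.species == "spB"]
        assert [w.accession for w in spB] == ["iso_similar"]

    def test_window_spans_scaffold_gap(self, rng):
        ref = _reference(rng)
        gapped = ref.cds[:150] + "N" * 30 + ref.cds[180:]
        transcript = random_dna(rng, 50) + gapped + random_dna(rng, 50)
        windows = cds.build_windows(transcript, ref)
        assert windows and windows[0].start == 50
        assert windows[0].end == 50 + len(gapped)

    def test_unalignable_gives_empty_list(self, rng):
        assert cds.build_windows(random_dna(rng, 300), _reference(rng)) == []


class TestValidateFrames:
    def test_clean_frame_full_length(self):
        transcript = "ATGAAACCCTGA"
        window = cds.OrthologWindow("ref", "a", 0, 12, 12, 12)
        calls = cds.validate_frames(transcript, window)
        best = cds.choose_call(calls)
        assert (best.start, best.end, best.frame) == (0, 12, 0)
        assert best.has_start and best.has_stop

    def test_premature_stop_in_every_frame_invalidates(self, rng):
        ref = _reference(rng, 60)
        broken = list(ref.cds)
        broken[90:93] = "TAA"  # internal stop in the planted frame
        transcript = "".join(broken)
        window = cds.OrthologWindow("ref", "a", 0, len(transcript), 100, len(ref.cds))
        calls = cds.validate_frames(transcript, window)
        assert all(c.frame != 0 for c in calls)

    def test_selenoprotein_internal_tga_tolerated(self, rng):
        ref = _reference(rng, 80, seleno=True)
        assert "TGA" in [ref.cds[i:i+3] for i in range(0, len(ref.cds), 3)][1:-1]
        transcript = ref.mrna
        window = cds.OrthologWindow("reference", ref.accession, ref.cds_start,
                                    ref.cds_end, 100, len(ref.cds))
        calls = cds.validate_frames(transcript, window, selenoprotein=True)
        best = cds.choose_call(calls)
        assert (best.start, best.end) == (ref.cds_start, ref.cds_end)
        assert best.has_start and best.has_stop
        # the same window without the selenoprotein flag must reject frame 0
        non_seleno = cds.validate_frames(transcript, window, selenoprotein=False)
        assert all(c.frame != 0 for c in non_seleno)

    def test_n_codons_treated_as_coding(self):
        transcript = "ATGAAANNNCCCTGA"
        window = cds.OrthologWindow("ref", "a", 0, 15, 15, 15)
        best = cds.choose_call(cds.validate_frames(transcript, window))
        assert (best.start, best.end) == (0, 15)
        assert best.spans_gap

    def test_start_extension_upstream(self):
        # window begins 6 nt into the true CDS; ATG found upstream in frame
        transcript = "CCATGAAAAAACCCTGACC"
        window = cds.OrthologWindow("ref", "a", 8, 17, 15, 15)
        best = cds.choose_call(cds.validate_frames(transcript, window))
        assert best.start == 2 and best.has_start


class TestChooseCall:
    def _call(self, frac, has_start=True, has_stop=True, length=90, frame=0):
        return cds.CdsCall(
            start=0, end=length, frame=frame, source=CdsSource.ORTHOLOG_WINDOW,
            has_start=has_start, has_stop=has_stop, completeness_fraction=frac,
        )

    def test_highest_completeness_wins(self):
        assert cds.choose_call([self._call(0.6), self._call(0.95)]).completeness_fraction == 0.95

    def test_tie_broken_by_terminus_count(self):
        a = self._call(0.9, has_start=False)
        b = self._call(0.9)
        assert cds.choose_call([a, b]) is b

    def test_single_call_identity(self):
        c = self._call(0.5)
        assert cds.choose_call([c]) is c

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cds.choose_call([])


def brute_force_orfs(seq):
    """Independent ORF enumeration: every ATG..stop pair in frame with no
    intermediate stop."""
    orfs = []
    n = len(seq)
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= n:
            codon = seq[j : j + 3]
            if codon in STOP_CODONS and j > i:
                orfs.append((i, j + 3))
                break
            j += 3
    # keep maximal ORFs only (drop nested same-stop ORFs with later starts)
    maximal = {}
    for i, j in orfs:
        if j not in maximal or i < maximal[j]:
            maximal[j] = i
    return sorted((i, j) for j, i in maximal.items())


class TestLongestOrf:
    def test_simple_orf(self):
        call = cds.longest_orf("CCATGAAATGACC")
        assert (call.start, call.end) == (2, 11)
        assert call.source == CdsSource.LONGEST_ORF

    def test_no_atg_longest_stop_free_stretch(self):
        seq = "CCCTAACCCCCCCCCCCC"
        call = cds.longest_orf(seq)
        assert not call.has_start and not call.has_stop
        assert cds.classify_completeness(call) == CdsStatus.INTERNAL

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            seq = random_dna(rng, rng.randint(60, 400))
            expected = brute_force_orfs(seq)
            call = cds.longest_orf(seq)
            if expected:
                best = max(expected, key=lambda iv: (iv[1] - iv[0], -iv[0]))
                assert (call.start, call.end) == best
            else:
                assert not call.has_start


class TestClassify:
    @pytest.mark.parametrize(
        "has_start,has_stop,expected",
        [
            (True, True, CdsStatus.FULL_LENGTH),
            (False, True, CdsStatus.PARTIAL_5P),
            (True, False, CdsStatus.PARTIAL_3P),
            (False, False, CdsStatus.INTERNAL),
        ],
    )
    def test_total_function(self, has_start, has_stop, expected):
        call = cds.CdsCall(0, 9, 0, CdsSource.ORTHOLOG_WINDOW, has_start, has_stop, 1.0)
        assert cds.classify_completeness(call) == expected


class TestFallbackOrder:
    class CountingPredictor:
        def __init__(self):
            self.calls = 0

        def __call__(self, sequence):
            self.calls += 1
            return cds.NaivePredictor()(sequence)

    def test_predictor_not_consulted_when_windows_succeed(self, rng):
        ref = _reference(rng)
        predictor = self.CountingPredictor()
        call = cds.identify_cds(ref.mrna, ref, predictor=predictor)
        assert call.source == CdsSource.ORTHOLOG_WINDOW
        assert predictor.calls == 0

    def test_predictor_consulted_when_windows_fail(self, rng):
        ref = _reference(rng)
        predictor = self.CountingPredictor()
        unrelated = random_dna(rng, 100) + _cds_seq(rng, 100) + random_dna(rng, 80)
        call = cds.identify_cds(unrelated, ref, predictor=predictor)
        assert predictor.calls == 1
        assert call.source == CdsSource.PREDICTOR

    def test_longest_orf_when_both_fail(self, rng):
        ref = _reference(rng)
        # no window alignment and no ORF long enough for the predictor
        junk = "CCCTAA" * 40
        call = cds.identify_cds(junk, ref, predictor=cds.NaivePredictor())
        assert call.source == CdsSource.LONGEST_ORF

    def test_every_emitted_call_translates_cleanly(self, rng):
        for seleno in (False, True):
            ref = _reference(rng, 100, seleno=seleno)
            transcript = random_dna(rng, 40) + ref.cds + random_dna(rng, 60)
            call = cds.identify_cds(transcript, ref)
            protein = translate(transcript[call.start : call.end], seleno)
            assert "*" not in protein[:-1]
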