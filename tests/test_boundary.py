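"""3'-end evidence tracks, fuzzy combination and clipping."""

import itertools

import numpy as np
import pytest

from orthocat import boundary

from conftest import random_dna


def _no_motif_seq(rng, length):
    """Random sequence scrubbed of poly(A) signal motifs."""
    while True:
        seq = random_dna(rng, length)
        if not any(m in seq for m in boundary.POLYA_MOTIFS):
            return seq


class TestPolyaSignalTrack:
    def test_single_motif_window(self, rng):
        seq = _no_motif_seq(rng, 200)
        p = 100
        seq = seq[:p] + "AATAAA" + seq[p + 6 :]
        track = boundary.scan_polya_signals(seq)
        assert (track[p + 16 : p + 36] == 1.0).all()
        assert track[p + 15] == 0.0 and track[p + 36] == 0.0

    def test_no_motif_all_zero(self, rng):
        assert not boundary.scan_polya_signals(_no_motif_seq(rng, 300)).any()

    def test_overlapping_windows_take_max(self, rng):
        seq = _no_motif_seq(rng, 200)
        seq = seq[:80] + "AATAAA" + seq[86:90] + "ATTAAA" + seq[96:]
        track = boundary.scan_polya_signals(seq)
        # strongest motif wins on the overlap of the two windows
        assert track[100] == 1.0


class TestCoverageDropTrack:
    def test_step_function_peaks_at_drop(self):
        cov = np.array([10.0] * 100 + [0.0] * 100)
        track = boundary.coverage_drop_track(cov, window=25)
        assert track[100] > 0.99
        assert track[50] < 0.05 and track[150] < 0.05

    def test_uniform_coverage_is_flat_zero(self):
        track = boundary.coverage_drop_track(np.full(200, 7.0), window=25)
        assert track.max() < 1e-9

    def test_half_drop_scores_half(self):
        cov = np.array([10.0] * 100 + [5.0] * 100)
        track = boundary.coverage_drop_track(cov, window=25)
        assert track[100] == pytest.approx(0.5, abs=0.01)

    def test_all_zero_coverage_warns_and_zeroes(self):
        assert not boundary.coverage_drop_track(np.zeros(50)).any()


class TestPolyaReadTrack:
    def test_counts_normalized_by_peak(self):
        track = boundary.polya_read_track(600, {499: 10, 300: 5})
        assert track[499] == 1.0 and track[300] == 0.5

    def test_no_reads_all_zero(self):
        assert not boundary.polya_read_track(100, {}).any()

    def test_sam_tail_purity_rule(self, tmp_path, rng):
        """Reads ending with soft-clipped tails: only >=90%-A tails of
        length >=5 support their end position."""
        ref = random_dna(rng, 120)
        sam = tmp_path / "r.sam"
        body = ref[40:100]
        rows = [
            ("good", body + "A" * 8, "60M8S"),        # supports pos 99
            ("impure", body + "AAAAG", "60M5S"),      # 80% A: rejected
            ("short", body + "AAAA", "60M4S"),        # tail too short
            ("nosoft", body, "60M"),                   # no tail at all
        ]
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\n@SQ\tSN:t1\tLN:120\n")
            for name, seq, cigar in rows:
                fh.write(f"{name}\t0\tt1\t41\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n")
        supports = boundary.tail_supports_from_sam(sam, "t1")
        assert supports == {99: 1}


class TestTerminusTrack:
    def test_triangular_peak_at_terminus(self, rng):
        ortholog = random_dna(rng, 400)
        seq = random_dna(rng, 100) + ortholog[-200:]
        track = boundary.terminus_track(seq, ortholog)
        peak = int(np.argmax(track))
        assert peak == len(seq) - 1 - 0 or track[len(seq) - 1] == track.max()
        # symmetric triangular shoulders of half-width 10
        assert track[peak] == pytest.approx(1.0)
        for off in (3, 7):
            lo, hi = peak - off, peak + off
            if hi < len(seq):
                assert track[lo] == pytest.approx(track[hi])

    def test_absent_terminus_is_zero(self, rng):
        assert not boundary.terminus_track(random_dna(rng, 200), random_dna(rng, 400)).any()


class TestFuzzyCombine:
    def _tracks(self, n, values):
        arrays = [np.full(n, v) for v in values]
        return boundary.FeatureTrack(*arrays)

    def test_all_zero_gives_zero_all_one_gives_one(self):
        assert boundary.fuzzy_combine(self._tracks(5, [0, 0, 0, 0]))[0] == 0.0
        assert boundary.fuzzy_combine(self._tracks(5, [1, 1, 1, 1]))[0] == pytest.approx(1.0)

    def test_monotone_in_every_feature_on_grid(self):
        """Raising any single feature never lowers the combined score."""
        grid = [0.0, 0.2, 0.5, 0.8, 1.0]
        for values in itertools.product(grid, repeat=4):
            base = boundary.fuzzy_combine(self._tracks(1, list(values)))[0]
            for k in range(4):
                for bump in (0.1, 0.3):
                    raised = list(values)
                    raised[k] = min(1.0, raised[k] + bump)
                    up = boundary.fuzzy_combine(self._tracks(1, raised))[0]
                    assert up >= base - 1e-12

    def test_bounded_unit_interval(self, rng):
        prng = np.random.default_rng(3)
        tracks = boundary.FeatureTrack(*[prng.random(50) for _ in range(4)])
        combined = boundary.fuzzy_combine(tracks)
        assert (combined >= 0).all() and (combined <= 1).all()

    def test_length_mismatch_is_hard_error(self):
        with pytest.raises(ValueError):
            boundary.FeatureTrack(np.zeros(5), np.zeros(4), np.zeros(5), np.zeros(5))

    def test_unavailable_features_renormalized(self):
        tracks = self._tracks(3, [1.0, 0.0, 0.0, 1.0])
        combined = boundary.fuzzy_combine(
            tracks, available={"drop": False, "reads": False})
        assert combined[0] == pytest.approx(1.0)


class TestClip3Prime:
    def test_below_threshold_no_clip(self):
        combined = np.full(200, 0.3)
        assert boundary.clip_3prime(200, 90, combined) is None

    def test_best_position_kept_inclusive(self):
        combined = np.zeros(200)
        combined[150] = 0.9
        decision = boundary.clip_3prime(200, 90, combined)
        assert decision.position == 151 and decision.end == "3p"

    def test_peak_inside_cds_ignored(self):
        combined = np.zeros(200)
        combined[50] = 1.0   # inside CDS: must be ignored
        combined[160] = 0.7  # downstream alternative
        decision = boundary.clip_3prime(200, 90, combined)
        assert decision.position == 161


class TestClip5Prime:
    def test_promoter_clip(self):
        decision = boundary.clip_5prime(cds_start=200, promoter_end=50)
        assert decision.position == 50 and decision.end == "5p"

    def test_no_promoter_no_clip(self):
        assert boundary.clip_5prime(200, None) is None

    def test_promoter_overlapping_cds_clamped(self):
        decision = boundary.clip_5prime(cds_start=40, promoter_end=60)
        assert decision.position == 40


class TestSplitIntercoding:
    def test_midpoint_without_evidence(self):
        cuts = boundary.split_intercoding([(0, 300), (500, 800)], np.zeros(800))
        assert cuts == [(400, 0.0, "intercoding_center")]

    def test_evidence_position_takes_precedence(self):
        combined = np.zeros(800)
        combined[380] = 0.8
        cuts = boundary.split_intercoding([(0, 300), (500, 800)], combined)
        assert cuts == [(380, 0.8, "intercoding_split")]

    def test_three_cds_regions_two_cuts(self):
        cuts = boundary.split_intercoding(
            [(0, 100), (200, 300), (400, 500)], np.zeros(500))
        assert [c[0] for c in cuts] == [150, 350]

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError):
            boundary.split_intercoding([(0, 300), (200, 500)], np.zeros(500))


class TestEndToEndClipping:
    def test_planted_cleavage_sites_recovered(self, rng):
        """Transcripts built as UTR+CDS+UTR+signal+polyA+trailing sequence
        with simulated coverage and tailed reads clip within +-10 nt of the
        planted site in >=90% of seeded fixtures."""
        prng = np.random.default_rng(11)
        hits = 0
        trials = 40
        for _ in range(trials):
            utr5 = _no_motif_seq(rng, 60)
            cds_len = 300
            body = _no_motif_seq(rng, cds_len)
            utr3 = _no_motif_seq(rng, 150)
            mrna = utr5 + body + utr3
            site = len(mrna)
            mrna = mrna[: site - 26] + "AATAAA" + mrna[site - 20 :]
            seq = mrna + "A" * 25 + _no_motif_seq(rng, 100)
            cov = np.concatenate([
                prng.poisson(30, size=site), prng.poisson(0.5, size=len(seq) - site)
            ]).astype(float)
            tracks = boundary.FeatureTrack(
                boundary.scan_polya_signals(seq),
                boundary.coverage_drop_track(cov),
                boundary.polya_read_track(len(seq), {site - 1: 10}),
                boundary.terminus_track(seq, mrna),
            )
            combined = boundary.fuzzy_combine(tracks)
            decision = boundary.clip_3prime(len(seq), 60 + cds_len, combined)
            assert decision is not None
            assert decision.position > 60 + cds_len  # never inside the CDS
            if abs(decision.position - site) <= 10:
                hits += 1
        assert hits / trials >= 0.9
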