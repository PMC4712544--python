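"""Ortholog-guided scaffolding: greedy cover optimality and reconstruction."""

import itertools
import random

import numpy as np
import pytest

from orthocat.align import fit_align
from orthocat.scaffold import (
    FragmentPlacement,
    build_scaffold,
    collect_candidates,
    greedy_min_cover,
)
from orthocat.model import TranscriptContig

from conftest import random_dna


def _placement(cid, t0, t1, template):
    """A synthetic placement backed by an exact fragment of the template."""
    frag = template[t0:t1]
    fit = fit_align(frag, template)
    assert (fit.template_start, fit.template_end) == (t0, t1)
    return FragmentPlacement(contig_id=cid, fit=fit, sequence=frag)


def _interval_placement(cid, t0, t1):
    """A placement carrying only interval information (greedy uses nothing
    else); the fragment maps base-for-base onto [t0, t1)."""
    from orthocat.align import FitResult

    fit = FitResult(
        score=t1 - t0, frag_start=0, frag_end=t1 - t0, template_start=t0,
        template_end=t1, identity=1.0, aligned_length=t1 - t0,
        mapping=np.arange(t0, t1),
    )
    return FragmentPlacement(contig_id=cid, fit=fit, sequence="A" * (t1 - t0))


def exhaustive_min_cover_size(core_mask: int, masks: list[int], target: int) -> int:
    """Smallest subset of candidate interval masks whose union (with the
    core) covers ``target``; brute force over all subsets."""
    best = None
    for k in range(len(masks) + 1):
        for combo in itertools.combinations(range(len(masks)), k):
            u = core_mask
            for i in combo:
                u |= masks[i]
            if u & target == target:
                return k
    raise AssertionError("target not coverable")


class TestGreedyMinCover:
    def test_two_flank_fragments_complete_the_cover(self, rng):
        template = random_dna(rng, 100)
        core = (40, 60)
        cands = [_placement("a", 0, 45, template), _placement("b", 55, 100, template)]
        selected = greedy_min_cover(core, cands, 100)
        assert {p.contig_id for p in selected} == {"a", "b"}

    def test_spec_of_largest_gain_first(self, rng):
        template = random_dna(rng, 100)
        core = (0, 10)
        cands = [
            _placement("A", 5, 50, template),
            _placement("B", 45, 100, template),
            _placement("D", 8, 95, template),
        ]
        selected = greedy_min_cover(core, cands, 100)
        assert [p.contig_id for p in selected] == ["D", "B"]

    def test_candidates_inside_core_add_nothing(self, rng):
        template = random_dna(rng, 100)
        cands = [_placement("a", 20, 40, template)]
        assert greedy_min_cover((0, 80), cands, 100) == []

    def test_cardinality_matches_exhaustive_oracle_on_random_instances(self):
        """On interval instances, greedy-selected cardinality equals the
        brute-force minimum subset achieving the same coverage."""
        prng = random.Random(99)
        for _trial in range(80):
            n = prng.randint(1, 8)
            ivs = []
            for _ in range(n):
                a = prng.randint(0, 55)
                b = prng.randint(a + 2, min(60, a + prng.randint(3, 30)))
                ivs.append((a, b))
            core = (20, 30)
            cands = [_interval_placement(f"c{i}", a, b) for i, (a, b) in enumerate(ivs)]
            selected = greedy_min_cover(core, cands, 60)
            covered = np.zeros(60, dtype=bool)
            covered[core[0] : core[1]] = True
            for p in selected:
                covered[p.template_start : p.template_end] = True
            target = sum(1 << i for i in range(60) if covered[i])
            core_mask = sum(1 << i for i in range(core[0], core[1]))
            masks = [sum(1 << i for i in range(a, b)) for a, b in ivs]
            assert len(selected) == exhaustive_min_cover_size(core_mask, masks, target)

    def test_monotone_coverage(self, rng):
        template = random_dna(rng, 100)
        cands = [_placement("a", 0, 30, template), _placement("b", 50, 90, template)]
        sel1 = greedy_min_cover((30, 50), cands[:1], 100)
        sel2 = greedy_min_cover((30, 50), cands, 100)
        cov = lambda sel: sum(p.template_end - p.template_start for p in sel) + 20
        assert cov(sel2) >= cov(sel1)


class TestBuildScaffold:
    def test_gap_sized_by_template_span(self, rng):
        template = random_dna(rng, 100)
        core = _placement("core", 0, 40, template)
        frag = _placement("f", 70, 100, template)
        seq, plan = build_scaffold(core, [frag], template, "G")
        assert seq == template[0:40] + "N" * 30 + template[70:100]
        assert plan.gap_lengths == [30]

    def test_adjacent_placements_have_no_gap(self, rng):
        template = random_dna(rng, 100)
        seq, plan = build_scaffold(
            _placement("core", 0, 50, template),
            [_placement("f", 50, 100, template)], template, "G")
        assert seq == template
        assert plan.gap_lengths == []

    def test_overlap_cut_at_template_midpoint(self, rng):
        template = random_dna(rng, 100)
        seq, plan = build_scaffold(
            _placement("core", 0, 60, template),
            [_placement("f", 40, 100, template)], template, "G")
        # junction at template 50: exact fragments reconstruct the source
        assert seq == template
        frags = [p for p in plan.parts if p.kind == "fragment"]
        assert frags[0].frag_end == 50 and frags[1].frag_start == 10

    def test_reconstruction_of_fragmented_mrnas(self, rng):
        """Fragmenting a known mRNA into >=3 pieces with 10-50 nt gaps and
        scaffolding recovers the source outside N runs, with N runs exactly
        matching the planted gaps."""
        for _ in range(5):
            mrna = random_dna(rng, rng.randint(600, 1200))
            k = rng.randint(3, 5)
            gaps = [rng.randint(10, 50) for _ in range(k - 1)]
            bounds, pos = [], 0
            usable = len(mrna) - sum(gaps)
            piece = usable // k
            for i in range(k):
                end = pos + piece if i < k - 1 else pos + usable - piece * (k - 1)
                bounds.append((pos, end))
                pos = end + (gaps[i] if i < k - 1 else 0)
            placements = [_placement(f"p{i}", a, b, mrna) for i, (a, b) in enumerate(bounds)]
            core, rest = placements[0], placements[1:]
            selected = greedy_min_cover(core.template_interval, rest, len(mrna))
            seq, plan = build_scaffold(core, selected, mrna, "G")
            assert plan.gap_lengths == gaps
            assert len(seq) == len(mrna)
            non_n = [i for i, ch in enumerate(seq) if ch != "N"]
            matches = sum(seq[i] == mrna[i] for i in non_n)
            assert matches / len(non_n) >= 0.99

    def test_provenance_covers_every_base(self, rng):
        template = random_dna(rng, 200)
        core = _placement("core", 0, 80, template)
        frag = _placement("f", 120, 200, template)
        seq, plan = build_scaffold(core, [frag], template, "G")
        assert sum(p.length for p in plan.parts) == len(seq)

    def test_collect_candidates_orients_minus_fragments(self, rng):
        from orthocat.model import reverse_complement

        template = random_dna(rng, 400)
        frag = TranscriptContig("f", reverse_complement(template[100:250]))
        placements = collect_candidates(template, [(frag, "-")])
        assert len(placements) == 1
        assert placements[0].template_interval == (100, 250)

    def test_unrelated_candidate_dropped(self, rng):
        template = random_dna(rng, 400)
        frag = TranscriptContig("f", random_dna(rng, 150))
        assert collect_candidates(template, [(frag, "+")]) == []
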