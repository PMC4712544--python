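"""Gene-symbol assignment: reciprocity, rescue, orientation, fusion handling."""

import itertools

import pytest

from orthocat import assign
from orthocat.align import AlignmentHit
from orthocat.model import (
    Assignment,
    AssignmentClass,
    ReferenceTranscript,
    TranscriptContig,
    reverse_complement,
    translate,
)
from orthocat.simulate import SimConfig, generate_contigs, generate_reference

from conftest import mutate, random_dna


def _hit(subject, score, length=100, q0=0):
    return AlignmentHit(
        query_id="q", subject_id=subject, q_start=q0, q_end=q0 + length,
        s_start=0, s_end=length, strand="+", score=score, identity=0.9,
        aligned_length=length,
    )


class TestBestPerQuery:
    def test_top_score_wins(self):
        assert assign.best_per_query([("r1", _hit("r1", 100)), ("r2", _hit("r2", 50))])[0] == "r1"

    def test_tie_broken_by_aligned_length(self):
        hits = [("r1", _hit("r1", 100, length=80)), ("r2", _hit("r2", 100, length=90))]
        assert assign.best_per_query(hits)[0] == "r2"

    def test_full_tie_broken_lexicographically(self):
        hits = [("rB", _hit("rB", 100)), ("rA", _hit("rA", 100))]
        assert assign.best_per_query(hits)[0] == "rA"

    def test_empty_gives_none(self):
        assert assign.best_per_query([]) is None


def _mrna(rng, cds, utr5=60, utr3=80):
    return random_dna(rng, utr5) + cds + random_dna(rng, utr3), utr5


def _make_world(rng, cds_list):
    """References + contigs where contig k is a mutated copy of mRNA k."""
    refs, contigs = [], []
    for k, cds in enumerate(cds_list):
        mrna, cds_start = _mrna(rng, cds)
        refs.append(
            ReferenceTranscript(
                accession=f"r{k}", gene_symbol=f"G{k}", mrna=mrna,
                cds_start=cds_start, cds_end=cds_start + len(cds), partial=False,
            )
        )
        contigs.append(TranscriptContig(f"c{k}", mutate(rng, mrna, 0.03)))
    return refs, contigs


def _random_cds(rng, n_codons):
    codons = []
    while len(codons) < n_codons - 2:
        c = random_dna(rng, 3)
        if c not in ("TAA", "TAG", "TGA", "ATG"):
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


def brute_force_reciprocity(matrix, contigs, references):
    """Exhaustive check of the BBH predicate over all (contig, ref) pairs."""
    pairs = set()
    for c, r in itertools.product(contigs, references):
        fwd = matrix.forward.get((c.id, r.accession))
        if fwd is None:
            continue
        best_f = assign.best_per_query(matrix.contig_hits(c.id))
        best_r = assign.best_per_query(matrix.reference_hits(r.accession))
        if best_f and best_f[0] == r.accession and best_r and best_r[0] == c.id:
            pairs.add((c.id, r.accession))
    return pairs


class TestAssignBBH:
    def test_paralog_score_matrix_pairs_correctly(self, rng):
        refs, contigs = _make_world(rng, [_random_cds(rng, 120), _random_cds(rng, 120)])
        matrix = assign.compute_hit_matrix(contigs, refs)
        got = {(a.contig_id, a.reference_accession) for a in assign.assign_bbh(contigs, refs, matrix)}
        assert got == brute_force_reciprocity(matrix, contigs, refs) == {("c0", "r0"), ("c1", "r1")}

    def test_non_reciprocal_pair_not_assigned(self):
        matrix = assign.HitMatrix()
        c1, c2 = TranscriptContig("c1", "A" * 50), TranscriptContig("c2", "A" * 50)
        r1 = ReferenceTranscript("r1", "G1", "ATGAAATAA" + "C" * 30, 0, 9)
        # c1's best is r1, but r1's best is c2
        matrix.forward[("c1", "r1")] = _hit("r1", 80)
        matrix.forward[("c2", "r1")] = _hit("r1", 95)
        matrix.reverse[("c1", "r1")] = _hit("c1", 80)
        matrix.reverse[("c2", "r1")] = _hit("c2", 95)
        got = assign.assign_bbh([c1, c2], [r1], matrix)
        assert [(a.contig_id, a.reference_accession) for a in got] == [("c2", "r1")]

    def test_identical_protein_paralogs_separate_on_nucleotide_level(self):
        """Calmodulin-like scenario: one protein, three CDSs differing only at
        synonymous sites; nucleotide BBH must keep the members apart."""
        cfg = SimConfig(
            n_genes=3, seed=5, paralog_families=1, paralog_family_size=3,
            seleno_count=0, fragmented_genes=0, fused_pairs=0,
            intron_retained_genes=0, vector_inserted_genes=0,
        )
        refs, _table = generate_reference(cfg)
        proteins = {translate(r.cds) for r in refs}
        assert len(proteins) == 1  # identical proteins
        assert len({r.cds for r in refs}) == 3  # distinct nucleotide CDSs
        contigs, truth, _ = generate_contigs(refs, cfg)
        matrix = assign.compute_hit_matrix(contigs, refs)
        assignments = assign.assign_bbh(contigs, refs, matrix)
        assert len(assignments) == 3
        for a in assignments:
            planted = truth.contigs[a.contig_id].genes
            assert [a.gene_symbol] == planted

    def test_partial_bijection(self, rng):
        refs, contigs = _make_world(rng, [_random_cds(rng, 100) for _ in range(4)])
        matrix = assign.compute_hit_matrix(contigs, refs)
        got = assign.assign_bbh(contigs, refs, matrix)
        assert len({a.contig_id for a in got}) == len(got)
        assert len({a.reference_accession for a in got}) == len(got)


class TestAssignSBH:
    def _leftover_world(self, rng):
        refs, contigs = _make_world(rng, [_random_cds(rng, 100) for _ in range(2)])
        matrix = assign.compute_hit_matrix(contigs, refs)
        return refs, contigs, matrix

    def test_single_leftover_rescued(self, rng):
        refs, contigs, matrix = self._leftover_world(rng)
        bbh = assign.assign_bbh([contigs[0]], refs, matrix)  # only c0 entered BBH
        sbh = assign.assign_sbh(contigs, refs, matrix, bbh)
        assert [(a.contig_id, a.reference_accession, a.klass) for a in sbh] == [
            ("c1", "r1", AssignmentClass.SBH)
        ]

    def test_conflicting_contigs_resolved_by_score(self, rng):
        refs, contigs = _make_world(rng, [_random_cds(rng, 100)])
        twin = TranscriptContig("c0b", contigs[0].sequence[:200])  # weaker copy
        all_contigs = contigs + [twin]
        matrix = assign.compute_hit_matrix(all_contigs, refs)
        sbh = assign.assign_sbh(all_contigs, refs, matrix, [])
        assert len(sbh) == 1 and sbh[0].contig_id == "c0"

    def test_near_tie_is_ambiguous(self):
        matrix = assign.HitMatrix()
        matrix.forward[("c1", "r1")] = _hit("r1", 100)
        matrix.forward[("c1", "r2")] = _hit("r2", 99)  # within 0.98 margin
        c1 = TranscriptContig("c1", "A" * 50)
        refs = [
            ReferenceTranscript("r1", "G1", "ATGAAATAA" + "C" * 30, 0, 9),
            ReferenceTranscript("r2", "G2", "ATGCCCTAA" + "C" * 30, 0, 9),
        ]
        assert assign.assign_sbh([c1], refs, matrix, []) == []


class TestOrient:
    def _assignment(self, strand):
        return Assignment("c1", "r1", "G1", AssignmentClass.BBH, 100, strand)

    def test_plus_strand_unchanged(self):
        c = TranscriptContig("c1", "ACGTACGT")
        oriented, a = assign.orient(c, self._assignment("+"))
        assert oriented.sequence == c.sequence and oriented.oriented

    def test_minus_strand_reverse_complemented(self, rng):
        seq = random_dna(rng, 300)
        c = TranscriptContig("c1", seq)
        oriented, a = assign.orient(c, self._assignment("-"))
        assert oriented.sequence == reverse_complement(seq)
        assert a.strand == "+"

    def test_interval_remap_arithmetic(self):
        # [10,20) on a length-100 contig lands at [80,90) after orientation
        length, start, end = 100, 10, 20
        assert (length - end, length - start) == (80, 90)


class TestMultiGene:
    def _fusion_world(self, rng, n_genes=2):
        cds_list = [_random_cds(rng, 150) for _ in range(n_genes)]
        refs = []
        mrnas = []
        for k, cds in enumerate(cds_list):
            mrna, cds_start = _mrna(rng, cds)
            mrnas.append(mrna)
            refs.append(ReferenceTranscript(f"r{k}", f"G{k}", mrna, cds_start, cds_start + len(cds)))
        fusion = TranscriptContig("fusion", "".join(mrnas))
        return refs, fusion, mrnas

    def test_planted_fusion_yields_two_regions(self, rng):
        refs, fusion, mrnas = self._fusion_world(rng)
        assignment = Assignment("fusion", "r0", "G0", AssignmentClass.BBH, 100, "+")
        regions = assign.detect_multi_gene(fusion, assignment, refs)
        assert [r.gene_symbol for r in regions] == ["G0", "G1"]
        assert regions[1].start >= len(mrnas[0]) - 50

    def test_single_gene_contig_single_region(self, rng):
        refs, _, mrnas = self._fusion_world(rng)
        contig = TranscriptContig("c", mrnas[0])
        assignment = Assignment("c", "r0", "G0", AssignmentClass.BBH, 100, "+")
        regions = assign.detect_multi_gene(contig, assignment, refs)
        assert [r.gene_symbol for r in regions] == ["G0"]

    def test_read_through_locus_contigs_report_planted_gene_counts(self, rng):
        """A three-gene read-through locus: every fusion variant must report
        exactly as many regions as genes it contains."""
        refs, _, mrnas = self._fusion_world(rng, n_genes=3)
        variants = {
            "AB": (mrnas[0] + mrnas[1], 2),
            "BC": (mrnas[1] + mrnas[2], 2),
            "ABC": (mrnas[0] + mrnas[1] + mrnas[2], 3),
            "A": (mrnas[0], 1),
        }
        for name, (seq, expected) in variants.items():
            contig = TranscriptContig(name, seq)
            primary = "r0" if "A" in name else "r1"
            assignment = Assignment(name, primary, primary.replace("r", "G"),
                                    AssignmentClass.BBH, 100, "+")
            regions = assign.detect_multi_gene(contig, assignment, refs)
            assert len(regions) == expected, name

    def test_split_copies_carry_full_sequence_and_distinct_ids(self, rng):
        refs, fusion, _ = self._fusion_world(rng)
        assignment = Assignment("fusion", "r0", "G0", AssignmentClass.BBH, 100, "+")
        regions = assign.detect_multi_gene(fusion, assignment, refs)
        copies = assign.split_multi_gene(fusion, regions)
        assert [c.id for c, _ in copies] == ["fusion~1", "fusion~2"]
        assert all(c.sequence == fusion.sequence for c, _ in copies)
        assert {r.gene_symbol for _, r in copies} == {"G0", "G1"}

    def test_single_region_is_identity(self, rng):
        refs, _, mrnas = self._fusion_world(rng)
        contig = TranscriptContig("c", mrnas[0])
        region = assign.GeneRegion("c", 0, 100, "G0", "r0", 100)
        assert assign.split_multi_gene(contig, [region]) == [(contig, region)]
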