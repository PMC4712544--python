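"""Validation harness: measures the package against independent oracles
and planted fixture truth.

Each function recomputes one headline property from scratch — generating
its own inputs from a seed, running the relevant stage(s), and measuring
the outcome against an oracle (full Smith-Waterman via Biopython,
exhaustive subset search, brute-force enumeration) or against the
generator's planted truth. Used by the test suite and by the repository's
acceptance script; all randomness is derived from the given seed.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import replace

import numpy as np

from . import boundary as boundary_mod
from . import cds as cds_mod
from .align import FitResult, local_hits
from .assign import assign_bbh, assign_sbh, best_per_query, compute_hit_matrix
from .model import ReferenceTranscript, reverse_complement
from .pipeline import PipelineConfig, run
from .scaffold import FragmentPlacement, build_scaffold, greedy_min_cover
from .simulate import SimConfig, generate_contigs, generate_reference, write_fixture_bundle
from .stats import n50

__all__ = [
    "sw_oracle_agreement",
    "bbh_symbol_recovery",
    "greedy_cover_optimality",
    "scaffold_reconstruction",
    "cds_recovery",
    "fusion_handling",
    "boundary_clipping",
    "n50_agreement",
    "pipeline_determinism",
]


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    return "".join(
        rng.choice([b for b in "ACGT" if b != ch]) if rng.random() < rate else ch
        for ch in seq
    )


def sw_oracle_agreement(seed: int, n_pairs: int = 200) -> dict:
    """Fraction of random pairs (<=300 nt) where the top local hit equals the
    full Smith-Waterman optimum computed by Biopython's PairwiseAligner."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7  # open + first extension, matching our accounting
    aligner.extend_gap_score = -2

    rng = random.Random(seed)
    agree = 0
    for trial in range(n_pairs):
        q = _random_dna(rng, rng.randint(30, 300))
        s = _random_dna(rng, rng.randint(30, 300))
        if trial % 3 == 0:  # plant a diverged homologous block
            i = rng.randint(0, max(0, len(s) - 60))
            q = (q[:10] + _mutate(rng, s[i : i + 60], 0.08) + q[10:])[:300]
        hits = local_hits(q, s)
        top = hits[0].score if hits else 0
        oracle = max(aligner.score(s, q), aligner.score(s, reverse_complement(q)))
        agree += int(top == oracle)
    return {"agree_pct": 100.0 * agree / n_pairs, "n": n_pairs}


def bbh_symbol_recovery(seed: int) -> dict:
    """Assignment accuracy on 50 genes including three identical-protein
    paralog families, contigs diverged 5% from the reference; BBH pairs are
    additionally checked against a brute-force reciprocity predicate."""
    cfg = SimConfig(
        n_genes=50, seed=seed, paralog_families=3, paralog_family_size=3,
        seleno_count=5, fragmented_genes=0, fused_pairs=0,
        intron_retained_genes=0, vector_inserted_genes=0,
    )
    references, _ = generate_reference(cfg)
    contigs, truth, _ = generate_contigs(references, cfg)
    matrix = compute_hit_matrix(contigs, references)
    bbh = assign_bbh(contigs, references, matrix)
    assignments = bbh + assign_sbh(contigs, references, matrix, bbh)
    correct = sum(
        1 for a in assignments if truth.contigs[a.contig_id].genes == [a.gene_symbol]
    )
    violations = 0
    for a in bbh:
        best_f = best_per_query(matrix.contig_hits(a.contig_id))
        best_r = best_per_query(matrix.reference_hits(a.reference_accession))
        if best_f[0] != a.reference_accession or best_r[0] != a.contig_id:
            violations += 1
    return {
        "recovery_pct": 100.0 * correct / len(contigs),
        "reciprocity_violations": violations,
        "n": len(contigs),
    }


def _interval_placement(cid: str, t0: int, t1: int) -> FragmentPlacement:
    fit = FitResult(
        score=t1 - t0, frag_start=0, frag_end=t1 - t0, template_start=t0,
        template_end=t1, identity=1.0, aligned_length=t1 - t0,
        mapping=np.arange(t0, t1),
    )
    return FragmentPlacement(contig_id=cid, fit=fit, sequence="A" * (t1 - t0))


def greedy_cover_optimality(seed: int, n_instances: int = 500) -> dict:
    """Greedy fragment selection vs exhaustive minimum subset on random
    interval instances (<=12 candidates on a 60-position template)."""
    rng = random.Random(seed)
    optimal = 0
    for _ in range(n_instances):
        n = rng.randint(1, 12)
        ivs = []
        for _ in range(n):
            a = rng.randint(0, 55)
            b = min(60, a + rng.randint(3, 30))
            ivs.append((a, b))
        core = (rng.randint(0, 40), 0)
        core = (core[0], core[0] + rng.randint(5, 15))
        cands = [_interval_placement(f"c{i}", a, b) for i, (a, b) in enumerate(ivs)]
        selected = greedy_min_cover(core, cands, 60)
        covered = core[1] - core[0]
        mask_core = ((1 << core[1]) - 1) ^ ((1 << core[0]) - 1)
        target = mask_core
        for p in selected:
            target |= ((1 << p.template_end) - 1) ^ ((1 << p.template_start) - 1)
        masks = [((1 << b) - 1) ^ ((1 << a) - 1) for a, b in ivs]
        best = None
        for k in range(len(masks) + 1):
            for combo in itertools.combinations(range(len(masks)), k):
                u = mask_core
                for i in combo:
                    u |= masks[i]
                if u & target == target:
                    best = k
                    break
            if best is not None:
                break
        optimal += int(len(selected) == best)
    return {"optimal_pct": 100.0 * optimal / n_instances, "n": n_instances}


def scaffold_reconstruction(seed: int, n_mrnas: int = 20) -> dict:
    """Fragment known mRNAs into 3-5 pieces with 10-50 nt gaps, scaffold
    them back, and check N-run lengths (exact) and non-N identity."""
    rng = random.Random(seed)
    gaps_exact = 0
    identities = []
    for _ in range(n_mrnas):
        mrna = _random_dna(rng, rng.randint(600, 1200))
        k = rng.randint(3, 5)
        gaps = [rng.randint(10, 50) for _ in range(k - 1)]
        usable = len(mrna) - sum(gaps)
        piece = usable // k
        bounds, pos = [], 0
        for i in range(k):
            end = pos + piece if i < k - 1 else pos + usable - piece * (k - 1)
            bounds.append((pos, end))
            pos = end + (gaps[i] if i < k - 1 else 0)
        placements = []
        from .align import fit_align

        for i, (a, b) in enumerate(bounds):
            fit = fit_align(mrna[a:b], mrna)
            placements.append(FragmentPlacement(f"p{i}", fit, mrna[a:b]))
        core, rest = placements[0], placements[1:]
        selected = greedy_min_cover(core.template_interval, rest, len(mrna))
        seq, plan = build_scaffold(core, selected, mrna, "G")
        gaps_exact += int(plan.gap_lengths == gaps and len(seq) == len(mrna))
        non_n = [i for i, ch in enumerate(seq) if ch != "N"]
        identities.append(sum(seq[i] == mrna[i] for i in non_n) / len(non_n))
    return {
        "gap_exact_pct": 100.0 * gaps_exact / n_mrnas,
        "non_n_identity_pct": 100.0 * float(np.mean(identities)),
        "n": n_mrnas,
    }


def cds_recovery(seed: int, n_genes: int = 100) -> dict:
    """Window-route CDS identification on fixture transcripts with planted
    CDSs (five selenoproteins among them), plus stop-codon discipline:
    selenoprotein in-frame UGA accepted, non-selenoprotein internal stops
    rejected."""
    cfg = SimConfig(
        n_genes=n_genes, seed=seed, paralog_families=0, paralog_family_size=3,
        seleno_count=5, fragmented_genes=0, fused_pairs=0,
        intron_retained_genes=0, vector_inserted_genes=0,
    )
    references, _ = generate_reference(cfg)
    contigs, truth, _ = generate_contigs(references, cfg)
    by_symbol = {r.gene_symbol: r for r in references}
    exact = 0
    seleno_total = seleno_ok = 0
    n_eval = 0
    rejected = total_broken = 0
    rng = random.Random(seed + 1)
    for ct in truth.contigs.values():
        symbol = ct.genes[0]
        ref = by_symbol[symbol]
        transcript = ct.sense_sequence
        planted = ct.cds_intervals[symbol]
        windows = cds_mod.build_windows(transcript, ref)
        calls = []
        for w in windows:
            calls.extend(cds_mod.validate_frames(transcript, w, ref.selenoprotein))
        n_eval += 1
        if calls:
            call = cds_mod.choose_call(calls)
            hit = (call.start, call.end) == tuple(planted)
            exact += int(hit)
            if ref.selenoprotein:
                seleno_total += 1
                seleno_ok += int(hit)
        # premature-stop rejection: corrupt a non-selenoprotein CDS
        if not ref.selenoprotein and total_broken < 20:
            s, e = planted
            mid = s + ((e - s) // 2 // 3) * 3
            broken = transcript[:mid] + "TAA" + transcript[mid + 3 :]
            bcalls = []
            for w in cds_mod.build_windows(broken, ref):
                bcalls.extend(cds_mod.validate_frames(broken, w, False))
            in_frame = [c for c in bcalls if c.start % 3 == s % 3 and c.end > mid + 3 and c.start < mid]
            rejected += int(not in_frame)
            total_broken += 1
    return {
        "window_exact_pct": 100.0 * exact / n_eval,
        "seleno_accept_pct": 100.0 * seleno_ok / seleno_total if seleno_total else 0.0,
        "premature_stop_reject_pct": 100.0 * rejected / total_broken,
        "n": n_eval,
    }


def _scrub_polya_motifs(seq: str) -> str:
    """Remove poly(A) signal motifs by a single-base substitution (AAT->AAC
    style edits cannot create stop codons in any frame)."""
    for motif in boundary_mod.POLYA_MOTIFS:
        while motif in seq:
            i = seq.index(motif)
            seq = seq[: i + 2] + "C" + seq[i + 3 :]
    return seq


def fusion_handling(seed: int, n_pairs: int = 20) -> dict:
    """Two-gene fusion contigs must split into two entries, each carrying
    its full planted CDS; the cut falls at the intercoding midpoint without
    poly(A) evidence and at the planted cleavage site with evidence."""
    # -- evidence-present route: full pipeline on a fusion-only scenario
    import tempfile
    from pathlib import Path

    cfg = SimConfig(
        n_genes=2 * n_pairs, seed=seed, paralog_families=0, seleno_count=0,
        fragmented_genes=0, fused_pairs=n_pairs, intron_retained_genes=0,
        vector_inserted_genes=0,
    )
    with tempfile.TemporaryDirectory() as tmp:
        bundle = write_fixture_bundle(cfg, Path(tmp) / "fix")
        result = run(PipelineConfig(
            contigs=str(bundle["contigs"]), reference_fasta=str(bundle["reference_fasta"]),
            reference_tsv=str(bundle["reference_tsv"]), coverage=str(bundle["coverage"]),
            reads=str(bundle["reads"]), out_dir=str(Path(tmp) / "out"),
            vecscreen=False,
        ))
        import json

        truth = json.loads(bundle["truth"].read_text())
    by_symbol = {e.gene_symbol: e for e in result.entries}
    fused = [ct for ct in truth["contigs"].values() if "fused" in ct["defects"]]
    split_ok = cds_ok = site_ok = 0
    for ct in fused:
        entries = [by_symbol.get(g) for g in ct["genes"]]
        if all(e is not None for e in entries):
            split_ok += 1
        else:
            continue
        good = True
        for g, e in zip(ct["genes"], entries):
            gene = truth["genes"][g]
            if gene["mrna"][gene["cds_start"] : gene["cds_end"]] not in e.sequence:
                good = False
        cds_ok += int(good)
        first = entries[0]
        site_a = ct["cleavage_sites"][ct["genes"][0]]
        if abs(len(first.sequence) - site_a) <= 10:
            site_ok += 1

    # -- no-evidence route: fusions of motif-scrubbed mRNAs, module level
    rng = random.Random(seed + 7)
    refs2, _ = generate_reference(replace(cfg, seed=seed + 1))
    midpoint_ok = 0
    pairs = [(refs2[2 * i], refs2[2 * i + 1]) for i in range(n_pairs)]
    for ra, rb in pairs:
        mrna_a = _scrub_polya_motifs(ra.mrna)
        mrna_b = _scrub_polya_motifs(rb.mrna)
        fusion_seq = mrna_a + mrna_b
        iv_a = (ra.cds_start, ra.cds_end)
        iv_b = (len(mrna_a) + rb.cds_start, len(mrna_a) + rb.cds_end)
        cuts = boundary_mod.split_intercoding(
            [iv_a, iv_b], np.zeros(len(fusion_seq)))
        midpoint = (iv_a[1] + iv_b[0]) // 2
        midpoint_ok += int(cuts[0][0] == midpoint and cuts[0][2] == "intercoding_center")
    return {
        "split_pct": 100.0 * split_ok / len(fused),
        "cds_intact_pct": 100.0 * cds_ok / len(fused),
        "evidence_cut_within10_pct": 100.0 * site_ok / max(split_ok, 1),
        "midpoint_exact_pct": 100.0 * midpoint_ok / n_pairs,
        "n": len(fused),
    }


def boundary_clipping(seed: int, n_fixtures: int = 100) -> dict:
    """Randomized transcripts (UTR+CDS+UTR+signal+poly(A)+trailing sequence)
    with simulated coverage and tailed reads: the 3' clip must land within
    +-10 nt of the planted cleavage site and never inside the CDS."""
    rng = random.Random(seed + 13)
    prng = np.random.default_rng(seed + 13)
    within = 0
    cds_violations = 0
    clipped = 0
    for _ in range(n_fixtures):
        utr5 = _scrub_polya_motifs(_random_dna(rng, rng.randint(40, 100)))
        body = _scrub_polya_motifs(_random_dna(rng, 3 * rng.randint(80, 200)))
        utr3 = _scrub_polya_motifs(_random_dna(rng, rng.randint(80, 200)))
        mrna = utr5 + body + utr3
        site = len(mrna)
        mrna = mrna[: site - 26] + "AATAAA" + mrna[site - 20 :]
        seq = mrna + "A" * 25 + _random_dna(rng, rng.randint(60, 150))
        cds_end = len(utr5) + len(body)
        cov = np.concatenate([
            prng.poisson(30, size=site), prng.poisson(0.5, size=len(seq) - site)
        ]).astype(float)
        tracks = boundary_mod.FeatureTrack(
            boundary_mod.scan_polya_signals(seq),
            boundary_mod.coverage_drop_track(cov),
            boundary_mod.polya_read_track(len(seq), {site - 1: 10}),
            boundary_mod.terminus_track(seq, mrna),
        )
        combined = boundary_mod.fuzzy_combine(tracks)
        decision = boundary_mod.clip_3prime(len(seq), cds_end, combined)
        if decision is None:
            continue
        clipped += 1
        if decision.position <= cds_end:
            cds_violations += 1
        if abs(decision.position - site) <= 10:
            within += 1
    return {
        "clip_within10_pct": 100.0 * within / n_fixtures,
        "clips_inside_cds": cds_violations,
        "clipped": clipped,
        "n": n_fixtures,
    }


def n50_agreement(seed: int, n_lists: int = 1000) -> dict:
    """n50 against a brute-force scan over all candidate lengths."""
    rng = random.Random(seed + 17)
    agree = 0
    for _ in range(n_lists):
        lengths = [rng.randint(1, 5000) for _ in range(rng.randint(1, 60))]
        total = sum(lengths)
        brute = None
        for L in sorted(set(lengths), reverse=True):
            if 2 * sum(x for x in lengths if x >= L) >= total:
                brute = L
                break
        result = n50(lengths)
        agree += int(result == brute and result in lengths)
    return {"agree_pct": 100.0 * agree / n_lists, "n": n_lists}


def pipeline_determinism(seed: int, workdir) -> dict:
    """Two full runs on the standard mixed-defect bundle must be
    byte-identical; also reports headline catalog numbers."""
    from pathlib import Path

    workdir = Path(workdir)
    cfg = SimConfig(n_genes=50, seed=seed)
    bundle = write_fixture_bundle(cfg, workdir / "fix")

    def one_run(out):
        return run(PipelineConfig(
            contigs=str(bundle["contigs"]), reference_fasta=str(bundle["reference_fasta"]),
            reference_tsv=str(bundle["reference_tsv"]),
            ortholog_table=str(bundle["ortholog_table"]),
            ortholog_cds=str(bundle["ortholog_cds"]), vector_db=str(bundle["vector"]),
            coverage=str(bundle["coverage"]), reads=str(bundle["reads"]),
            out_dir=str(out),
        ))

    r1 = one_run(workdir / "out1")
    r2 = one_run(workdir / "out2")
    identical = all(
        (workdir / "out1" / name).read_bytes() == (workdir / "out2" / name).read_bytes()
        for name in ["transcripts.fa", "cds.fa", "catalog.gff3", "catalog.tsv",
                     "assignments.tsv", "scaffolds.tsv", "summary.json"]
    )
    s = r1.summary
    return {
        "identical": int(identical),
        "transcripts": s.transcript_count,
        "genes": s.gene_count,
        "full_length": s.cds_status_counts.get("full_length", 0),
        "catalog_n50": s.n50,
        "scaffolded_genes": s.scaffolded_gene_count,
        "median_fold_increase": s.median_fold_increase,
        "n": s.contig_count,
    }
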