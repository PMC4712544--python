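# Methods

This note records the models, parameter choices and numerical conventions
behind `orthocat`, and what the synthetic fixtures do and do not show
about real data.

## Coordinates and sequence model

All internal coordinates are 0-based half-open; GFF3 output converts to
1-based inclusive at write time and the converters are inverse bijections.
Sequences are over {A,C,G,T,N}; any other symbol is collapsed to N on
input (with a count) rather than rejected, because assembler output
contains at most N as an ambiguity code. Codons containing N are treated
as non-stop ("coding") during frame validation and flagged, so a CDS may
legitimately span a scaffold N gap.

## Alignment engine

The package ships its own nucleotide aligner rather than shelling out to
BLASTN/MAFFT/needle: the external tools are interchangeable engines, not
part of the method, and an internal engine makes results reproducible and
testable. An adapter protocol (the `AlignmentHit` contract) accepts an
external aligner for production-scale runs.

* **Scoring.** match +1, mismatch −2, affine gaps with cost
  `open + k·extend` for a length-`k` gap (open −5, extend −2), word size
  11 — megablast-like, appropriate for orthologs at roughly ≥ 85%
  nucleotide identity (within-rodent to human–rodent range). All
  configurable.
* **`local_hits`.** Below a cell-count cutoff (default 512×512 = 262 144
  cells) the exact affine Smith–Waterman DP runs on the full matrix, so on
  small instances the top hit *is* the global optimum of the local
  alignment problem. Above the cutoff, shared 11-mers are grouped into
  diagonal bands, each band's padded bounding box gets the exact DP, and
  near-duplicate hits from overlapping boxes are pruned. Distant repeats
  of the same subject on one query therefore surface as separate hits,
  which multi-gene detection requires. Ties sort by aligned length, then
  position, for determinism.
* **`fit_align`.** Fragment-onto-template placement is an overlap (free
  end-gap) alignment: both sequence overhangs are penalty-free, internal
  gaps are affine. The result carries a per-base fragment→template map
  used for scaffold junction cuts. Results scoring below
  `min_score_fraction` (default 0.3–0.4 by caller) of the maximum
  attainable are reported unalignable.
* **`terminus_align`** locally aligns the final ≤ 50 nt of the ortholog
  mRNA and normalizes by the maximum attainable score; normalized scores
  below 0.4 are indistinguishable from chance alignments of random
  50-mers (which score ≈ 0.2–0.25) and yield no evidence.

The DP kernels are numba-compiled; Biopython's `PairwiseAligner`
(configured identically) serves as the independent oracle in the test
suite, never as the engine.

## Assignment

BBH runs contig → reference-CDS and CDS → full-contig; a pair is assigned
only under strict reciprocity, which makes the result a partial bijection
by construction. SBH rescue requires the runner-up hit to fall below 0.98
of the top score — "single best hit" taken literally would assign
arbitrarily between near-tied paralogs. Multi-gene detection reports hits
to other genes overlapping the primary orthologous region by less than
0.2 of the hit span, at least 100 nt long and scoring ≥ 60; copies carry
the full sequence and the physical cut is deferred to boundary refinement,
matching the stage order (fusion detection precedes boundary
identification). All thresholds are configuration.

## Scaffolding

Candidates are unassigned contigs with hits to an identified ortholog,
fit-aligned to the ortholog mRNA. Selection uses the classical optimal
interval-cover greedy: take the leftmost reachable-but-uncovered template
position and, among candidates covering it, the one reaching furthest
right. For interval instances this provably attains the minimum
cardinality for the coverage it reaches — which is what "minimum number of
fragments spanning most of the reference" asks for; a max-new-coverage
rule was evaluated and discarded because it is suboptimal on
counterexample instances (two flanking fragments beaten to the punch by a
centered one). No minimum-span threshold is enforced; scaffolds covering
under 50% of the ortholog are flagged in the log.

Junctions: disjoint consecutive placements are separated by an N run of
exactly the intervening template span, so scaffold coordinates track the
ortholog frame; overlapping placements are cut at the template midpoint of
their overlap, each side contributing its aligned half (symmetric and
deterministic; nothing in the data prefers either fragment). The
outermost placements keep their unaligned overhangs — UTR sequence the
ortholog frame does not cover. Fragments whose orientation conflicts with
their hit strand are dropped rather than re-oriented, since mis-oriented
fragments are more likely spurious hits.

## CDS identification

The primary route transfers ortholog CDS windows: the assigned reference
CDS and, per extra species in the ortholog table, the isoform most similar
to the reference CDS (by alignment score). Frames over the window are
validated with ±6 nt end slack: a stop earlier than `window.end − 3 −
slack` disqualifies the frame; UGA is exempt when the reference flags the
gene as a selenoprotein (selenoprotein status comes from the reference
annotation, not de novo SECIS detection). The start is extended upstream
in-frame to the nearest ATG within 90 nt (transfer jitter from UTR
alignment rarely exceeds this), and the end runs to the first stop at or
beyond the window end. Among valid calls the one most complete relative
to its ortholog CDS length wins; ties break on present termini, then
length, then frame index.

Fallbacks are strict: a predictor adapter is consulted only when no
window yields a valid frame, and the longest ORF only when the predictor
also fails. The built-in predictor is deliberately naive — maximal ORFs ≥
150 nt scored by length with a small Kozak-context bonus, no promoter
calls — and any external tool returning intervals can replace it through
the same contract. "Most similar prediction" is measured as the
nucleotide alignment score between the predicted region and the ortholog
CDS.

## mRNA boundaries

Four per-position tracks in [0,1]:

* **signal** — each poly(A) motif occurrence deposits its weight on the
  positions 10–30 nt downstream of the motif end (cleavage happens in
  that window); strongest motif wins per position. Default table: AATAAA
  1.0, ATTAAA 0.8, ten common single-base variants 0.5.
* **drop** — `clamp(1 − mean(cov[i:i+w]) / max(mean(cov[i−w:i]), ε))`
  with w = 25; positions whose upstream window averages below one read
  score zero, because a drop needs coverage to drop *from* (otherwise an
  uncovered tail is a wall of perfect drops).
* **reads** — a read supports the position of its last aligned base if
  its 3' soft-clip is ≥ 5 bases of ≥ 90% A; counts are normalized by the
  per-transcript maximum.
* **terminus** — the normalized ortholog-terminus score as a triangular
  peak of half-width 10 at the aligned end.

Each track passes a piecewise-linear membership ramp (0 below 0.1, 1
above 0.9) and the memberships combine as a weighted sum (signal 0.3,
drop 0.2, reads 0.3, terminus 0.2) — monotone in every feature and
bounded in [0,1]. When an evidence source is unavailable for an entry
(no coverage/reads supplied, or a scaffolded sequence whose coordinates no
longer match the read alignments) its weight is redistributed over the
remaining features. The 3' clip takes the best position at or past the
stop codon when the combined score reaches 0.5, keeping the supported end
inclusive; a clip can never remove CDS bases of the entry's own gene.
Multi-CDS transcripts are cut within each intercoding interval at the
best supported position, else at the center. 5' clipping follows a
predicted promoter's downstream edge and is a no-op under the built-in
predictor. The ramp shapes, weights and the 0.5 threshold are stated
configuration defaults in line with common poly(A)-site practice, not
fitted values. Whether the poly(A) tail itself survives clipping is
convention; we keep bases up to and including the supported cleavage
position.

Read evidence coordinates refer to sense-oriented transcripts
(re-alignment happens after orientation), so the pipeline applies
coverage and tail supports after orienting each contig.

## Redundancy reduction and vector screen

Clustering is off by default: on real assemblies collapsing near-identical
contigs risks merging paralogs or joining neighbors, and the one-to-one
assignment removes redundancy anyway. When enabled, greedy longest-first
clustering joins a contig to the first representative it matches at ≥ 95%
identity over ≥ 90% of its own length. The vector screen annotates and
never masks; category bands default to the published VecScreen values
(terminal strong ≥ 24 / moderate ≥ 19 / weak ≥ 16; internal 30/25/23)
applied to this package's scoring scheme — the original criteria are
defined for a different mismatch penalty, so the bands here are a stated
convention, not a claim of NCBI equivalence.

## Synthetic fixtures

The generator builds the full input universe with known truth: a
reference transcriptome (valid CDSs; identical-protein paralog families
made by synonymous codon swaps at probability 0.5; selenoproteins with
one internal in-frame TGA and a non-UGA terminator, since under
read-through a UGA terminator would leave the CDS end undefined),
target-species contigs at 5% divergence (codon-aware inside the CDS:
substitutions creating stops are reverted and start/stop preserved — an
orthologous protein-coding CDS is itself a valid CDS, so free per-base
mutation would be the wrong null model), planted defects (fragmentation
into 3–5 pieces with 10–50 nt gaps, fusions of gene pairs, retained
introns in the 3' UTR, terminal vector insertions, random orientation),
poly(A) tails of 25 nt with a canonical signal 26 nt upstream of the
cleavage site, 80–150 nt of trailing unprocessed sequence, 30× coverage
and 10 tailed reads per site. The standard scenario is 50 genes with
three paralog families of three and five selenoproteins. All randomness
derives from one seed; reruns are byte-identical.

What the fixtures do **not** model: sequencing error profiles, GC and
positional coverage bias, duplicated reads, alternative splicing and
alternative poly(A) sites, genomic paralogy beyond the planted families,
and indel divergence between species. Passing tests therefore demonstrate
the pipeline's structural logic — assignment, splitting, scaffolding,
frame validation, evidence-based clipping — under clean divergence, not
robustness to assembler artifacts beyond those planted. Published
catalog-scale numbers from real organisms (tens of thousands of
transcripts) require real RNA-seq data and are out of scope here; the
acceptance script reports the same statistics on the 50-gene standard
scenario, whose values are properties of that scenario.

## Problem sizes and determinism

Validation measurements use: 200 random pairs ≤ 300 nt for
aligner-oracle agreement; 50 genes for assignment recovery; 500 random
interval instances (≤ 12 candidates, exhaustive subset oracle) for cover
optimality; 20 fragmented mRNAs for scaffold reconstruction; 100
transcripts for CDS recovery; 20 fusion pairs; 100 boundary fixtures;
1000 random length lists for N50. These sizes make every oracle
exhaustive or exact while keeping the whole suite interactive. Everything
downstream of a seed is deterministic: no hash-order dependence, sorted
iteration everywhere, and the full pipeline is byte-identical across
reruns with the same inputs (manifests differ only in recorded timings).

## Known limitations

* Fitting alignment is heuristic above the exact-DP cutoff only in hit
  discovery; a fragment placed by a wrong seed chain would be cut at a
  wrong junction. Not observed on fixtures, but conceivable at high
  divergence.
* SBH rescue inherits BBH's blind spot: a species-specific paralog absent
  from the reference is absorbed into its closest reference gene.
* The intercoding cut of a fusion without any 3'-end evidence is the
  interval midpoint — correct on average, wrong in detail whenever the
  true boundary is asymmetric.
* 5' refinement is only as good as the promoter predictor; with the
  built-in one it never fires.
* Selenoprotein handling trusts the reference flag; a mis-annotated
  reference propagates.
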