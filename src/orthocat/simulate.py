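"""Synthetic reference transcriptomes and defect-planted contig sets.

Every pipeline stage is testable without downloads: the generator builds a
reference transcriptome (valid CDSs, optional selenoproteins with in-frame
UGA, identical-protein paralog families diverged only at synonymous
sites), derives target-species contigs carrying planted defects
(fragmentation, fusion of neighboring genes, intron retention, vector
insertions, random orientation, point divergence, poly(A) tails plus
trailing unprocessed sequence), and emits the read evidence the boundary
stage consumes (per-base coverage as bedGraph, poly(A)-tailed read
alignments as SAM). A truth record accompanies every file so planted
properties can be verified by direct inspection.

Divergence inside a CDS is codon-aware: substitutions that would create a
premature stop are reverted and the start/stop codons are preserved, since
an orthologous protein-coding sequence is itself a valid CDS. UTR bases
mutate freely. Read-evidence coordinates refer to the sense orientation of
each contig (re-alignment happens after orientation in the pipeline).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    OrthologTable,
    ReferenceTranscript,
    STOP_CODONS,
    TranscriptContig,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "GeneTruth",
    "ContigTruth",
    "FixtureTruth",
    "generate_reference",
    "generate_contigs",
    "simulate_read_evidence",
    "write_fixture_bundle",
]

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_SYNONYMS: dict[str, list[str]] = {}
from .model import _CODON_TABLE  # noqa: E402  (internal reuse)

for _codon, _aa in _CODON_TABLE.items():
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, []).append(_codon)


@dataclass
class SimConfig:
    """Study conditions for fixture generation.

    Defaults model a small ortholog-annotation scenario: 50 genes of which
    three families of three paralogs encode identical proteins (synonymous
    divergence only, swap probability 0.5 per codon) and five are
    selenoproteins; contigs diverge 5% per base from the reference; two
    extra ortholog species diverge at 15% of codons; fragmented genes break
    into 3-5 pieces separated by 10-50 nt gaps; cleavage sites carry a
    25 nt poly(A) tail, a planted canonical signal 26 nt upstream, and
    80-150 nt of trailing unprocessed sequence; read evidence is 30x
    coverage and 10 poly(A)-tailed reads per site.
    """

    n_genes: int = 50
    seed: int = 0
    utr5_range: tuple[int, int] = (50, 150)
    cds_codon_range: tuple[int, int] = (100, 400)
    utr3_range: tuple[int, int] = (100, 300)
    paralog_families: int = 3
    paralog_family_size: int = 3
    paralog_swap_prob: float = 0.5
    seleno_count: int = 5
    extra_species: tuple[str, ...] = ("spB", "spC")
    species_codon_divergence: float = 0.15
    contig_divergence: float = 0.05
    fragmented_genes: int = 8
    fragment_pieces: tuple[int, int] = (3, 5)
    fragment_gap_range: tuple[int, int] = (10, 50)
    fused_pairs: int = 4
    intron_retained_genes: int = 3
    vector_inserted_genes: int = 3
    flip_probability: float = 0.5
    polya_tail_length: int = 25
    genomic_tail_range: tuple[int, int] = (80, 150)
    read_depth: int = 30
    tailed_reads_per_site: int = 10
    read_length: int = 60

    def __post_init__(self) -> None:
        needed = (
            self.paralog_families * self.paralog_family_size
            + self.seleno_count
            + self.fragmented_genes
            + 2 * self.fused_pairs
            + self.intron_retained_genes
            + self.vector_inserted_genes
        )
        if needed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for requested defect counts ({needed})"
            )

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 0) -> "SimConfig":
        """Standard scenario scaled down (or up) to ``n_genes`` genes,
        keeping the defect proportions of the 50-gene default."""
        f = n_genes / 50
        families = int(f * 3) if n_genes >= 2 * 3 else 0
        return cls(
            n_genes=n_genes,
            seed=seed,
            paralog_families=families,
            seleno_count=int(f * 5),
            fragmented_genes=max(1, int(f * 8)) if n_genes >= 3 else 0,
            fused_pairs=int(f * 4),
            intron_retained_genes=int(f * 3),
            vector_inserted_genes=int(f * 3),
        )


@dataclass
class GeneTruth:
    symbol: str
    mrna: str  # target-species mRNA (sense)
    cds_start: int
    cds_end: int
    cleavage_site: int  # == len(mrna)
    selenoprotein: bool = False
    paralog_family: int | None = None


@dataclass
class ContigTruth:
    contig_id: str
    genes: list[str]
    defects: list[str]
    flipped: bool
    sense_sequence: str
    cds_intervals: dict[str, tuple[int, int]]  # sense coordinates
    cleavage_sites: dict[str, int] = field(default_factory=dict)
    fragment_interval: tuple[int, int] | None = None  # interval on source mRNA


@dataclass
class FixtureTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    contigs: dict[str, ContigTruth] = field(default_factory=dict)
    fragment_gaps: dict[str, list[int]] = field(default_factory=dict)  # per fragmented gene

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "contigs": {k: asdict(v) for k, v in self.contigs.items()},
            "fragment_gaps": self.fragment_gaps,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls()
        for k, v in payload["genes"].items():
            truth.genes[k] = GeneTruth(**v)
        for k, v in payload["contigs"].items():
            v["cds_intervals"] = {g: tuple(iv) for g, iv in v["cds_intervals"].items()}
            if v.get("fragment_interval"):
                v["fragment_interval"] = tuple(v["fragment_interval"])
            truth.contigs[k] = ContigTruth(**v)
        truth.fragment_gaps = {k: list(v) for k, v in payload["fragment_gaps"].items()}
        return truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = [_SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)]
    stop = sorted(STOP_CODONS)[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _synonymize(rng: np.random.Generator, cds: str, swap_prob: float) -> str:
    """Replace internal codons with synonyms: identical protein, different DNA."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k in range(1, len(codons) - 1):
        if rng.random() < swap_prob:
            options = [c for c in _SYNONYMS[_CODON_TABLE[codons[k]]] if c != codons[k]]
            if options:
                codons[k] = options[rng.integers(0, len(options))]
    return "".join(codons)


def _diverge_codons(rng: np.random.Generator, cds: str, codon_rate: float) -> str:
    """Resample a fraction of internal codons to random non-stop codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for k in range(1, len(codons) - 1):
        if rng.random() < codon_rate:
            codons[k] = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))]
    return "".join(codons)


def _mutate_bases(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Per-base substitutions with nonsense repair: the start codon, the
    terminal stop and the absence of premature stops are preserved."""
    mutated = _mutate_bases(rng, cds, rate)
    codons = [mutated[i : i + 3] for i in range(0, len(mutated), 3)]
    original = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    codons[0] = "ATG"
    codons[-1] = original[-1]
    for k in range(1, len(codons) - 1):
        if codons[k] in STOP_CODONS:
            codons[k] = original[k]
    return "".join(codons)


def generate_reference(cfg: SimConfig) -> tuple[list[ReferenceTranscript], OrthologTable]:
    """Build the reference transcriptome and the multi-species ortholog table.

    Deterministic given the config (seeded generator; no hash-order
    dependence). Paralog family members translate to identical proteins but
    differ in synonymous sites; selenoprotein CDSs carry one internal
    in-frame TGA and the corresponding flag.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    references: list[ReferenceTranscript] = []
    table = OrthologTable()

    symbols = [f"GENE{k:03d}" for k in range(1, cfg.n_genes + 1)]
    # layout: paralog families first, then selenoproteins, then plain genes
    family_of: dict[str, int] = {}
    idx = 0
    family_cds: dict[int, str] = {}
    for fam in range(cfg.paralog_families):
        n_codons = int(rng.integers(*cfg.cds_codon_range))
        family_cds[fam] = _random_cds(rng, n_codons)
        for _ in range(cfg.paralog_family_size):
            family_of[symbols[idx]] = fam
            idx += 1
    seleno_symbols = set(symbols[idx : idx + cfg.seleno_count])

    for symbol in symbols:
        fam = family_of.get(symbol)
        if fam is not None:
            cds = _synonymize(rng, family_cds[fam], cfg.paralog_swap_prob)
        else:
            cds = _random_cds(rng, int(rng.integers(*cfg.cds_codon_range)))
        seleno = symbol in seleno_symbols
        if seleno:
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            k = int(rng.integers(len(codons) // 3, 2 * len(codons) // 3))
            codons[k] = "TGA"
            if codons[-1] == "TGA":
                # the terminator of a selenoprotein CDS must be a non-UGA stop,
                # otherwise read-through leaves the CDS end undefined
                codons[-1] = "TAA"
            cds = "".join(codons)
        utr5 = _random_seq(rng, int(rng.integers(*cfg.utr5_range)))
        utr3 = _random_seq(rng, int(rng.integers(*cfg.utr3_range)))
        mrna = utr5 + cds + utr3
        references.append(
            ReferenceTranscript(
                accession=f"{symbol}.ref",
                gene_symbol=symbol,
                mrna=mrna,
                cds_start=len(utr5),
                cds_end=len(utr5) + len(cds),
                selenoprotein=seleno,
                species="reference",
            )
        )
        for species in cfg.extra_species:
            sp_cds = _diverge_codons(rng, cds, cfg.species_codon_divergence)
            table.add(symbol, species, f"{symbol}.{species}", sp_cds)
    return references, table


def _plant_signal(mrna: str, cds_end: int) -> str:
    """Plant a canonical poly(A) signal 26 nt before the cleavage site."""
    pos = len(mrna) - 26
    if pos < cds_end:
        return mrna
    return mrna[:pos] + "AATAAA" + mrna[pos + 6 :]


def generate_contigs(
    references: list[ReferenceTranscript],
    cfg: SimConfig,
) -> tuple[list[TranscriptContig], FixtureTruth, dict[str, str]]:
    """Derive defect-planted target-species contigs from the reference.

    Returns the contig set, the truth record, and a synthetic vector
    database used for the planted vector insertions.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    truth = FixtureTruth()
    contigs: list[TranscriptContig] = []
    vector_seq = _random_seq(rng, 2000)
    vector_db = {"synthetic_vector": vector_seq}

    # target-species mRNA per gene
    for ref in references:
        utr5 = _mutate_bases(rng, ref.mrna[: ref.cds_start], cfg.contig_divergence)
        cds = _mutate_cds(rng, ref.cds, cfg.contig_divergence)
        utr3 = _mutate_bases(rng, ref.mrna[ref.cds_end :], cfg.contig_divergence)
        mrna = _plant_signal(utr5 + cds + utr3, len(utr5) + len(cds))
        truth.genes[ref.gene_symbol] = GeneTruth(
            symbol=ref.gene_symbol,
            mrna=mrna,
            cds_start=len(utr5),
            cds_end=len(utr5) + len(cds),
            cleavage_site=len(mrna),
            selenoprotein=ref.selenoprotein,
        )

    # defect assignment: draw from plain genes (outside paralog families and
    # selenoproteins) so each planted scenario is attributable
    n_special = cfg.paralog_families * cfg.paralog_family_size + cfg.seleno_count
    plain = [r.gene_symbol for r in references][n_special:]
    pool = list(plain)
    draw = lambda k: [pool.pop(0) for _ in range(k)]  # noqa: E731  (pool is pre-shuffled)
    rng.shuffle(pool)
    fragmented = draw(cfg.fragmented_genes)
    fused = [(draw(1)[0], draw(1)[0]) for _ in range(cfg.fused_pairs)]
    intron_retained = draw(cfg.intron_retained_genes)
    vector_inserted = draw(cfg.vector_inserted_genes)
    fused_symbols = {s for pair in fused for s in pair}

    def emit(contig_id: str, sense_seq: str, genes: list[str], defects: list[str],
             cds_intervals: dict[str, tuple[int, int]],
             cleavage_sites: dict[str, int],
             fragment_interval: tuple[int, int] | None = None) -> None:
        flipped = bool(rng.random() < cfg.flip_probability)
        seq = reverse_complement(sense_seq) if flipped else sense_seq
        if flipped:
            defects = defects + ["reverse_oriented"]
        contigs.append(TranscriptContig(id=contig_id, sequence=seq))
        truth.contigs[contig_id] = ContigTruth(
            contig_id=contig_id, genes=genes, defects=defects, flipped=flipped,
            sense_sequence=sense_seq, cds_intervals=cds_intervals,
            cleavage_sites=cleavage_sites, fragment_interval=fragment_interval,
        )

    def with_tail(gene: GeneTruth) -> tuple[str, int]:
        tail = "A" * cfg.polya_tail_length + _random_seq(
            rng, int(rng.integers(*cfg.genomic_tail_range)))
        return gene.mrna + tail, gene.cleavage_site

    for symbol in sorted(truth.genes):
        gene = truth.genes[symbol]
        if symbol in fused_symbols or symbol in fragmented:
            continue
        if symbol in intron_retained:
            # retained intron inserted mid-3'UTR (structural contamination)
            intron = _random_seq(rng, int(rng.integers(80, 200)))
            at = gene.cds_end + (len(gene.mrna) - gene.cds_end) // 2
            sense = gene.mrna[:at] + intron + gene.mrna[at:]
            seq = sense + "A" * cfg.polya_tail_length + _random_seq(
                rng, int(rng.integers(*cfg.genomic_tail_range)))
            emit(f"contig_{symbol}", seq, [symbol], ["intron_retained", "mutated"],
                 {symbol: (gene.cds_start, gene.cds_end)},
                 {symbol: gene.cleavage_site + len(intron)})
        elif symbol in vector_inserted:
            vstart = int(rng.integers(0, len(vector_seq) - 60))
            vlen = int(rng.integers(40, 60))
            insert = vector_seq[vstart : vstart + vlen]
            seq, site = with_tail(gene)
            sense = insert + seq
            emit(f"contig_{symbol}", sense, [symbol], ["vector_inserted", "mutated"],
                 {symbol: (gene.cds_start + vlen, gene.cds_end + vlen)},
                 {symbol: site + vlen})
        else:
            seq, site = with_tail(gene)
            emit(f"contig_{symbol}", seq, [symbol], ["mutated"],
                 {symbol: (gene.cds_start, gene.cds_end)}, {symbol: site})

    for symbol in fragmented:
        gene = truth.genes[symbol]
        k = int(rng.integers(cfg.fragment_pieces[0], cfg.fragment_pieces[1] + 1))
        # every piece must stay >= 80 nt after removing the gaps
        k = max(2, min(k, (len(gene.mrna) + cfg.fragment_gap_range[1]) // 130))
        gaps = [int(rng.integers(*cfg.fragment_gap_range)) for _ in range(k - 1)]
        usable = len(gene.mrna) - sum(gaps)
        lengths = None
        for _attempt in range(200):  # rejection-sample roughly even pieces
            cuts = np.sort(rng.integers(1, usable, size=k - 1))
            cand = np.diff(np.concatenate([[0], cuts, [usable]]))
            if (cand >= 80).all():
                lengths = cand
                break
        if lengths is None:
            base = usable // k
            lengths = np.array([base] * (k - 1) + [usable - base * (k - 1)])
        truth.fragment_gaps[symbol] = gaps
        pos = 0
        for piece_idx, plen in enumerate(lengths):
            piece = gene.mrna[pos : pos + int(plen)]
            emit(
                f"{symbol}_frag{piece_idx + 1}", piece, [symbol],
                ["fragmented", "mutated"], {}, {},
                fragment_interval=(pos, pos + int(plen)),
            )
            pos += int(plen) + (gaps[piece_idx] if piece_idx < len(gaps) else 0)

    for gene_a, gene_b in fused:
        a, b = truth.genes[gene_a], truth.genes[gene_b]
        sense = a.mrna + b.mrna
        tail = "A" * cfg.polya_tail_length + _random_seq(
            rng, int(rng.integers(*cfg.genomic_tail_range)))
        emit(
            f"fusion_{gene_a}_{gene_b}", sense + tail, [gene_a, gene_b],
            ["fused", "mutated"],
            {gene_a: (a.cds_start, a.cds_end),
             gene_b: (len(a.mrna) + b.cds_start, len(a.mrna) + b.cds_end)},
            {gene_a: a.cleavage_site, gene_b: len(a.mrna) + b.cleavage_site},
        )

    contigs.sort(key=lambda c: c.id)
    return contigs, truth, vector_db


def simulate_read_evidence(
    truth: FixtureTruth,
    cfg: SimConfig,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Simulate the boundary-stage inputs for every contig with a cleavage site.

    Returns per-contig coverage arrays (sense coordinates) and SAM record
    lines (without header) for poly(A)-tailed reads: coverage follows the
    configured depth up to the (last) cleavage site and is near zero after;
    each site gets ``tailed_reads_per_site`` reads whose alignments end at
    the site with a 10 nt soft-clipped poly(A) tail.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))
    coverage: dict[str, np.ndarray] = {}
    sam_lines: list[str] = []
    for contig_id in sorted(truth.contigs):
        ct = truth.contigs[contig_id]
        if not ct.cleavage_sites:
            continue
        seq = ct.sense_sequence
        last_site = max(ct.cleavage_sites.values())
        cov = np.concatenate([
            rng.poisson(cfg.read_depth, size=min(last_site, len(seq))),
            rng.poisson(0.5, size=max(0, len(seq) - last_site)),
        ]).astype(float)
        coverage[contig_id] = cov
        for gene in sorted(ct.cleavage_sites):
            site = ct.cleavage_sites[gene]
            rlen = min(cfg.read_length, site)
            body = seq[site - rlen : site]
            for r in range(cfg.tailed_reads_per_site):
                sam_lines.append(
                    "\t".join([
                        f"{contig_id}.{gene}.tail{r}", "0", contig_id,
                        str(site - rlen + 1), "60", f"{rlen}M10S", "*", "0", "0",
                        body + "A" * 10, "*",
                    ])
                )
    return coverage, sam_lines


def write_fixture_bundle(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete fixture bundle on disk.

    Emits contigs.fa, reference.fa + reference.tsv, orthologs.tsv +
    ortholog_cds.fa, vector.fa, coverage.bedgraph, reads.sam and
    truth.json; the same files the pipeline readers consume. Byte-identical
    across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    references, table = generate_reference(cfg)
    contigs, truth, vector_db = generate_contigs(references, cfg)
    coverage, sam_lines = simulate_read_evidence(truth, cfg)

    paths = {name: out / fname for name, fname in [
        ("contigs", "contigs.fa"), ("reference_fasta", "reference.fa"),
        ("reference_tsv", "reference.tsv"), ("ortholog_table", "orthologs.tsv"),
        ("ortholog_cds", "ortholog_cds.fa"), ("vector", "vector.fa"),
        ("coverage", "coverage.bedgraph"), ("reads", "reads.sam"),
        ("truth", "truth.json"),
    ]}

    with open(paths["contigs"], "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.sequence}\n")
    with open(paths["reference_fasta"], "w") as fh:
        for r in references:
            fh.write(f">{r.accession}\n{r.mrna}\n")
    with open(paths["reference_tsv"], "w") as fh:
        fh.write("accession\tgene_symbol\tcds_start\tcds_end\tselenoprotein\tspecies\n")
        for r in references:
            fh.write(f"{r.accession}\t{r.gene_symbol}\t{r.cds_start}\t{r.cds_end}\t"
                     f"{int(r.selenoprotein)}\t{r.species}\n")
    with open(paths["ortholog_table"], "w") as fh:
        fh.write("gene_symbol\tspecies\taccession\n")
        for gene in table.genes():
            for species, accs in sorted(table.species_for(gene).items()):
                for acc in accs:
                    fh.write(f"{gene}\t{species}\t{acc}\n")
    with open(paths["ortholog_cds"], "w") as fh:
        for gene in table.genes():
            for species, accs in sorted(table.species_for(gene).items()):
                for acc in accs:
                    fh.write(f">{acc}\n{table.sequence(acc)}\n")
    with open(paths["vector"], "w") as fh:
        for vid, vseq in sorted(vector_db.items()):
            fh.write(f">{vid}\n{vseq}\n")
    with open(paths["coverage"], "w") as fh:
        for contig_id in sorted(coverage):
            cov = coverage[contig_id]
            start = 0
            for i in range(1, len(cov) + 1):
                if i == len(cov) or cov[i] != cov[start]:
                    fh.write(f"{contig_id}\t{start}\t{i}\t{cov[start]:g}\n")
                    start = i
    with open(paths["reads"], "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.id}\tLN:{len(c.sequence)}\n")
        for line in sam_lines:
            fh.write(line + "\n")
    truth.to_json(paths["truth"])
    return paths
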