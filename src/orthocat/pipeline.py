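"""End-to-end orchestration of the annotation stages.

Stage order is fixed: primary processing (optional redundancy reduction) ->
gene-symbol assignment (BBH, SBH, orientation, multi-gene detection and
splitting) -> scaffolding -> CDS identification -> mRNA boundary
refinement -> vector screening of the final transcripts -> descriptive
statistics. Each stage writes a plain-text artifact into the output
directory and a manifest records input/output hashes and the parameter
snapshot, so a run is reproducible from its manifest. Reruns with the same
config and inputs are byte-identical (manifests differ only in timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assign as assign_mod
from . import boundary as boundary_mod
from . import cds as cds_mod
from . import cleanup as cleanup_mod
from . import io as io_mod
from . import scaffold as scaffold_mod
from . import stats as stats_mod
from .align import KmerIndex, ScoringScheme, fit_align
from .model import (
    Assignment,
    CatalogEntry,
    ClipRecord,
    ReferenceTranscript,
    TranscriptContig,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run"]


@dataclass
class PipelineConfig:
    """Paths, stage toggles and parameters of one pipeline run."""

    contigs: str
    reference_fasta: str
    reference_tsv: str
    out_dir: str
    ortholog_table: str | None = None
    ortholog_cds: str | None = None
    vector_db: str | None = None
    coverage: str | None = None
    reads: str | None = None
    # stage toggles
    redundancy_reduction: bool = False  # conservative default: keep the primary assembly
    scaffolding: bool = True
    boundary_refinement: bool = True
    vecscreen: bool = True
    # parameters
    seed: int = 0
    min_hit_score: int = 40
    sbh_ambiguity_margin: float = 0.98
    cluster_identity: float = 0.95
    cluster_containment: float = 0.9
    multigene_overlap_fraction: float = 0.2
    multigene_min_length: int = 100
    multigene_min_score: int = 60
    scaffold_min_fit_fraction: float = 0.4
    cds_end_slack: int = 6
    cds_start_search: int = 90
    clip_threshold: float = 0.5
    terminal_margin: int = 25
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 11

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open,
                             self.gap_extend, self.word_size)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def validate_paths(self) -> None:
        for name in ("contigs", "reference_fasta", "reference_tsv", "ortholog_table",
                     "ortholog_cds", "vector_db", "coverage", "reads"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config path {name}={value} does not exist")


@dataclass
class RunManifest:
    parameters: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class _Working:
    """A catalog entry under construction."""

    entry_id: str
    sequence: str
    assignment: Assignment
    reference: ReferenceTranscript
    source_contig_id: str
    region: assign_mod.GeneRegion | None = None
    fusion_group: str | None = None  # source contig id when the contig held >1 gene
    scaffold_plan: scaffold_mod.ScaffoldPlan | None = None
    core_length: int | None = None
    offset: int = 0  # start of this entry's slice on the oriented source contig
    cds_call: cds_mod.CdsCall | None = None
    clips: list[ClipRecord] = field(default_factory=list)


@dataclass
class PipelineResult:
    entries: list[CatalogEntry]
    summary: stats_mod.CatalogSummary
    manifest: RunManifest
    out_dir: Path


def run(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the catalog plus reports."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    manifest = RunManifest(parameters=asdict(config))
    t_start = time.perf_counter()

    def timed(stage: str):
        manifest.timings[stage] = round(time.perf_counter() - t_start, 3)

    # ------------------------------------------------------------------ inputs
    contigs = io_mod.read_contigs(config.contigs)
    references = io_mod.read_reference(config.reference_fasta, config.reference_tsv)
    by_acc = {r.accession: r for r in references}
    ortho_table = None
    if config.ortholog_table and config.ortholog_cds:
        ortho_table = io_mod.read_ortholog_table(config.ortholog_table, config.ortholog_cds)
    for name in ("contigs", "reference_fasta", "reference_tsv", "ortholog_table",
                 "ortholog_cds", "vector_db", "coverage", "reads"):
        value = getattr(config, name)
        if value:
            manifest.inputs[str(value)] = _sha256(value)
    n_contigs_in = len(contigs)

    # ------------------------------------------------- primary processing (ii)
    if config.redundancy_reduction:
        clusters = cleanup_mod.cluster_redundant(
            contigs, config.cluster_identity, config.cluster_containment, scheme
        )
        reps = {c.representative for c in clusters}
        contigs = [c for c in contigs if c.id in reps]
        pd.DataFrame(
            [{"representative": c.representative, "members": ",".join(sorted(c.members))}
             for c in clusters]
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    timed("primary_processing")

    # --------------------------------------------- gene symbol assignment (iii)
    matrix = assign_mod.compute_hit_matrix(contigs, references, scheme, config.min_hit_score)
    bbh = assign_mod.assign_bbh(contigs, references, matrix)
    sbh = assign_mod.assign_sbh(contigs, references, matrix, bbh, config.sbh_ambiguity_margin)
    assignments = bbh + sbh
    by_contig = {c.id: c for c in contigs}
    pd.DataFrame(
        [{"contig_id": a.contig_id, "accession": a.reference_accession,
          "gene_symbol": a.gene_symbol, "class": a.klass.value,
          "score": a.score, "strand": a.strand}
         for a in sorted(assignments, key=lambda a: a.contig_id)]
    ).to_csv(out / "assignments.tsv", sep="\t", index=False)
    timed("assignment")

    # -------------------------------------- orientation + fusion detection (iv)
    ref_indexes = {r.accession: KmerIndex(r.cds, scheme.word_size) for r in references}
    workings: list[_Working] = []
    multigene_rows = []
    assigned_refs = {a.reference_accession for a in assignments}
    for assignment in sorted(assignments, key=lambda a: a.contig_id):
        contig, oriented_assignment = assign_mod.orient(by_contig[assignment.contig_id], assignment)
        regions = assign_mod.detect_multi_gene(
            contig, oriented_assignment, references, scheme,
            config.multigene_overlap_fraction, config.multigene_min_length,
            config.multigene_min_score, ref_indexes,
        )
        copies = assign_mod.split_multi_gene(contig, regions)
        if len(copies) > 1:
            for region in regions:
                multigene_rows.append({
                    "contig_id": contig.id, "gene_symbol": region.gene_symbol,
                    "start": region.start, "end": region.end, "score": region.score,
                })
        claimed: set[str] = set()
        for copy, region in copies:
            if region.gene_symbol == oriented_assignment.gene_symbol:
                entry_assignment = oriented_assignment
            else:
                # secondary gene found on a fusion contig: admit it only if its
                # reference is still unrepresented (one-to-one catalog)
                if region.accession in assigned_refs or region.accession in claimed:
                    continue
                claimed.add(region.accession)
                entry_assignment = Assignment(
                    contig_id=copy.id, reference_accession=region.accession,
                    gene_symbol=region.gene_symbol, klass=oriented_assignment.klass,
                    score=region.score, strand="+",
                )
            workings.append(
                _Working(
                    entry_id=entry_assignment.reference_accession,
                    sequence=copy.sequence,
                    assignment=entry_assignment,
                    reference=by_acc[entry_assignment.reference_accession],
                    source_contig_id=assignment.contig_id,
                    region=region,
                    fusion_group=assignment.contig_id if len(copies) > 1 else None,
                )
            )
        assigned_refs.update(claimed)
    pd.DataFrame(multigene_rows, columns=["contig_id", "gene_symbol", "start", "end", "score"]) \
        .to_csv(out / "multigene.tsv", sep="\t", index=False)
    timed("fusion_detection")

    # --------------------------------------------------------- scaffolding (v)
    scaffold_rows = []
    if config.scaffolding:
        assigned_contig_ids = {a.contig_id for a in assignments}
        unassigned = [c for c in contigs if c.id not in assigned_contig_ids]
        for work in workings:
            if work.fusion_group is not None:
                continue  # fusion copies are split, not extended
            acc = work.assignment.reference_accession
            fragments = []
            for contig in unassigned:
                hit = matrix.forward.get((contig.id, acc))
                if hit is not None:
                    fragments.append((contig, hit.strand))
            if not fragments:
                continue
            mrna = work.reference.mrna
            core_fit = fit_align(work.sequence, mrna, scheme, min_score_fraction=0.2)
            if not core_fit.aligned:
                continue
            core = scaffold_mod.FragmentPlacement(
                contig_id=work.source_contig_id, fit=core_fit, sequence=work.sequence)
            candidates = scaffold_mod.collect_candidates(
                mrna, fragments, scheme, config.scaffold_min_fit_fraction)
            selected = scaffold_mod.greedy_min_cover(
                core.template_interval, candidates, len(mrna))
            if not selected:
                continue
            sequence, plan = scaffold_mod.build_scaffold(
                core, selected, mrna, work.assignment.gene_symbol)
            work.core_length = len(work.sequence)
            work.sequence = sequence
            work.scaffold_plan = plan
            for k, part in enumerate(plan.parts):
                scaffold_rows.append({
                    "gene_symbol": plan.gene_symbol, "part_index": k, "type": part.kind,
                    "contig_id": part.contig_id or ".",
                    "template_start": part.template_start,
                    "template_end": part.template_end, "length": part.length,
                })
    pd.DataFrame(
        scaffold_rows,
        columns=["gene_symbol", "part_index", "type", "contig_id",
                 "template_start", "template_end", "length"],
    ).to_csv(out / "scaffolds.tsv", sep="\t", index=False)
    timed("scaffolding")

    # ------------------------------------------------- CDS identification (vi)
    predictor = cds_mod.NaivePredictor()
    for work in workings:
        work.cds_call = cds_mod.identify_cds(
            work.sequence, work.reference, ortho_table, predictor, scheme,
            config.cds_end_slack, config.cds_start_search,
        )
    timed("cds")

    # ------------------------------------------------- mRNA boundaries (vii)
    if config.boundary_refinement:
        coverage_data = io_mod.read_bedgraph(config.coverage) if config.coverage else {}
        _refine_boundaries(workings, coverage_data, config, scheme)
    timed("boundaries")

    # one-to-one catalog: one entry per reference accession
    final: dict[str, _Working] = {}
    for work in workings:
        acc = work.assignment.reference_accession
        if acc in final and final[acc].assignment.score >= work.assignment.score:
            manifest.warnings.append(f"dropped duplicate entry for {acc}")
            continue
        final[acc] = work
    workings = [final[acc] for acc in sorted(final)]

    entries: list[CatalogEntry] = []
    for work in workings:
        call = work.cds_call
        entries.append(
            CatalogEntry(
                entry_id=work.entry_id,
                gene_symbol=work.assignment.gene_symbol,
                reference_accession=work.assignment.reference_accession,
                sequence=work.sequence,
                cds_start=call.start,
                cds_end=call.end,
                cds_status=cds_mod.classify_completeness(call),
                cds_source=call.source,
                completeness_fraction=call.completeness_fraction,
                clip_records=work.clips,
                scaffold_plan=work.scaffold_plan,
                assignment=work.assignment,
                source_contig_id=work.source_contig_id,
            )
        )

    # ------------------------------------------------------- vecscreen (viii-)
    if config.vecscreen and config.vector_db:
        vector_db = io_mod.read_fasta(config.vector_db)
        flags = cleanup_mod.vecscreen(
            {e.entry_id: e.sequence for e in entries}, vector_db,
            config.terminal_margin, scheme=scheme,
        )
        by_entry: dict[str, list] = {}
        for flag in flags:
            by_entry.setdefault(flag.transcript_id, []).append(flag)
        for entry in entries:
            entry.vector_flags = by_entry.get(entry.entry_id, [])
    timed("vecscreen")

    # ------------------------------------------------------------ stats (viii)
    core_lengths = {w.entry_id: w.core_length for w in workings if w.core_length}
    summary = stats_mod.summarize(entries, n_contigs_in, core_lengths)
    summary.to_json(out / "summary.json")
    files = io_mod.write_catalog(entries, out)
    log.info("catalog summary:\n%s", summary.log_block())
    timed("stats")

    for path in [files.transcripts_fasta, files.cds_fasta, files.gff3, files.summary_tsv,
                 out / "assignments.tsv", out / "multigene.tsv", out / "scaffolds.tsv",
                 out / "summary.json"]:
        manifest.outputs[path.name] = _sha256(path)
    manifest.write(out / "manifest.json")
    return PipelineResult(entries=entries, summary=summary, manifest=manifest, out_dir=out)


def _refine_boundaries(
    workings: list[_Working],
    coverage_data: dict,
    config: PipelineConfig,
    scheme: ScoringScheme,
) -> None:
    """3'/5' clipping and physical separation of fusion copies, in place."""
    supports_cache: dict[str, dict[int, int]] = {}

    def evidence(work: _Working):
        """(coverage intervals | None, tail supports | None) in the coordinates
        of the oriented source contig; None when the evidence does not apply
        (scaffolded sequence, shifted coordinates) or was not provided."""
        if work.scaffold_plan is not None:
            return None, None
        cov = coverage_data.get(work.source_contig_id)
        supports = None
        if config.reads:
            if work.source_contig_id not in supports_cache:
                supports_cache[work.source_contig_id] = boundary_mod.tail_supports_from_sam(
                    config.reads, work.source_contig_id)
            supports = supports_cache[work.source_contig_id]
        return cov, supports

    def combined_track(work: _Working, seq: str, offset: int) -> np.ndarray:
        cov_intervals, supports = evidence(work)
        n = len(seq)
        signal = boundary_mod.scan_polya_signals(seq)
        if cov_intervals is not None:
            length = max(offset + n, max(end for _, end, _ in cov_intervals))
            cov_full = boundary_mod.coverage_from_bedgraph(cov_intervals, length)
            drop = boundary_mod.coverage_drop_track(cov_full)[offset : offset + n]
        else:
            drop = np.zeros(n)
        if supports is not None:
            shifted = {pos - offset: c for pos, c in supports.items() if offset <= pos < offset + n}
            reads = boundary_mod.polya_read_track(n, shifted)
        else:
            reads = np.zeros(n)
        terminus = boundary_mod.terminus_track(seq, work.reference.mrna, scheme=scheme)
        tracks = boundary_mod.FeatureTrack(signal, drop, reads, terminus)
        return boundary_mod.fuzzy_combine(
            tracks,
            available={"drop": cov_intervals is not None, "reads": supports is not None},
        )

    # -- physical separation of fusion copies
    groups: dict[str, list[_Working]] = {}
    for work in workings:
        if work.fusion_group is not None:
            groups.setdefault(work.fusion_group, []).append(work)
    for group in groups.values():
        group.sort(key=lambda w: w.cds_call.start)
        full_len = len(group[0].sequence)
        cds_ivs = [(w.cds_call.start, w.cds_call.end) for w in group]
        if any(a[1] > b[0] for a, b in zip(cds_ivs, cds_ivs[1:])):
            log.warning("fusion group %s: overlapping CDS calls, split skipped",
                        group[0].fusion_group)
            continue
        combined = combined_track(group[0], group[0].sequence, 0)
        cuts = boundary_mod.split_intercoding(cds_ivs, combined, config.clip_threshold)
        bounds = [0] + [c[0] for c in cuts] + [full_len]
        for k, work in enumerate(group):
            lo, hi = bounds[k], bounds[k + 1]
            work.sequence = work.sequence[lo:hi]
            work.offset = lo
            call = work.cds_call
            call.start -= lo
            call.end -= lo
            if k > 0:
                work.clips.append(ClipRecord("5p", lo, cuts[k - 1][2]))
            if k < len(cuts):
                work.clips.append(ClipRecord("3p", full_len - hi, cuts[k][2]))

    # -- 3' clipping at the supported poly(A) position
    for work in workings:
        seq = work.sequence
        combined = combined_track(work, seq, work.offset)
        decision = boundary_mod.clip_3prime(
            len(seq), work.cds_call.end, combined, config.clip_threshold)
        if decision is not None:
            removed = len(seq) - decision.position
            work.sequence = seq[: decision.position]
            work.clips.append(ClipRecord("3p", removed, decision.reason))

    # -- 5' promoter clipping (no-op under the built-in predictor, which
    #    makes no promoter calls)
    for work in workings:
        decision = boundary_mod.clip_5prime(work.cds_call.start, None)
        if decision is not None:
            work.sequence = work.sequence[decision.position :]
            work.cds_call.start -= decision.position
            work.cds_call.end -= decision.position
            work.clips.append(ClipRecord("5p", decision.position, decision.reason))
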