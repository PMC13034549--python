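"""End-to-end orchestration of the design pipeline.

Peak modes: annotation -> peaks (narrowPeak or fallback caller) ->
window selection -> template extraction -> left-primer design ->
transcriptome specificity screen -> per-gene panel optimization ->
reports. Distance mode: 3'-terminal templates -> design -> reports.

"No primers found" for a gene is a reported outcome, never an error;
errors are reserved for configuration and I/O problems.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

from . import __version__
from .annotation import load_annotation, build_transcriptome
from .optimize import (
    CoverageCandidate,
    CoverageInstance,
    PanelSelection,
    greedy_set_cover,
    single_peak_select,
)
from .peaks import (
    call_peaks_fallback,
    coverage_from_bam,
    read_bedgraph,
    read_narrowpeak,
)
from .primers import (
    DesignConstraints,
    FallbackDesigner,
    Primer3Designer,
    design_primers,
    extract_template,
    make_distance_templates,
    template_to_genomic,
)
from .qc import FailureRecord, build_summary, write_failures_tsv
from .specificity import (
    FilterConfig,
    NaiveAligner,
    ExternalAlignerAdapter,
    REASON_OFF_TARGET,
    align_all,
    on_target_perfect_hits,
    three_stage_filter,
)
from .windows import (
    SelectionConfig,
    assign_peaks_to_genes,
    select_windows,
    write_windows_bed,
)

PANEL_COLUMNS = [
    "gene_id", "primer_id", "sequence", "tm", "gc", "chrom",
    "genomic_start", "genomic_end", "strand", "covered_isoforms",
    "dist_to_3prime", "selection_rank",
]


@dataclass
class RunConfig:
    mode: str = "single_peak"  # single_peak | multi_peak | distance
    outdir: str = "tailprimer_out"
    gtf: str | None = None
    genome: str | None = None
    gene_list: str | None = None
    narrowpeak: str | None = None
    bedgraph: str | None = None
    bam: str | None = None
    transcriptome: str | None = None
    tx2gene: str | None = None
    transcripts_fasta: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    constraints: DesignConstraints = field(default_factory=DesignConstraints)
    filter: FilterConfig = field(default_factory=FilterConfig)
    max_primers_per_gene: int = 3
    peak_min_depth: int = 10
    peak_flank: int = 500
    peak_fdr: float = 0.05
    distance_window_nt: int = 200
    distance_excluded_3prime_nt: int = 40
    designer: str = "fallback"  # fallback | primer3
    aligner: str = "naive"  # naive | external
    make_plots: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in {"single_peak", "multi_peak", "distance"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "distance":
            if self.transcripts_fasta is None and not (self.gtf and self.genome):
                raise ValueError(
                    "distance mode needs --transcripts or a GTF + genome"
                )
        else:
            if not (self.gtf and self.genome):
                raise ValueError("peak modes need a GTF and a genome FASTA")
            if not (self.narrowpeak or self.bedgraph or self.bam):
                raise ValueError(
                    "peak modes need peaks (narrowPeak) or coverage "
                    "(bedGraph/BAM) for the fallback caller"
                )
        for p in (self.gtf, self.genome, self.gene_list, self.narrowpeak,
                  self.bedgraph, self.bam, self.transcriptome, self.tx2gene,
                  self.transcripts_fasta):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _get_designer(config: RunConfig):
    return Primer3Designer() if config.designer == "primer3" else FallbackDesigner()


def _get_aligner(config: RunConfig):
    if config.aligner == "external":
        return ExternalAlignerAdapter(max_mm=config.filter.max_mismatches)
    return NaiveAligner(
        max_mm=config.filter.max_mismatches,
        count_antisense=config.filter.count_antisense_hits,
    )


def _read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def _read_tx2gene(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for ln in fh:
            if ln.strip():
                tid, gid = ln.split()[:2]
                out[tid] = gid
    return out


def _read_fasta_dict(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _primer_genomic_span(primer, window):
    g1 = template_to_genomic(window, primer.template_start)
    g2 = template_to_genomic(window, primer.template_end - 1)
    return min(g1, g2), max(g1, g2) + 1


def _write_panel_tsv(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in PANEL_COLUMNS) + "\n")


def _write_primers_fasta(rows, path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(f">{row['primer_id']}\n{row['sequence']}\n")


class RunResult:
    def __init__(self, outdir, summary, panel_rows, failures, rejections,
                 windows=None):
        self.outdir = Path(outdir)
        self.summary = summary
        self.panel_rows = panel_rows
        self.failures = failures
        self.rejections = rejections
        self.windows = windows or []

    @property
    def panel_path(self) -> Path:
        return self.outdir / "panel.tsv"


def run(config: RunConfig) -> RunResult:
    """Execute a full peak-mode or distance-mode run."""
    config.validate()
    if config.mode == "distance":
        return run_distance(config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    requested = _read_gene_list(config.gene_list) if config.gene_list else None
    genes, missing = load_annotation(
        config.gtf, set(requested) if requested else None
    )
    if requested is None:
        requested = sorted(genes)
    failures: list[FailureRecord] = [
        FailureRecord(g, "annotation", "gene_not_in_annotation") for g in missing
    ]

    coverage = None
    if config.narrowpeak:
        peaks = read_narrowpeak(config.narrowpeak)
    else:
        genome_idx = Fasta(config.genome)
        chrom_lengths = {name: len(genome_idx[name]) for name in genome_idx.keys()}
        if config.bedgraph:
            coverage = read_bedgraph(config.bedgraph, chrom_lengths)
        else:
            coverage = coverage_from_bam(config.bam)
        peaks = call_peaks_fallback(
            coverage,
            min_depth=config.peak_min_depth,
            flank=config.peak_flank,
            fdr=config.peak_fdr,
        )

    assigned, n_unassigned_peaks = assign_peaks_to_genes(peaks, genes)
    sel_cfg = dataclasses.replace(config.selection, mode=config.mode)
    windows, win_failures = select_windows(assigned, sel_cfg, genes)
    if coverage is not None:
        win_failures = [
            _refine_coverage_reason(f, genes, coverage, config.peak_min_depth)
            for f in win_failures
        ]
    failures.extend(win_failures)

    genome = Fasta(config.genome)
    designer = _get_designer(config)
    all_candidates = []
    genes_with_candidates = set()
    for w in windows:
        try:
            template = extract_template(w, genome)
            cands = design_primers(
                template, config.constraints, engine=designer,
                gene_id=w.gene_id, window_ref=w,
            )
        except ValueError as exc:
            failures.append(
                FailureRecord(w.gene_id, "primer_design",
                              "sequence complexity preventing primer design",
                              str(exc), peak_name=w.source_peak.name)
            )
            continue
        if not cands:
            failures.append(
                FailureRecord(w.gene_id, "primer_design",
                              "sequence complexity preventing primer design",
                              "engine returned zero candidates",
                              peak_name=w.source_peak.name)
            )
            continue
        all_candidates.extend(cands)
        genes_with_candidates.add(w.gene_id)

    if config.transcriptome and config.tx2gene:
        tx_seqs = _read_fasta_dict(config.transcriptome)
        tx2gene = _read_tx2gene(config.tx2gene)
    else:
        tx_seqs, tx2gene = build_transcriptome(genes, genome)
    tx_len = {tid: len(s) for tid, s in tx_seqs.items()}

    hits = align_all(all_candidates, tx_seqs, tx2gene, engine=_get_aligner(config))
    survivors, rejections = three_stage_filter(hits, all_candidates, config.filter)
    surviving_genes = {p.gene_id for p in survivors}
    rejected_reasons: dict[str, set[str]] = {}
    for pid, reason, _detail in rejections:
        gid = pid.split("|", 1)[0]
        rejected_reasons.setdefault(gid, set()).add(reason)
    for gid in sorted(genes_with_candidates - surviving_genes):
        reasons = rejected_reasons.get(gid, set())
        reason = REASON_OFF_TARGET if REASON_OFF_TARGET in reasons \
            else "no_on_target_hit"
        failures.append(
            FailureRecord(gid, "specificity", reason,
                          "no candidate passed the three-stage filter")
        )

    # panel optimization: coverage sets from perfect on-target binding
    # sites whose 3'-distance lies inside the amplicon bounds
    amp_min = config.constraints.amplicon_min
    panel_rows = []
    selections: dict[str, PanelSelection] = {}
    primer_by_id = {p.primer_id: p for p in all_candidates}
    by_gene: dict[str, list] = {}
    for p in survivors:
        by_gene.setdefault(p.gene_id, []).append(p)
    for gid in sorted(by_gene):
        cands = []
        cand_info = {}
        for p in by_gene[gid]:
            good = [
                h for h in on_target_perfect_hits(hits, p, config.filter)
                if h.dist_to_3prime >= amp_min
            ]
            if not good:
                continue
            covered = frozenset(h.transcript_id for h in good)
            dist = min(h.dist_to_3prime for h in good)
            cands.append(CoverageCandidate(p.primer_id, covered, dist))
            cand_info[p.primer_id] = dist
        if not cands:
            failures.append(
                FailureRecord(gid, "optimization", "no_on_target_hit",
                              "no perfect binding site within the amplicon bounds")
            )
            continue
        inst = CoverageInstance(
            gene_id=gid, candidates=cands,
            max_primers=config.max_primers_per_gene,
        )
        sel = (
            single_peak_select(inst) if config.mode == "single_peak"
            else greedy_set_cover(inst)
        )
        if not sel.chosen:
            failures.append(
                FailureRecord(gid, "optimization", "no_on_target_hit",
                              "optimizer selected no primer")
            )
            continue
        selections[gid] = sel
        chosen_covered = {
            c.primer_id: c.covered_isoforms for c in cands
        }
        for rank, pid in enumerate(sel.chosen, start=1):
            p = primer_by_id[pid]
            w = p.window_ref
            gstart, gend = _primer_genomic_span(p, w)
            p.genomic_start, p.genomic_end = gstart, gend
            panel_rows.append(
                {
                    "gene_id": gid,
                    "primer_id": pid,
                    "sequence": p.sequence,
                    "tm": f"{p.tm:.2f}",
                    "gc": f"{p.gc:.2f}",
                    "chrom": w.interval.chrom,
                    "genomic_start": gstart,
                    "genomic_end": gend,
                    "strand": w.interval.strand,
                    "covered_isoforms": ",".join(sorted(chosen_covered[pid])),
                    "dist_to_3prime": cand_info[pid],
                    "selection_rank": rank,
                }
            )

    panel_genes = set(selections)
    perfect_counts = {}
    final_ids = {row["primer_id"] for row in panel_rows}
    for pid in final_ids:
        perfect_counts[pid] = len(
            {h.gene_id for h in hits if h.primer_id == pid and h.mismatches == 0}
        )
    isoforms_covered = {gid: len(sel.covered) for gid, sel in selections.items()}
    summary = build_summary(
        requested, failures, panel_genes, perfect_counts, isoforms_covered
    )

    _write_panel_tsv(panel_rows, outdir / "panel.tsv")
    _write_primers_fasta(panel_rows, outdir / "primers.fa")
    write_windows_bed(windows, outdir / "windows.bed")
    write_failures_tsv(failures, outdir / "qc_failures.tsv")
    summary.to_json(outdir / "qc_summary.json")
    with open(outdir / "rejections.tsv", "w") as fh:
        fh.write("primer_id\treason\tdetail\n")
        for pid, reason, detail in rejections:
            fh.write(f"{pid}\t{reason}\t{detail}\n")
    manifest = {
        "tool": "tailprimer",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "n_unassigned_peaks": n_unassigned_peaks,
        "summary": json.loads(summary.to_json()),
        "timestamps": {"started": started,
                       "finished": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    if config.make_plots:
        _make_plots(genes, coverage, assigned, windows, panel_rows,
                    primer_by_id, outdir / "plots")

    return RunResult(outdir, summary, panel_rows, failures, rejections, windows)


def _refine_coverage_reason(f: FailureRecord, genes, coverage, min_depth):
    """Distinguish 'insufficient coverage' from 'no significant peaks'
    when per-base depth is available."""
    if f.reason != "no significant peaks" or f.gene_id not in genes:
        return f
    gene = genes[f.gene_id]
    cov = coverage.get(gene.chrom)
    if cov is None:
        return f
    max_depth = max(
        (float(cov[e.start : e.end].max()) for e in gene.exonic_union
         if e.end <= len(cov)),
        default=0.0,
    )
    if max_depth < min_depth:
        return FailureRecord(f.gene_id, f.stage, "insufficient coverage",
                             f"max exonic depth {max_depth:g} < {min_depth}")
    return f


def _make_plots(genes, coverage, assigned, windows, panel_rows, primer_by_id,
                plots_dir):
    from .qc import plot_gene

    plots_dir = Path(plots_dir)
    plots_dir.mkdir(parents=True, exist_ok=True)
    win_by_gene = {w.gene_id: w for w in windows}
    rows_by_gene: dict[str, list] = {}
    for row in panel_rows:
        rows_by_gene.setdefault(row["gene_id"], []).append(row)
    for gid, gene in genes.items():
        cov = coverage.get(gene.chrom) if coverage else None
        peaks = [a.peak for a in assigned.get(gid, [])]
        primers = [primer_by_id[r["primer_id"]] for r in rows_by_gene.get(gid, [])]
        plot_gene(gene, cov, peaks, win_by_gene.get(gid), primers,
                  plots_dir / f"{gid}.png")


def run_distance(config: RunConfig) -> RunResult:
    """Distance-based design on 3'-terminal transcript windows."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")

    if config.transcripts_fasta:
        tx_seqs = _read_fasta_dict(config.transcripts_fasta)
        items = sorted(tx_seqs.items())
    else:
        requested = _read_gene_list(config.gene_list) if config.gene_list else None
        genes, _missing = load_annotation(
            config.gtf, set(requested) if requested else None
        )
        genome = Fasta(config.genome)
        tx_seqs, _ = build_transcriptome(genes, genome)
        items = sorted(tx_seqs.items())

    templates, skipped = make_distance_templates(
        items,
        window_nt=config.distance_window_nt,
        excluded_3prime_nt=config.distance_excluded_3prime_nt,
    )
    failures = [
        FailureRecord(tid, "primer_design",
                      "sequence complexity preventing primer design",
                      "transcript shorter than the usable design window")
        for tid in skipped
    ]
    designer = _get_designer(config)
    panel_rows = []
    panel_targets = set()
    for t in templates:
        try:
            cands = design_primers(
                t.sequence, config.constraints, engine=designer,
                gene_id=t.transcript_id, window_ref=t,
                excluded_3prime_nt=t.excluded_3prime_nt,
                id_prefix=t.transcript_id,
            )
        except ValueError as exc:
            failures.append(
                FailureRecord(t.transcript_id, "primer_design",
                              "sequence complexity preventing primer design",
                              str(exc))
            )
            continue
        if not cands:
            failures.append(
                FailureRecord(t.transcript_id, "primer_design",
                              "sequence complexity preventing primer design",
                              "engine returned zero candidates")
            )
            continue
        best = cands[0]
        dist = len(t.sequence) - best.template_end
        panel_targets.add(t.transcript_id)
        panel_rows.append(
            {
                "gene_id": t.transcript_id,
                "primer_id": best.primer_id,
                "sequence": best.sequence,
                "tm": f"{best.tm:.2f}",
                "gc": f"{best.gc:.2f}",
                "chrom": t.transcript_id,
                "genomic_start": t.template_offset + best.template_start,
                "genomic_end": t.template_offset + best.template_end,
                "strand": "+",
                "covered_isoforms": t.transcript_id,
                "dist_to_3prime": dist,
                "selection_rank": 1,
            }
        )

    requested_ids = [tid for tid, _ in items]
    summary = build_summary(
        requested_ids, failures, panel_targets,
        {row["primer_id"]: 1 for row in panel_rows},
        {row["gene_id"]: 1 for row in panel_rows},
    )
    _write_panel_tsv(panel_rows, outdir / "panel.tsv")
    _write_primers_fasta(panel_rows, outdir / "primers.fa")
    write_failures_tsv(failures, outdir / "qc_failures.tsv")
    summary.to_json(outdir / "qc_summary.json")
    manifest = {
        "tool": "tailprimer",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "summary": json.loads(summary.to_json()),
        "timestamps": {"started": started,
                       "finished": time.strftime("%Y-%m-%dT%H:%M:%S")},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return RunResult(outdir, summary, panel_rows, failures, [])
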