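"""Peak-to-gene assignment, significance/exonic filtering, ranking and
exon-boundary trimming of design windows.

A design window is the exon-trimmed footprint of a selected coverage
peak, carried with the gene's strand so the downstream template is
oriented 5'->3' in mRNA sense. In ``single_peak`` mode only the
top-ranked peak per gene survives; ``multi_peak`` keeps every peak that
passes the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotation import GeneModel
from .intervals import GenomicInterval, intersect
from .peaks import Peak
from .qc import FailureRecord


@dataclass
class SelectionConfig:
    metric: str = "score"  # "score" or "qvalue"
    max_q: float = 0.05
    min_score: float = 0.0
    min_exonic_overlap_frac: float = 0.5
    min_exonic_overlap_nt: int | None = None  # alternative absolute-nt switch
    min_window_len: int = 70
    force_exonic_trimming: bool = True
    mode: str = "single_peak"

    def __post_init__(self) -> None:
        if self.metric not in {"score", "qvalue"}:
            raise ValueError(f"unknown ranking metric {self.metric!r}")
        if not 0.0 <= self.min_exonic_overlap_frac <= 1.0:
            raise ValueError("min_exonic_overlap_frac must be in [0, 1]")
        if self.max_q < 0 or self.min_score < 0 or self.min_window_len < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    exonic_overlap_frac: float
    exonic_overlap_nt: int
    ambiguous: bool  # peak also overlaps another requested gene's exons


@dataclass
class TargetWindow:
    gene_id: str
    source_peak: Peak
    interval: GenomicInterval  # carries the gene's strand
    covered_isoforms: set[str]
    qc_flags: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.source_peak.name}"


def assign_peaks_to_genes(
    peaks: list[Peak], genes: dict[str, GeneModel]
) -> tuple[dict[str, list[PeakAssignment]], int]:
    """Assign each peak to every gene whose exonic union it overlaps >= 1 nt.

    Returns the per-gene assignment lists plus the count of peaks that
    overlapped no requested gene (dropped, but counted).
    """
    trees: dict[str, IntervalTree] = {}
    for gid, gene in genes.items():
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for ex in gene.exonic_union:
            tree.addi(ex.start, ex.end, gid)

    assigned: dict[str, list[PeakAssignment]] = {gid: [] for gid in genes}
    n_unassigned = 0
    for pk in peaks:
        iv = pk.interval
        hits = trees.get(iv.chrom, IntervalTree()).overlap(iv.start, iv.end)
        per_gene_nt: dict[str, int] = {}
        for h in hits:
            nt = min(h.end, iv.end) - max(h.begin, iv.start)
            per_gene_nt[h.data] = per_gene_nt.get(h.data, 0) + nt
        if not per_gene_nt:
            n_unassigned += 1
            continue
        ambiguous = len(per_gene_nt) > 1
        for gid, nt in per_gene_nt.items():
            assigned[gid].append(
                PeakAssignment(
                    peak=pk,
                    exonic_overlap_frac=nt / iv.length,
                    exonic_overlap_nt=nt,
                    ambiguous=ambiguous,
                )
            )
    return assigned, n_unassigned


def _trim_to_exons(
    peak_iv: GenomicInterval, gene: GeneModel
) -> GenomicInterval | None:
    """Intersect a peak with the gene's exonic union; keep the largest
    fragment (ties: the fragment closer to the gene's 3' end)."""
    frags = intersect(peak_iv, gene.exonic_union)
    if not frags:
        return None
    three_prime = gene.three_prime_end

    def key(f: GenomicInterval):
        dist = min(abs(f.start - three_prime), abs(f.end - 1 - three_prime))
        return (-f.length, dist, f.start)

    best = min(frags, key=key)
    return best.with_strand(gene.strand)


def _dist_to_gene_3p(iv: GenomicInterval, gene: GeneModel) -> int:
    tp = gene.three_prime_end
    return min(abs(iv.start - tp), abs(iv.end - 1 - tp))


def covered_isoforms(window_iv: GenomicInterval, gene: GeneModel) -> set[str]:
    """Transcripts whose exon set fully contains the window interval."""
    return {
        t.transcript_id
        for t in gene.transcripts
        if t.contains_interval(window_iv)
    }


def select_windows(
    assigned: dict[str, list[PeakAssignment]],
    cfg: SelectionConfig,
    genes: dict[str, GeneModel],
) -> tuple[list[TargetWindow], list[FailureRecord]]:
    """Filter, rank and trim peaks into design windows.

    Ranking tie-break chain: primary metric, the other metric, longer
    trimmed window, interval closer to the gene 3' end, lexicographic
    peak name — fully deterministic and invariant to input order.
    """
    if cfg.mode not in {"single_peak", "multi_peak"}:
        raise ValueError(f"select_windows does not handle mode {cfg.mode!r}")
    windows: list[TargetWindow] = []
    failures: list[FailureRecord] = []
    min_q_neglog10 = None
    if cfg.max_q > 0:
        import math

        min_q_neglog10 = -math.log10(cfg.max_q)

    for gid in sorted(genes):
        gene = genes[gid]
        assignments = assigned.get(gid, [])
        if not assignments:
            failures.append(
                FailureRecord(gid, "peak_calling", "no significant peaks",
                              "no peak overlaps the gene's exons")
            )
            continue
        survivors = []
        for a in assignments:
            pk = a.peak
            if min_q_neglog10 is not None and pk.qvalue_neglog10 < min_q_neglog10:
                continue
            if pk.ranking_score < cfg.min_score:
                continue
            if cfg.min_exonic_overlap_nt is not None:
                if a.exonic_overlap_nt < cfg.min_exonic_overlap_nt:
                    continue
            elif a.exonic_overlap_frac < cfg.min_exonic_overlap_frac:
                continue
            survivors.append(a)
        if not survivors:
            failures.append(
                FailureRecord(gid, "window_selection", "no significant peaks",
                              "all peaks failed significance/exonic-overlap filters")
            )
            continue

        trimmed: list[tuple[PeakAssignment, GenomicInterval]] = []
        for a in survivors:
            if cfg.force_exonic_trimming:
                iv = _trim_to_exons(a.peak.interval, gene)
            else:
                iv = a.peak.interval.with_strand(gene.strand)
            if iv is not None:
                trimmed.append((a, iv))
        if not trimmed:
            failures.append(
                FailureRecord(gid, "window_selection", "window_too_short",
                              "no exonic fragment after trimming")
            )
            continue

        def rank_key(item):
            a, iv = item
            pk = a.peak
            if cfg.metric == "score":
                primary = (-pk.ranking_score, -pk.qvalue_neglog10)
            else:
                primary = (-pk.qvalue_neglog10, -pk.ranking_score)
            return primary + (
                -iv.length,
                _dist_to_gene_3p(iv, gene),
                pk.name,
            )

        trimmed.sort(key=rank_key)
        kept = trimmed[:1] if cfg.mode == "single_peak" else trimmed

        emitted = 0
        for a, iv in kept:
            if iv.length < cfg.min_window_len:
                failures.append(
                    FailureRecord(
                        gid, "window_selection", "window_too_short",
                        f"trimmed window {iv.length} nt < {cfg.min_window_len}",
                        peak_name=a.peak.name,
                    )
                )
                continue
            flags = []
            if a.ambiguous:
                flags.append("ambiguous_gene_overlap")
            iso = covered_isoforms(iv, gene)
            if not iso:
                flags.append("window_spans_isoform_junction")
            windows.append(
                TargetWindow(
                    gene_id=gid,
                    source_peak=a.peak,
                    interval=iv,
                    covered_isoforms=iso,
                    qc_flags=flags,
                )
            )
            emitted += 1
        if emitted == 0 and not any(
            f.gene_id == gid and f.reason == "window_too_short" for f in failures
        ):
            failures.append(
                FailureRecord(gid, "window_selection", "window_too_short",
                              "no window met the minimum length")
            )
    return windows, failures


def write_windows_bed(windows: list[TargetWindow], path) -> None:
    """Emit selected windows as 6-column BED (score = peak ranking score)."""
    with open(path, "w") as fh:
        for w in windows:
            iv = w.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{w.name}\t"
                f"{w.source_peak.ranking_score:g}\t{iv.strand}\n"
            )
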