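"""Per-gene status tracking, run summaries and per-gene design plots.

Every requested gene must end a run accounted for exactly once: either
with at least one failure record, or in the final panel. ``build_summary``
enforces this and derives the stage-attrition table and the selectivity
and isoform-coverage statistics the run reports.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field, asdict

STAGES = (
    "annotation",
    "peak_calling",
    "window_selection",
    "primer_design",
    "specificity",
    "optimization",
)

REASONS = (
    "insufficient coverage",
    "no significant peaks",
    "window_too_short",
    "sequence complexity preventing primer design",
    "excessive off-target binding",
    "no_on_target_hit",
    "gene_not_in_annotation",
)


@dataclass(frozen=True)
class FailureRecord:
    gene_id: str
    stage: str
    reason: str
    detail: str = ""
    peak_name: str | None = None
    primer_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.reason not in REASONS:
            raise ValueError(f"reason {self.reason!r} not in the fixed vocabulary")


@dataclass
class RunSummary:
    n_genes_requested: int
    n_with_peaks: int
    n_with_designed_primers: int
    n_passing_specificity: int
    n_in_final_panel: int
    attrition: dict[str, int]
    proportion_perfect_selectivity: float
    mean_isoforms_covered: float
    median_isoforms_covered: float
    failure_counts: dict[str, int]

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunSummary":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


# stage groups that end a gene before each attrition checkpoint
_PRE_PEAK_STAGES = {"annotation", "peak_calling", "window_selection"}


def build_summary(
    requested_genes: list[str],
    failures: list[FailureRecord],
    panel_genes: set[str],
    primer_perfect_gene_counts: dict[str, int] | None = None,
    isoforms_covered: dict[str, int] | None = None,
) -> RunSummary:
    """Aggregate the full run ledger into a RunSummary.

    ``primer_perfect_gene_counts`` maps each final primer to the number
    of distinct genes it hits with zero mismatches (1 = perfect
    selectivity); ``isoforms_covered`` maps each panel gene to the count
    of isoforms its chosen primers cover.
    """
    requested = list(dict.fromkeys(requested_genes))
    failed_genes = {f.gene_id for f in failures}
    unaccounted = [g for g in requested if g not in failed_genes and g not in panel_genes]
    if unaccounted:
        raise ValueError(
            f"genes unaccounted for in the run ledger: {', '.join(unaccounted)}"
        )

    # a gene's terminal stage is its earliest failing stage
    stage_rank = {s: i for i, s in enumerate(STAGES)}
    gene_fail_stage: dict[str, str] = {}
    for f in failures:
        if f.gene_id in panel_genes:
            continue  # per-peak/per-primer failures of an ultimately successful gene
        cur = gene_fail_stage.get(f.gene_id)
        if cur is None or stage_rank[f.stage] < stage_rank[cur]:
            gene_fail_stage[f.gene_id] = f.stage

    n_req = len(requested)
    n_fail_pre_peak = sum(1 for s in gene_fail_stage.values() if s in _PRE_PEAK_STAGES)
    n_fail_design = sum(1 for s in gene_fail_stage.values() if s == "primer_design")
    n_fail_spec = sum(1 for s in gene_fail_stage.values() if s == "specificity")

    n_with_peaks = n_req - n_fail_pre_peak
    n_designed = n_with_peaks - n_fail_design
    n_spec = n_designed - n_fail_spec
    n_panel = len(panel_genes & set(requested))

    counts = primer_perfect_gene_counts or {}
    prop_perfect = (
        sum(1 for c in counts.values() if c == 1) / len(counts) if counts else 0.0
    )
    iso = list((isoforms_covered or {}).values())
    failure_counts: dict[str, int] = {}
    for f in failures:
        failure_counts[f.reason] = failure_counts.get(f.reason, 0) + 1

    return RunSummary(
        n_genes_requested=n_req,
        n_with_peaks=n_with_peaks,
        n_with_designed_primers=n_designed,
        n_passing_specificity=n_spec,
        n_in_final_panel=n_panel,
        attrition={
            "requested": n_req,
            "with_peaks": n_with_peaks,
            "with_designed_primers": n_designed,
            "passing_specificity": n_spec,
            "final_panel": n_panel,
        },
        proportion_perfect_selectivity=prop_perfect,
        mean_isoforms_covered=float(statistics.mean(iso)) if iso else 0.0,
        median_isoforms_covered=float(statistics.median(iso)) if iso else 0.0,
        failure_counts=failure_counts,
    )


def write_failures_tsv(failures: list[FailureRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstage\treason\tdetail\tpeak_name\tprimer_id\n")
        for f in failures:
            fh.write(
                f"{f.gene_id}\t{f.stage}\t{f.reason}\t{f.detail}\t"
                f"{f.peak_name or ''}\t{f.primer_id or ''}\n"
            )


def plot_gene(
    gene,
    coverage,
    peaks,
    window,
    primers,
    out_path,
) -> dict:
    """Render a per-gene design plot and return its data model.

    The returned dict (also written as a JSON sidecar next to the
    image) describes what was drawn — tracks, peak bars, window extent
    and primer arrow directions — so orientation and content can be
    tested without pixel comparison. ``coverage`` may be None, in which
    case the coverage track is omitted and flagged.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    span = gene.span
    model: dict = {
        "gene_id": gene.gene_id,
        "strand": gene.strand,
        "span": [span.chrom, span.start, span.end],
        "tracks": [],
        "peaks": [[p.interval.start, p.interval.end] for p in peaks],
        "window": None,
        "primer_arrows": [],
        "flags": [],
    }
    fig, (ax_cov, ax_struct) = plt.subplots(
        2, 1, figsize=(9, 4), sharex=True, height_ratios=[2, 3]
    )
    if coverage is not None:
        x = np.arange(span.start, span.end)
        y = np.asarray(coverage[span.start : span.end])
        ax_cov.fill_between(x, y, step="mid", color="0.4")
        model["tracks"].append("coverage")
    else:
        model["flags"].append("missing_coverage")
    ax_cov.set_ylabel("depth")

    model["tracks"].append("structure")
    for row, t in enumerate(gene.transcripts):
        y = -row
        ax_struct.plot(
            [t.exons[0].start, t.exons[-1].end], [y, y], color="0.6", lw=1
        )
        painted = {("cds", c) for c in t.cds}
        for e in t.exons:
            ax_struct.add_patch(
                plt.Rectangle((e.start, y - 0.3), e.length, 0.6,
                              color="#4878b0", lw=0)
            )
        for u in t.utr3:
            ax_struct.add_patch(
                plt.Rectangle((u.start, y - 0.2), u.length, 0.4,
                              color="#e07b39", lw=0)
            )
        for u in t.utr5:
            ax_struct.add_patch(
                plt.Rectangle((u.start, y - 0.2), u.length, 0.4,
                              color="#9ecae9", lw=0)
            )
    for p in peaks:
        ax_struct.axvspan(p.interval.start, p.interval.end, color="red", alpha=0.15)
    if window is not None:
        ax_struct.axvspan(
            window.interval.start, window.interval.end, color="gold", alpha=0.35
        )
        model["window"] = [window.interval.start, window.interval.end]
    else:
        model["flags"].append("no_window")

    # primer arrows point toward the gene 3' end: +1 = increasing coordinate
    direction = 1 if gene.strand == "+" else -1
    for pr in primers or []:
        gstart = getattr(pr, "genomic_start", None)
        if gstart is None and window is not None:
            gstart = (window.interval.start + window.interval.end) // 2
        if gstart is None:
            continue
        ax_struct.annotate(
            "",
            xy=(gstart + direction * 30, 1.0),
            xytext=(gstart, 1.0),
            arrowprops=dict(arrowstyle="->", color="green"),
        )
        model["primer_arrows"].append({"primer_id": pr.primer_id,
                                       "direction": direction})
    ax_struct.set_ylim(-len(gene.transcripts), 2)
    ax_struct.set_yticks([])
    ax_struct.set_xlabel(f"{span.chrom} position")
    ax_cov.set_title(f"{gene.gene_id} ({gene.strand})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)

    sidecar = str(out_path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(model, fh, indent=1)
    return model
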