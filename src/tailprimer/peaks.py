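"""Coverage peaks: narrowPeak I/O and a simple fallback peak caller.

The fallback caller exists so the pipeline runs without an external
model-based peak caller: it thresholds per-base depth, scores each
candidate run with an upper-tail Poisson probability against a local
flanking background, and controls FDR with Benjamini-Hochberg. It makes
no attempt at fragment-size modelling; an external caller remains
pluggable through narrowPeak input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .intervals import GenomicInterval

# floor for p-values before taking log10, to keep scores finite
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class Peak:
    """A scored coverage interval (strandless until assigned to a gene).

    ``score`` is the narrowPeak column-5 integer as parsed;
    ``ranking_score`` is the quantity used for ranking: -10*log10 of the
    raw peak P value (10 x the -log10 p column), which is not clamped
    the way column 5 is.
    """

    interval: GenomicInterval
    summit_offset: int
    score: float
    pvalue_neglog10: float
    qvalue_neglog10: float
    name: str

    def __post_init__(self) -> None:
        if self.pvalue_neglog10 < 0 or self.qvalue_neglog10 < 0:
            raise ValueError(f"peak {self.name}: significance columns must be >= 0")
        if self.summit_offset < -1:
            raise ValueError(f"peak {self.name}: summit offset {self.summit_offset}")
        if self.summit_offset >= self.interval.length:
            raise ValueError(f"peak {self.name}: summit beyond interval end")

    @property
    def ranking_score(self) -> float:
        return 10.0 * self.pvalue_neglog10

    @property
    def qvalue(self) -> float:
        return 10.0 ** (-self.qvalue_neglog10)


def peak_score_from_p(p: float) -> float:
    """Peak score -10*log10(p); monotone decreasing in p."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def _fmt(x: float) -> str:
    return f"{x:g}"


def read_narrowpeak(path) -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}: line {lineno}: narrowPeak needs 10 columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, score, _strand, _signal, p, q, summit = fields
            summit_i = int(summit)
            if summit_i < -1:
                raise ValueError(
                    f"{path}: line {lineno}: negative summit {summit_i} (only -1 "
                    "means unknown)"
                )
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, int(start), int(end), "."),
                    summit_offset=summit_i,
                    score=float(score),
                    pvalue_neglog10=float(p),
                    qvalue_neglog10=float(q),
                    name=name,
                )
            )
    return peaks


def write_narrowpeak(peaks, path) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            iv = pk.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        pk.name,
                        _fmt(pk.score),
                        ".",
                        _fmt(pk.ranking_score),
                        _fmt(pk.pvalue_neglog10),
                        _fmt(pk.qvalue_neglog10),
                        str(pk.summit_offset),
                    ]
                )
                + "\n"
            )


def call_peaks_fallback(
    coverage: dict[str, np.ndarray],
    min_depth: int = 10,
    flank: int = 500,
    fdr: float = 0.05,
    mean_floor: float | None = None,
) -> list[Peak]:
    """Call peaks as maximal runs of depth >= ``min_depth``.

    Each run's P value is the upper-tail Poisson probability of its
    maximum depth under a local background rate lambda estimated from
    the ``flank`` nt on each side (floored at the genome-wide mean, or
    at ``mean_floor`` when given). Benjamini-Hochberg q-values are
    computed across all candidate runs and runs with q <= ``fdr`` are
    returned, summit at the maximum-depth base (leftmost on ties).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not coverage:
        return []
    all_cov = np.concatenate([np.asarray(c, dtype=float) for c in coverage.values()])
    genome_mean = float(all_cov.mean()) if all_cov.size else 0.0
    lam_floor = genome_mean if mean_floor is None else mean_floor
    lam_floor = max(lam_floor, 1e-3)

    candidates = []  # (chrom, start, end, summit_rel, p)
    for chrom in sorted(coverage):
        cov = np.asarray(coverage[chrom], dtype=float)
        if cov.size == 0:
            continue
        above = cov >= min_depth
        if not above.any():
            continue
        run_starts = np.flatnonzero(above & ~np.r_[False, above[:-1]])
        run_ends = np.flatnonzero(above & ~np.r_[above[1:], False]) + 1
        for s, e in zip(run_starts, run_ends):
            peak_max = float(cov[s:e].max())
            summit_rel = int(np.argmax(cov[s:e]))
            left = cov[max(0, s - flank) : s]
            right = cov[e : e + flank]
            flank_vals = np.concatenate([left, right])
            lam = float(flank_vals.mean()) if flank_vals.size else 0.0
            lam = max(lam, lam_floor)
            # P(X >= max depth) under Poisson(lam)
            p = float(stats.poisson.sf(peak_max - 1, lam))
            candidates.append((chrom, int(s), int(e), summit_rel, p))

    if not candidates:
        return []
    pvals = np.array([c[4] for c in candidates])
    qvals = stats.false_discovery_control(pvals, method="bh")
    peaks = []
    idx = 0
    for (chrom, s, e, summit_rel, p), q in zip(candidates, qvals):
        if q > fdr:
            continue
        idx += 1
        p_clamped = max(p, _P_FLOOR)
        q_clamped = max(float(q), _P_FLOOR)
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, s, e, "."),
                summit_offset=summit_rel,
                score=min(1000.0, round(peak_score_from_p(p_clamped))),
                pvalue_neglog10=-math.log10(p_clamped),
                qvalue_neglog10=-math.log10(q_clamped),
                name=f"fallback_peak_{idx}",
            )
        )
    return peaks


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Read bedGraph into per-chrom depth arrays (unlisted bases are 0)."""
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
            chrom, start, end, value = fields
            if chrom not in cov:
                raise ValueError(f"{path}: line {lineno}: unknown chrom {chrom}")
            cov[chrom][int(start) : int(end)] = float(value)
    return cov


def write_bedgraph(coverage: dict[str, np.ndarray], path) -> None:
    """Write per-base coverage as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            cov = np.asarray(coverage[chrom])
            if cov.size == 0:
                continue
            change = np.flatnonzero(np.diff(cov)) + 1
            bounds = np.r_[0, change, cov.size]
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = cov[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(float(v))}\n")


def coverage_from_bam(bam_path) -> dict[str, np.ndarray]:
    """Per-base depth from a coordinate-sorted indexed BAM (read spans only)."""
    import pysam

    cov = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for ref, length in zip(bam.references, bam.lengths):
            arr = np.zeros(length, dtype=float)
            for read in bam.fetch(ref):
                if read.is_unmapped:
                    continue
                arr[read.reference_start : read.reference_end] += 1
            cov[ref] = arr
    return cov
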