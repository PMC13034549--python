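"""Transcriptome specificity screening.

Candidates are aligned against the full transcript set (pluggable
aligner; the built-in naive engine is an exhaustive ungapped Hamming
scan with no seeds or heuristics, so it is complete by construction for
hits within the mismatch budget). Hits then pass a three-stage filter:

  Stage 1  keep hits with mismatches <= max_mismatches
  Stage 2  keep hits with dist_to_3prime <= max_dist_3prime
  Stage 3  keep a primer iff its surviving hits map to exactly one
           gene, that gene is the primer's intended target, and at
           least one surviving sense hit is a perfect match

Stages 1 and 2 are per-hit predicates and commute; stage 3 is the
per-primer uniqueness rule that rejects cross-amplifying primers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import reverse_complement
from .primers import PrimerCandidate

REASON_OFF_TARGET = "excessive off-target binding"
REASON_NO_ON_TARGET = "no_on_target_hit"


@dataclass(frozen=True)
class AlignmentHit:
    """One primer-to-transcript alignment (transcript mRNA coordinates).

    ``dist_to_3prime`` is measured from the hit's 3'-most base to the
    transcript terminus (= transcript_length - t_end): extension starts
    at the primer 3' end, so this is the prospective amplicon length to
    the poly(A) junction.
    """

    primer_id: str
    transcript_id: str
    gene_id: str
    t_start: int
    t_end: int
    hit_strand: str  # "sense" or "antisense"
    mismatches: int
    dist_to_3prime: int

    def __post_init__(self) -> None:
        if self.mismatches < 0 or self.dist_to_3prime < 0:
            raise ValueError("mismatches and dist_to_3prime must be >= 0")


@dataclass
class FilterConfig:
    max_mismatches: int = 3
    max_dist_3prime: int = 1000
    require_unique_gene: bool = True
    count_antisense_hits: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _scan_one(
    primer_arr: np.ndarray, tx_arr: np.ndarray, max_mm: int
) -> list[tuple[int, int]]:
    """All (start, mismatches) of ungapped windows with <= max_mm mismatches."""
    L = primer_arr.size
    if tx_arr.size < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(tx_arr, L)
    mm = (windows != primer_arr).sum(axis=1)
    idx = np.flatnonzero(mm <= max_mm)
    return [(int(i), int(mm[i])) for i in idx]


def naive_align(
    primer_seq: str,
    transcriptome: dict[str, str],
    tx2gene: dict[str, str],
    max_mm: int,
    primer_id: str = "primer",
    count_antisense: bool = True,
) -> list[AlignmentHit]:
    """Exhaustive Hamming scan of every same-length window of every
    transcript (sense, and antisense when configured). No seeding, no
    heuristics: the complete set of ungapped hits within the budget.

    Transcripts shorter than the primer are skipped.
    """
    hits = []
    p_sense = _encode(primer_seq)
    p_anti = _encode(reverse_complement(primer_seq))
    for tid in sorted(transcriptome):
        seq = transcriptome[tid]
        if tid not in tx2gene:
            raise KeyError(f"transcript {tid} missing from the transcript->gene map")
        tx_arr = _encode(seq)
        n = len(seq)
        for strand, parr in (("sense", p_sense), ("antisense", p_anti)):
            if strand == "antisense" and not count_antisense:
                continue
            for start, mm in _scan_one(parr, tx_arr, max_mm):
                end = start + len(primer_seq)
                hits.append(
                    AlignmentHit(
                        primer_id=primer_id,
                        transcript_id=tid,
                        gene_id=tx2gene[tid],
                        t_start=start,
                        t_end=end,
                        hit_strand=strand,
                        mismatches=mm,
                        dist_to_3prime=n - end,
                    )
                )
    return hits


class NaiveAligner:
    """Aligner engine wrapping :func:`naive_align` (the completeness oracle)."""

    name = "naive"

    def __init__(self, max_mm: int = 3, count_antisense: bool = True):
        self.max_mm = max_mm
        self.count_antisense = count_antisense

    def align(self, primers, transcriptome, tx2gene):
        hits = []
        for p in primers:
            hits.extend(
                naive_align(
                    p.sequence,
                    transcriptome,
                    tx2gene,
                    self.max_mm,
                    primer_id=p.primer_id,
                    count_antisense=self.count_antisense,
                )
            )
        return hits


class ExternalAlignerAdapter:
    """Adapter for a short-read aligner shelling out in local mode with
    all-alignments reporting (flags equivalent to ``-a -L 15 -N 1``) and
    parsing SAM. Gapped alignments are scored as substitutions plus
    inserted/deleted bases (a conservative superset of the mismatch
    count). Requires the external binary; the naive engine is the
    default and the completeness oracle.
    """

    name = "external"

    def __init__(self, command: str = "bowtie2", max_mm: int = 3):
        self.command = command
        self.max_mm = max_mm

    def align(self, primers, transcriptome, tx2gene):
        import shutil
        import subprocess
        import tempfile
        from pathlib import Path

        if shutil.which(self.command) is None:
            raise RuntimeError(
                f"external aligner {self.command!r} not found on PATH; "
                "use the naive engine instead"
            )
        with tempfile.TemporaryDirectory() as td:
            td = Path(td)
            ref = td / "ref.fa"
            with open(ref, "w") as fh:
                for tid, seq in transcriptome.items():
                    fh.write(f">{tid}\n{seq}\n")
            reads = td / "primers.fa"
            with open(reads, "w") as fh:
                for p in primers:
                    fh.write(f">{p.primer_id}\n{p.sequence}\n")
            idx = td / "idx"
            subprocess.run(
                [self.command + "-build", "-q", str(ref), str(idx)], check=True
            )
            sam = td / "out.sam"
            subprocess.run(
                [
                    self.command, "-x", str(idx), "-f", "-U", str(reads),
                    "--local", "-a", "-L", "15", "-N", "1", "-S", str(sam),
                    "--quiet",
                ],
                check=True,
            )
            return self._parse_sam(sam, transcriptome, tx2gene)

    def _parse_sam(self, sam_path, transcriptome, tx2gene):
        import pysam

        hits = []
        with pysam.AlignmentFile(str(sam_path), "r") as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                tid = rec.reference_name
                if tid not in tx2gene:
                    raise KeyError(
                        f"transcript {tid} missing from the transcript->gene map"
                    )
                # NM counts substitutions plus inserted/deleted bases
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                mm = int(nm)
                if mm > self.max_mm:
                    continue
                n = len(transcriptome[tid])
                hits.append(
                    AlignmentHit(
                        primer_id=rec.query_name,
                        transcript_id=tid,
                        gene_id=tx2gene[tid],
                        t_start=rec.reference_start,
                        t_end=rec.reference_end,
                        hit_strand="antisense" if rec.is_reverse else "sense",
                        mismatches=mm,
                        dist_to_3prime=n - rec.reference_end,
                    )
                )
        return hits


def align_all(
    primers: list[PrimerCandidate],
    transcriptome: dict[str, str],
    tx2gene: dict[str, str],
    engine=None,
) -> list[AlignmentHit]:
    """Align every candidate against the transcriptome."""
    missing = set(transcriptome) - set(tx2gene)
    if missing:
        raise KeyError(
            f"transcripts missing from the transcript->gene map: {sorted(missing)[:5]}"
        )
    engine = engine or NaiveAligner()
    return engine.align(primers, transcriptome, tx2gene)


def three_stage_filter(
    hits: list[AlignmentHit],
    primers: list[PrimerCandidate],
    cfg: FilterConfig,
) -> tuple[list[PrimerCandidate], list[tuple[str, str, str]]]:
    """Apply the mismatch / 3'-distance / unique-gene filter cascade.

    Returns (surviving primers, rejection ledger) where each ledger
    entry is (primer_id, reason, detail). Hits on multiple transcripts
    of the same gene do not violate the uniqueness rule.
    """
    known = {p.primer_id for p in primers}
    for h in hits:
        if h.primer_id not in known:
            raise KeyError(f"hit references unknown primer {h.primer_id}")

    by_primer: dict[str, list[AlignmentHit]] = {p.primer_id: [] for p in primers}
    for h in hits:
        if not cfg.count_antisense_hits and h.hit_strand == "antisense":
            continue
        if h.mismatches > cfg.max_mismatches:  # stage 1
            continue
        if h.dist_to_3prime > cfg.max_dist_3prime:  # stage 2
            continue
        by_primer[h.primer_id].append(h)

    survivors, rejections = [], []
    for p in primers:
        surviving = by_primer[p.primer_id]
        gene_set = {h.gene_id for h in surviving}
        has_on_target_perfect = any(
            h.gene_id == p.gene_id and h.mismatches == 0 and h.hit_strand == "sense"
            for h in surviving
        )
        off_targets = gene_set - {p.gene_id}
        if cfg.require_unique_gene and off_targets:
            rejections.append(
                (
                    p.primer_id,
                    REASON_OFF_TARGET,
                    f"hits {len(off_targets)} non-target gene(s): "
                    + ",".join(sorted(off_targets)[:5]),
                )
            )
        elif not has_on_target_perfect:
            rejections.append(
                (p.primer_id, REASON_NO_ON_TARGET,
                 "no surviving perfect-match sense hit on the target gene")
            )
        else:
            survivors.append(p)
    return survivors, rejections


def on_target_perfect_hits(
    hits: list[AlignmentHit], primer: PrimerCandidate, cfg: FilterConfig
) -> list[AlignmentHit]:
    """The primer's perfect sense hits on its target gene (post stage 1+2)."""
    return [
        h
        for h in hits
        if h.primer_id == primer.primer_id
        and h.gene_id == primer.gene_id
        and h.hit_strand == "sense"
        and h.mismatches == 0
        and h.dist_to_3prime <= cfg.max_dist_3prime
    ]
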