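"""Deterministic synthetic datasets with planted, known-answer peaks.

The generator emulates what the pipeline assumes about real 3'-end
RNA-seq input: multi-isoform genes on both strands whose isoforms share
a 3'-terminal exon, Poisson background coverage over exonic sequence,
and a rectangular high-depth coverage peak planted near each annotated
3' end. Shared decoy segments copied between gene pairs create planted
transcriptome off-targets. Everything is a pure function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

from .annotation import load_annotation, build_transcriptome, reverse_complement
from .peaks import Peak, write_narrowpeak, write_bedgraph
from .intervals import GenomicInterval
from .primers import DesignConstraints, fallback_tm, gc_percent, max_homopolymer_run, \
    longest_self_revcomp_match

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    seed: int = 1
    n_genes: int = 20
    strand_minus_frac: float = 0.5
    isoforms_min: int = 1
    isoforms_max: int = 3
    exons_min: int = 2
    exons_max: int = 4
    exon_len_min: int = 150
    exon_len_max: int = 400
    intron_len_min: int = 100
    intron_len_max: int = 300
    intergenic_min: int = 300
    intergenic_max: int = 800
    peak_offset_3p: int = 150  # mRNA distance from window 3' edge to tx terminus
    peak_width: int = 150
    peak_depth: int = 100
    background_depth: float = 1.0
    decoy_repeats: int = 2  # shared segments, one per consecutive gene pair
    decoy_len: int = 40
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.peak_width < 1 or self.peak_depth < 1:
            raise ValueError("counts must be positive")
        if self.decoy_repeats * 2 > self.n_genes:
            raise ValueError("not enough genes to host the decoy pairs")
        if self.decoy_len >= self.peak_width:
            raise ValueError("decoy must fit inside the planted peak window")
        if self.peak_offset_3p + self.peak_width > self.exon_len_min:
            # the 3'-terminal exon is sized up to hold the peak; this only
            # guards against absurd combinations
            if self.peak_offset_3p + self.peak_width > 10_000:
                raise ValueError("planted peak exceeds any plausible exon")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _valid_anchor(seq: str, constraints: DesignConstraints) -> bool:
    """Does this sequence itself pass the fallback designer's filters?"""
    if set(seq) - set("ACGT"):
        return False
    gc = gc_percent(seq)
    tm = fallback_tm(seq)
    return (
        constraints.gc_min <= gc <= constraints.gc_max
        and constraints.tm_min <= tm <= constraints.tm_max
        and max_homopolymer_run(seq) <= constraints.max_homopolymer
        and longest_self_revcomp_match(seq) <= constraints.max_self_any
    )


def _sample_anchor(rng: np.random.Generator, constraints: DesignConstraints) -> str:
    """A 22-mer with exactly 14 G/C that passes every fallback filter,
    planted at window starts so every gene has a designable site."""
    while True:
        # 14 G/C in 22 nt: Tm 60.4 C under the GC-count formula, GC 63.6 %
        seq = "".join(
            rng.permutation(np.array(list("G" * 7 + "C" * 7 + "A" * 4 + "T" * 4)))
        )
        if _valid_anchor(seq, constraints):
            return seq


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    n_isoforms: int
    peak: tuple[int, int]  # genomic, half-open; also the expected window
    anchor_site: tuple[int, int]  # genomic span of the planted designable site
    decoy_partner: str | None
    decoy_site: tuple[int, int] | None


def generate_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write the full fixture and return a manifest with ground truth.

    Files written: ``genome.fa``, ``annotation.gtf``, ``transcriptome.fa``,
    ``tx2gene.tsv``, ``coverage.bedGraph``, ``peaks.narrowPeak``,
    ``genes.txt``, ``ground_truth.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    constraints = DesignConstraints()

    n_minus = int(round(spec.n_genes * spec.strand_minus_frac))
    strands = ["-"] * n_minus + ["+"] * (spec.n_genes - n_minus)
    rng.shuffle(strands)

    gene_ids = [f"G{i + 1:02d}" for i in range(spec.n_genes)]
    genome_parts: list[str] = []
    pos = 0
    gtf_lines: list[str] = []
    truths: dict[str, GeneTruth] = {}
    peak_regions: list[tuple[str, int, int]] = []
    exonic_regions: list[tuple[int, int]] = []
    # deferred sequence edits: (genomic_start, forward-strand sequence)
    edits: list[tuple[int, str]] = []

    decoys = [_sample_decoy(rng, spec, constraints) for _ in range(spec.decoy_repeats)]
    decoy_of_gene = {}
    for k in range(spec.decoy_repeats):
        decoy_of_gene[gene_ids[2 * k]] = (k, gene_ids[2 * k + 1])
        decoy_of_gene[gene_ids[2 * k + 1]] = (k, gene_ids[2 * k])

    for gid, strand in zip(gene_ids, strands):
        gap = int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1))
        genome_parts.append(_rand_seq(rng, gap))
        pos += gap

        n_exons = int(rng.integers(spec.exons_min, spec.exons_max + 1))
        n_iso = int(rng.integers(spec.isoforms_min, min(spec.isoforms_max, n_exons) + 1))
        exon_lens = [
            int(rng.integers(spec.exon_len_min, spec.exon_len_max + 1))
            for _ in range(n_exons)
        ]
        # size the 3'-terminal exon to hold the planted peak
        terminal_len = spec.peak_offset_3p + spec.peak_width + int(
            rng.integers(40, 121)
        )
        exon_lens[-1] = terminal_len  # mRNA order: last = 3'-terminal
        intron_lens = [
            int(rng.integers(spec.intron_len_min, spec.intron_len_max + 1))
            for _ in range(n_exons - 1)
        ]

        # genomic layout: for '+' mRNA order runs left->right, for '-'
        # the 5'-most exon sits at the highest coordinates
        order = list(range(n_exons)) if strand == "+" else list(
            reversed(range(n_exons))
        )
        exon_g: dict[int, tuple[int, int]] = {}
        cursor = pos
        for idx, mrna_idx in enumerate(order):
            ln = exon_lens[mrna_idx]
            exon_g[mrna_idx] = (cursor, cursor + ln)
            cursor += ln
            if idx < n_exons - 1:
                gaps = intron_lens[mrna_idx] if strand == "+" else intron_lens[
                    mrna_idx - 1
                ]
                cursor += gaps
        gene_len = cursor - pos
        genome_parts.append(_rand_seq(rng, gene_len))
        gene_start, gene_end = pos, cursor
        pos = cursor

        for s, e in exon_g.values():
            exonic_regions.append((s, e))

        # isoform j (j = 0..n_iso-1) uses mRNA exons j..n_exons-1, so all
        # isoforms share the 3'-terminal exon
        for j in range(n_iso):
            tid = f"{gid}.t{j + 1}"
            for mrna_idx in range(j, n_exons):
                s, e = exon_g[mrna_idx]
                gtf_lines.append(
                    f"{spec.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{tid}";\n'
                )

        ts, te = exon_g[n_exons - 1]  # 3'-terminal exon, genomic
        if strand == "+":
            peak_g = (te - spec.peak_offset_3p - spec.peak_width,
                      te - spec.peak_offset_3p)
        else:
            peak_g = (ts + spec.peak_offset_3p,
                      ts + spec.peak_offset_3p + spec.peak_width)
        peak_regions.append((gid, peak_g[0], peak_g[1]))

        # the template's 5'-most segment (mRNA sense) hosts either the
        # shared decoy or a gene-unique designable anchor
        if gid in decoy_of_gene:
            k, partner = decoy_of_gene[gid]
            planted = decoys[k]
        else:
            k, partner = None, None
            planted = _sample_anchor_padded(rng, spec, constraints)
        if strand == "+":
            site = (peak_g[0], peak_g[0] + len(planted))
            edits.append((site[0], planted))
        else:
            site = (peak_g[1] - len(planted), peak_g[1])
            edits.append((site[0], reverse_complement(planted)))

        truths[gid] = GeneTruth(
            gene_id=gid,
            strand=strand,
            n_isoforms=n_iso,
            peak=peak_g,
            anchor_site=site,
            decoy_partner=partner,
            decoy_site=site if partner is not None else None,
        )

    genome_parts.append(_rand_seq(rng, 200))
    genome = list("".join(genome_parts))
    for start, seq in edits:
        genome[start : start + len(seq)] = list(seq)
    genome_seq = "".join(genome)

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i : i + 80] + "\n")
    gtf_path = outdir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.writelines(gtf_lines)

    # coverage: Poisson background over exonic bases + rectangular peaks
    cov = np.zeros(len(genome_seq), dtype=float)
    for s, e in exonic_regions:
        cov[s:e] += rng.poisson(spec.background_depth, size=e - s)
    for _gid, s, e in peak_regions:
        cov[s:e] += spec.peak_depth
    coverage = {spec.chrom: cov}
    bedgraph_path = outdir / "coverage.bedGraph"
    write_bedgraph(coverage, bedgraph_path)

    peaks = [
        Peak(
            interval=GenomicInterval(spec.chrom, s, e, "."),
            summit_offset=(e - s) // 2,
            score=300,
            pvalue_neglog10=30.0,
            qvalue_neglog10=25.0,
            name=f"true_{gid}",
        )
        for gid, s, e in peak_regions
    ]
    narrowpeak_path = outdir / "peaks.narrowPeak"
    write_narrowpeak(peaks, narrowpeak_path)

    genes_path = outdir / "genes.txt"
    with open(genes_path, "w") as fh:
        fh.write("\n".join(gene_ids) + "\n")

    models, _missing = load_annotation(gtf_path, set(gene_ids))
    fasta = Fasta(str(genome_path))
    tx_seqs, tx2gene = build_transcriptome(models, fasta)
    tx_path = outdir / "transcriptome.fa"
    with open(tx_path, "w") as fh:
        for tid in sorted(tx_seqs):
            fh.write(f">{tid}\n{tx_seqs[tid]}\n")
    map_path = outdir / "tx2gene.tsv"
    with open(map_path, "w") as fh:
        for tid in sorted(tx2gene):
            fh.write(f"{tid}\t{tx2gene[tid]}\n")

    truth_path = outdir / "ground_truth.json"
    truth_json = {gid: asdict(t) for gid, t in truths.items()}
    with open(truth_path, "w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)

    return {
        "spec": asdict(spec),
        "genome": str(genome_path),
        "gtf": str(gtf_path),
        "transcriptome": str(tx_path),
        "tx2gene": str(map_path),
        "bedgraph": str(bedgraph_path),
        "narrowpeak": str(narrowpeak_path),
        "gene_list": str(genes_path),
        "ground_truth": truth_json,
        "chrom_lengths": {spec.chrom: len(genome_seq)},
    }


def _sample_anchor_padded(rng, spec: FixtureSpec, constraints) -> str:
    """A decoy-length segment whose first 22 nt are a valid primer site."""
    anchor = _sample_anchor(rng, constraints)
    pad = _rand_seq(rng, max(0, spec.decoy_len - len(anchor)))
    return (anchor + pad)[: spec.decoy_len]


def _sample_decoy(rng, spec: FixtureSpec, constraints) -> str:
    """A shared segment hosting a valid primer site at its start; copied
    into two genes it plants a guaranteed two-gene off-target."""
    return _sample_anchor_padded(rng, spec, constraints)


def write_coverage_bam(coverage: dict[str, np.ndarray], path) -> None:
    """Emit a coordinate-sorted indexed BAM whose read spans reproduce
    the given per-base depth exactly (run-length: depth d over a run
    becomes d unspliced reads spanning the run). For adapter testing
    behind the same interface as the bedGraph emitter.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": int(len(arr))} for chrom, arr in sorted(
                coverage.items()
            )
        ],
    }
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for ref_id, (chrom, arr) in enumerate(sorted(coverage.items())):
            arr = np.asarray(arr)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.r_[0, change, arr.size]
            n_read = 0
            for s, e in zip(bounds[:-1], bounds[1:]):
                depth = int(arr[s])
                for d in range(depth):
                    a = pysam.AlignedSegment()
                    a.query_name = f"r_{chrom}_{s}_{d}"
                    a.reference_id = ref_id
                    a.reference_start = int(s)
                    a.mapping_quality = 60
                    a.cigartuples = [(0, int(e - s))]
                    a.query_sequence = "A" * int(e - s)
                    a.flag = 0
                    bam.write(a)
                    n_read += 1
    pysam.index(path)
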