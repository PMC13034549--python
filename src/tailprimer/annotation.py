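"""Gene annotation model: GTF parsing, transcript/gene structures and
transcript <-> genomic coordinate mapping.

GTF input follows the Ensembl dialect (``gene_id``/``transcript_id`` in
the attribute column, 1-based inclusive coordinates). Internally all
coordinates are 0-based half-open. Transcript coordinates run 5'->3' in
mRNA sense: position 0 of a minus-strand transcript maps to its highest
genomic exonic coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import GenomicInterval, merge_intervals, total_length

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_EXONIC_FEATURES = {"exon", "CDS", "five_prime_utr", "three_prime_utr", "UTR"}


class GTFParseError(ValueError):
    pass


@dataclass
class TranscriptModel:
    """One transcript: ordered exons on a single chrom/strand.

    ``three_prime_end`` is the genomic coordinate (0-based) of the
    annotated 3' terminal base: last exon end - 1 on ``+``, first exon
    start on ``-``. The 3' end is taken from annotation, not from
    observed polyadenylation sites.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        strands = {e.strand for e in self.exons}
        if len(strands) != 1 or strands <= {"."}:
            raise ValueError(f"transcript {self.transcript_id}: inconsistent strand")
        if not self.utr5 and not self.utr3 and self.cds:
            self._derive_utrs()

    def _derive_utrs(self) -> None:
        cds_lo = min(c.start for c in self.cds)
        cds_hi = max(c.end for c in self.cds)
        before, after = [], []
        for e in self.exons:
            if e.start < cds_lo:
                before.append(
                    GenomicInterval(e.chrom, e.start, min(e.end, cds_lo), e.strand)
                )
            if e.end > cds_hi:
                after.append(
                    GenomicInterval(e.chrom, max(e.start, cds_hi), e.end, e.strand)
                )
        if self.strand == "+":
            self.utr5, self.utr3 = before, after
        else:
            self.utr5, self.utr3 = after, before

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return total_length(self.exons)

    @property
    def three_prime_end(self) -> int:
        if self.strand == "+":
            return self.exons[-1].end - 1
        return self.exons[0].start

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map an exonic genomic position to a transcript (mRNA) position."""
        offset = 0
        for e in self.exons:
            if e.start <= gpos < e.end:
                plus_pos = offset + (gpos - e.start)
                if self.strand == "+":
                    return plus_pos
                return self.length - 1 - plus_pos
            offset += e.length
        raise ValueError(
            f"position {gpos} is not exonic in transcript {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a transcript (mRNA) position back to its genomic coordinate."""
        if not 0 <= tpos < self.length:
            raise ValueError(
                f"transcript position {tpos} out of range [0, {self.length})"
            )
        plus_pos = tpos if self.strand == "+" else self.length - 1 - tpos
        offset = 0
        for e in self.exons:
            if plus_pos < offset + e.length:
                return e.start + (plus_pos - offset)
            offset += e.length
        raise AssertionError("unreachable")

    def contains_interval(self, iv: GenomicInterval) -> bool:
        """True when every base of ``iv`` lies on this transcript's exons."""
        if iv.chrom != self.chrom:
            return False
        covered = sum(e.overlap_len(iv) for e in self.exons)
        return covered == iv.length

    def spliced_sequence(self, genome) -> str:
        """mRNA-sense sequence from an indexed genome (pyfaidx.Fasta)."""
        parts = [str(genome[self.chrom][e.start : e.end]) for e in self.exons]
        seq = "".join(parts).upper()
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        self.transcripts.sort(key=lambda t: t.transcript_id)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.exons[0].start for t in self.transcripts)
        end = max(t.exons[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exonic_union(self) -> list[GenomicInterval]:
        return merge_intervals(
            [e for t in self.transcripts for e in t.exons]
        )

    @property
    def three_prime_end(self) -> int:
        """The gene-level 3'-most annotated position across isoforms."""
        ends = [t.three_prime_end for t in self.transcripts]
        return max(ends) if self.strand == "+" else min(ends)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _parse_gtf_line(line: str, lineno: int):
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 9:
        raise GTFParseError(
            f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
        )
    chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
    if start_i < 1 or end_i < start_i:
        raise GTFParseError(f"line {lineno}: invalid coordinates {start}-{end}")
    attr_map = dict(_ATTR_RE.findall(attrs))
    return chrom, feature, start_i - 1, end_i, strand, attr_map


def load_annotation(
    gtf_path, gene_ids: set[str] | None = None
) -> tuple[dict[str, GeneModel], list[str]]:
    """Parse a GTF into GeneModels.

    Returns ``(models, missing)`` where ``missing`` lists requested gene
    ids absent from the annotation (reported, never silently dropped).
    Only exon/CDS/UTR features are consumed; 1-based inclusive GTF
    coordinates become 0-based half-open.
    """
    requested = set(gene_ids) if gene_ids is not None else None
    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    utr5: dict[str, list[GenomicInterval]] = {}
    utr3: dict[str, list[GenomicInterval]] = {}
    plain_utr: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            chrom, feature, start, end, strand, attrs = _parse_gtf_line(line, lineno)
            if feature not in _EXONIC_FEATURES:
                continue
            gid = attrs.get("gene_id")
            tid = attrs.get("transcript_id")
            if gid is None or tid is None:
                raise GTFParseError(
                    f"line {lineno}: missing gene_id/transcript_id attribute"
                )
            if requested is not None and gid not in requested:
                continue
            iv = GenomicInterval(chrom, start, end, strand)
            tx_gene[tid] = gid
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(tid, []).append(iv)
            elif feature == "five_prime_utr":
                utr5.setdefault(tid, []).append(iv)
            elif feature == "three_prime_utr":
                utr3.setdefault(tid, []).append(iv)
            else:
                plain_utr.setdefault(tid, []).append(iv)

    by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, ex in exons.items():
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=tx_gene[tid],
            exons=ex,
            cds=sorted(cds.get(tid, [])),
            utr5=sorted(utr5.get(tid, [])),
            utr3=sorted(utr3.get(tid, [])),
        )
        if tid in plain_utr and not t.utr5 and not t.utr3 and t.cds:
            cds_lo = min(c.start for c in t.cds)
            for u in plain_utr[tid]:
                side_5 = (u.end <= cds_lo) == (t.strand == "+")
                (t.utr5 if side_5 else t.utr3).append(u)
        by_gene.setdefault(t.gene_id, []).append(t)

    models = {gid: GeneModel(gid, txs) for gid, txs in sorted(by_gene.items())}
    missing = sorted(requested - models.keys()) if requested is not None else []
    return models, missing


def build_transcriptome(
    genes: dict[str, GeneModel], genome
) -> tuple[dict[str, str], dict[str, str]]:
    """Splice every transcript; returns (tx_id -> sequence, tx_id -> gene_id)."""
    seqs, tx2gene = {}, {}
    for gene in genes.values():
        for t in gene.transcripts:
            seqs[t.transcript_id] = t.spliced_sequence(genome)
            tx2gene[t.transcript_id] = gene.gene_id
    return seqs, tx2gene
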