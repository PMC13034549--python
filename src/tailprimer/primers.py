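"""Template extraction and left-primer design.

Templates are always handed to the designer 5'->3' in mRNA sense (the
genomic forward sequence for plus-strand genes, its reverse complement
for minus-strand genes), so only *left* primers are ever designed:
every primer points toward the transcript 3' end, where the anchored
oligo(dT) primer defines the other amplicon boundary.

The design engine is pluggable. The production adapter drives Primer3;
the default fallback engine is a deterministic exhaustive scanner using
a GC-count melting-temperature formula — adequate for screening and
testing, and explicitly not a nearest-neighbor thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

from .annotation import TranscriptModel, reverse_complement
from .windows import TargetWindow


@dataclass
class DesignConstraints:
    """Thermodynamic and geometric constraints on candidate primers.

    Defaults follow a strict uniform-amplification regime: Tm 59-61 C,
    GC 35-65 %, amplicon (primer 3' end to transcript terminus) 40-1000 nt.
    """

    tm_min: float = 59.0
    tm_opt: float = 60.0
    tm_max: float = 61.0
    gc_min: float = 35.0
    gc_max: float = 65.0
    amplicon_min: int = 40
    amplicon_max: int = 1000
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 25
    max_self_any: int = 8  # longest self-reverse-complement match, nt
    max_self_end: int = 4
    max_homopolymer: int = 4
    n_candidates: int = 10

    def __post_init__(self) -> None:
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("require tm_min <= tm_opt <= tm_max")
        if self.gc_min > self.gc_max:
            raise ValueError("require gc_min <= gc_max")
        if self.amplicon_min > self.amplicon_max:
            raise ValueError("require amplicon_min <= amplicon_max")
        if not self.primer_len_min <= self.primer_len_max:
            raise ValueError("require primer_len_min <= primer_len_max")


@dataclass
class PrimerCandidate:
    primer_id: str
    gene_id: str
    window_ref: object  # TargetWindow or DistanceTemplate
    sequence: str
    template_start: int
    tm: float
    gc: float
    penalty: float

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.primer_id}: non-ACGT base in primer sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def template_end(self) -> int:
        return self.template_start + len(self.sequence)


@dataclass
class DistanceTemplate:
    """A 3'-terminal transcript subsequence for distance-based design.

    ``excluded_3prime_nt`` final bases are blocked so primer 3' ends
    land at least that far upstream of the transcript terminus.
    """

    transcript_id: str
    sequence: str
    transcript_length: int
    template_offset: int  # transcript coordinate of template position 0
    excluded_3prime_nt: int

    @property
    def gene_id(self) -> str:  # distance mode treats transcript as the target
        return self.transcript_id


class DesignEngine(Protocol):
    def design(
        self,
        template: str,
        constraints: DesignConstraints,
        excluded_3prime_nt: int = 0,
    ) -> list[tuple[str, int, float, float, float]]:
        """Return (sequence, template_start, tm, gc_percent, penalty) tuples."""
        ...


def fallback_tm(seq: str) -> float:
    """GC-count melting temperature: 64.9 + 41*(G+C - 16.4)/N.

    A standard quick formula; engine-specific and not claimed to match
    a nearest-neighbor model.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)} in sequence")
    gc = seq.count("G") + seq.count("C")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def gc_percent(seq: str) -> float:
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def longest_self_revcomp_match(seq: str) -> int:
    """Length of the longest substring whose reverse complement also
    occurs in the sequence (a simple self-complementarity screen)."""
    n = len(seq)
    rc = reverse_complement(seq)
    best = 0
    # longest common substring of seq and its reverse complement
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if seq[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


class FallbackDesigner:
    """Exhaustive deterministic left-primer scanner.

    Enumerates every substring within the length bounds, filters by the
    GC-count Tm, GC fraction, homopolymer run and a self-complementarity
    screen, and scores penalty = |Tm - tm_opt| + 0.1*|len - len_opt|.
    A pure function of (template, constraints): identical inputs give
    identical outputs.
    """

    name = "fallback"

    def design(self, template, constraints, excluded_3prime_nt=0):
        c = constraints
        out = []
        usable_end = len(template) - excluded_3prime_nt
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            for start in range(0, usable_end - length + 1):
                seq = template[start : start + length]
                if set(seq) - set("ACGT"):
                    continue
                gc = gc_percent(seq)
                if not c.gc_min <= gc <= c.gc_max:
                    continue
                tm = fallback_tm(seq)
                if not c.tm_min <= tm <= c.tm_max:
                    continue
                if max_homopolymer_run(seq) > c.max_homopolymer:
                    continue
                if longest_self_revcomp_match(seq) > c.max_self_any:
                    continue
                penalty = abs(tm - c.tm_opt) + 0.1 * abs(length - c.primer_len_opt)
                out.append((seq, start, tm, gc, penalty))
        out.sort(key=lambda t: (t[4], t[1], len(t[0])))
        return out[: c.n_candidates]


class Primer3Designer:
    """Adapter for the Primer3 thermodynamic engine (optional dependency).

    Emits SEQUENCE_TEMPLATE / SEQUENCE_EXCLUDED_REGION with
    PRIMER_PICK_LEFT_PRIMER=1, PRIMER_PICK_RIGHT_PRIMER=0.
    """

    name = "primer3"

    def design(self, template, constraints, excluded_3prime_nt=0):
        try:
            import primer3  # noqa: F401
        except ImportError as exc:
            raise RuntimeError(
                "the primer3-py package is required for the Primer3 engine; "
                "install the 'primer3' extra or use the fallback engine"
            ) from exc
        c = constraints
        seq_args = {
            "SEQUENCE_ID": "template",
            "SEQUENCE_TEMPLATE": template,
        }
        if excluded_3prime_nt > 0:
            seq_args["SEQUENCE_EXCLUDED_REGION"] = [
                [len(template) - excluded_3prime_nt, excluded_3prime_nt]
            ]
        global_args = {
            "PRIMER_TASK": "generic",
            "PRIMER_PICK_LEFT_PRIMER": 1,
            "PRIMER_PICK_RIGHT_PRIMER": 0,
            "PRIMER_PICK_INTERNAL_OLIGO": 0,
            "PRIMER_NUM_RETURN": c.n_candidates,
            "PRIMER_MIN_TM": c.tm_min,
            "PRIMER_OPT_TM": c.tm_opt,
            "PRIMER_MAX_TM": c.tm_max,
            "PRIMER_MIN_GC": c.gc_min,
            "PRIMER_MAX_GC": c.gc_max,
            "PRIMER_MIN_SIZE": c.primer_len_min,
            "PRIMER_OPT_SIZE": c.primer_len_opt,
            "PRIMER_MAX_SIZE": c.primer_len_max,
            "PRIMER_MAX_POLY_X": c.max_homopolymer,
        }
        res = primer3.bindings.design_primers(seq_args, global_args)
        out = []
        for i in range(res.get("PRIMER_LEFT_NUM_RETURNED", 0)):
            seq = res[f"PRIMER_LEFT_{i}_SEQUENCE"].upper()
            start, _length = res[f"PRIMER_LEFT_{i}"]
            out.append(
                (
                    seq,
                    start,
                    res[f"PRIMER_LEFT_{i}_TM"],
                    res[f"PRIMER_LEFT_{i}_GC_PERCENT"],
                    res[f"PRIMER_LEFT_{i}_PENALTY"],
                )
            )
        return out


def extract_template(window: TargetWindow, genome) -> str:
    """Orientation-normalized template for a design window.

    Plus-strand genes: the genomic forward subsequence. Minus-strand
    genes: its reverse complement. Either way template position 0 is
    the 5'-most mRNA base and coordinates increase toward the 3' end.
    Ambiguity codes (N) are retained for the designer to reject.
    """
    iv = window.interval
    contig = genome[iv.chrom]
    if iv.end > len(contig):
        raise ValueError(
            f"window {iv.chrom}:{iv.start}-{iv.end} exceeds contig length "
            f"{len(contig)}"
        )
    seq = str(contig[iv.start : iv.end]).upper()
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


def template_to_genomic(window: TargetWindow, template_pos: int) -> int:
    """Genomic coordinate of a template position (mRNA sense)."""
    iv = window.interval
    if iv.strand == "-":
        return iv.end - 1 - template_pos
    return iv.start + template_pos


def design_primers(
    template: str,
    constraints: DesignConstraints,
    engine: DesignEngine | None = None,
    gene_id: str = "",
    window_ref=None,
    excluded_3prime_nt: int = 0,
    id_prefix: str | None = None,
) -> list[PrimerCandidate]:
    """Design left primers on an mRNA-sense template.

    Returns candidates sorted by engine penalty (at most
    ``constraints.n_candidates``); an empty list means the engine found
    no valid primer on this template.
    """
    if len(template) < constraints.primer_len_min:
        raise ValueError(
            f"template length {len(template)} < primer_len_min "
            f"{constraints.primer_len_min}"
        )
    engine = engine or FallbackDesigner()
    raw = engine.design(template, constraints, excluded_3prime_nt=excluded_3prime_nt)
    prefix = id_prefix or (getattr(window_ref, "name", None) or gene_id or "t")
    candidates = []
    for i, (seq, start, tm, gc, penalty) in enumerate(raw):
        if template[start : start + len(seq)] != seq:
            raise AssertionError("engine returned a sequence off its template slot")
        candidates.append(
            PrimerCandidate(
                primer_id=f"{prefix}|p{i:02d}",
                gene_id=gene_id,
                window_ref=window_ref,
                sequence=seq,
                template_start=start,
                tm=tm,
                gc=gc,
                penalty=penalty,
            )
        )
    return candidates


def make_distance_templates(
    transcripts,
    window_nt: int = 200,
    excluded_3prime_nt: int = 40,
    genome=None,
) -> tuple[list[DistanceTemplate], list[str]]:
    """3'-terminal design templates for distance-based mode.

    ``transcripts`` is an iterable of (id, mRNA sequence) pairs,
    Bio.SeqRecord objects, or TranscriptModel objects (the latter need
    ``genome`` for splicing). The template is the final
    min(window_nt, length) bases of each transcript; the last
    ``excluded_3prime_nt`` bases are excluded so primer 3' ends land
    between ``excluded_3prime_nt`` and ``window_nt`` upstream of the
    terminus. Returns (templates, skipped transcript ids).
    """
    if not window_nt > excluded_3prime_nt >= 0:
        raise ValueError("require window_nt > excluded_3prime_nt >= 0")
    templates, skipped = [], []
    for item in transcripts:
        if isinstance(item, TranscriptModel):
            if genome is None:
                raise ValueError("TranscriptModel input requires a genome")
            tid, seq = item.transcript_id, item.spliced_sequence(genome)
        elif isinstance(item, tuple):
            tid, seq = item
        else:  # Bio.SeqRecord
            tid, seq = item.id, str(item.seq)
        seq = seq.upper()
        take = min(window_nt, len(seq))
        if take - excluded_3prime_nt < 1:
            skipped.append(tid)
            continue
        templates.append(
            DistanceTemplate(
                transcript_id=tid,
                sequence=seq[len(seq) - take :],
                transcript_length=len(seq),
                template_offset=len(seq) - take,
                excluded_3prime_nt=excluded_3prime_nt,
            )
        )
    return templates, skipped
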