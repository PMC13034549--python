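# Methods

## Model and assumptions

`tailprimer` designs second-strand synthesis primers for 3′-end RNA-seq
chemistries in which reverse transcription is anchored at the poly(A)
junction by an oligo(dT)-VN primer. Two consequences shape the whole
design space:

* Only **left primers** make sense: the gene-specific primer must
  extend toward the transcript 3′ terminus, where the universal
  anchored primer defines the other end of the amplicon. Templates are
  therefore normalized to 5′→3′ mRNA sense before design (forward
  genomic sequence for `+` genes, reverse complement for `−` genes),
  and the designer is only ever asked for left primers.
* The **amplicon length is the distance from the primer's 3′ end to the
  transcript terminus**, not a distance between two designed primers.
  Amplicon bounds (default 40–1000 nt) are enforced on that distance:
  the maximum through the specificity filter's 3′-distance threshold,
  the minimum when coverage sets are built for the optimizer (isoforms
  whose perfect binding site lies closer than `amplicon_min` to the
  terminus do not count as covered).

Coordinates are 0-based half-open internally; GTF (1-based inclusive)
is converted at the I/O boundary, narrowPeak/BED/bedGraph are already
half-open. Transcript coordinates run 5′→3′ in mRNA sense, so position
0 of a minus-strand transcript is its highest genomic exonic base.
Transcript 3′ ends come from the annotation, not from observed
polyadenylation sites; users wanting poly(A)-site-corrected ends should
supply an annotation carrying them.

## Peak processing

Peaks are strandless on input (as peak callers emit them) and inherit
the gene's strand at window assignment. Ranking uses the peak score
defined as −10·log₁₀ of the raw peak P value — recomputed from the
−log₁₀ *p* column rather than taken from the clamped integer BED score
column — or the q-value, selectable per run. A peak is assigned to
every gene whose exonic union it overlaps by at least one base; the
exonic overlap filter is a fraction of peak length by default
(`min_exonic_overlap_frac`, default 0.5) with an absolute-nt switch,
since either reading of "minimum exonic overlap" is defensible.

Trimming intersects the peak with the gene's exonic union (all
isoforms pooled, so windows are not biased toward one reference
isoform). When an intron splits the peak, the single largest exonic
fragment is kept (ties: the fragment nearer the gene's 3′ end) — one
contiguous template keeps primer design well-posed. Windows shorter
than `min_window_len` (default 70 nt: a primer plus flanks) are dropped
and reported. Ranking ties break deterministically: primary metric →
other metric → longer trimmed window → closer to the gene 3′ end →
lexicographic peak name. A window trimmed against the multi-isoform
union can occasionally be contained in no single transcript; such
windows are flagged (`window_spans_isoform_junction`) rather than
dropped, because isoform coverage is later established per primer from
actual perfect binding sites, not from window containment.

### Fallback peak caller

The built-in caller exists so the pipeline runs end-to-end without an
external model-based caller, and is deliberately simple: candidate
regions are maximal runs of depth ≥ `min_depth` (default 10); each
run's P value is the upper-tail Poisson probability of its maximum
depth under a local background λ estimated from `flank` nt (default
500) on each side, floored at the genome-wide mean; Benjamini–Hochberg
q-values are computed across candidates and runs with q ≤ `fdr`
(default 0.05) are kept, summit at the leftmost maximum. There is no
fragment-size model, duplicate handling or multi-scale background; an
external caller remains first-class through narrowPeak input.

## Primer design engines

The engine interface is "generate left primers on a template with
constraints and an excluded 3′ region". The default engine is an
exhaustive deterministic scanner: every substring within the length
bounds (default 18–25, optimum 20) is checked against GC (35–65 %),
melting temperature, homopolymer run (≤ 4) and a self-complementarity
screen (longest substring whose reverse complement also occurs in the
primer, ≤ 8 nt), then scored `|Tm − Tm_opt| + 0.1·|len − len_opt|` and
truncated to `n_candidates` (default 10 — enough alternatives for the
specificity stage to discard some). Its melting temperature is the
GC-count formula Tm = 64.9 + 41·(G+C − 16.4)/N — adequate for
screening, deterministic, and explicitly **not** a nearest-neighbor
model; under it the Tm 59–61 °C and GC ≤ 65 % constraints are jointly
satisfiable only for primers of 22–25 nt, which the scanner finds
automatically. A Primer3 adapter (optional `primer3` extra) exposes the
same interface for production-grade thermodynamics; its constraint
values are passed through unchanged.

## Specificity screening

The default aligner is an exhaustive ungapped Hamming scan of every
same-length window of every transcript — complete by construction for
hits within the mismatch budget, with no seeds or heuristics, and fast
enough for panel-scale inputs via vectorized window comparison.
Antisense hits (the primer matching the transcript's reverse
complement) are counted as off-target evidence by default — in an
amplified library a primer can mis-prime on either cDNA strand — and
can be switched off. `dist_to_3prime` is measured from the hit's
3′-most base to the transcript terminus for both orientations, because
extension initiates at the primer 3′ end. An adapter for an external
SAM-producing local aligner (all-alignments mode, seed length 15, one
seed mismatch) is provided; its gapped alignments are scored as
substitutions plus indel bases, a conservative superset of the
mismatch count, and the naive scan remains the completeness oracle.

The three-stage filter: (1) keep hits with mismatches ≤ 3 by default —
primers with 1–3 mismatches can still cross-amplify; (2) keep hits
within the 3′-distance threshold (default 1000 nt, matching the
amplicon maximum — a required, assay-specific choice); (3) keep a
primer only if its surviving hits map to exactly one gene, that gene
is the intended target, and at least one surviving sense hit is a
perfect match. Hits on multiple transcripts of the same gene are
allowed; the per-gene distance is the minimum across its transcripts.

## Panel optimization

Per gene, candidates pool across all peaks (no per-peak quota). Each
candidate's coverage set is the set of isoforms carrying a perfect
sense binding site within the amplicon bounds; its distance is the
minimum over that set. Multi-peak mode runs greedy set cover: pick the
candidate adding the most uncovered isoforms; ties → smallest
3′-distance → lexicographic id; stop at `max_primers_per_gene`
(default 3) or when the best candidate adds nothing (zero-gain primers
waste pool capacity and are never selected). Single-peak mode is the
same rule truncated to one pick. Greedy is the standard
ln(n)-approximation, not exact cover — acceptable because per-gene
instances are tiny and determinism matters more than optimality.

## Synthetic data generator

`tailprimer.fixtures` emulates exactly the features the pipeline relies
on: multi-isoform genes on both strands whose isoforms share the
3′-terminal exon (isoforms are 5′-truncations of one exon chain),
iid-uniform base composition, Poisson(λ = 1) background coverage over
exonic bases, and a rectangular 100×-depth peak planted in the shared
terminal exon spanning mRNA distances 150–300 nt from the annotated 3′
end — inside the default distance bound and amplicon window. Each
planted window begins (in mRNA sense) with a 40-nt segment containing
a known-valid 22-mer primer site, so design success on every gene is a
ground truth rather than a coin flip; for decoy gene pairs that segment
is *shared verbatim* between the two genes, planting a guaranteed
two-gene perfect off-target whose candidates must die at the
uniqueness stage. Decoy segments are 40 nt — long enough to contain
full-length passing candidates, which a shorter shared k-mer could not
host under the Tm/GC constraint set.

What the generator does **not** emulate: read-level artifacts (UMIs,
duplicates, fragmentation), soft peak shapes, overlapping genes,
GC-biased composition, repetitive elements, or realistic transcriptome
scale. Passing the planted-answer tests therefore demonstrates the
correctness of the interval algebra, orientation handling, filter
cascade and optimizer — not the empirical peak-calling or
thermodynamic accuracy on real libraries, which belongs to the
external engines.

## Numerical choices and degenerate inputs

* P values are floored at 1e−300 before log-transformation.
* BH q-values come from `scipy.stats.false_discovery_control`.
* All tie-breaks end in a lexicographic comparison, so every selection
  step is a pure function of its inputs; repeated runs are
  byte-identical (timestamps live in a separate manifest field).
* Empty outcomes ("no peaks", "no candidates", "no survivors") are
  reported per gene with a closed failure-reason vocabulary, never
  raised; errors are reserved for malformed input (reported with line
  numbers) and configuration mistakes.
* Templates containing N are retained and rejected at the candidate
  level; transcripts shorter than the primer are skipped with a note.

## Problem sizes

The bundled study conditions use 20 genes (~60 kb genome, ~65
transcripts) for end-to-end checks and 500–1000 randomized instances
for the oracle-equivalence properties; these sizes exercise every code
path while keeping the full suite and the acceptance script in the
seconds-to-minutes range.

## Known limitations

* The fallback Tm model makes the default Tm/GC window implicitly a
  length constraint (22–25 nt); Primer3's nearest-neighbor model does
  not share this coupling.
* No cross-primer interaction screening (primer dimers across the
  pool) and no thermodynamic off-target ΔG model.
* Specificity is screened against the supplied transcript set; if only
  the target genes' GTF is given, the screen cannot see off-targets
  elsewhere in the transcriptome — supply a full transcriptome FASTA
  plus transcript-to-gene map for production panels.
* UTR classification relies on annotated CDS/UTR features; genes
  without CDS are treated as all-exonic, which only affects plot
  shading, never window selection.
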