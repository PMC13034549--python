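# tailprimer

Coverage-peak-guided, strand-aware design of gene-specific second-strand
cDNA primers for targeted 3′-end RNA-seq.

## The problem

3′-end RNA-seq captures polyadenylated transcripts with an anchored
oligo(dT) primer and sequences only their 3′ termini — one fragment per
transcript, so read counts track expression directly. Second-strand
synthesis in these protocols is usually random-primed, which wastes
depth on abundant RNAs and penalizes low-abundance targets. Replacing
the random primer with a pool of gene-specific primers redirects
sequencing toward a chosen panel — but those primers must sit exactly
where the 3′ coverage actually accumulates, point toward the poly(A)
junction, and bind nowhere else in the transcriptome.

`tailprimer` automates that design for bulk, single-cell or spatial
workflows built on oligo(dT) capture:

1. **Peak selection** — significant 3′ coverage peaks (ENCODE
   narrowPeak input, or a built-in Poisson fallback caller on
   bedGraph/BAM coverage) are assigned to genes, filtered by q-value,
   peak score (−10·log₁₀ *p*) and exonic overlap, ranked, and trimmed
   to exon/UTR boundaries.
2. **Left-primer design** — each window's template is
   orientation-normalized to 5′→3′ mRNA sense, so only *left* primers
   are designed: every primer extends toward the transcript 3′ end.
   The default engine is a deterministic exhaustive scanner under a
   strict constraint set (Tm 59–61 °C by a GC-count formula, GC 35–65 %,
   homopolymer ≤ 4, self-complementarity screen); a Primer3 adapter is
   available as an optional engine.
3. **Specificity screening** — candidates are aligned against the
   transcriptome (exhaustive ungapped Hamming scan by default; an
   external SAM-producing aligner is pluggable) and pass a three-stage
   filter: mismatch budget (default ≤ 3), distance to the transcript
   3′ end (the prospective amplicon length), and unique-gene mapping
   with a required perfect on-target site.
4. **Panel optimization** — per gene, either the single primer with the
   widest isoform coverage, or (multi-peak mode) a greedy set cover
   over isoforms with ties broken toward the 3′-most primer.
5. **QC** — every requested gene ends either in the panel or with an
   explicit failure reason (insufficient coverage, no significant
   peaks, window too short, sequence complexity, off-target binding);
   runs emit attrition tables, a JSON manifest and per-gene plots.

A distance-based mode designs primers on a fixed 3′-terminal window of
each transcript (default: last 200 nt, final 40 nt excluded) when no
coverage data exist — e.g. for spike-in control panels.

## Worked example

Generate a deterministic synthetic dataset (20 genes, half on the minus
strand, 100× coverage peaks planted near the annotated 3′ ends, two
decoy segments shared between gene pairs) and design a panel:

```bash
tailprimer make-fixture --outdir fx --seed 1
tailprimer design-peaks \
    --gtf fx/annotation.gtf --genome fx/genome.fa \
    --genes fx/genes.txt --bedgraph fx/coverage.bedGraph \
    --outdir run
```

The run log prints the stage attrition:

```
== stage attrition ==
                 requested: 20
                with_peaks: 20
     with_designed_primers: 20
       passing_specificity: 20
               final_panel: 20
  perfect selectivity: 1.00
  mean isoforms covered: 1.80
```

All 20 genes reach the panel; every chosen primer hits exactly one gene
with zero mismatches (perfect selectivity 1.00) and covers on average
1.8 isoforms of its gene. `run/panel.tsv` holds one primer per gene
with sequence, Tm, GC, genomic coordinates, covered isoforms and the
3′-distance (= expected amplicon length to the poly(A) junction);
`run/rejections.tsv` shows the candidates discarded at the uniqueness
stage — including those sitting on the planted decoy repeats, rejected
as "excessive off-target binding".

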