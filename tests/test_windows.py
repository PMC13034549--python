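"""Peak-to-gene assignment, ranking, tie-breaking and exonic trimming."""

import itertools

import pytest

from tailprimer.annotation import GeneModel, TranscriptModel
from tailprimer.intervals import GenomicInterval
from tailprimer.peaks import Peak
from tailprimer.windows import (
    SelectionConfig,
    assign_peaks_to_genes,
    select_windows,
)


def mk_peak(start, end, name="p", pneg=30.0, qneg=25.0, chrom="chr1"):
    return Peak(
        interval=GenomicInterval(chrom, start, end, "."),
        summit_offset=(end - start) // 2,
        score=100,
        pvalue_neglog10=pneg,
        qvalue_neglog10=qneg,
        name=name,
    )


def mk_gene(gid, exon_coords, strand="+"):
    t = TranscriptModel(
        f"{gid}.t1", gid,
        [GenomicInterval("chr1", s, e, strand) for s, e in exon_coords],
    )
    return GeneModel(gid, [t])


class TestAssignment:
    def test_overlap_fraction(self, gene_one_exon):
        assigned, n_drop = assign_peaks_to_genes(
            [mk_peak(100, 250)], {"G1": gene_one_exon}
        )
        assert n_drop == 0
        a = assigned["G1"][0]
        assert a.exonic_overlap_nt == 100
        assert a.exonic_overlap_frac == pytest.approx(100 / 150)

    def test_intronic_peak_not_assigned(self):
        gene = mk_gene("G1", [(100, 200), (500, 600)])
        assigned, n_drop = assign_peaks_to_genes(
            [mk_peak(300, 400)], {"G1": gene}
        )
        assert assigned["G1"] == []
        assert n_drop == 1

    def test_peak_spanning_two_genes_flagged_ambiguous(self):
        g1 = mk_gene("G1", [(100, 300)])
        g2 = mk_gene("G2", [(250, 500)])
        assigned, _ = assign_peaks_to_genes(
            [mk_peak(200, 320)], {"G1": g1, "G2": g2}
        )
        # brute-force overlap check
        assert len(assigned["G1"]) == 1 and len(assigned["G2"]) == 1
        assert assigned["G1"][0].ambiguous and assigned["G2"][0].ambiguous


class TestSelection:
    def test_highest_score_wins_single_peak(self):
        gene = mk_gene("G1", [(0, 1000)])
        peaks = [
            mk_peak(100, 300, "low", pneg=2.0),
            mk_peak(500, 700, "high", pneg=3.0),
        ]
        assigned, _ = assign_peaks_to_genes(peaks, {"G1": gene})
        wins, fails = select_windows(assigned, SelectionConfig(), {"G1": gene})
        assert len(wins) == 1
        assert wins[0].source_peak.name == "high"

    def test_trimmed_to_exon_boundary(self, gene_one_exon):
        assigned, _ = assign_peaks_to_genes(
            [mk_peak(100, 250)], {"G1": gene_one_exon}
        )
        cfg = SelectionConfig(min_window_len=50)
        wins, _ = select_windows(assigned, cfg, {"G1": gene_one_exon})
        assert (wins[0].interval.start, wins[0].interval.end) == (150, 250)
        assert wins[0].interval.strand == "+"

    def test_short_window_dropped_with_reason(self, gene_one_exon):
        assigned, _ = assign_peaks_to_genes(
            [mk_peak(110, 190)], {"G1": gene_one_exon}
        )  # trims to (150,190): 40 nt
        cfg = SelectionConfig(min_window_len=50)
        wins, fails = select_windows(assigned, cfg, {"G1": gene_one_exon})
        assert wins == []
        assert any(f.reason == "window_too_short" for f in fails)

    def test_tie_break_deterministic_under_permutation(self):
        """Score ties resolve by smaller q, then longer trimmed window,
        then 3'-proximity, then name — same winner for every input order."""
        gene = mk_gene("G1", [(0, 2000)])
        peaks = [
            mk_peak(100, 260, "a", pneg=3.0, qneg=2.0),
            mk_peak(600, 760, "b", pneg=3.0, qneg=2.5),   # better q
            mk_peak(1200, 1360, "c", pneg=3.0, qneg=2.5),  # ties with b, closer 3'
        ]
        winners = set()
        for perm in itertools.permutations(peaks):
            assigned, _ = assign_peaks_to_genes(list(perm), {"G1": gene})
            wins, _ = select_windows(assigned, SelectionConfig(), {"G1": gene})
            winners.add(wins[0].source_peak.name)
        assert winners == {"c"}

    def test_exonic_containment_invariant(self, fixture_small):
        from tailprimer.annotation import load_annotation
        from tailprimer.peaks import read_narrowpeak

        genes, _ = load_annotation(fixture_small["gtf"])
        peaks = read_narrowpeak(fixture_small["narrowpeak"])
        assigned, _ = assign_peaks_to_genes(peaks, genes)
        wins, _ = select_windows(assigned, SelectionConfig(), genes)
        assert wins
        for w in wins:
            gene = genes[w.gene_id]
            covered = sum(e.overlap_len(w.interval) for e in gene.exonic_union)
            assert covered == w.interval.length
            assert w.covered_isoforms  # planted windows sit on shared exons

    def test_single_peak_subset_of_multi_peak(self):
        gene = mk_gene("G1", [(0, 2000)])
        peaks = [mk_peak(100, 300, "a", pneg=3.0), mk_peak(700, 900, "b", pneg=4.0)]
        assigned, _ = assign_peaks_to_genes(peaks, {"G1": gene})
        single, _ = select_windows(
            assigned, SelectionConfig(mode="single_peak"), {"G1": gene}
        )
        multi, _ = select_windows(
            assigned, SelectionConfig(mode="multi_peak"), {"G1": gene}
        )
        single_names = {w.name for w in single}
        multi_names = {w.name for w in multi}
        assert single_names <= multi_names and len(multi) == 2

    def test_relaxing_max_q_never_reduces_windows(self):
        gene = mk_gene("G1", [(0, 2000)])
        peaks = [
            mk_peak(100, 300, "a", qneg=1.0),   # q = 0.1
            mk_peak(700, 900, "b", qneg=3.0),   # q = 0.001
        ]
        assigned, _ = assign_peaks_to_genes(peaks, {"G1": gene})
        strict, _ = select_windows(
            assigned, SelectionConfig(mode="multi_peak", max_q=0.01), {"G1": gene}
        )
        relaxed, _ = select_windows(
            assigned, SelectionConfig(mode="multi_peak", max_q=0.5), {"G1": gene}
        )
        assert {w.name for w in strict} <= {w.name for w in relaxed}

    def test_no_peaks_failure_recorded(self):
        gene = mk_gene("G1", [(0, 500)])
        wins, fails = select_windows({"G1": []}, SelectionConfig(), {"G1": gene})
        assert wins == []
        assert fails[0].reason == "no significant peaks"
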