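"""Naive aligner completeness and the three-stage specificity filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailprimer.annotation import reverse_complement
from tailprimer.primers import PrimerCandidate
from tailprimer.specificity import (
    AlignmentHit,
    FilterConfig,
    REASON_NO_ON_TARGET,
    REASON_OFF_TARGET,
    naive_align,
    three_stage_filter,
)


def mk_primer(pid="p1", gene="geneA", seq="ACGTACGTACGTACGTACGT"):
    return PrimerCandidate(pid, gene, None, seq, 0, 60.0, 50.0, 0.0)


def mk_hit(pid, gene, mm, dist, tid=None, strand="sense"):
    return AlignmentHit(pid, tid or f"{gene}.t1", gene, 0, 20, strand, mm, dist)


class TestNaiveAlign:
    def test_unique_planted_site(self):
        """A primer equal to a unique 20-mer ending at t_end 180 of a
        500-nt transcript gives one sense hit at distance 320."""
        rng = np.random.default_rng(3)
        tx = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
        primer = tx[160:180]
        hits = naive_align(primer, {"T": tx}, {"T": "G"}, max_mm=0)
        sense = [h for h in hits if h.hit_strand == "sense"]
        assert len(sense) == 1
        h = sense[0]
        assert (h.t_start, h.t_end) == (160, 180)
        assert h.mismatches == 0
        assert h.dist_to_3prime == 320

    def test_two_gene_plant(self):
        rng = np.random.default_rng(4)
        site = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
        t1 = "AAAA" + site + "CCCCGGGG" * 10
        t2 = "TTTTTTTT" + site + "ACACAC" * 15
        hits = naive_align(site, {"A.t1": t1, "B.t1": t2},
                           {"A.t1": "A", "B.t1": "B"}, max_mm=0)
        sense = [h for h in hits if h.hit_strand == "sense" and h.mismatches == 0]
        assert {h.gene_id for h in sense} == {"A", "B"}

    def test_mismatch_counting_vs_hamming(self):
        rng = np.random.default_rng(5)
        tx = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        primer = list(tx[100:120])
        primer[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[primer[3]]
        primer[15] = {"A": "G", "C": "T", "G": "A", "T": "C"}[primer[15]]
        primer = "".join(primer)
        hits = naive_align(primer, {"T": tx}, {"T": "G"}, max_mm=3)
        at_site = [h for h in hits if h.t_start == 100]
        assert len(at_site) == 1
        # independent Hamming count
        expected = sum(a != b for a, b in zip(primer, tx[100:120]))
        assert at_site[0].mismatches == expected == 2

    def test_exact_length_transcript(self):
        hits = naive_align("ACGTACGTACGTACGTACGT",
                           {"T": "ACGTACGTACGTACGTACGT"}, {"T": "G"}, max_mm=0)
        sense = [h for h in hits if h.hit_strand == "sense"]
        assert len(sense) == 1 and sense[0].dist_to_3prime == 0

    def test_antisense_detection(self):
        rng = np.random.default_rng(6)
        primer = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
        tx = "GGGG" + reverse_complement(primer) + "AAAA" * 10
        hits = naive_align(primer, {"T": tx}, {"T": "G"}, max_mm=0,
                           count_antisense=True)
        assert any(h.hit_strand == "antisense" and h.mismatches == 0 for h in hits)
        hits_off = naive_align(primer, {"T": tx}, {"T": "G"}, max_mm=0,
                               count_antisense=False)
        assert all(h.hit_strand == "sense" for h in hits_off)

    def test_unknown_transcript_in_map_is_error(self):
        with pytest.raises(KeyError):
            naive_align("ACGT" * 5, {"T": "ACGT" * 20}, {}, max_mm=0)


class TestThreeStageFilter:
    def test_distant_off_target_removed_then_unique(self):
        """Hand-trace: the geneB hit dies at the distance stage, leaving a
        unique on-target primer."""
        p = mk_primer()
        hits = [mk_hit("p1", "geneA", 0, 100), mk_hit("p1", "geneB", 2, 5000)]
        cfg = FilterConfig(max_mismatches=3, max_dist_3prime=1000)
        surv, rej = three_stage_filter(hits, [p], cfg)
        assert [s.primer_id for s in surv] == ["p1"]
        assert rej == []

    def test_two_gene_hit_rejected(self):
        p = mk_primer()
        hits = [mk_hit("p1", "geneA", 0, 100), mk_hit("p1", "geneB", 1, 200)]
        cfg = FilterConfig(max_mismatches=3, max_dist_3prime=1000)
        surv, rej = three_stage_filter(hits, [p], cfg)
        assert surv == []
        assert rej[0][1] == REASON_OFF_TARGET

    def test_no_surviving_hits_is_no_on_target(self):
        p = mk_primer()
        hits = [mk_hit("p1", "geneA", 4, 100)]
        cfg = FilterConfig(max_mismatches=3, max_dist_3prime=1000)
        surv, rej = three_stage_filter(hits, [p], cfg)
        assert surv == []
        assert rej[0][1] == REASON_NO_ON_TARGET

    def test_multiple_transcripts_same_gene_allowed(self):
        p = mk_primer()
        hits = [
            mk_hit("p1", "geneA", 0, 100, tid="geneA.t1"),
            mk_hit("p1", "geneA", 1, 400, tid="geneA.t2"),
        ]
        cfg = FilterConfig()
        surv, _ = three_stage_filter(hits, [p], cfg)
        assert len(surv) == 1

    @settings(max_examples=100, derandomize=True)
    @given(
        mismatches=st.lists(st.integers(0, 6), min_size=1, max_size=20),
        dists=st.lists(st.integers(0, 3000), min_size=1, max_size=20),
        max_mm=st.integers(0, 4),
        max_dist=st.integers(100, 2000),
    )
    def test_stage1_stage2_commute(self, mismatches, dists, max_mm, max_dist):
        """The per-hit mismatch and distance predicates commute."""
        n = min(len(mismatches), len(dists))
        hits = [mk_hit("p1", "geneA", mismatches[i], dists[i]) for i in range(n)]

        def stage1(hs):
            return [h for h in hs if h.mismatches <= max_mm]

        def stage2(hs):
            return [h for h in hs if h.dist_to_3prime <= max_dist]

        assert stage1(stage2(hits)) == stage2(stage1(hits))

    def test_monotonicity_in_thresholds(self):
        """Relaxing stage-1/2 thresholds never shrinks the surviving-hit
        set; the primer-level survivor set may shrink as off-targets appear."""
        rng = np.random.default_rng(9)
        genes = ["geneA", "geneB", "geneC"]
        primers = [mk_primer(f"p{i}", "geneA") for i in range(6)]
        hits = []
        for p in primers:
            for _ in range(rng.integers(1, 8)):
                hits.append(
                    mk_hit(
                        p.primer_id,
                        genes[rng.integers(0, 3)],
                        int(rng.integers(0, 5)),
                        int(rng.integers(0, 2500)),
                    )
                )

        def surviving_hits(cfg):
            return {
                (h.primer_id, h.gene_id, h.mismatches, h.dist_to_3prime, i)
                for i, h in enumerate(hits)
                if h.mismatches <= cfg.max_mismatches
                and h.dist_to_3prime <= cfg.max_dist_3prime
            }

        tight = FilterConfig(max_mismatches=1, max_dist_3prime=500)
        loose = FilterConfig(max_mismatches=4, max_dist_3prime=2500)
        assert surviving_hits(tight) <= surviving_hits(loose)
        surv_tight, _ = three_stage_filter(hits, primers, tight)
        surv_loose, _ = three_stage_filter(hits, primers, loose)
        # brute-force reimplementation agrees at both settings
        for cfg, surv in [(tight, surv_tight), (loose, surv_loose)]:
            expected = _brute_force_stage3(hits, primers, cfg)
            assert {p.primer_id for p in surv} == expected


def _brute_force_stage3(hits, primers, cfg):
    """Independent per-primer set reimplementation of the cascade."""
    out = set()
    for p in primers:
        kept = [
            h for h in hits
            if h.primer_id == p.primer_id
            and h.mismatches <= cfg.max_mismatches
            and h.dist_to_3prime <= cfg.max_dist_3prime
            and (cfg.count_antisense_hits or h.hit_strand == "sense")
        ]
        genes = {h.gene_id for h in kept}
        perfect = [
            h for h in kept
            if h.gene_id == p.gene_id and h.mismatches == 0
            and h.hit_strand == "sense"
        ]
        if genes == {p.gene_id} and perfect:
            out.add(p.primer_id)
    return out
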