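"""sRNA candidate detection, origin rules, quality filters and the
built-in folding score vs exhaustive search."""

from itertools import combinations

import numpy as np
import pytest

import rnannotate as rn
from rnannotate.boundary_annotate import UTRCall
from rnannotate.genome_io import CoverageTrack, Feature, Genome, Library
from rnannotate.srna_detect import (
    SRNAParams,
    apply_quality_filters,
    builtin_fold_score,
    detect_intergenic,
    detect_utr_derived,
)
from rnannotate.transcript_detect import TranscriptCall
from rnannotate.tss_ps_detect import SiteCall

FRAG = Library("frag_c1_1", "fragmented", "c1", 1)


def _gene(start, end, strand="+", gid="g"):
    return Feature("c", "t", "gene", start, end, strand, attributes={"ID": [gid]})


def _tx(start, end, strand="+"):
    return TranscriptCall("c", strand, start, end)


def _tss(pos, strand="+"):
    return SiteCall("c", strand, pos, "TSS", step_height=10.0)


def _ps(pos, strand="+"):
    return SiteCall("c", strand, pos, "PS", step_height=10.0)


class TestDetectIntergenic:
    def test_short_tss_anchored_transcript(self):
        (cand,) = detect_intergenic([_tx(100, 180)], [], [_tss(100)], [], [])
        assert (cand.origin, cand.end_anchor) == ("intergenic", "transcript_edge")
        assert cand.tss_position == 100

    def test_antisense_origin(self):
        (cand,) = detect_intergenic(
            [_tx(100, 180)], [_gene(120, 160, strand="-")], [_tss(100)], [], []
        )
        assert cand.origin == "antisense"

    def test_same_strand_gene_excludes(self):
        assert detect_intergenic(
            [_tx(100, 180)], [_gene(120, 160)], [_tss(100)], [], []
        ) == []

    def test_no_tss_rejected_reason(self):
        (cand,) = detect_intergenic([_tx(100, 180)], [], [], [], [])
        assert cand.tss_position is None
        genome = Genome("c", "A" * 300)
        apply_quality_filters([cand], genome, check_fold=False)
        assert not cand.passed_filters
        assert "no TSS" in cand.reject_reasons

    def test_long_transcript_refined_at_drop(self):
        values = np.zeros(1200)
        values[99:700] = 50.0  # high coverage then a sharp drop at 701
        values[700:999] = 2.0
        track = CoverageTrack("c", "+", FRAG, values)
        (cand,) = detect_intergenic(
            [_tx(100, 999)], [], [_tss(100)], [], [track]
        )
        assert cand.end_anchor == "drop_point"
        assert cand.end == 701
        assert cand.length < 900

    def test_ps_beats_later_drop(self):
        values = np.zeros(1200)
        values[99:999] = 50.0
        track = CoverageTrack("c", "+", FRAG, values)
        (cand,) = detect_intergenic(
            [_tx(100, 999)], [], [_tss(100)], [_ps(400)], [track]
        )
        assert (cand.end_anchor, cand.end) == ("processing_site", 400)
        assert cand.ps_position == 400


class TestDetectUtrDerived:
    def test_five_utr_tss_to_ps(self):
        utr = UTRCall("five_prime", "c", "+", 100, 200, "g", "TSS")
        (cand,) = detect_utr_derived(
            [_tx(100, 500)], [_gene(201, 450)], [_tss(100)], [_ps(160)], [], [utr]
        )
        assert (cand.origin, cand.start, cand.end) == ("five_utr", 100, 160)
        assert cand.end_anchor == "processing_site"

    def test_three_utr_ps_to_edge(self):
        utr = UTRCall("three_prime", "c", "+", 460, 520, "g", "transcript_edge")
        (cand,) = detect_utr_derived(
            [_tx(100, 520)], [_gene(150, 459)], [], [_ps(465)], [], [utr]
        )
        assert (cand.origin, cand.start, cand.end) == ("three_utr", 465, 520)
        assert cand.ps_position == 465

    def test_inter_cds_requires_ps_start(self):
        genes = [_gene(100, 200, gid="a"), _gene(400, 500, gid="b")]
        assert detect_utr_derived([_tx(80, 520)], genes, [], [], [], []) == []
        (cand,) = detect_utr_derived(
            [_tx(80, 520)], genes, [], [_ps(230), _ps(330)], [], []
        )
        assert (cand.origin, cand.start, cand.end) == ("inter_cds", 230, 330)


class TestBuiltinFoldScore:
    def test_known_hairpin(self):
        assert builtin_fold_score("GGGGAAACCCC") == pytest.approx(-4 / 11)

    def test_unpairable(self):
        assert builtin_fold_score("AAAAAAA") == 0.0

    def test_score_range(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 40))))
            assert -0.5 <= builtin_fold_score(seq) <= 0.0

    @staticmethod
    def _brute_force_pairs(seq):
        """Exhaustive max non-crossing matching with loop >= 3."""
        pairs = {
            ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
        }
        n = len(seq)
        candidates = [
            (i, j) for i, j in combinations(range(n), 2)
            if j - i > 3 and (seq[i], seq[j]) in pairs
        ]

        def best(chosen, remaining):
            if not remaining:
                return len(chosen)
            (i, j), rest = remaining[0], remaining[1:]
            score = best(chosen, rest)  # skip this pair
            # compatibility: no shared base, no crossing
            compatible = all(
                i != a and i != b and j != a and j != b
                and not (a < i < b < j) and not (i < a < j < b)
                for a, b in chosen
            )
            if compatible:
                score = max(score, best(chosen + [(i, j)], rest))
            return score

        return best([], candidates)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_small(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 12))))
        assert builtin_fold_score(seq) == pytest.approx(
            -self._brute_force_pairs(seq) / len(seq)
        )


class TestQualityFilters:
    def _candidate(self, genome_seq, start, end, origin="intergenic", tss=None):
        from rnannotate.srna_detect import SRNACandidate

        return SRNACandidate("c", "+", start, end, origin, tss_position=tss), Genome("c", genome_seq)

    def test_short_candidate_rejected(self):
        cand, genome = self._candidate("A" * 100, 10, 34, tss=10)
        apply_quality_filters([cand], genome)
        assert "length<30" in cand.reject_reasons

    def test_polya_rejected_for_fold(self):
        cand, genome = self._candidate("A" * 200, 10, 89, tss=10)
        apply_quality_filters([cand], genome)
        assert "unstable fold" in cand.reject_reasons

    def test_hairpin_passes_all(self):
        hp = "GGGGGGGGGGGGAAAACCCCCCCCCCCC"
        seq = "A" * 9 + hp * 3 + "A" * 100
        cand, genome = self._candidate(seq, 10, 9 + 3 * len(hp), tss=10)
        apply_quality_filters([cand], genome)
        assert cand.passed_filters, cand.reject_reasons
        assert cand.fold_score <= -0.05

    def test_filters_individually_deactivatable(self):
        cand, genome = self._candidate("A" * 200, 10, 89, tss=None)
        apply_quality_filters([cand], genome, check_fold=False, check_anchor=False)
        assert cand.passed_filters

    def test_known_srna_bypasses_filters(self):
        cand, genome = self._candidate("A" * 200, 10, 34, tss=None)  # too short + no TSS
        known = [Feature("c", "db", "sRNA", 5, 40, "+", attributes={"ID": ["k1"]})]
        apply_quality_filters([cand], genome, known_srnas=known)
        assert cand.passed_filters

    def test_passed_candidates_satisfy_every_filter(self, small_dataset, small_tracks,
                                                    called_transcripts, called_tss,
                                                    called_ps):
        ds = small_dataset
        utrs = rn.derive_utrs(called_tss, called_transcripts, [], ds.genes)
        cands = detect_intergenic(
            called_transcripts, ds.genes, called_tss, called_ps, small_tracks
        )
        cands += detect_utr_derived(
            called_transcripts, ds.genes, called_tss, called_ps, small_tracks, utrs
        )
        apply_quality_filters(cands, ds.genome)
        params = SRNAParams()
        for c in cands:
            if c.passed_filters:
                assert params.min_len <= c.length <= params.max_len
                assert c.fold_score <= params.fold_cutoff
                if c.origin in ("intergenic", "antisense", "five_utr"):
                    assert c.tss_position is not None


class TestRecoveryOnSynthetic:
    def test_planted_intergenic_srnas_recovered(self, small_dataset, small_tracks,
                                                called_transcripts, called_tss,
                                                called_ps):
        ds = small_dataset
        cands = detect_intergenic(
            called_transcripts, ds.genes, called_tss, called_ps, small_tracks
        )
        apply_quality_filters(cands, ds.genome)
        passed = [c for c in cands if c.passed_filters]
        recovered = sum(
            any(
                c.strand == p.strand
                and abs(c.start - p.start) <= 5
                and abs(c.end - p.end) <= 5
                for c in passed
            )
            for p in ds.truth.srnas
        )
        assert recovered >= 0.9 * len(ds.truth.srnas)
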