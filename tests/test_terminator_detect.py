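"""Hairpin enumeration vs brute force, convergent-pair heuristic and
coverage-drop confirmation."""

import numpy as np
import pytest

import rnannotate as rn
from rnannotate.genome_io import CoverageTrack, Feature, Genome, Library
from rnannotate.terminator_detect import (
    Hairpin,
    HairpinConstraints,
    TerminatorCall,
    confirm_by_coverage,
    dedupe_per_gene,
    detect_convergent,
    find_hairpins,
    reverse_complement,
)

FRAG = Library("frag_c1_1", "fragmented", "c1", 1)

_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


def brute_force_hairpins(seq, c=HairpinConstraints()):
    """Independent enumerator over (stem, loop, offset)."""
    seq = seq.upper()
    out = []
    for off in range(len(seq)):
        for stem in range(c.stem_min, c.stem_max + 1):
            for loop in range(c.loop_min, c.loop_max + 1):
                total = 2 * stem + loop
                if off + total > len(seq):
                    continue
                left = seq[off : off + stem]
                right = seq[off + stem + loop : off + total]
                unpaired = sum(
                    (left[k], right[stem - 1 - k]) not in _PAIRS for k in range(stem)
                )
                if unpaired <= c.max_unpaired_frac * stem:
                    out.append((off + 1, stem, loop, unpaired))
    return sorted(out)


class TestFindHairpins:
    def test_perfect_palindrome(self):
        hps = find_hairpins("GCGCGCAAAAGCGCGC")
        assert any(
            (h.stem_len, h.loop_len, h.unpaired_in_stem) == (6, 4, 0) for h in hps
        )

    def test_stem_below_minimum_rejected(self):
        assert find_hairpins("GCGAAAGC") == []

    def test_unpaired_fraction_bound(self):
        # stem 4 allows at most one unpaired position (25%)
        hps = find_hairpins("GGGGAAAACCCA", HairpinConstraints(stem_max=4))
        assert any(h.unpaired_in_stem == 1 for h in hps)
        for h in hps:
            assert h.unpaired_in_stem / h.stem_len <= 0.25

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        got = sorted(
            (h.stem_start, h.stem_len, h.loop_len, h.unpaired_in_stem)
            for h in find_hairpins(seq)
        )
        assert got == brute_force_hairpins(seq)

    def test_all_outputs_satisfy_printed_bounds(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            for h in find_hairpins(seq):
                assert 4 <= h.stem_len <= 20
                assert 3 <= h.loop_len <= 10
                assert h.unpaired_in_stem / h.stem_len <= 0.25


def _gene(start, end, strand, gid="g"):
    return Feature("c", "t", "gene", start, end, strand, attributes={"ID": [gid]})


def _genome_with_gap(gap_seq, left_len=100, right_len=100):
    rng = np.random.default_rng(0)
    filler = lambda n: "".join(rng.choice(list("AC"), size=n))  # no hairpins, no T
    seq = filler(left_len) + gap_seq + filler(right_len)
    genes = [
        _gene(1, left_len, "+", "gl"),
        _gene(left_len + len(gap_seq) + 1, left_len + len(gap_seq) + right_len, "-", "gr"),
    ]
    return Genome("c", seq), genes


class TestDetectConvergent:
    def test_hairpin_plus_t_tract_called(self):
        genome, genes = _genome_with_gap("GCGCGCAAAAGCGCGC" + "TTTTTTT" + "ACACACAC")
        calls = detect_convergent(genes, genome)
        assert any(c.strand == "+" for c in calls)
        call = next(c for c in calls if c.strand == "+")
        assert call.start == 101  # hairpin begins right at the gap start
        assert call.method == "convergent_heuristic"

    def test_gap_longer_than_80_skipped(self):
        gap = "GCGCGCAAAAGCGCGC" + "TTTTTTT" + "A" * 70  # 93 nt
        genome, genes = _genome_with_gap(gap)
        assert detect_convergent(genes, genome) == []

    def test_codirectional_pair_never_considered(self):
        genome, genes = _genome_with_gap("GCGCGCAAAAGCGCGCTTTTTTT")
        genes[1] = _gene(genes[1].start, genes[1].end, "+", "gr")
        assert detect_convergent(genes, genome) == []

    def test_too_few_thymines_rejected(self):
        genome, genes = _genome_with_gap("GCGCGCAAAAGCGCGC" + "TTTTTAA" + "ACACAC")
        calls = detect_convergent(genes, genome)
        assert all(c.strand != "+" for c in calls)  # only 5 T in any window

    def test_minus_orientation_detected(self):
        # motif readable on the reverse complement of the gap
        motif = reverse_complement("GCGCGCAAAAGCGCGC" + "TTTTTTT")
        genome, genes = _genome_with_gap(motif + "ACACAC")
        calls = detect_convergent(genes, genome)
        assert any(c.strand == "-" for c in calls)


def _track(values, strand="+"):
    return CoverageTrack("c", strand, FRAG, np.asarray(values, dtype=float))


def _cand(start, end, strand="+", confirmed=False, ratio=None):
    return TerminatorCall("c", strand, start, end, "external_confirmed",
                          drop_ratio=ratio, confirmed=confirmed)


class TestConfirmByCoverage:
    def test_drop_confirmed(self):
        values = [100.0] * 60 + [100, 80, 40, 10] + [10.0] * 60
        (out,) = confirm_by_coverage([_cand(61, 64)], [_track(values)], 0.5, flank=30)
        assert out.confirmed
        assert out.drop_ratio == pytest.approx(0.1)

    def test_flat_not_confirmed(self):
        (out,) = confirm_by_coverage([_cand(31, 33)], [_track([50.0] * 100)], 0.5)
        assert not out.confirmed and out.drop_ratio == 1.0

    def test_all_zero_not_confirmed(self):
        (out,) = confirm_by_coverage([_cand(31, 33)], [_track([0.0] * 100)], 0.5)
        assert not out.confirmed and out.drop_ratio == 1.0

    def test_region_clipped_at_replicon_ends(self):
        values = [100.0, 50.0, 10.0, 5.0, 5.0]
        (out,) = confirm_by_coverage([_cand(1, 3)], [_track(values)], 0.5, flank=30)
        assert out.confirmed

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(1, 100, size=400)
        cands = [_cand(s, s + 20) for s in range(40, 320, 40)]
        tracks = [_track(values)]
        confirmed_sets = []
        for cutoff in (0.2, 0.5, 0.9):
            out = confirm_by_coverage(cands, tracks, cutoff)
            confirmed_sets.append({(c.start, c.end) for c in out if c.confirmed})
        assert confirmed_sets[0] <= confirmed_sets[1] <= confirmed_sets[2]


class TestDedupePerGene:
    def test_keeps_lowest_drop_ratio(self):
        gene = _gene(1, 100, "+")
        cands = [
            _cand(120, 140, confirmed=True, ratio=0.4),
            _cand(160, 180, confirmed=True, ratio=0.1),
        ]
        out = dedupe_per_gene(cands, [gene])
        assert [(c.start, c.drop_ratio) for c in out] == [(160, 0.1)]

    def test_single_candidate_kept(self):
        out = dedupe_per_gene([_cand(120, 140, confirmed=True, ratio=0.3)], [_gene(1, 100, "+")])
        assert len(out) == 1

    def test_candidates_for_different_genes_both_kept(self):
        genes = [_gene(1, 100, "+", "a"), _gene(500, 600, "+", "b")]
        cands = [
            _cand(120, 140, confirmed=True, ratio=0.4),
            _cand(620, 640, confirmed=True, ratio=0.1),
        ]
        assert len(dedupe_per_gene(cands, genes)) == 2


class TestOnSynthetic:
    def test_planted_terminators_all_confirmed(self, small_dataset, small_tracks):
        ds = small_dataset
        frag = [t for t in small_tracks if t.library.treatment != "TEX_plus"]
        cands = [
            TerminatorCall(ds.truth.replicon_id, t.strand, t.start, t.end, "external_confirmed")
            for t in ds.truth.terminators
        ]
        out = confirm_by_coverage(cands, frag, 0.5, flank=30)
        assert all(c.confirmed for c in out)

    def test_convergent_pair_found_in_synthetic_genome(self, small_dataset):
        calls = detect_convergent(small_dataset.genes, small_dataset.genome)
        planted = [
            t for t in small_dataset.truth.terminators
        ]
        # the explicitly planted convergent-gap terminator is among the calls
        assert any(
            any(c.start <= p.end and p.start <= c.end for c in calls) for p in planted
        )
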