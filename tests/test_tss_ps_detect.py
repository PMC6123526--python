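"""Site statistics, threshold calling vs a brute-force oracle,
classification and curated-set evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rnannotate as rn
from rnannotate.genome_io import CoverageTrack, Feature, Library
from rnannotate.tss_ps_detect import (
    EPSILON,
    CuratedSet,
    ParamSet,
    SiteCall,
    call_sites,
    classify_tss,
    evaluate,
    site_statistics,
)

PLUS_LIB = Library("tex_plus_c1_1", "TEX_plus", "c1", 1)
MINUS_LIB = Library("tex_minus_c1_1", "TEX_minus", "c1", 1)


def _pair(plus_values, minus_values, strand="+"):
    return (
        CoverageTrack("c", strand, PLUS_LIB, np.asarray(plus_values, float)),
        CoverageTrack("c", strand, MINUS_LIB, np.asarray(minus_values, float)),
    )


class TestSiteStatistics:
    def test_sharp_step(self):
        tp, tm = _pair([1, 1, 50], [1, 1, 5])
        sh, sf, en = site_statistics(tp, tm, 3)
        assert (sh, sf, en) == (49.0, 50.0, 10.0)

    def test_flat(self):
        tp, tm = _pair([5, 5, 5], [5, 5, 5])
        sh, sf, en = site_statistics(tp, tm, 2)
        assert (sh, sf) == (0.0, 1.0)

    def test_pseudocount_when_minus_zero(self):
        tp, tm = _pair([1, 8], [0, 0])
        _, _, en = site_statistics(tp, tm, 2)
        assert en == 8.0 / EPSILON

    def test_minus_strand_upstream_neighbor(self):
        # on the minus strand the upstream neighbor of position p is p+1
        tp, tm = _pair([50, 1, 1], [5, 1, 1], strand="-")
        sh, sf, en = site_statistics(tp, tm, 1)
        assert (sh, sf, en) == (49.0, 50.0, 10.0)

    def test_first_oriented_position_errors(self):
        tp, tm = _pair([1, 2], [1, 1])
        with pytest.raises(IndexError):
            site_statistics(tp, tm, 1)


def brute_force_sites(plus, minus, params, mode, strand="+"):
    """Independent per-position threshold oracle (no clustering)."""
    a = list(plus)
    b = list(minus)
    if strand == "-":
        a, b = a[::-1], b[::-1]
    if mode == "PS":
        a, b = b, a
        enrich_threshold = params.processing_site_factor
    else:
        enrich_threshold = params.enrichment_factor
    hits = []
    for i in range(1, len(a)):
        sh = a[i] - a[i - 1]
        sf = a[i] / max(a[i - 1], EPSILON)
        en = a[i] / max(b[i], EPSILON)
        strict = sh >= params.height and sf >= params.factor
        reduced = (
            en >= enrich_threshold
            and sh >= params.height - params.height_reduction
            and sf >= params.factor - params.factor_reduction
        )
        if a[i] >= params.base_height and en >= 1.0 and (strict or reduced):
            pos = i + 1 if strand == "+" else len(a) - i
            hits.append(pos)
    return sorted(hits)


@st.composite
def _tracks_and_params(draw):
    n = draw(st.integers(min_value=5, max_value=120))
    plus = draw(st.lists(st.integers(min_value=0, max_value=60), min_size=n, max_size=n))
    minus = draw(st.lists(st.integers(min_value=0, max_value=60), min_size=n, max_size=n))
    params = ParamSet(
        height=draw(st.floats(min_value=0, max_value=5)),
        height_reduction=0.0,
        factor=draw(st.floats(min_value=0, max_value=5)),
        factor_reduction=0.0,
        enrichment_factor=draw(st.floats(min_value=0, max_value=4)),
        processing_site_factor=draw(st.floats(min_value=0, max_value=4)),
        base_height=draw(st.floats(min_value=0, max_value=10)),
    )
    strand = draw(st.sampled_from("+-"))
    mode = draw(st.sampled_from(["TSS", "PS"]))
    return plus, minus, params, strand, mode


class TestCallSites:
    def test_single_sharp_step_is_one_tss(self):
        plus = [1, 1, 1, 1, 80, 80, 80, 1, 1, 1]
        minus = [1, 1, 1, 1, 2, 2, 2, 1, 1, 1]
        tp, tm = _pair(plus, minus)
        calls = call_sites([tp], [tm], ParamSet(), mode="TSS")
        assert [c.position for c in calls] == [5]
        assert calls[0].conditions == ("c1",)

    def test_enrichment_branches(self):
        # identical TEX+/TEX- step: enrichment 1 < enrichment_factor, but the
        # non-reduced branch passes on its own (en >= 1 still required)
        step = [1, 1, 1, 40, 40, 40]
        tp, tm = _pair(step, step)
        params = ParamSet(height=2.0, factor=3.0, enrichment_factor=2.0)
        calls = call_sites([tp], [tm], params, mode="TSS")
        assert [c.position for c in calls] == [4]
        # raising factor above the step disables the strict branch; the
        # reduced branch now needs enrichment >= 2, which is absent
        params = ParamSet(height=2.0, factor=100.0, enrichment_factor=2.0)
        assert call_sites([tp], [tm], params, mode="TSS") == []

    def test_ps_mode_reverse_pattern(self):
        plus = [1, 1, 1, 1, 1, 1]
        minus = [1, 1, 1, 40, 40, 40]
        tp, tm = _pair(plus, minus)
        calls = call_sites([tp], [tm], ParamSet(), mode="PS")
        assert [c.position for c in calls] == [4]
        assert calls[0].site_type == "PS"

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            call_sites([], [], ParamSet(), mode="TSS")

    @given(_tracks_and_params())
    @settings(max_examples=120, deadline=None)
    def test_oracle_equivalence(self, case):
        plus, minus, params, strand, mode = case
        tp, tm = _pair(plus, minus, strand=strand)
        calls = call_sites([tp], [tm], params, mode=mode, cluster_width=0)
        assert sorted(c.position for c in calls) == brute_force_sites(
            plus, minus, params, mode, strand
        )

    def test_monotonic_in_thresholds(self, tex_pairs):
        tex_plus, tex_minus = tex_pairs
        base = ParamSet(height=0.3, height_reduction=0.0, factor=1.5,
                        factor_reduction=0.0, enrichment_factor=1.5, base_height=0.0)
        n_base = len(call_sites(tex_plus, tex_minus, base, mode="TSS"))
        for name in ("height", "factor", "enrichment_factor", "base_height"):
            kwargs = base.as_dict()
            kwargs[name] = kwargs[name] + 5.0
            n = len(call_sites(tex_plus, tex_minus, ParamSet(**kwargs), mode="TSS"))
            assert n <= n_base

    def test_clustering_keeps_highest_step(self):
        plus = [1, 1, 30, 60, 1, 1]
        minus = [1, 1, 1, 1, 1, 1]
        tp, tm = _pair(plus, minus)
        params = ParamSet(height=2, factor=1.5, enrichment_factor=1.5)
        calls = call_sites([tp], [tm], params, mode="TSS", cluster_width=3)
        assert len(calls) == 1
        # step at 4 (60-30=30) is larger than at 3 (30-1=29)
        assert calls[0].position == 4


def _gene(start, end, strand="+", gid="g"):
    return Feature("c", "t", "gene", start, end, strand, attributes={"ID": [gid]})


def _tss(pos, strand="+", step=10.0):
    return SiteCall("c", strand, pos, "TSS", step_height=step)


class TestClassifyTss:
    def test_single_upstream_is_primary(self):
        (s,) = classify_tss([_tss(150)], [_gene(200, 400)])
        assert s.classes == {"primary"}

    def test_strongest_wins_primary_others_secondary(self):
        sites = classify_tss(
            [_tss(150, step=20), _tss(80, step=5)], [_gene(200, 400)]
        )
        by_pos = {s.position: s.classes for s in sites}
        assert by_pos[150] == {"primary"}
        assert by_pos[80] == {"secondary"}

    def test_internal_and_antisense(self):
        sites = classify_tss(
            [_tss(250), _tss(260, strand="-")], [_gene(200, 400)]
        )
        by = {(s.position, s.strand): s.classes for s in sites}
        assert by[(250, "+")] == {"internal"}
        assert by[(260, "-")] == {"antisense"}

    def test_orphan(self):
        (s,) = classify_tss([_tss(5000)], [_gene(200, 400)])
        assert s.classes == {"orphan"}

    def test_every_tss_classified(self, called_tss):
        assert all(s.classes for s in called_tss)

    def test_minus_strand_primary_window(self):
        (s,) = classify_tss([_tss(450, strand="-")], [_gene(200, 400, strand="-")])
        assert s.classes == {"primary"}


class TestEvaluate:
    def test_match_within_tolerance(self):
        curated = CuratedSet({("c", "+", 100)}, 1, 1000)
        stats = evaluate([_tss(101)], curated, match_tolerance=2)
        assert (stats.TP, stats.FP, stats.TPR) == (1, 0, 1.0)

    def test_miss_counts_fp(self):
        curated = CuratedSet({("c", "+", 100)}, 1, 1000)
        stats = evaluate([_tss(150)], curated, match_tolerance=2)
        assert (stats.TP, stats.FP) == (0, 1)

    def test_fpr_denominator(self):
        curated = CuratedSet(
            {("c", "+", i) for i in range(1, 101)}, 1, 10_000
        )
        calls = [_tss(5000 + 10 * i) for i in range(33)]
        stats = evaluate(calls, curated, match_tolerance=2)
        assert stats.FP == 33
        assert stats.FPR == pytest.approx(33 / 9900)

    def test_calls_outside_region_ignored(self):
        curated = CuratedSet({("c", "+", 100)}, 1, 200)
        stats = evaluate([_tss(100), _tss(500)], curated)
        assert (stats.TP, stats.FP) == (1, 0)

    def test_each_call_matches_at_most_one_site(self):
        curated = CuratedSet({("c", "+", 100), ("c", "+", 102)}, 1, 200)
        stats = evaluate([_tss(101)], curated, match_tolerance=2)
        assert (stats.TP, stats.FP) == (1, 0)

    def test_empty_curated_errors(self):
        with pytest.raises(ValueError):
            evaluate([_tss(1)], CuratedSet(set(), 1, 100))


class TestOnSynthetic:
    def test_planted_tss_all_recovered_at_defaults(self, small_dataset, called_tss):
        planted = {(s.strand, s.position) for s in small_dataset.truth.tss}
        called = {(s.strand, s.position) for s in called_tss}
        assert planted <= called

    def test_planted_ps_recovered(self, small_dataset, called_ps):
        planted = {(s.strand, s.position) for s in small_dataset.truth.ps}
        called = {(s.strand, s.position) for s in called_ps}
        assert planted <= called

    def test_tss_and_ps_are_disjoint_site_sets(self, called_tss, called_ps):
        tss_pos = {(s.strand, s.position) for s in called_tss}
        ps_pos = {(s.strand, s.position) for s in called_ps}
        assert not (tss_pos & ps_pos)
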