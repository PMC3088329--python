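import math

import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from numtsieve.substitution_profile import SubstitutionCounts
from numtsieve.trait_battery import (
    TRAIT_IDS,
    TraitReference,
    compute_traits,
    default_reference,
    evaluate,
    load_reference,
    proportion_ci,
)


def published_coi_counts():
    """Raw counts of the 1557 bp beetle COI haplotype survey (58 haplotypes)."""
    return SubstitutionCounts(
        total=125, pos1=15, pos2=2, pos3=108, nonsyn=13,
        c_to_t=25, c_to_t_with_context=25, gc_to_gt=3,
        insertions=0, deletions=0, extra_stops=0,
        ts3=95, tv3=13, ts_all=110, tv_all=15,
        gc_percent=34.6, n_columns=1557, n_haplotypes=58,
    )


class TestDefaultReference:
    def test_covers_all_eleven_traits_once(self):
        refs = default_reference()
        assert sorted(r.trait_id for r in refs) == sorted(TRAIT_IDS)
        assert len(refs) == 11

    @pytest.mark.parametrize(
        "trait_id,expected,margin",
        [
            ("pct_pos1", 14.9, 9.4),
            ("pct_pos2", 4.5, 3.5),
            ("pct_pos3", 80.6, 21.0),
            ("pct_nonsyn", 7.47, 5.4),
            ("pct_gc_to_gt_of_ct", 25.0, 14.0),
            ("pct_ts3", 84.9, 18.1),
            ("pct_tv3", 15.1, 7.6),
            ("gc_percent", 28.66, 10.5),
        ],
    )
    def test_interval_traits(self, trait_id, expected, margin):
        ref = {r.trait_id: r for r in default_reference()}[trait_id]
        assert (ref.expected, ref.margin) == (expected, margin)

    @pytest.mark.parametrize("trait_id", ["insertions", "deletions", "extra_stops"])
    def test_zero_traits(self, trait_id):
        ref = {r.trait_id: r for r in default_reference()}[trait_id]
        assert ref.require_zero


class TestComputeTraits:
    def test_published_count_percentages(self):
        t = compute_traits(published_coi_counts())
        assert t["pct_pos1"] == pytest.approx(12.0)
        assert t["pct_pos2"] == pytest.approx(1.6)
        assert t["pct_pos3"] == pytest.approx(86.4)
        assert t["pct_nonsyn"] == pytest.approx(10.4)
        assert t["pct_gc_to_gt_of_ct"] == pytest.approx(12.0)
        assert t["pct_ts3"] == pytest.approx(100 * 95 / 108)
        assert t["pct_tv3"] == pytest.approx(100 * 13 / 108)
        assert t["ts_tv_ratio"] == pytest.approx(110 / 15)  # ~7.33

    def test_position_percentages_sum_to_100(self):
        t = compute_traits(published_coi_counts())
        assert t["pct_pos1"] + t["pct_pos2"] + t["pct_pos3"] == pytest.approx(100, abs=0.15)
        assert t["pct_ts3"] + t["pct_tv3"] == pytest.approx(100, abs=0.15)

    def test_all_zero_counts_not_evaluable(self):
        t = compute_traits(SubstitutionCounts(gc_percent=30.0))
        for key in ("pct_pos1", "pct_pos2", "pct_pos3", "pct_nonsyn",
                    "pct_gc_to_gt_of_ct", "pct_ts3", "pct_tv3", "ts_tv_ratio"):
            assert t[key] is None

    def test_no_transversions_gives_infinite_ratio(self):
        c = SubstitutionCounts(total=2, pos3=2, ts3=2, ts_all=2, gc_percent=30.0)
        assert compute_traits(c)["ts_tv_ratio"] == math.inf


class TestEvaluate:
    def test_published_observations_pass_all_eleven(self):
        counts = published_coi_counts()
        report = evaluate(compute_traits(counts), counts=counts)
        assert report.verdict == "PASS"
        assert report.failing_traits == []
        assert sum(r.passed for r in report.results) == 11

    def test_excess_nonsynonymous_flags(self):
        t = compute_traits(published_coi_counts())
        t["pct_nonsyn"] = 50.0
        report = evaluate(t)
        assert report.verdict == "FLAG"
        assert report.failing_traits == ["pct_nonsyn"]

    def test_any_insertion_flags(self):
        t = compute_traits(published_coi_counts())
        t["insertions"] = 2.0
        report = evaluate(t)
        assert report.verdict == "FLAG" and "insertions" in report.failing_traits

    def test_not_evaluable_passes_with_annotation(self):
        c = SubstitutionCounts(
            total=2, pos3=2, ts3=2, ts_all=2, gc_percent=30.0, n_haplotypes=2
        )
        report = evaluate(compute_traits(c))
        gc_gt = {r.trait_id: r for r in report.results}["pct_gc_to_gt_of_ct"]
        assert gc_gt.passed and not gc_gt.evaluable

    def test_relaxed_mode_tolerates_failures(self):
        t = compute_traits(published_coi_counts())
        t["pct_nonsyn"] = 50.0
        assert evaluate(t, relaxed_k=10).verdict == "PASS"

    def test_missing_trait_is_configuration_error(self):
        t = compute_traits(published_coi_counts())
        del t["pct_pos1"]
        with pytest.raises(ValueError):
            evaluate(t)

    def test_incomplete_reference_set_rejected(self):
        refs = default_reference()[:-1]
        with pytest.raises(ValueError, match="gc_percent"):
            evaluate(compute_traits(published_coi_counts()), references=refs)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(0, 30), st.integers(0, 10))
    def test_widening_margins_never_breaks_a_pass(self, extra, idx):
        counts = published_coi_counts()
        traits = compute_traits(counts)
        refs = default_reference()
        before = evaluate(traits, references=refs)
        widened = [
            r if i != idx or r.require_zero
            else TraitReference(r.trait_id, r.expected, r.margin + extra, source=r.source)
            for i, r in enumerate(refs)
        ]
        after = evaluate(traits, references=widened)
        for b, a in zip(before.results, after.results):
            assert not (b.passed and not a.passed)

    def test_custom_reference_file_round_trip(self, tmp_path):
        p = tmp_path / "ref.yaml"
        p.write_text(
            "\n".join(
                [
                    "pct_pos1: {expected: 10, margin: 5}",
                    "pct_pos2: {expected: 5, margin: 5}",
                    "pct_pos3: {expected: 85, margin: 15}",
                    "pct_nonsyn: {expected: 8, margin: 6}",
                    "pct_gc_to_gt_of_ct: {expected: 25, margin: 15}",
                    "insertions: zero",
                    "deletions: zero",
                    "extra_stops: zero",
                    "pct_ts3: {expected: 85, margin: 15}",
                    "pct_tv3: {expected: 15, margin: 10}",
                    "gc_percent: {expected: 30, margin: 12}",
                ]
            )
        )
        refs = load_reference(p)
        assert len(refs) == 11
        assert {r.trait_id: r for r in refs}["insertions"].require_zero


class TestProportionCI:
    def test_boundaries(self):
        assert proportion_ci(0, 20)[0] == 0.0
        assert proportion_ci(20, 20)[1] == 100.0

    def test_half_of_hundred(self):
        low, high = proportion_ci(50, 100, 0.05)
        assert low == pytest.approx(40.38, abs=0.05)
        assert high == pytest.approx(59.62, abs=0.05)

    @pytest.mark.parametrize("x,n", [(3, 25), (13, 125), (95, 108), (1, 7), (49, 50)])
    def test_matches_independent_wilson_implementation(self, x, n):
        low, high = proportion_ci(x, n, 0.05)
        ref_low, ref_high = proportion_confint(x, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(100 * ref_low, abs=1e-6)
        assert high == pytest.approx(100 * ref_high, abs=1e-6)

    def test_width_shrinks_with_n(self):
        widths = []
        for n in (20, 80, 320, 1280):
            low, high = proportion_ci(n // 4, n, 0.05)
            widths.append(high - low)
        assert widths == sorted(widths, reverse=True)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)
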