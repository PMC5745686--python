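"""Coverage ratios, aggregation, hygiene categories, device comparisons."""

import numpy as np
import pytest

from fluoroplaque.datasets import example_device_cohort
from fluoroplaque.metrics import (
    aggregate_coverage,
    classify_hygiene,
    comparison_report,
    coverage_ratio,
    coverage_report,
    device_delta,
    summarize_cohort,
)


class TestCoverageRatio:
    @pytest.mark.parametrize(
        "n_plaque,n_tooth,expected",
        [(0, 1000, 0.0), (1000, 0, 1.0), (50, 150, 0.25)],
    )
    def test_ratio_definition(self, n_plaque, n_tooth, expected):
        assert coverage_ratio(n_plaque, n_tooth).ratio == expected

    def test_no_visible_tooth_is_undefined(self):
        res = coverage_ratio(0, 0)
        assert res.ratio is None and res.category is None and not res.defined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            coverage_ratio(-1, 10)

    def test_scale_invariance(self, rng):
        """Upsampling an image by any integer factor leaves the ratio fixed."""
        for _ in range(20):
            p, t = int(rng.integers(0, 500)), int(rng.integers(1, 500))
            k = int(rng.integers(2, 10))
            assert coverage_ratio(k * p, k * t).ratio == pytest.approx(
                coverage_ratio(p, t).ratio, abs=1e-15
            )


class TestClassifyHygiene:
    @pytest.mark.parametrize(
        "ratio,category",
        [
            (0.0, "excellent"),
            (0.049, "excellent"),
            (0.05, "fair"),      # 0.05 assigned to fair by convention
            (0.10, "fair"),
            (0.15, "fair"),      # poor is strictly above 0.15
            (0.1501, "poor"),
            (0.2, "poor"),
            (1.0, "poor"),
        ],
    )
    def test_baseline_partition(self, ratio, category):
        assert classify_hygiene(ratio) == category

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                classify_hygiene(bad)

    def test_category_never_improves_as_ratio_grows(self):
        rank = {"excellent": 0, "fair": 1, "poor": 2}
        grid = np.linspace(0, 1, 501)
        ranks = [rank[classify_hygiene(r)] for r in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestAggregateCoverage:
    def test_singleton_aggregate_is_that_ratio(self):
        r = coverage_ratio(30, 70)
        agg = aggregate_coverage([r], "S1")
        assert agg.aggregate_ratio == r.ratio

    def test_pooled_pixel_arithmetic(self):
        rs = [coverage_ratio(10, 90), coverage_ratio(30, 70)]
        assert aggregate_coverage(rs).aggregate_ratio == pytest.approx(40 / 200)

    def test_identical_ratios_agree_across_both_modes(self):
        rs = [coverage_ratio(10, 90), coverage_ratio(20, 180)]
        pooled = aggregate_coverage(rs, method="pooled").aggregate_ratio
        mean = aggregate_coverage(rs, method="mean").aggregate_ratio
        assert pooled == pytest.approx(0.1) and mean == pytest.approx(0.1)

    def test_pooled_equals_pixel_weighted_mean(self, rng):
        """Algebraic identity between pooling and tooth-area weighting."""
        for _ in range(50):
            counts = [
                (int(rng.integers(0, 1000)), int(rng.integers(1, 1000)))
                for _ in range(int(rng.integers(1, 10)))
            ]
            rs = [coverage_ratio(p, t) for p, t in counts]
            pooled = aggregate_coverage(rs).aggregate_ratio
            weights = np.array([p + t for p, t in counts], dtype=float)
            ratios = np.array([r.ratio for r in rs])
            assert pooled == pytest.approx(np.average(ratios, weights=weights), abs=1e-12)

    def test_aggregate_stays_within_per_image_range(self, rng):
        rs = [
            coverage_ratio(int(rng.integers(0, 100)), int(rng.integers(1, 100)))
            for _ in range(6)
        ]
        agg = aggregate_coverage(rs).aggregate_ratio
        ratios = [r.ratio for r in rs]
        assert min(ratios) <= agg <= max(ratios)

    def test_empty_and_undefined_inputs(self):
        with pytest.raises(ValueError):
            aggregate_coverage([])
        agg = aggregate_coverage([coverage_ratio(0, 0)])
        assert agg.aggregate_ratio is None and agg.category is None


class TestDeviceDelta:
    def test_published_cohort_deltas(self):
        expected = {
            "M2": 0.2267,
            "M3": 0.3457,
            "M18": 0.1856,
            "M24": 0.4770,
            "M100": 0.2933,
        }
        for row in example_device_cohort().itertuples(index=False):
            comp = device_delta(row.ref_ratio, row.pf_ratio, row.subject_id)
            assert comp.delta == expected[row.subject_id]

    def test_antisymmetry(self, rng):
        for _ in range(25):
            a, b = rng.uniform(0, 1, size=2)
            assert device_delta(a, b).delta == pytest.approx(-device_delta(b, a).delta)

    def test_identical_ratios_give_zero(self):
        assert device_delta(0.3, 0.3).delta == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            device_delta(1.2, 0.1)


class TestSummarizeCohort:
    def test_published_rows_are_all_positive(self):
        comps = [
            device_delta(r.ref_ratio, r.pf_ratio, r.subject_id)
            for r in example_device_cohort().itertuples(index=False)
        ]
        summary = summarize_cohort(comps)
        assert summary.n_subjects == 5
        assert summary.n_positive_delta == 5
        assert summary.n_negative_delta == 0 and summary.n_ties == 0

    def test_tie_is_its_own_bucket(self):
        summary = summarize_cohort([device_delta(0.2, 0.2, "T")])
        assert (summary.n_positive_delta, summary.n_negative_delta, summary.n_ties) == (0, 0, 1)

    def test_signs_match_construction(self, rng):
        signs = rng.choice([-1, 0, 1], size=30)
        comps = [
            device_delta(0.5 + 0.1 * s, 0.5, str(i)) for i, s in enumerate(signs)
        ]
        summary = summarize_cohort(comps)
        assert summary.n_positive_delta == int((signs > 0).sum())
        assert summary.n_negative_delta == int((signs < 0).sum())
        assert summary.n_ties == int((signs == 0).sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])


class TestReports:
    def test_coverage_report_schema(self):
        df = coverage_report([coverage_ratio(10, 90, "img1.png")], subject_ids=["S1"])
        assert list(df.columns) == [
            "image_id", "subject_id", "mode", "n_plaque", "n_tooth", "ratio", "category",
        ]
        assert df.loc[0, "ratio"] == 0.1 and df.loc[0, "category"] == "fair"

    def test_comparison_report_schema(self):
        df = comparison_report([device_delta(0.4, 0.1, "S1")])
        assert list(df.columns) == ["subject_id", "ref_ratio", "pf_ratio", "delta"]
        assert df.loc[0, "delta"] == 0.3
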