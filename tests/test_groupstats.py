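"""Stratum comparisons (KS, Mann-Whitney) and qualitative bin summaries."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuzzyord import (
    IEDSample,
    QualitativeResponse,
    SEVERITY,
    compare_all_levels,
    ied_sample,
    ks_compare,
    mw_compare,
    qualitative_bin_summary,
)
from fuzzyord.groupstats import DegenerateSampleError, bin_summaries_frame
from tests.conftest import make_interval


def sample(values, level="Mild", stratum="doctor"):
    return IEDSample(level=level, stratum=stratum, values=np.asarray(values, float))


class TestKS:
    def test_identical_samples_give_zero_statistic(self):
        a = sample([1, 5, 30, 70])
        b = sample([1, 5, 30, 70], stratum="patient")
        d, p = ks_compare(a, b)
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_give_one(self):
        d, _ = ks_compare(sample([1, 2, 3]), sample([90, 91, 92], stratum="patient"))
        assert d == 1.0

    def test_hand_computed_ecdf_gap(self):
        d, _ = ks_compare(sample([1, 2]), sample([1, 3], stratum="patient"))
        assert d == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 100), min_size=1, max_size=12),
        b=st.lists(st.integers(0, 100), min_size=1, max_size=12),
    )
    def test_matches_brute_force_ecdf_scan(self, a, b):
        d, _ = ks_compare(sample(a), sample(b, stratum="patient"))
        av, bv = np.asarray(a, float), np.asarray(b, float)
        gaps = [
            abs(np.mean(av <= x) - np.mean(bv <= x)) for x in np.concatenate([av, bv])
        ]
        assert d == pytest.approx(max(gaps), abs=1e-12)
        assert 0.0 <= d <= 1.0


class TestMW:
    def test_complete_separation_gives_zero_u(self):
        u, _ = mw_compare(sample([1, 2]), sample([3, 4], stratum="patient"))
        assert u == 0.0

    def test_identical_samples_give_half_n_squared(self):
        u, _ = mw_compare(sample([1, 2, 3]), sample([1, 2, 3], stratum="patient"))
        assert u == pytest.approx(9 / 2)

    def test_matches_pairwise_count_oracle(self):
        # a={1,3}, b={2,4}: 3 of 4 pairs have a<b, so U(a>b)=1, U'(a<b)=3
        u, _ = mw_compare(sample([1, 3]), sample([2, 4], stratum="patient"))
        assert u == 1.0

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 100), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 100), min_size=1, max_size=6),
    )
    def test_complement_identity_and_exhaustive_oracle(self, a, b):
        """U(a over b) from exhaustive pair counting; U + U' = n_a * n_b."""
        u, _ = mw_compare(sample(a), sample(b, stratum="patient"))
        wins = sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x, y in itertools.product(a, b)
        )
        assert u == pytest.approx(wins, abs=1e-9)
        u2, _ = mw_compare(sample(b), sample(a, stratum="patient"))
        assert u + u2 == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sample([])


class TestIEDExtraction:
    def test_extremes_pool_both_endpoints(self):
        rs = [make_interval("Mild", 10, 30, rid="a"), make_interval("Mild", 20, 40, rid="b")]
        s = ied_sample(rs, "Mild", "doctor", "extremes")
        assert sorted(s.values) == [10, 20, 30, 40]

    def test_centroids_and_rps(self):
        rs = [make_interval("Mild", 10, 31, rp=25), make_interval("Mild", 20, 40, rid="b")]
        assert sorted(ied_sample(rs, "Mild", "doctor", "centroids").values) == [21, 30]
        assert list(ied_sample(rs, "Mild", "doctor", "rps").values) == [25]

    def test_missing_stratum_level_raises(self):
        rs = [make_interval("Mild", 10, 30)]
        with pytest.raises(DegenerateSampleError):
            ied_sample(rs, "Severe", "doctor", "extremes")


class TestCompareAllLevels:
    def _survey(self, shift=0):
        rs = []
        rng = np.random.default_rng(0)
        for stratum in ("doctor", "patient"):
            for level, center in zip(SEVERITY, (10, 30, 50, 70, 90)):
                for i in range(12):
                    c = center + (shift if stratum == "patient" else 0)
                    lo = int(np.clip(c - 5 + rng.integers(-3, 4), 0, 100))
                    hi = int(np.clip(c + 5 + rng.integers(-3, 4), 0, 100))
                    rs.append(
                        make_interval(level, min(lo, hi), max(lo, hi), rid=f"{stratum}{i}",
                                      stratum=stratum)
                    )
        return rs

    def test_one_row_per_level_with_expected_columns(self):
        df = compare_all_levels(self._survey(), source="extremes")
        assert list(df.index) == list(SEVERITY)
        assert set(df.columns) == {"ks_stat", "ks_p", "mw_u", "mw_p", "n_a", "n_b"}
        assert (df["n_a"] == 24).all()  # 12 respondents x 2 endpoints

    def test_missing_level_in_one_stratum_is_named(self):
        rs = self._survey()
        rs = [r for r in rs if not (r.level == "Severe" and r.stratum == "patient")]
        with pytest.raises(ValueError, match="Severe"):
            compare_all_levels(rs)

    def test_large_shift_detected(self):
        df = compare_all_levels(self._survey(shift=25), source="centroids")
        assert (df["mw_p"] < 0.01).all()


class TestQualitativeBins:
    @staticmethod
    def _responses(pairs):
        return [
            QualitativeResponse(f"q{i}", value, level)
            for i, (value, level) in enumerate(pairs)
        ]

    def test_full_range_granularity_3_gives_33_bins(self):
        responses = self._responses((v, "Mild") for v in range(1, 100))
        bins = qualitative_bin_summary(responses, granularity=3)
        assert len(bins) == 33
        assert bins[0].bin_lo == 1 and bins[-1].bin_hi == 99

    def test_majority_without_statistical_significance(self):
        # 6 vs 4: mode share 0.6 > 0.5 but chi2 = 0.4, p ~ 0.527
        responses = self._responses([(2, "Mild")] * 6 + [(2, "Moderate")] * 4)
        (b,) = qualitative_bin_summary(responses, granularity=3)
        assert b.mode_level == "Mild"
        assert b.prevalence_class == "majority"
        assert b.p_value == pytest.approx(0.527, abs=0.001)

    def test_unanimous_bin_is_statistical_majority(self):
        # 10 vs 0: chi2 = 10, p ~ 0.0016
        responses = self._responses([(50, "Severe")] * 10)
        (b,) = qualitative_bin_summary(responses, granularity=3)
        assert b.prevalence_class == "statistical_majority"
        assert b.p_value == pytest.approx(0.00157, abs=0.0001)

    def test_mode_tie_breaks_to_lower_scale_rank(self):
        responses = self._responses([(10, "Severe")] * 3 + [(10, "Mild")] * 3)
        (b,) = qualitative_bin_summary(responses, granularity=3)
        assert b.mode_level == "Mild"
        assert b.prevalence_class == "superiority"

    def test_empty_bins_omitted_and_counts_partition(self):
        responses = self._responses([(1, "Absent")] * 4 + [(99, "Extreme")] * 5)
        bins = qualitative_bin_summary(responses, granularity=3)
        assert len(bins) == 2
        assert sum(b.total for b in bins) == 9

    @settings(max_examples=50, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.sampled_from(SEVERITY.levels), st.integers(1, 20), min_size=1, max_size=5
        )
    )
    def test_prevalence_class_is_monotone(self, counts):
        """statistical_majority => majority => superiority on fuzzed counts."""
        pairs = [(5, level) for level, c in counts.items() for _ in range(c)]
        (b,) = qualitative_bin_summary(self._responses(pairs), granularity=3)
        total = sum(counts.values())
        top = max(counts.values())
        if b.prevalence_class == "statistical_majority":
            assert top / total > 0.5 and b.p_value < 0.05
        if b.prevalence_class in ("statistical_majority", "majority"):
            assert top / total > 0.5
        assert counts[b.mode_level] == top

    def test_frame_view_has_one_row_per_bin(self):
        responses = self._responses([(1, "Absent")] * 4 + [(50, "Moderate")] * 2)
        bins = qualitative_bin_summary(responses, granularity=3)
        df = bin_summaries_frame(bins)
        assert len(df) == 2
        assert df["n_Absent"].sum() == 4
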