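"""Welch inference, SD separation, and radius unit conversion."""

import numpy as np
import pytest
from scipy import stats as sps

from lungnet.cohort_stats import (
    CohortRecord,
    rd_metric_mm,
    sd_separation,
    t_critical,
    welch_from_samples,
    welch_from_summaries,
    welch_metric_test,
)
from lungnet.degree_analysis import NetworkMetrics
from lungnet.errors import (
    DomainError,
    InsufficientDataError,
    UndefinedStatisticError,
)


class TestWelch:
    def test_equal_means_give_zero_t(self):
        w = welch_from_summaries(5, 2, 10, 5, 7, 12)
        assert w.t_stat == 0

    def test_hand_computed_case(self):
        # equal variances and sizes reduce Welch df to n1 + n2 - 2
        w = welch_from_summaries(10, 4, 30, 8, 4, 30)
        assert w.t_stat == pytest.approx(3.8730, abs=1e-4)
        assert w.df == 58
        assert w.df_exact == pytest.approx(58)

    def test_df_floor_for_reporting(self):
        w = welch_from_summaries(10, 4, 30, 8, 9, 20)
        assert w.df == int(np.floor(w.df_exact))

    def test_antisymmetric_in_group_order(self):
        w1 = welch_from_summaries(10, 4, 30, 8, 9, 20)
        w2 = welch_from_summaries(8, 9, 20, 10, 4, 30)
        assert w1.t_stat == pytest.approx(-w2.t_stat)
        assert w1.p_two_tail == pytest.approx(w2.p_two_tail)

    def test_both_zero_variances_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            welch_from_summaries(1, 0, 5, 2, 0, 5)

    def test_small_groups_rejected(self):
        with pytest.raises(InsufficientDataError):
            welch_from_summaries(1, 1, 1, 2, 1, 5)

    def test_agrees_with_scipy_on_seeded_cohorts(self):
        """Independent cross-check against scipy's Welch implementation."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           rng.integers(5, 40))
            b = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3),
                           rng.integers(5, 40))
            w = welch_from_samples(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert abs(w.t_stat - ref.statistic) <= 1e-10
            assert w.p_two_tail == pytest.approx(ref.pvalue, rel=1e-9)

    def test_summaries_match_raw_computation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a = rng.normal(0, 1, 12)
            b = rng.normal(1, 2, 9)
            w1 = welch_from_samples(a, b)
            w2 = welch_from_summaries(a.mean(), a.var(ddof=1), a.size,
                                      b.mean(), b.var(ddof=1), b.size)
            assert abs(w1.t_stat - w2.t_stat) <= 1e-10


class TestTCritical:
    @pytest.mark.parametrize(
        "df,tails,expected",
        [
            (82, 1, 1.663649),
            (82, 2, 1.989319),
            (64, 1, 1.669013),
            (64, 2, 1.99773),
            (92, 1, 1.661585),
            (92, 2, 1.986086),
        ],
    )
    def test_printed_critical_values(self, df, tails, expected):
        assert t_critical(df, 0.05, tails) == pytest.approx(expected, abs=5e-7)

    def test_normal_limit(self):
        assert t_critical(1e9, 0.05, 2) == pytest.approx(1.959964, abs=1e-6)

    def test_strictly_decreasing_in_df(self):
        vals = [t_critical(df, 0.05, 2) for df in range(2, 200)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            t_critical(0, 0.05, 2)
        with pytest.raises(DomainError):
            t_critical(10, 1.5, 2)
        with pytest.raises(DomainError):
            t_critical(10, 0.05, 3)


def _records(dild_vals, normal_vals, band="ggo"):
    recs = []
    for i, v in enumerate(dild_vals):
        recs.append(CohortRecord(f"D{i}", "dild", band,
                                 NetworkMetrics(int(v), float(v), int(v))))
    for i, v in enumerate(normal_vals):
        recs.append(CohortRecord(f"N{i}", "normal", band,
                                 NetworkMetrics(int(v), float(v), int(v))))
    return recs


class TestSdSeparation:
    def test_equal_sds_split_fifty_fifty(self):
        recs = _records([0, 2, 4], [10, 12, 14])
        _, _, rel_d, rel_n = sd_separation(recs, "total_count", band="ggo")
        assert (rel_d, rel_n) == (pytest.approx(50), pytest.approx(50))

    def test_three_to_one_ratio(self):
        recs = _records([0, 6], [0, 2])
        sd_d, sd_n, rel_d, rel_n = sd_separation(recs, "total_count", band="ggo")
        assert sd_d == pytest.approx(3 * sd_n)
        assert (rel_d, rel_n) == (pytest.approx(75), pytest.approx(25))

    def test_constant_group_boundary(self):
        recs = _records([1, 5], [3, 3])
        _, _, rel_d, rel_n = sd_separation(recs, "total_count", band="ggo")
        assert (rel_d, rel_n) == (pytest.approx(100), pytest.approx(0))

    def test_insufficient_group(self):
        with pytest.raises(InsufficientDataError):
            sd_separation(_records([1], [2, 3]), "total_count", band="ggo")


def test_welch_metric_test_combines_bands_per_sample():
    recs = _records([10, 20, 30], [1, 2, 3], band="ggo")
    recs += _records([10, 20, 30], [1, 2, 3], band="consolidation")
    w = welch_metric_test(recs, "total_count", band=None)
    # total_count sums over bands: groups are (20,40,60) vs (2,4,6)
    assert w.mean1 == pytest.approx(40)
    assert w.mean2 == pytest.approx(4)


@pytest.mark.parametrize(
    "rd,spacing,expected",
    [(4, 0.74, 2.96), (1, 1.0, 1.0), (8, 0.74, 5.92)],
)
def test_rd_metric_mm(rd, spacing, expected):
    assert rd_metric_mm(rd, spacing) == pytest.approx(expected)


def test_rd_metric_mm_domain():
    with pytest.raises(DomainError):
        rd_metric_mm(0, 0.74)
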