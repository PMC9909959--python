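"""Normality gate, group comparison, and report shape."""

import numpy as np
import pytest
from scipy import stats as sps

from ctoam.densitometry import BTVProfile
from ctoam.stats import btv_report, compare_groups, ks_normal


class TestKsNormal:
    def test_normal_draws_pass_in_most_seeds(self):
        """Under the null the screen keeps >=95% of normal samples."""
        passed = sum(
            ks_normal(np.random.default_rng(seed).normal(5, 2, 1000)).is_normal
            for seed in range(40)
        )
        assert passed >= 38

    def test_uniform_draws_fail_for_typical_seeds(self):
        rejected = sum(
            not ks_normal(np.random.default_rng(seed).uniform(0, 1, 1000)).is_normal
            for seed in range(20)
        )
        assert rejected >= 18

    def test_statistic_nonnegative(self):
        res = ks_normal([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res.statistic >= 0

    def test_constant_sample_raises(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normal([3.0, 3.0, 3.0, 3.0])

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ks_normal([1.0, 2.0])


class TestCompareGroups:
    def test_identical_samples_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(a, a)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_hand_computed_pooled_t(self):
        """a={1..5}, b={2..6}: pooled t = -1 with 8 df."""
        res = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res.test_used == "student_t"
        # closed form: means 3 and 4, each s^2 = 2.5, pooled SE = 1
        expected_p = 2 * sps.t.sf(1.0, df=8)
        assert res.p_value == pytest.approx(expected_p, rel=1e-12)

    def test_nonnormal_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        skewed = rng.exponential(1.0, 500)
        normal = rng.normal(1.0, 0.3, 500)
        assert not ks_normal(skewed).is_normal  # precondition of the gate
        res = compare_groups(skewed, normal)
        assert res.test_used == "mann_whitney"

    def test_degenerate_equal_constants_flagged(self):
        res = compare_groups([2.0] * 5, [2.0] * 5)
        assert res.degenerate and res.p_value == 1.0 and not res.significant

    def test_distinct_constants_detected(self):
        res = compare_groups([0.0] * 8, [5.0] * 8)
        assert not res.degenerate
        assert res.significant

    def test_large_shift_significant_with_direction(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1, 15)
        b = rng.normal(7, 1, 15)
        res = compare_groups(a, b)
        assert res.significant
        assert res.group_means_sd[0][0] > res.group_means_sd[1][0]

    def test_type_i_error_roughly_nominal(self):
        """Null rejection rate near 5% (sample-level quick check)."""
        rng = np.random.default_rng(7)
        rejections = sum(
            compare_groups(rng.normal(0, 1, 15), rng.normal(0, 1, 15)).significant
            for _ in range(300)
        )
        assert 0.01 <= rejections / 300 <= 0.10

    def test_power_monotone_in_effect_size(self):
        """Rejection rate is nondecreasing over a 3-point effect sweep."""
        rates = []
        for shift in (0.0, 0.8, 1.6):
            rng = np.random.default_rng(11)
            hits = sum(
                compare_groups(rng.normal(shift, 1, 15), rng.normal(0, 1, 15)).significant
                for _ in range(200)
            )
            rates.append(hits / 200)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9

    def test_welch_option(self):
        res = compare_groups([1, 2, 3, 4, 5], [2, 3, 4, 5, 6], welch=True)
        assert res.test_used == "welch_t"


def _profile(volumes, bone="distal_femur", side="right"):
    return BTVProfile(volumes_mm3=np.asarray(volumes, float), bone=bone, side=side)


def _cohort(rng, n, bone="distal_femur", sides=("right", "left"), shift_bin=None, factor=1.0):
    base = np.array([900, 1500, 1300, 1000, 700, 400, 200, 100, 50, 25, 12, 6], float)
    out = []
    for side in sides:
        for _ in range(n):
            vols = base * rng.lognormal(0.0, 0.2, size=12)
            if shift_bin is not None:
                vols[shift_bin] *= factor
            out.append(_profile(vols, bone=bone, side=side))
    return out


class TestBtvReport:
    def test_identical_cohorts_nothing_significant(self):
        rng = np.random.default_rng(1)
        cohort = _cohort(rng, 15)
        report = btv_report(cohort, cohort)
        for df in report.between.values():
            assert not df["significant"].any()

    def test_twelve_rows_in_interval_order(self):
        rng = np.random.default_rng(2)
        report = btv_report(_cohort(rng, 5), _cohort(rng, 5))
        df = report.between["right"]
        assert len(df) == 12
        assert df["hu_range"].iloc[0] == "100-200"
        assert df["hu_range"].iloc[-1] == "1201-maximum"
        assert list(df["density_class"][:4]) == ["low"] * 4

    def test_mixed_bones_raise(self):
        rng = np.random.default_rng(3)
        a = _cohort(rng, 3, bone="distal_femur")
        b = _cohort(rng, 3, bone="tibial_plateau")
        with pytest.raises(ValueError, match="bones"):
            btv_report(a, b)

    def test_injected_single_bin_shift_is_flagged(self):
        """Tripling one small bin's volume flags that bin in nearly every
        seed while the (tiny) compositional spill rarely flags the rest."""
        hits, spill_hits = 0, 0
        n_seeds = 20
        shifted = 7  # 801-900, ~1.6% of the baseline composition
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            a = _cohort(rng, 15, sides=("right",), shift_bin=shifted, factor=3.0)
            b = _cohort(rng, 15, sides=("right",))
            df = btv_report(a, b).between["right"]
            if df["significant"].iloc[shifted]:
                hits += 1
            others = [i for i in range(12) if i != shifted]
            spill_hits += int(df["significant"].iloc[others].sum())
        assert hits >= 0.9 * n_seeds
        assert spill_hits <= 0.2 * 11 * n_seeds

    def test_within_group_left_right_contrast_present(self):
        rng = np.random.default_rng(5)
        report = btv_report(_cohort(rng, 8), _cohort(rng, 8))
        assert set(report.within) == {"judo", "control"}
        assert len(report.within["judo"]) == 12

    def test_paired_option(self):
        rng = np.random.default_rng(6)
        report = btv_report(_cohort(rng, 8), _cohort(rng, 8), paired=True)
        assert set(report.within["judo"]["test"]).issubset({"paired_t", "wilcoxon", "degenerate"})

    def test_correction_reduces_significance(self):
        rng = np.random.default_rng(8)
        a = _cohort(rng, 15, sides=("right",), shift_bin=4, factor=1.4)
        b = _cohort(rng, 15, sides=("right",))
        raw = btv_report(a, b).between["right"]
        adj = btv_report(a, b, correction="holm").between["right"]
        assert adj["p_value"].ge(raw["p_value"] - 1e-12).all()
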