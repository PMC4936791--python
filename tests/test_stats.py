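import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fourdose import (
    bonferroni_alpha,
    compare_arms,
    lilliefors,
    motion_regression,
    paired_t,
)
from fourdose.fourd import ARM_NAMES
from fourdose.stats_compare import _lilliefors_stat


def test_paired_t_hand_example():
    """Differences {1,2,3}: t = 2/(1/sqrt(3)) = 3.4641; p checked against an
    independent t-distribution evaluation."""
    t, p = paired_t(np.array([1.0, 2.0, 3.0]))
    assert abs(t - 3.4641016) < 1e-6
    assert abs(p - 2 * (1 - sps.t.cdf(3.4641016, df=2))) < 1e-8


def test_paired_t_matches_scipy_ttest_rel():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(3, 30))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        t, p = paired_t(a - b)
        ref = sps.ttest_rel(a, b)
        assert np.isclose(t, ref.statistic, atol=1e-10)
        assert np.isclose(p, ref.pvalue, atol=1e-12)


def test_paired_t_degenerate_and_symmetry():
    t, p = paired_t(np.zeros(5))
    assert np.isnan(t) and np.isnan(p)
    d = np.array([0.5, 1.5, -0.3, 2.0])
    t1, p1 = paired_t(d)
    t2, p2 = paired_t(-d)
    assert np.isclose(t1, -t2) and np.isclose(p1, p2)
    with pytest.raises(ValueError):
        paired_t(np.array([1.0]))


def test_lilliefors_statistic_affine_invariant():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    s1 = _lilliefors_stat(x)
    s2 = _lilliefors_stat(5.0 * x - 17.0)
    assert np.isclose(s1, s2, atol=1e-12)


def test_lilliefors_statistic_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.diagnostic")
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.normal(size=int(rng.integers(10, 60)))
        stat, _ = sm.lilliefors(x, dist="norm")
        assert np.isclose(_lilliefors_stat(x), stat, atol=1e-10)


def test_lilliefors_null_calibration():
    """Under the null the MC p-value is uniform: the median p over repeated
    normal samples is near 0.5."""
    rng = np.random.default_rng(3)
    ps = [lilliefors(rng.normal(size=500), n_mc=400, seed=s)[1] for s in range(40)]
    assert abs(np.median(ps) - 0.5) < 0.15


def test_lilliefors_power_against_exponential():
    rng = np.random.default_rng(4)
    rejections = sum(
        lilliefors(rng.exponential(size=50), n_mc=1000, seed=s)[1] < 0.05
        for s in range(40)
    )
    assert rejections >= 38  # >= 95% power


def test_lilliefors_small_n_rejected():
    with pytest.raises(ValueError):
        lilliefors(np.array([1.0, 2.0, 3.0]))


def test_bonferroni_values():
    assert bonferroni_alpha(0.05, 4) == 0.0125
    assert bonferroni_alpha(0.07, 1) == 0.07
    assert bonferroni_alpha(0.05, 10) == 0.005
    assert bonferroni_alpha(0.05, 4) * 4 == 0.05
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def _endpoint_table(n_cases, offset_skin_15t=0.0, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cases):
        base = {
            "gtv_d98": 56 + rng.normal(0, noise),
            "skin_d2": 9 + rng.normal(0, noise),
            "lung_mean": 5 + rng.normal(0, noise),
            "integral_energy_j": 30 + rng.normal(0, noise),
        }
        for arm in ARM_NAMES:
            row = {"case": c, "arm": arm}
            for k, v in base.items():
                row[k] = v + rng.normal(0, noise)
            if arm.endswith("1.5T"):
                row["skin_d2"] += offset_skin_15t
            rows.append(row)
    return pd.DataFrame(rows)


def test_compare_arms_identical_arms_nothing_significant():
    df = _endpoint_table(8, noise=0.0)
    # all arms identical per case -> degenerate differences, none significant
    report = compare_arms(df, seed=0)
    assert not any(c.significant for c in report.comparisons)
    assert all(c.degenerate for c in report.comparisons)


def test_compare_arms_detects_injected_skin_offset():
    """A +2 Gy skin-D2 offset at 1.5 T across 9 cases is flagged significant
    at the Bonferroni level 0.0125."""
    df = _endpoint_table(9, offset_skin_15t=2.0, noise=0.3, seed=5)
    report = compare_arms(df, seed=0)
    c = report.get("skin_d2", "conventional: 1.5T - 0T")
    assert c.primary and c.alpha_applied == 0.0125
    assert c.p_value < 0.0125 and c.significant
    # cross-check the t-test on the same differences
    t, p = paired_t(c.differences)
    assert np.isclose(p, c.p_value)


def test_compare_arms_primary_alpha_is_00125_and_exploratory_005():
    df = _endpoint_table(6, seed=6)
    df["extra_metric"] = np.random.default_rng(1).normal(size=len(df))
    report = compare_arms(df, seed=0)
    for c in report.comparisons:
        assert c.alpha_applied == (0.0125 if c.primary else 0.05)
    assert {c.contrast for c in report.comparisons} == {
        "conventional: 1.5T - 0T", "tracked: 1.5T - 0T",
        "0T: tracked - conventional", "1.5T: tracked - conventional",
    }


def test_compare_arms_invariant_to_case_order():
    df = _endpoint_table(7, offset_skin_15t=1.0, seed=7)
    shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
    r1 = compare_arms(df, seed=0)
    r2 = compare_arms(shuffled, seed=0)
    f1 = r1.to_frame().sort_values(["endpoint", "contrast"]).reset_index(drop=True)
    f2 = r2.to_frame().sort_values(["endpoint", "contrast"]).reset_index(drop=True)
    pd.testing.assert_frame_equal(f1, f2)


def test_compare_arms_missing_arm_rejected():
    df = _endpoint_table(4)
    with pytest.raises(KeyError):
        compare_arms(df[df.arm != "track_0T"], seed=0)


def test_compare_arms_type_one_error_calibration():
    """Null cohorts: the paired t rejects at the Bonferroni level about
    1.25% of the time."""
    rng = np.random.default_rng(8)
    n_sim, n = 600, 9
    rej = sum(paired_t(rng.normal(size=n))[1] < 0.0125 for _ in range(n_sim))
    rate = rej / n_sim
    se = np.sqrt(0.0125 * (1 - 0.0125) / n_sim)
    assert abs(rate - 0.0125) < 4 * se + 1e-9


def test_motion_regression_collinear():
    r = motion_regression(np.array([1, 2, 3, 4.0]), np.array([-2, -4, -6, -8.0]))
    assert np.isclose(r.slope, -2.0) and np.isclose(r.intercept, 0.0)
    assert np.isclose(r.r, -1.0)


def test_motion_regression_matches_normal_equations():
    x = np.array([1.0, 3.0, 4.0, 7.0, 9.0])
    y = np.array([2.0, 1.5, 3.0, 4.5, 6.0])
    r = motion_regression(x, y)
    n = x.size
    slope = (n * np.sum(x * y) - x.sum() * y.sum()) / (n * np.sum(x**2) - x.sum() ** 2)
    intercept = y.mean() - slope * x.mean()
    pearson = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert np.isclose(r.slope, slope)
    assert np.isclose(r.intercept, intercept)
    assert np.isclose(r.r, pearson)


def test_motion_regression_constructed_negative_correlation():
    rng = np.random.default_rng(9)
    motion = rng.uniform(1.5, 14.1, size=9)
    benefit = -0.1 * motion + rng.normal(0, 0.05, size=9)
    r = motion_regression(motion, benefit)
    assert r.r < -0.8


def test_motion_regression_errors():
    with pytest.raises(ValueError):
        motion_regression(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        motion_regression(np.ones(5), np.arange(5.0))


def test_report_summary_renders(tmp_path):
    df = _endpoint_table(5, offset_skin_15t=1.5, seed=10)
    report = compare_arms(df, seed=0)
    report.regressions.append(
        motion_regression(np.array([2.0, 5, 8, 11, 14]),
                          np.array([-0.1, -0.4, -0.9, -1.2, -1.5]), "lung_mean")
    )
    text = report.summary()
    assert "skin_d2" in text and "Pearson r" in text
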