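"""Fit statistics, scaling, overall statistic and the sensitivity harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from alauda.params import INTEGER_PARAMETERS, SkylarkParams
from alauda.pom import (
    RunnerError,
    SIX_STATISTICS,
    density_series_fit,
    fit_scan,
    load_annual_pairs,
    overall_fit,
    perturbation_values,
    regression_origin,
    scaled_r2_fit,
    scaled_slope_fit,
    sensitivity_scan,
    ssd_distribution_fit,
)


# ------------------------------------------------------------- regression

def test_identity_data_gives_unit_slope_and_r2():
    b, r2 = regression_origin([1, 2, 3], [1, 2, 3])
    assert b == 1.0 and r2 == 1.0


def test_exact_proportionality():
    b, r2 = regression_origin([1, 2, 3], [2, 4, 6])
    assert b == 2.0 and r2 == pytest.approx(1.0)


def test_regression_matches_brute_force_least_squares():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 3.0, 7.0])
    b, r2 = regression_origin(x, y)
    assert b == pytest.approx(29 / 14)
    # independent oracle: minimise SS_err over the slope numerically
    res = minimize_scalar(lambda s: ((y - s * x) ** 2).sum(), bounds=(-10, 10),
                          method="bounded")
    assert b == pytest.approx(res.x, abs=1e-6)
    ss_err = ((y - b * x) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert r2 == pytest.approx(1 - ss_err / ss_tot)


def test_regression_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(200):
        n = int(rng.integers(2, 12))
        x = rng.normal(0, 3, n)
        if np.allclose(x, 0):
            continue
        y = rng.normal(0, 3, n)
        b, _r2 = regression_origin(x, y)
        res = minimize_scalar(lambda s: ((y - s * x) ** 2).sum(),
                              bounds=(-100, 100), method="bounded")
        assert b == pytest.approx(res.x, abs=1e-6)


def test_all_zero_x_is_an_error():
    with pytest.raises(ValueError):
        regression_origin([0, 0, 0], [1, 2, 3])


def test_r2_can_be_negative_for_poor_through_origin_fits():
    _b, r2 = regression_origin([1.0, 2.0, 3.0], [5.0, -1.0, 4.0])
    assert r2 < 1.0


# ------------------------------------------------------------- SSD fits

def test_identical_distributions_score_zero():
    p = np.array([0.2, 0.5, 0.3])
    assert ssd_distribution_fit(p, p) == (0.0, 0.0)


def test_disjoint_point_masses_reach_the_scale_maximum():
    p = np.zeros(11)
    q = np.zeros(11)
    p[0] = 1.0
    q[-1] = 1.0
    raw, scaled = ssd_distribution_fit(p, q)
    assert raw == 2.0 and scaled == 1.0


def test_small_mass_shift_raw_ssd():
    p = np.array([0.5, 0.5, 0.0])
    q = np.array([0.4, 0.6, 0.0])
    raw, _ = ssd_distribution_fit(p, q)
    assert raw == pytest.approx(0.02)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=13),
       st.lists(st.floats(0, 1), min_size=2, max_size=13))
def test_ssd_symmetric_and_zero_iff_equal(p, q):
    n = min(len(p), len(q))
    p, q = np.array(p[:n]), np.array(q[:n])
    ab = ssd_distribution_fit(p, q)
    ba = ssd_distribution_fit(q, p)
    assert ab == ba
    if np.array_equal(p, q):
        assert ab[0] == 0.0
    elif ab[0] == 0.0:
        assert np.allclose(p, q)


def test_mismatched_bins_rejected():
    with pytest.raises(ValueError):
        ssd_distribution_fit([0.5, 0.5], [1.0])


# ------------------------------------------------------------- series fit

def test_perfect_series_scores_zero():
    assert density_series_fit([5, 5], [5, 5]) == 0.0


def test_extinct_population_scores_one():
    assert density_series_fit([5, 5], [0, 0]) == 1.0


def test_series_arithmetic():
    assert density_series_fit([5, 5], [4, 6]) == pytest.approx(2 / 50)


def test_overshoot_clamped_to_one():
    assert density_series_fit([1, 1], [10, 10]) == 1.0


def test_all_zero_observed_is_an_error():
    with pytest.raises(ValueError):
        density_series_fit([0, 0], [1, 1])


# ------------------------------------------------------------- scaled stats

def test_perfect_slope_scores_zero():
    assert scaled_slope_fit(1.0, 1.0) == 0.0


def test_best_observed_r2_scores_zero():
    assert scaled_r2_fit(0.8, 0.8) == 0.0


def test_slope_scaling_arithmetic():
    assert scaled_slope_fit(0.5, 1.0) == 0.5
    assert scaled_slope_fit(3.0, 1.0) == 1.0  # clamped


def test_non_positive_m_rejected():
    with pytest.raises(ValueError):
        scaled_slope_fit(1.0, 0.0)
    with pytest.raises(ValueError):
        scaled_r2_fit(0.5, -1.0)


# ------------------------------------------------------------- overall fit

def _stats(values):
    return dict(zip(SIX_STATISTICS, values))


def test_constant_statistics_are_weight_invariant():
    for s in [0.0, 0.3, 1.0]:
        assert overall_fit(_stats([s] * 6)) == pytest.approx(s)


def test_double_weighting_of_sets_one_and_two():
    stats = _stats([0, 0, 0, 0, 1, 1])
    assert overall_fit(stats) == pytest.approx((2 * 0 + 2 * 0 + 1 * 1) / 5)


def test_unweighted_fallback_is_the_plain_mean():
    stats = _stats([0, 0, 0, 0, 1, 1])
    assert overall_fit(stats, weights=(1, 1, 1)) == pytest.approx(1 / 3)


def test_overall_zero_iff_all_six_zero():
    assert overall_fit(_stats([0] * 6)) == 0.0
    stats = _stats([0, 0, 0, 0, 0, 0.1])
    assert overall_fit(stats) > 0


def test_out_of_range_statistic_rejected():
    with pytest.raises(ValueError):
        overall_fit(_stats([0, 0, 0, 0, 0, 1.5]))


# ------------------------------------------------------------- pattern data

def test_packaged_scrape_counts_average_to_the_published_mean():
    df = load_annual_pairs()
    assert sorted(df["pairs"]) == [8, 13, 17, 17]
    assert df["pairs"].mean() == pytest.approx(13.75)


# ------------------------------------------------------------- sensitivity

def test_integer_parameter_perturbation_grid():
    assert perturbation_values("NEST_MORT_PROB", 23) == [15, 19, 21, 22, 24, 25, 27, 31]
    assert "NEST_MORT_PROB" in INTEGER_PARAMETERS


def test_continuous_parameter_perturbation_grid():
    vals = perturbation_values("EGGTEMP", 36.1)
    expect = [36.1 * f for f in (0.6, 0.8, 0.9, 0.95, 1.05, 1.1, 1.2, 1.4)]
    assert vals == pytest.approx(expect)


def _fake_runner(sensitive_to="EGGTEMP"):
    base = SkylarkParams()

    def runner(params: SkylarkParams) -> dict:
        delta = abs(getattr(params, sensitive_to) - getattr(base, sensitive_to))
        s = min(1.0, delta / getattr(base, sensitive_to))
        return _stats([s, s, s, s, s, s])

    return runner


def test_runner_ignored_parameter_is_classified_insensitive():
    table = sensitivity_scan(_fake_runner("EGGTEMP"), SkylarkParams(),
                             ["HQTALL", "EGGTEMP"])
    by_param = table.groupby("parameter")
    assert by_param["deviation"].max()["HQTALL"] == 0.0
    assert bool(by_param["insensitive"].first()["HQTALL"])
    # EGGTEMP at +-40% moves the fake statistic by 0.4 > 0.1
    assert not bool(by_param["insensitive"].first()["EGGTEMP"])


def test_scan_records_eight_runs_per_parameter():
    table = sensitivity_scan(_fake_runner(), SkylarkParams(), ["EGGTEMP", "HQTALL"])
    assert table.groupby("parameter").size().tolist() == [8, 8]
    assert set(SIX_STATISTICS) <= set(table.columns)


def test_runner_failure_names_the_parameter():
    def broken(params):
        if params.EGGTEMP != SkylarkParams().EGGTEMP:
            raise RuntimeError("boom")
        return _stats([0] * 6)

    with pytest.raises(RunnerError, match="EGGTEMP"):
        sensitivity_scan(broken, SkylarkParams(), ["EGGTEMP"])


def test_fit_scan_ranks_by_overall():
    runner = _fake_runner("EGGTEMP")
    table = fit_scan(runner, SkylarkParams(), {"EGGTEMP": [36.1, 30.0, 40.0]})
    assert table.iloc[0]["EGGTEMP"] == 36.1
    assert table["overall"].is_monotonic_increasing
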