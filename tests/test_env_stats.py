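"""OLS driver fits, the light-limitation ratio and the seasonal comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aquaveg import (
    EnvRecord,
    EnvSeriesSpec,
    flag_light_limitation,
    generate_env_series,
    linear_fit,
    seasonal_compare,
    zm_zsd_ratio,
)


def test_exact_line_recovered():
    x = np.arange(5, dtype=float)
    fit = linear_fit(x, 2 * x + 1)
    assert fit.slope == pytest.approx(2.0)
    assert fit.intercept == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)


def test_constant_y_gives_zero_slope_and_r2():
    fit = linear_fit([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])
    assert fit.slope == pytest.approx(0.0)
    assert fit.r_squared == pytest.approx(0.0, abs=1e-12)


def test_noisy_slope_within_three_standard_errors(rng):
    a, b, sigma = 1.0, -3.0, 0.5
    x = rng.uniform(0, 2, size=200)
    y = a + b * x + rng.normal(0, sigma, size=200)
    fit = linear_fit(x, y)
    assert abs(fit.slope - b) < 3 * fit.stderr
    assert fit.p_value < 1e-6


def test_fit_errors():
    with pytest.raises(ValueError, match="at least 3"):
        linear_fit([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError, match="constant"):
        linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_scaling_x_equivariance(rng):
    x = rng.uniform(0, 1, size=50)
    y = 0.3 - 2.0 * x + rng.normal(0, 0.1, size=50)
    f1, f10 = linear_fit(x, y), linear_fit(10 * x, y)
    assert f10.slope == pytest.approx(f1.slope / 10)
    assert f10.r_squared == pytest.approx(f1.r_squared)
    assert f10.p_value == pytest.approx(f1.p_value)


def test_r2_equals_squared_correlation(rng):
    x = rng.uniform(0, 1, size=40)
    y = 1 - x + rng.normal(0, 0.2, size=40)
    fit = linear_fit(x, y)
    assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


def test_slope_ci_contains_estimate():
    x = np.arange(10, dtype=float)
    fit = linear_fit(x, 0.5 * x + np.sin(x))
    lo, hi = fit.slope_ci()
    assert lo < fit.slope < hi


def test_zm_zsd_ratio_values():
    assert zm_zsd_ratio(2.0, 0.5) == pytest.approx(4.0)
    assert zm_zsd_ratio(1.3, 1.3) == pytest.approx(1.0)
    # summer Secchi 35 cm against ~1.96 m depth -> ratio 5.6
    assert zm_zsd_ratio(1.96, 0.35) == pytest.approx(5.6)
    rec = EnvRecord(date="2020-07-15", season="summer", TP=0.05, TN=1.0,
                    Z_M=2.0, Z_SD=0.5)
    assert zm_zsd_ratio(rec) == pytest.approx(4.0)
    with pytest.raises(ValueError, match="Secchi"):
        zm_zsd_ratio(2.0, 0.0)


def test_light_limitation_flag_strict_at_threshold():
    assert flag_light_limitation(5.2, 5.17)
    assert not flag_light_limitation(5.17, 5.17)
    assert not flag_light_limitation(1.0)
    # monotone in the ratio
    assert not flag_light_limitation(5.0) and flag_light_limitation(6.0)


def test_env_record_rejects_negative_concentrations():
    with pytest.raises(ValueError, match="TP"):
        EnvRecord(date="2020-04-15", season="spring", TP=-0.1, TN=1.0,
                  Z_M=2.0, Z_SD=0.5)


def _season_frame(rng, means, n=30):
    rows = []
    for season, mu in means.items():
        for v in rng.normal(mu, 1.0, size=n):
            rows.append({"season": season, "TP": v})
    return pd.DataFrame(rows)


def test_seasonal_compare_null_shares_letter(rng):
    df = _season_frame(rng, {"spring": 10.0, "summer": 10.0}, n=80)
    out = seasonal_compare(df, "TP")
    letters = dict(zip(out["season"], out["letters"]))
    assert set(letters["spring"]) & set(letters["summer"])


def test_seasonal_compare_separated_groups_get_distinct_letters(rng):
    df = _season_frame(rng, {"spring": 0.0, "summer": 10.0}, n=30)
    out = seasonal_compare(df, "TP")
    letters = dict(zip(out["season"], out["letters"]))
    assert not (set(letters["spring"]) & set(letters["summer"]))


def test_seasonal_compare_three_group_pattern(rng):
    # spring well below the two indistinguishable high seasons
    df = _season_frame(rng, {"spring": 0.0, "summer": 10.0, "autumn": 10.1}, n=40)
    out = seasonal_compare(df, "TP")
    letters = dict(zip(out["season"], out["letters"]))
    assert not (set(letters["spring"]) & set(letters["summer"]))
    assert set(letters["summer"]) & set(letters["autumn"])


def test_seasonal_compare_single_group_no_letters(rng):
    df = _season_frame(rng, {"spring": 1.0}, n=10)
    out = seasonal_compare(df, "TP")
    assert len(out) == 1 and out["letters"].iloc[0] == ""
    assert out["n"].iloc[0] == 10


def test_seasonal_compare_type_one_error_rate():
    # identical distributions: rejection (distinct letters) should be rare
    rejections = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        df = _season_frame(r, {"a": 5.0, "b": 5.0}, n=25)
        out = seasonal_compare(df, "TP", group="season")
        letters = dict(zip(out["season"], out["letters"]))
        if not (set(letters["a"]) & set(letters["b"])):
            rejections += 1
    assert rejections / 100 <= 0.10  # nominal 0.05


def test_generated_series_noiseless_relation_is_exact():
    env, cov, truth = generate_env_series(
        EnvSeriesSpec(n_dates=20, coverage_noise_sd=0.0, seed=5)
    )
    fit = linear_fit(env["TP"].to_numpy(), cov["sav_coverage"].to_numpy())
    assert fit.slope == pytest.approx(truth["slope"])
    assert fit.intercept == pytest.approx(truth["intercept"])
    assert fit.r_squared == pytest.approx(1.0)


def test_parameter_recovery_ci_coverage():
    # 95% CI for the slope should cover the truth in >= 90% of simulations
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        env, cov, truth = generate_env_series(
            EnvSeriesSpec(n_dates=50, slope=-5.0, coverage_noise_sd=0.05, seed=seed)
        )
        fit = linear_fit(env["TP"].to_numpy(), cov["sav_coverage"].to_numpy())
        lo, hi = fit.slope_ci(0.95)
        hits += lo <= truth["slope"] <= hi
    assert hits / n_rep >= 0.90


def test_null_slope_rejection_rate_near_alpha():
    rejections = 0
    n_rep = 200
    for seed in range(n_rep):
        env, cov, _ = generate_env_series(
            EnvSeriesSpec(n_dates=50, slope=0.0, coverage_noise_sd=0.05,
                          seed=10_000 + seed)
        )
        fit = linear_fit(env["TP"].to_numpy(), cov["sav_coverage"].to_numpy())
        rejections += fit.p_value < 0.05
    assert 0.02 <= rejections / n_rep <= 0.09


def test_negative_tp_slope_power():
    negatives = 0
    n_rep = 50
    for seed in range(n_rep):
        env, cov, _ = generate_env_series(
            EnvSeriesSpec(n_dates=50, slope=-5.0, coverage_noise_sd=0.05,
                          seed=20_000 + seed)
        )
        fit = linear_fit(env["TP"].to_numpy(), cov["sav_coverage"].to_numpy())
        negatives += fit.slope < 0
    assert negatives / n_rep >= 0.95
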